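"""NCCC template matching with the box-spline Gaussian approximation.

The similarity between an image and a radially symmetric template of
half-width ``a`` inside an engulfing cubic window of half-size ``b`` is the
normalized cross-correlation coefficient (NCCC): the windowed, mean-subtracted,
variance-normalized inner product, ranging over [-1, 1].  With the order-n
box-spline template, every term of the NCCC reduces to finite differences of
prefix-sum volumes, so one radius costs O(N) and a full sweep over
``a = 1..a_max`` costs O(a_max * N).

Discrete NCCC at voxel X for half-width a:

    num(X)   = V_b * (f * h^(n))(X) - W_b{f}(X)
    den1(X)  = sqrt(V_b * W_b{f^2}(X) - W_b{f}(X)^2)
    den2     = sqrt(V_b * E1(a, n)^D - 1)
    NCCC(X)  = num / (den1 * den2)

where ``V_b = (2b+1)^D`` is the window volume, ``W_b`` the window sum, and
``E1`` the 1-D kernel energy (sum of squared taps).  Voxels whose local image
variance is degenerate carry the sentinel score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boxconv import (PrefixStack, cumulative_stack, kernel_energy,
                      window_sum, windowed_difference)

__all__ = ["TemplateConfig", "NCCCResult", "ScanStacks", "prepare_stacks",
           "nccc_fixed_radius", "nccc_maximized", "max_radius"]

#: relative threshold under which the local image variance counts as zero
VARIANCE_EPS = 1e-12

GAUSSIAN = "gaussian"


@dataclass(frozen=True)
class TemplateConfig:
    """Template-matching parameters.

    Parameters
    ----------
    n : convolution order (int >= 1), or the string ``"gaussian"`` for the
        truncated-Gaussian FFT baseline.
    b : engulfing half-size of the statistics window; the window is the cube
        of ``(2b+1)^D`` voxels.
    a_max : largest box half-width tried in a sweep.  Admissibility requires
        ``0 < a_max < b / n`` so the spline support fits inside the window.
    b_prime : half-size of the local-statistics window of the O(N) engine
        (only used there); must be < b.
    """

    n: int | str = 2
    b: int = 18
    a_max: int = 8
    b_prime: int | None = None

    def __post_init__(self) -> None:
        if self.b < 1:
            raise ValueError(f"b must be positive, got {self.b}")
        if self.a_max < 1:
            raise ValueError(f"a_max must be >= 1, got {self.a_max}")
        n_eff = 1 if self.n == GAUSSIAN else self.n
        if not isinstance(n_eff, int) or n_eff < 1:
            raise ValueError(f"n must be an integer >= 1 or 'gaussian', got {self.n!r}")
        if not self.a_max < self.b / n_eff:
            raise ValueError(
                f"inadmissible template: need 0 < a_max < b/n, got "
                f"a_max={self.a_max}, b={self.b}, n={self.n}")
        if self.b_prime is not None and not self.b_prime < self.b:
            raise ValueError(f"b_prime must be < b, got {self.b_prime} >= {self.b}")


def max_radius(cfg: TemplateConfig) -> int:
    """Largest admissible integer half-width, the integer just below b/n."""
    n_eff = 1 if cfg.n == GAUSSIAN else cfg.n
    hi = int(np.ceil(cfg.b / n_eff)) - 1
    return max(hi, 1)


@dataclass
class NCCCResult:
    """Voxel-wise maximized NCCC map with the argmax template radius."""

    nccc: np.ndarray
    a_opt: np.ndarray
    config: TemplateConfig
    method_tag: str


@dataclass
class ScanStacks:
    """Prefix stacks reused across all radii of a sweep.

    ``sn`` is the order-n stack of f (margin fits the largest half-width);
    ``s1f`` and ``s1f2`` are order-1 stacks of f and f^2 used for the window
    sums of half-size b.  ``wb_f`` / ``wb_f2`` cache those window sums, which
    are radius-independent.
    """

    sn: PrefixStack
    wb_f: np.ndarray
    wb_f2: np.ndarray
    n: int
    b: int
    a_cap: int
    den1: np.ndarray = field(init=False)
    degenerate: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        D = self.wb_f.ndim
        vb = float((2 * self.b + 1) ** D)
        var = vb * self.wb_f2 - self.wb_f ** 2
        np.maximum(var, 0.0, out=var)
        self.degenerate = var <= VARIANCE_EPS * vb
        self.den1 = np.sqrt(var)
        self.den1[self.degenerate] = 1.0  # avoid 0/0; masked to sentinel later


def prepare_stacks(f: np.ndarray, cfg: TemplateConfig,
                   a_cap: int | None = None) -> ScanStacks:
    """Build all prefix-sum volumes needed by the scan/linear engines."""
    if cfg.n == GAUSSIAN:
        raise ValueError("prefix-sum engine requires an integer order n")
    f = np.asarray(f, dtype=np.float64)
    a_cap = cfg.a_max if a_cap is None else a_cap
    n = cfg.n
    sn = cumulative_stack(f, n, margin=n * a_cap + n)
    s1f = cumulative_stack(f, 1, margin=cfg.b + 1)
    s1f2 = cumulative_stack(f * f, 1, margin=cfg.b + 1)
    wb_f = window_sum(s1f, cfg.b)
    wb_f2 = window_sum(s1f2, cfg.b)
    return ScanStacks(sn=sn, wb_f=wb_f, wb_f2=wb_f2, n=n, b=cfg.b, a_cap=a_cap)


def _den2(a: int, n: int, b: int, D: int) -> float:
    """Template-variance factor sqrt(V_b * E1^D - 1) of the denominator."""
    vb = float((2 * b + 1) ** D)
    return float(np.sqrt(vb * kernel_energy(a, n) ** D - 1.0))


def nccc_fixed_radius(f: np.ndarray, a: int, cfg: TemplateConfig,
                      stacks: ScanStacks | None = None) -> np.ndarray:
    """NCCC map between ``f`` and the order-n template of half-width ``a``."""
    f = np.asarray(f, dtype=np.float64)
    n_eff = 1 if cfg.n == GAUSSIAN else cfg.n
    if not (1 <= a < cfg.b / n_eff):
        raise ValueError(f"inadmissible half-width a={a} for b={cfg.b}, n={cfg.n}")
    if stacks is None:
        stacks = prepare_stacks(f, cfg, a_cap=a)
    D = f.ndim
    vb = float((2 * cfg.b + 1) ** D)
    conv = windowed_difference(stacks.sn, a) / float((2 * a + 1) ** (stacks.n * D))
    num = vb * conv - stacks.wb_f
    out = num / (stacks.den1 * _den2(a, stacks.n, cfg.b, D))
    out[stacks.degenerate] = 0.0
    return out


def nccc_maximized(f: np.ndarray, cfg: TemplateConfig) -> NCCCResult:
    """Voxel-wise maximum NCCC over ``a = 1..a_max`` with the argmax radius.

    Only the running maximum and argmax volumes are retained besides the
    prefix stacks.  Ties keep the smaller radius (first writer wins).
    """
    f = np.asarray(f, dtype=np.float64)
    stacks = prepare_stacks(f, cfg)
    D = f.ndim
    vb = float((2 * cfg.b + 1) ** D)
    best = np.full(f.shape, -np.inf)
    a_opt = np.zeros(f.shape, dtype=np.int16)
    for a in range(1, cfg.a_max + 1):
        conv = windowed_difference(stacks.sn, a) / float((2 * a + 1) ** (stacks.n * D))
        score = (vb * conv - stacks.wb_f) / (stacks.den1 * _den2(a, stacks.n, cfg.b, D))
        improved = score > best
        best[improved] = score[improved]
        a_opt[improved] = a
    best[stacks.degenerate] = 0.0
    a_opt[stacks.degenerate] = 1
    return NCCCResult(nccc=best, a_opt=a_opt, config=cfg, method_tag="scan")
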