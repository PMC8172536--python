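"""Linear-time local image statistics for analytic radius selection.

The O(N) engine models the neighborhood of every voxel as a Gaussian bump on
a flat background and needs two local descriptors of the smoothed image
``f_s`` inside the cube of half-size ``b'``:

* ``mu(X)`` — the weighted centroid offset (vector, voxels) of the
  background-subtracted intensity, i.e. where the local bright mass sits
  relative to the voxel;
* ``sigma(X)`` — a scalar spread (voxels): the square root of 1/D of the
  trace of the weighted second-moment matrix about the centroid.

The background is the moving minimum of the smoothed image over the same
window, subtracted so that a bump on a bright plateau is measured against the
plateau, not against zero.  All window sums are prefix-sum differences, so the
whole pass is O(N) regardless of the window size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .boxconv import cumulative_stack, window_sum

__all__ = ["LocalStats", "gaussian_smooth", "moving_min", "local_mean",
           "local_sd", "compute_local_stats"]

#: window-relative threshold below which the weight mass counts as empty
DENOM_EPS = 1e-12


@dataclass
class LocalStats:
    """Per-voxel centroid offset and spread of the smoothed image."""

    mu: np.ndarray          # shape (D, *grid); units voxels
    sigma: np.ndarray       # shape grid; units voxels
    f_s: np.ndarray
    f_bg: np.ndarray
    window_half: int

    @property
    def mu_norm(self) -> np.ndarray:
        return np.sqrt(np.sum(self.mu ** 2, axis=0))


def gaussian_smooth(f: np.ndarray, sd: float, window_half: int) -> np.ndarray:
    """Separable truncated-Gaussian smoothing with zero padding.

    The 1-D kernel has ``2 * window_half + 1`` taps and is renormalized to
    sum 1 after truncation.
    """
    if sd <= 0:
        raise ValueError(f"smoothing SD must be positive, got {sd}")
    f = np.asarray(f, dtype=np.float64)
    k = np.arange(-window_half, window_half + 1, dtype=np.float64)
    taps = np.exp(-(k * k) / (2.0 * sd * sd))
    taps /= taps.sum()
    out = f
    for axis in range(f.ndim):
        out = ndimage.correlate1d(out, taps, axis=axis, mode="constant", cval=0.0)
    return out


def moving_min(f_s: np.ndarray, window_half: int) -> np.ndarray:
    """Per-voxel minimum over the cubic window, separably per axis.

    At the boundary the window is truncated to the volume (no padding value is
    ever the minimum), which avoids fabricating a zero background inside
    tissue near the edges.
    """
    f_s = np.asarray(f_s)
    w = 2 * window_half + 1
    if any(w > s for s in f_s.shape):
        raise ValueError(f"window {w} does not fit in volume of shape {f_s.shape}")
    # 'nearest' replication only repeats values already inside the truncated
    # window, so the result equals the truncated-window minimum
    return ndimage.minimum_filter(f_s, size=w, mode="nearest")


class _MomentSums:
    """Window sums of f_s and its coordinate-weighted variants (prefix sums)."""

    def __init__(self, f_s: np.ndarray, b_prime: int):
        f_s = np.asarray(f_s, dtype=np.float64)
        self.b = b_prime
        m = b_prime + 1
        D = f_s.ndim
        grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in f_s.shape],
                            indexing="ij", sparse=True)
        self.w_f = window_sum(cumulative_stack(f_s, 1, m), b_prime)
        self.w_uf = [window_sum(cumulative_stack(g * f_s, 1, m), b_prime)
                     for g in grids]
        r2 = sum((g * g for g in grids), start=np.zeros(()))
        self.w_u2f = window_sum(cumulative_stack(r2 * f_s, 1, m), b_prime)
        self.coords = grids
        self.D = D
        self.vol = float((2 * b_prime + 1) ** D)


def _denominator(sums: _MomentSums, f_bg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    den = sums.w_f - sums.vol * np.asarray(f_bg, dtype=np.float64)
    safe = den > DENOM_EPS * sums.vol
    return den, safe


def local_mean(f_s: np.ndarray, f_bg: np.ndarray, b_prime: int,
               _sums: _MomentSums | None = None) -> np.ndarray:
    """Centroid offset mu(X) of the background-subtracted smoothed image.

    Returns an array of shape ``(D, *grid)``.  The background term of the
    numerator vanishes exactly by the symmetry of the window, so only the
    window sums of ``f_s`` and of the coordinate-weighted ``u * f_s`` enter.
    Voxels with a degenerate weight mass get the sentinel mu = 0.
    """
    sums = _sums if _sums is not None else _MomentSums(f_s, b_prime)
    den, safe = _denominator(sums, f_bg)
    mu = np.zeros((sums.D,) + sums.w_f.shape)
    for j in range(sums.D):
        num = sums.w_uf[j] - sums.coords[j] * sums.w_f
        np.divide(num, den, out=mu[j], where=safe)
    return mu


def local_sd(f_s: np.ndarray, f_bg: np.ndarray, mu: np.ndarray, b_prime: int,
             _sums: _MomentSums | None = None) -> np.ndarray:
    """Scalar spread sigma(X): sqrt of 1/D of the weighted second moment
    about the centroid.

    The weighted mean of ``||X'||^2`` expands into window sums of
    ``||u||^2 f_s``, ``u f_s`` and ``f_s`` plus the closed-form second moment
    of the background over the cube; negative round-off is clamped to zero
    before the root.  Degenerate voxels get the sentinel sigma = 0.
    """
    sums = _sums if _sums is not None else _MomentSums(f_s, b_prime)
    den, safe = _denominator(sums, f_bg)
    b = sums.b
    # sum of ||X'||^2 over the centered cube, per unit background weight
    bg_r2 = sums.vol * sums.D * b * (b + 1) / 3.0
    num = sums.w_u2f.copy()
    r2c = np.zeros(sums.w_f.shape)
    for j in range(sums.D):
        num -= 2.0 * sums.coords[j] * sums.w_uf[j]
        r2c += sums.coords[j] ** 2
    num += r2c * sums.w_f
    num -= np.asarray(f_bg, dtype=np.float64) * bg_r2
    mean_r2 = np.zeros(sums.w_f.shape)
    np.divide(num, den, out=mean_r2, where=safe)
    mu_norm2 = np.sum(np.asarray(mu) ** 2, axis=0)
    var = (mean_r2 - mu_norm2) / sums.D
    np.maximum(var, 0.0, out=var)
    sigma = np.sqrt(var)
    sigma[~safe] = 0.0
    return sigma


def compute_local_stats(f: np.ndarray, b_prime: int, smooth_sd: float = 2.0,
                        presmoothed: bool = False) -> LocalStats:
    """Full local-statistics pass: smooth, background, centroid, spread.

    Smoothing, moving minimum and the moment windows all share the same
    ``(2 b' + 1)^D`` window.  ``smooth_sd`` defaults to 2 voxels.
    """
    f_s = np.asarray(f, dtype=np.float64) if presmoothed else \
        gaussian_smooth(f, smooth_sd, b_prime)
    f_bg = moving_min(f_s, b_prime)
    sums = _MomentSums(f_s, b_prime)
    mu = local_mean(f_s, f_bg, b_prime, _sums=sums)
    sigma = local_sd(f_s, f_bg, mu, b_prime, _sums=sums)
    return LocalStats(mu=mu, sigma=sigma, f_s=f_s, f_bg=f_bg, window_half=b_prime)
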