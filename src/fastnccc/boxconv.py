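"""Repeated-box (B-spline) convolution via order-n prefix sums.

A uniform box kernel convolved with itself ``n - 1`` times approximates a
Gaussian (central limit theorem).  Because the order-n kernel is a piecewise
polynomial, convolving an image with it reduces to a fixed, radius-independent
number of signed samples of the order-n running sum of the image.  The running
sums are computed once and reused for every kernel half-width ``a``, which is
what makes a whole sweep of template radii cost O(a_max * N) instead of
O(a_max * N * kernel_size).

Discretization convention
-------------------------
The discrete box kernel of half-width ``a`` is the odd-width uniform kernel
with ``2a + 1`` taps of value ``1 / (2a + 1)``.  With half-open prefix sums
``S[x] = sum_{t <= x} f[t]``, the width-(2a+1) window sum is
``S[x + a] - S[x - a - 1]``, so the n-fold box convolution becomes an n-fold
finite difference of the order-n prefix sum:

    (f * h^(n))[x] = (2a+1)^{-n} * sum_{j=0}^{n} (-1)^j C(n, j)
                     S_n[x + a*n - j*(2a+1)]

The signed binomial coefficients are exactly the non-zero entries of the
gamma table below; the lattice offsets ``a*k - (n-k)/2`` are the half-open
calibration of the continuous offsets ``a*k``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial

import numpy as np

__all__ = [
    "GammaTable",
    "PrefixStack",
    "BoxKernel1D",
    "gamma_coefficients",
    "cumulative_stack",
    "box_convolve",
    "box_kernel_1d",
    "kernel_energy",
    "beta_n",
    "window_sum",
]


@dataclass(frozen=True)
class GammaTable:
    """Signed integer coefficients of the closed-form repeated-box convolution.

    ``coeffs[k + order]`` holds gamma_{n,k} for k = -n..n.  Entries with
    ``n + k`` odd are zero; the rest are alternating-sign binomials (a signed
    Pascal's triangle).
    """

    order: int
    coeffs: np.ndarray

    def __getitem__(self, k: int) -> int:
        if abs(k) > self.order:
            return 0
        return int(self.coeffs[k + self.order])


def gamma_coefficients(n: int) -> GammaTable:
    """Coefficients gamma_{n,k}, k = -n..n, via the closed form.

    gamma_{n,k} = (-1)^(n+s) C(n, s) when n + k = 2s, and 0 otherwise.
    Satisfies the recursion gamma_{n+1,k} = gamma_{n,k-1} - gamma_{n,k+1}
    with base case gamma_{0,0} = 1.
    """
    if n < 0:
        raise ValueError(f"order must be non-negative, got {n}")
    coeffs = np.zeros(2 * n + 1, dtype=np.int64)
    for k in range(-n, n + 1):
        if (n + k) % 2 == 0:
            s = (n + k) // 2
            coeffs[k + n] = (-1) ** (n + s) * comb(n, s)
    return GammaTable(order=n, coeffs=coeffs)


@dataclass(frozen=True)
class PrefixStack:
    """Order-n running sums of a volume, applied along every axis.

    ``data`` is the padded cumulative volume: the base volume is embedded in a
    zero margin of ``margin`` voxels on each side of every axis, and the
    running sum is applied ``order`` times along each axis in turn.  The zero
    margin lets the finite-difference closed form sample the prefix sums of
    the implicit zero-padded extension of the image.
    """

    order: int
    margin: int
    base_shape: tuple[int, ...]
    data: np.ndarray


def cumulative_stack(base: np.ndarray, n: int, margin: int = 0) -> PrefixStack:
    """Order-n cumulative sum of ``base`` along every axis (n passes per axis).

    Parameters
    ----------
    base : finite-valued volume (any dimension).
    n : number of cumulative-sum passes per axis, >= 1.
    margin : zero padding added on each side of every axis before summation.
    """
    base = np.asarray(base)
    if n < 1:
        raise ValueError(f"stack order must be >= 1, got {n}")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    if not np.all(np.isfinite(base)):
        raise ValueError("input volume contains non-finite values")
    if margin:
        data = np.zeros(tuple(s + 2 * margin for s in base.shape), dtype=np.float64)
        data[tuple(slice(margin, margin + s) for s in base.shape)] = base
    else:
        data = base.astype(np.float64, copy=True)
    for axis in range(base.ndim):
        for _ in range(n):
            np.cumsum(data, axis=axis, out=data)
    return PrefixStack(order=n, margin=margin, base_shape=base.shape, data=data)


def _diff_axis(data: np.ndarray, axis: int, out_len: int, margin: int,
               offsets: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """gamma-weighted sum of shifted slices along one axis.

    ``data`` carries a margin of ``margin`` voxels on ``axis``; the result has
    length ``out_len`` on that axis (margins on other axes untouched).
    """
    out = None
    for off, c in zip(offsets, coeffs):
        sl = [slice(None)] * data.ndim
        start = margin + int(off)
        sl[axis] = slice(start, start + out_len)
        term = data[tuple(sl)]
        out = c * term if out is None else out + c * term
    return out


def _difference_offsets(a: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Lattice offsets and signed coefficients of the n-fold window difference.

    Offset j (j = 0..n) sits at ``a*n - j*(2a+1)`` with coefficient
    ``(-1)^j C(n, j)`` — the non-zero gamma entries on the half-open lattice.
    """
    j = np.arange(n + 1)
    offsets = a * n - j * (2 * a + 1)
    coeffs = np.array([(-1) ** jj * comb(n, jj) for jj in j], dtype=np.float64)
    return offsets, coeffs


def windowed_difference(stack: PrefixStack, a: int) -> np.ndarray:
    """Un-normalized n-fold box convolution from a prefix stack.

    Returns ``(2a+1)^{n*D} * (f * h^(n))`` on the original grid, i.e. the
    n-fold sliding-window sum, separably along each axis.
    """
    n = stack.order
    m = stack.margin
    if m < n * a + n:
        raise ValueError(
            f"stack margin {m} too small for half-width {a} at order {n}; "
            f"need at least {n * a + n}")
    offsets, coeffs = _difference_offsets(a, n)
    data = stack.data
    for axis in range(data.ndim):
        data = _diff_axis(data, axis, stack.base_shape[axis], m, offsets, coeffs)
    return data


def window_sum(stack: PrefixStack, w: int) -> np.ndarray:
    """Sliding-window sum over the cube of half-size ``w`` (order-1 stack)."""
    if stack.order != 1:
        raise ValueError("window_sum requires an order-1 stack")
    return windowed_difference(stack, w)


@dataclass(frozen=True)
class BoxKernel1D:
    """Explicit taps of the order-n 1-D box-spline kernel (oracle object)."""

    half_width: int
    order: int
    taps: np.ndarray


def box_kernel_1d(a: int, n: int) -> BoxKernel1D:
    """Discrete order-n kernel: the (2a+1)-tap uniform kernel self-convolved
    n-1 times.  Taps are non-negative, symmetric, and sum to 1."""
    if a < 1:
        raise ValueError(f"half-width must be >= 1, got {a}")
    if n < 1:
        raise ValueError(f"order must be >= 1, got {n}")
    box = np.full(2 * a + 1, 1.0 / (2 * a + 1))
    taps = box
    for _ in range(n - 1):
        taps = np.convolve(taps, box)
    return BoxKernel1D(half_width=a, order=n, taps=taps)


def box_convolve(f: np.ndarray, a: int, n: int,
                 stack: PrefixStack | None = None) -> np.ndarray:
    """Separable order-n box convolution of ``f`` with half-width ``a``.

    Out-of-volume samples are treated as zero.  Equals direct convolution with
    the explicit :func:`box_kernel_1d` taps applied along each axis.
    """
    f = np.asarray(f)
    if a < 1:
        raise ValueError(f"half-width must be >= 1, got {a}")
    if n < 1:
        raise ValueError(f"order must be >= 1, got {n}")
    if 2 * n * a + 1 > min(f.shape):
        raise ValueError(
            f"kernel support {2 * n * a + 1} exceeds smallest volume extent "
            f"{min(f.shape)}")
    if stack is None:
        stack = cumulative_stack(f, n, margin=n * a + n)
    else:
        if stack.order != n:
            raise ValueError(
                f"stack order {stack.order} does not match requested order {n}")
        if stack.base_shape != f.shape:
            raise ValueError("stack was built from a volume of different shape")
    raw = windowed_difference(stack, a)
    return raw / float((2 * a + 1) ** (n * f.ndim))


def kernel_energy(a: int, n: int) -> float:
    """Sum of squared taps of the 1-D order-n kernel.

    This is the exact discrete counterpart of ``beta_n / a``: the energy of
    the unit-mass spline kernel, which enters the template-variance factor of
    the NCCC denominator (raised to the power D).
    """
    return float(np.sum(box_kernel_1d(a, n).taps ** 2))


def beta_n(n: int) -> float:
    """Energy of the order-n unit-width spline, (1/2pi) int sinc^{2n}.

    Closed form: n * sum_{i=0}^{n-1} (-1)^i (n-i)^{2n-1} / (i! (2n-i)!).
    The discrete ``kernel_energy(a, n)`` approaches ``beta_n(n) / a`` for
    large ``a``.
    """
    if n < 1:
        raise ValueError(f"order must be >= 1, got {n}")
    total = 0.0
    for i in range(n):
        total += (-1) ** i * (n - i) ** (2 * n - 1) / (
            factorial(i) * factorial(2 * n - i))
    return n * total
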