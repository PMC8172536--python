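import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def direct_spline_nccc(f, a, b, n):
    """Brute-force windowed NCCC with the explicit discrete spline template.

    Independent of the prefix-sum path: builds the dense template on the
    window lattice and evaluates the mean-subtracted, variance-normalized
    inner product patch by patch (zero padding outside the volume).
    """
    from fastnccc.boxconv import box_kernel_1d

    D = f.ndim
    t1 = box_kernel_1d(a, n).taps
    half = n * a
    k = np.arange(-b, b + 1)
    prof = np.zeros(2 * b + 1)
    prof[(k >= -half) & (k <= half)] = t1
    return _direct_nccc_with_profile(f, prof, b)


def direct_gaussian_nccc(f, a, b):
    """Brute-force windowed NCCC with the truncated Gaussian template."""
    k = np.arange(-b, b + 1)
    prof = np.exp(-k ** 2 / (2.0 * a ** 2))
    return _direct_nccc_with_profile(f, prof, b)


def _direct_nccc_with_profile(f, prof, b):
    D = f.ndim
    tmpl = prof
    for _ in range(D - 1):
        tmpl = np.multiply.outer(tmpl, prof)
    t_c = tmpl - tmpl.mean()
    den2 = np.sqrt((t_c ** 2).sum())
    out = np.zeros(f.shape)
    fp = np.pad(f, b)
    for idx in np.ndindex(f.shape):
        patch = fp[tuple(slice(i, i + 2 * b + 1) for i in idx)]
        pc = patch - patch.mean()
        den1 = np.sqrt((pc ** 2).sum())
        if den1 * den2 < 1e-9:
            continue
        out[idx] = (pc * t_c).sum() / (den1 * den2)
    return out


def interior(shape, b):
    """Slices selecting voxels whose window never leaves the volume."""
    return tuple(slice(b, s - b) for s in shape)
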