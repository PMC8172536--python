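"""NIfTI volume I/O and intensity normalization."""

from __future__ import annotations



import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume", "minmax_normalize"]


def read_volume(path) -> tuple[np.ndarray, nib.Nifti1Image]:
    """Load a 3-D NIfTI volume as float64 plus the source image (affine and
    header are carried through untouched for round-tripping)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a single 3-D volume, got shape {img.shape}; "
            "split 4-D series before detection")
    return data.astype(np.float64), img


def write_volume(path, data: np.ndarray,
                 like: nib.Nifti1Image | None = None) -> None:
    """Write ``data`` as NIfTI, reusing the affine/header of ``like``."""
    affine = like.affine if like is not None else np.eye(4)
    header = like.header if like is not None else None
    img = nib.Nifti1Image(np.asarray(data), affine, header=header)
    nib.save(img, str(path))


def minmax_normalize(f: np.ndarray) -> np.ndarray:
    """Map intensities to [0, 1] by (f - min) / (max - min).

    NCCC is invariant under positive affine intensity maps, so this changes
    no score; it fixes the numeric scale so that the variance sentinel and
    the prefix-sum dynamic range behave predictably.
    """
    f = np.asarray(f, dtype=np.float64)
    lo = float(f.min())
    hi = float(f.max())
    if hi == lo:
        raise ValueError("constant volume cannot be min-max normalized")
    return (f - lo) / (hi - lo)
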