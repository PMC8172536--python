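"""Top-N detection with spherical suppression and TPF/FPF evaluation.

Instead of thresholding the NCCC map, the detector keeps the ``N_top``
highest-scoring voxels: repeatedly take the global maximum, record it, mask a
suppression sphere of twice the detected radius with -inf, and continue.
Detections are converted to binary label volumes (spheres of a calibrated
multiple of the detected radius) and compared against a manual annotation
with the true positive fraction (sensitivity over annotated voxels) and the
false positive fraction (fraction of detected voxels outside the annotation,
i.e. the false discovery rate), both in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scan import NCCCResult

__all__ = ["Detection", "top_n_detections", "detections_to_label",
           "tpf_fpf", "tpf_fpf_curve", "detections_to_frame"]


@dataclass(frozen=True)
class Detection:
    center: tuple[int, ...]
    radius_a: float
    score: float
    rank: int


def _ball_slices(center, radius, shape):
    """Bounding box and boolean closed-ball mask around ``center``."""
    lo = [max(0, int(np.floor(c - radius))) for c in center]
    hi = [min(s, int(np.ceil(c + radius)) + 1) for c, s in zip(center, shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return None, None
    grids = np.ogrid[tuple(slice(l, h) for l, h in zip(lo, hi))]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return tuple(slice(l, h) for l, h in zip(lo, hi)), dist2 <= radius * radius


def top_n_detections(result: NCCCResult, n_top: int,
                     suppression_factor: float = 2.0) -> list[Detection]:
    """Greedy maxima of the NCCC map with spherical suppression.

    Ties in the maximum resolve by lexicographic scan order of coordinates.
    Returns fewer than ``n_top`` detections if the map runs out of finite
    voxels.
    """
    if n_top < 1:
        raise ValueError(f"n_top must be >= 1, got {n_top}")
    work = np.array(result.nccc, dtype=np.float64, copy=True)
    a_opt = np.asarray(result.a_opt)
    out: list[Detection] = []
    for rank in range(1, n_top + 1):
        flat = int(np.argmax(work))
        center = np.unravel_index(flat, work.shape)
        score = float(work[center])
        if not np.isfinite(score):
            break
        radius_a = float(a_opt[center])
        out.append(Detection(center=tuple(int(c) for c in center),
                             radius_a=radius_a, score=score, rank=rank))
        box, ball = _ball_slices(center, suppression_factor * radius_a, work.shape)
        work[box][ball] = -np.inf
    return out


def detections_to_label(detections: list[Detection], k: int,
                        radius_multiplier: float,
                        grid_shape: tuple[int, ...]) -> np.ndarray:
    """Binary volume with closed-ball spheres at the first ``k`` detections.

    Sphere radius is ``radius_multiplier * radius_a``; overlapping spheres
    union without double counting; spheres are clipped to the grid.
    """
    if k > len(detections):
        raise ValueError(f"asked for {k} detections but only {len(detections)} given")
    label = np.zeros(grid_shape, dtype=bool)
    for det in detections[:k]:
        box, ball = _ball_slices(det.center, radius_multiplier * det.radius_a,
                                 grid_shape)
        if box is not None:
            label[box][ball] = True
    return label


def tpf_fpf(label_auto: np.ndarray, label_manual: np.ndarray) -> tuple[float, float]:
    """True positive fraction and false positive fraction, in percent.

    TPF = |A and M| / |M| * 100; FPF = |A and not M| / |A| * 100.  An empty
    automatic label yields FPF = 0 with a warning; an empty manual label is
    an error (TPF undefined).
    """
    la = np.asarray(label_auto).astype(bool)
    lm = np.asarray(label_manual).astype(bool)
    if la.shape != lm.shape:
        raise ValueError("label volumes must share a grid")
    n_m = int(lm.sum())
    if n_m == 0:
        raise ValueError("manual label volume is empty; TPF undefined")
    n_a = int(la.sum())
    tp = int((la & lm).sum())
    tpf = 100.0 * tp / n_m
    if n_a == 0:
        warnings.warn("automatic label volume is empty; reporting FPF = 0",
                      stacklevel=2)
        return tpf, 0.0
    fpf = 100.0 * (n_a - tp) / n_a
    return tpf, fpf


def tpf_fpf_curve(result: NCCCResult, label_manual: np.ndarray,
                  n_top_max: int, radius_multiplier: float,
                  suppression_factor: float = 2.0) -> pd.DataFrame:
    """TPF/FPF for cumulative detection counts N_top = 1..n_top_max.

    The label volume grows by one sphere per step (cumulative union), so TPF
    is non-decreasing in N_top.
    """
    dets = top_n_detections(result, n_top_max, suppression_factor)
    label = np.zeros(np.asarray(label_manual).shape, dtype=bool)
    rows = []
    for i, det in enumerate(dets, start=1):
        box, ball = _ball_slices(det.center, radius_multiplier * det.radius_a,
                                 label.shape)
        if box is not None:
            label[box][ball] = True
        t, f = tpf_fpf(label, label_manual)
        rows.append({"n_top": i, "tpf": t, "fpf": f})
    return pd.DataFrame(rows)


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    """Detections as a table (rank, x, y, z, a_opt, score); coordinates are
    0-based voxel indices in array order."""
    rows = []
    for det in detections:
        row = {"rank": det.rank}
        for name, c in zip("xyz", det.center):
            row[name] = c
        row.update(a_opt=det.radius_a, score=det.score)
        rows.append(row)
    return pd.DataFrame(rows)
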