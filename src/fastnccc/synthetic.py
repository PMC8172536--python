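"""Synthetic binary-sphere volumes and the calibration experiment.

The benchmark places one bright sphere (value 1 inside a closed ball, 0
outside) at a random admissible position in an otherwise empty volume.  Each
engine detects the sphere and reports a template radius; because the template
is (approximately) Gaussian while the target is a binary ball, the detected
radius is proportional — not equal — to the true radius.  A no-intercept
least-squares regression of true radius on detected radius measures that
proportionality constant, which is then used as the calibration multiplier
for converting detected template radii to lesion radii.

The default grid is 161^3: large enough to hold the engulfing margin b = 50
plus the largest sphere radius 21 on every side, while keeping a full
20-volume, three-engine run at desk scale.  The calibration ratio itself is
scale-free.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detect import top_n_detections
from .fftmatch import nccc_fft_maximized
from .localstats import compute_local_stats
from .radius import nccc_linear, optimal_radius
from .scan import TemplateConfig, nccc_maximized

__all__ = ["SphereSpec", "CalibrationResult", "make_sphere_volume",
           "sphere_specs", "calibration_experiment", "no_intercept_fit",
           "timing_harness", "SYNTH_CONFIG"]

#: template parameters of the synthetic calibration experiment
SYNTH_CONFIG = TemplateConfig(n=2, b=50, a_max=24, b_prime=24)

#: SD (voxels) of the Gaussian pre-smoothing used by the O(N) engine
SMOOTH_SD = 2.0


@dataclass(frozen=True)
class SphereSpec:
    grid_shape: tuple[int, int, int]
    center: tuple[int, int, int]
    radius: float
    seed: int = 0

    def __post_init__(self) -> None:
        margin = self.radius
        for c, s in zip(self.center, self.grid_shape):
            if c - margin < 0 or c + margin > s - 1:
                raise ValueError(
                    f"sphere of radius {self.radius} at {self.center} does "
                    f"not fit in grid {self.grid_shape}")


def make_sphere_volume(spec: SphereSpec) -> tuple[np.ndarray, np.ndarray]:
    """Binary volume with 1 inside the closed ball, plus the identical label."""
    grids = np.ogrid[tuple(slice(0, s) for s in spec.grid_shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, spec.center))
    label = dist2 <= spec.radius ** 2
    return label.astype(np.float64), label


def sphere_specs(n_volumes: int, grid_shape: tuple[int, int, int],
                 radius_range: tuple[int, int], margin: int,
                 seed: int) -> list[SphereSpec]:
    """Random sphere placements: integer radii uniform over the inclusive
    range, centers uniform over positions at least ``radius + margin`` from
    every face."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_volumes):
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        lo = r + margin
        center = tuple(int(rng.integers(lo, s - lo)) for s in grid_shape)
        specs.append(SphereSpec(grid_shape=tuple(grid_shape), center=center,
                                radius=r, seed=seed + i))
    return specs


def no_intercept_fit(x: np.ndarray, y: np.ndarray):
    """Least squares of y on x through the origin.

    Returns (slope, standard error, p-value).  The closed form is
    slope = sum(xy) / sum(x^2); the SE and the t-test come from the
    one-regressor OLS fit without constant.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    fit = sm.OLS(y, x[:, None]).fit()
    return float(fit.params[0]), float(fit.bse[0]), float(fit.pvalues[0])


@dataclass
class CalibrationResult:
    """Outcome of the sphere-calibration experiment for one engine."""

    engine: str
    records: pd.DataFrame
    slope: float
    slope_se: float
    p_value: float
    mean_center_error: float
    sd_center_error: float
    # O(N) engine only: the ratio measured at the true centers, and the
    # rerun with radii rescaled by that ratio
    slope_true_center: float | None = None
    slope_true_center_se: float | None = None
    corrected: "CalibrationResult | None" = field(default=None, repr=False)


def _detect_linear(volume, cfg, calibration=1.0):
    stats = compute_local_stats(volume, cfg.b_prime, smooth_sd=SMOOTH_SD)
    rmap = optimal_radius(stats.mu, stats.sigma, cfg=cfg, calibration=calibration)
    result = nccc_linear(volume, rmap, cfg)
    det = top_n_detections(result, 1)[0]
    scaled = calibration * rmap.a_star
    return det, scaled, result


def calibration_experiment(engine: str,
                           n_volumes: int = 20,
                           radius_range: tuple[int, int] = (8, 21),
                           grid_shape: tuple[int, int, int] = (161, 161, 161),
                           cfg: TemplateConfig = SYNTH_CONFIG,
                           seed: int = 0,
                           specs: list[SphereSpec] | None = None,
                           fft_dtype=np.float32) -> CalibrationResult:
    """Run the sphere-detection calibration for one engine.

    Per volume: generate the sphere, run the engine, take the global NCCC
    maximum as the detected center and the radius at that voxel as the
    detected SD, and record the center error.  Fit the no-intercept
    regression of true radius on detected SD.  For the ``linear`` engine the
    ratio is additionally measured with the analytic radius looked up at the
    *true* centers, and the whole detection is rerun with the radii rescaled
    by that ratio.

    Passing the same ``specs`` (or the same ``seed`` and geometry) to all
    engines evaluates them on identical volumes.  The FFT engine computes in
    ``fft_dtype`` (single precision by default; the spheres are exactly
    representable and the detected maxima are unaffected).
    """
    if engine not in {"scan", "fft", "linear"}:
        raise ValueError(f"unknown engine {engine!r}")
    if specs is None:
        specs = sphere_specs(n_volumes, grid_shape, radius_range,
                             margin=cfg.b, seed=seed)
    rows = []
    a_true_list = []
    for spec in specs:
        volume, _ = make_sphere_volume(spec)
        if engine == "scan":
            det = top_n_detections(nccc_maximized(volume, cfg), 1)[0]
            detected_sd = det.radius_a
        elif engine == "fft":
            det = top_n_detections(
                nccc_fft_maximized(volume.astype(fft_dtype), cfg), 1)[0]
            detected_sd = det.radius_a
        else:
            det, a_star, _ = _detect_linear(volume, cfg)
            detected_sd = float(a_star[det.center])
            a_true_list.append(float(a_star[spec.center]))
        err = float(np.linalg.norm(np.subtract(det.center, spec.center)))
        rows.append({"radius": spec.radius, "detected_sd": detected_sd,
                     "center_error": err,
                     "center": det.center, "true_center": spec.center})
    records = pd.DataFrame(rows)
    slope, se, p = no_intercept_fit(records["detected_sd"], records["radius"])
    result = CalibrationResult(
        engine=engine, records=records, slope=slope, slope_se=se, p_value=p,
        mean_center_error=float(records["center_error"].mean()),
        sd_center_error=float(records["center_error"].std()))
    if engine == "linear":
        slope_t, se_t, _ = no_intercept_fit(np.asarray(a_true_list),
                                            records["radius"])
        result.slope_true_center = slope_t
        result.slope_true_center_se = se_t
        result.corrected = _corrected_rerun(specs, cfg, slope_t)
    return result


def _corrected_rerun(specs, cfg, calibration):
    """Rerun the O(N) detection with radii rescaled by the true-center ratio."""
    rows = []
    for spec in specs:
        volume, _ = make_sphere_volume(spec)
        det, scaled, _ = _detect_linear(volume, cfg, calibration=calibration)
        detected_sd = float(scaled[det.center])
        err = float(np.linalg.norm(np.subtract(det.center, spec.center)))
        rows.append({"radius": spec.radius, "detected_sd": detected_sd,
                     "center_error": err,
                     "center": det.center, "true_center": spec.center})
    records = pd.DataFrame(rows)
    slope, se, p = no_intercept_fit(records["detected_sd"], records["radius"])
    return CalibrationResult(
        engine="linear-corrected", records=records, slope=slope, slope_se=se,
        p_value=p, mean_center_error=float(records["center_error"].mean()),
        sd_center_error=float(records["center_error"].std()))


def timing_harness(engines: list[str], grid_shapes: list[tuple[int, int, int]],
                   repeats: int, cfg: TemplateConfig = SYNTH_CONFIG,
                   sphere_radius: int = 17) -> pd.DataFrame:
    """Wall/CPU times of each engine on centered-sphere volumes.

    Bookkeeping only — one row per (engine, shape) with the mean and SD over
    ``repeats`` runs; makes no correctness claims.
    """
    rows = []
    for shape in grid_shapes:
        spec = SphereSpec(grid_shape=tuple(shape),
                          center=tuple(s // 2 for s in shape),
                          radius=sphere_radius)
        volume, _ = make_sphere_volume(spec)
        for engine in engines:
            wall, cpu = [], []
            for _ in range(repeats):
                w0, c0 = time.perf_counter(), time.process_time()
                if engine == "scan":
                    nccc_maximized(volume, cfg)
                elif engine == "fft":
                    nccc_fft_maximized(volume.astype(np.float32), cfg)
                elif engine == "linear":
                    _detect_linear(volume, cfg)
                else:
                    raise ValueError(f"unknown engine {engine!r}")
                wall.append(time.perf_counter() - w0)
                cpu.append(time.process_time() - c0)
            rows.append({"engine": engine, "shape": tuple(shape),
                         "voxels": int(np.prod(shape)), "repeats": repeats,
                         "wall_mean": float(np.mean(wall)),
                         "wall_sd": float(np.std(wall)),
                         "cpu_mean": float(np.mean(cpu)),
                         "cpu_sd": float(np.std(cpu))})
    return pd.DataFrame(rows)
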