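# Methods

## Problem and model

`fastnccc` detects bright, roughly spherical structures (the motivating case
is hyperintense multiple-sclerosis lesions in FLAIR MRI with isotropic
voxels) in a 3-D scalar volume by template matching.  The similarity measure
is the normalized cross-correlation coefficient (NCCC): inside a cubic
engulfing window Ω_b of half-size `b` centered at each voxel, both the image
patch and the template are mean-subtracted and variance-normalized before
taking their inner product, so scores lie in [−1, 1] and are invariant to
positive affine intensity maps.  The template is a radially symmetric
Gaussian-like bump whose width `a` must be searched over, since lesion sizes
vary.

Three engines compute the same statistic:

1. **Prefix-sum sweep, O(a_max·N).**  The Gaussian is approximated by the
   order-n B-spline: the uniform box kernel of half-width `a` self-convolved
   n−1 times (central limit theorem; n = 2 already suffices in practice).
   Because the repeated box is a piecewise polynomial, its convolution with
   the image collapses to a fixed number of signed samples of the order-n
   running sum of the image — the signed-Pascal coefficients γ.  The running
   sums are radius-independent, so after one O(N) precomputation every
   additional radius costs O(N) with a tiny constant.
2. **Single-pass analytic radius, O(N).**  Modeling the local neighborhood
   itself as a Gaussian of SD σ(X) centered at offset μ(X) from the voxel,
   the NCCC between two Gaussians has a closed form whose maximizer over the
   template width is

       a*(X) = sqrt(‖μ‖²/D + sqrt(‖μ‖⁴/D² + σ⁴)).

   σ and μ are measured in linear time from the smoothed, background-
   subtracted image; the NCCC is then evaluated once per voxel at its own
   a*, eliminating the radius sweep.
3. **FFT baseline, O(a_max·N log N).**  The truncated Gaussian template
   (the n → ∞ limit) correlated with the image in the frequency domain;
   the reference implementation the fast engines are validated against.

## Discretization

The formulas above are continuous; the package fixes the discrete
conventions once and verifies them against brute-force oracles:

* The discrete box kernel has odd width 2a+1 with taps 1/(2a+1); all
  continuous normalizers are replaced by their exact discrete counterparts —
  window volume (2b+1)^D, per-pass normalization (2a+1)^n, and the template
  energy `kernel_energy(a, n)` (the sum of squared taps of the discrete
  order-n kernel) in place of β_n/a.  β_n = (1/2π)∫sinc^{2n} remains as the
  asymptotic reference; a·kernel_energy(a,n) → β_n as a grows.
* Prefix sums are half-open (`S[x] = Σ_{t≤x} f[t]`), so the n-fold box
  convolution is the n-fold difference with coefficients (−1)^j·C(n,j) at
  offsets a·n − j(2a+1), j = 0…n — the non-zero γ entries on this lattice.
  This mapping reproduces direct convolution to ~1e−13 and is frozen in the
  tests.
* Outside the volume the image is zero (brain volumes have zero background);
  consequently the trivial identities (constant volume → zero NCCC, affine
  invariance, translation equivariance) hold exactly at voxels whose window
  stays inside the volume, and only there.
* Degenerate windows: where the local image variance term
  V_b·W_b{f²} − W_b{f}² is ≤ 1e−12·V_b (image assumed min–max normalized to
  [0,1]), the score is the sentinel 0 — "no correlation" — so empty
  background neither wins nor poisons the running maximum.  The FFT engine
  scales this threshold with the machine epsilon of its compute dtype
  because spectral round-off grows with window energy.
* Radius sweeps resolve ties in the running maximum toward the smaller
  radius (first writer wins), making the argmax deterministic.
* a* is continuous but the prefix-sum template needs a lattice half-width:
  a_eff = clamp(round(c·a*), 1, ⌈b/n⌉−1), with the calibration multiplier c
  applied before the clamp.  Interpolating between lattice radii is out of
  scope.

## Local statistics

Smoothing, background estimation and the moments all share the
(2b′+1)^D window:

* Gaussian pre-smoothing, SD 2 voxels by default (counters voxel noise),
  kernel truncated to the window and renormalized to unit sum, zero padding.
* Background f_BG: moving minimum of the smoothed image over the window,
  computed separably.  At the volume boundary the window is truncated rather
  than zero-padded, so edges do not fabricate a zero background inside
  tissue.
* μ and σ are the first and second moments of f_s − f_BG over the window
  (σ² is 1/D of the trace of the second-moment matrix about the centroid,
  matching the radially symmetric template).  All moment sums are
  γ-weighted prefix-sum differences, including the coordinate- and
  squared-coordinate-weighted volumes.  Degenerate weight mass (≤ 1e−12 per
  window voxel) yields the sentinels μ = 0, σ = 0, which propagate to
  a* = 0 and are clamped to radius 1; such voxels score 0 via the variance
  sentinel.

## Detection and evaluation

Rather than thresholding the NCCC map, the detector keeps the N_top highest
maxima: repeatedly take the global maximum (ties broken by lexicographic
scan order), record (center, radius, score), fill the closed ball of twice
the detected radius with −∞, repeat.  Detections become binary labels by
drawing closed balls of `radius_multiplier` times the detected radius —
1.61 by default for the sweep/FFT engines (the measured sphere-to-template
ratio), 1.0 for the O(N) engine when the 2.12 calibration has already been
applied to a*.  Labels are scored against a manual annotation with
TPF = |A∩M|/|M| and FPF = |A∩¬M|/|A| (percent); the cumulative curve over
N_top is non-decreasing in TPF by construction.

## Synthetic benchmark

The generator emulates the calibration experiment: one binary sphere (value
1 inside a closed ball) per volume, integer radius uniform in [8, 21],
center uniform over positions at least radius + b voxels from every face.
The default grid is 161³ — the smallest round size that accommodates the
b = 50 engulfing margin plus the largest sphere on every side — so a full
20-volume, three-engine run completes at desk scale; the calibration ratio
itself is scale-free.  Template parameters follow the benchmark conditions:
b = 50, a_max = 24, n = 2 (sweep), truncated Gaussian (FFT), b′ = 24
(single-pass).  For clinical-style runs the CLI defaults are b = 18,
a_max = 8, n = 2.

Because the detected template width is proportional — not equal — to the
binary sphere radius, each engine's ratio is measured by least squares of
true radius on detected width through the origin (a ratio is sought, so no
intercept; the slope's standard error and t-test come from the one-regressor
OLS).  For the O(N) engine the ratio is also read at the true centers, and
the whole detection is rerun with a* rescaled by that ratio, after which the
refit slope should be ≈ 1.

What the synthetic data do not emulate: tissue texture, intensity
inhomogeneity, partial-volume edges, non-spherical lesion shape, and
multiple interacting lesions.  Passing the benchmark therefore validates
the numerics and the calibration ratios, not clinical detection accuracy.

Numerical choice: the FFT engine computes in the dtype of its input, and
the benchmark feeds it float32 — binary spheres are exact in float32, the
spectra are half the size, and the integer-argmax detection is unaffected;
the float64 path is exercised by the small-volume oracle tests.

## Problem sizes and determinism

The bundled experiment runs 20 volumes of 161³ voxels per engine (the
single-pass engine twice, for the corrected rerun); one full pass over all
engines takes roughly 10–12 minutes on one CPU core.  All randomness flows
from a single seed through `numpy.random.default_rng`; identical seeds give
identical volumes, detections and slopes.

## Known limitations

* Isotropic voxels are assumed throughout (anisotropic templates are not
  implemented).
* The engulfing window must fit inside the volume; no special-casing for
  volumes smaller than 2b+1.
* The O(N) engine stores several auxiliary volumes (coordinate-weighted
  prefix sums), so its memory footprint is the largest of the three.
* Runtime and memory are reported by `timing_harness` for orientation only;
  no performance claims are asserted by the test suite.
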