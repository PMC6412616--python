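# Methods

## Scope and model

`qube` quantifies myocardial blush from an angiographic run as the sum
of the maximum increase and maximum decrease of a per-frame blush
intensity curve, computed inside a myocardial region of interest after
median-filter background subtraction.  The package covers the scoring
pipeline itself, a rudimentary integer panning correction, manual-track
cardiac motion correction, the association statistics used to relate
scores to the visual Myocardial Blush Grade (MBG 0–3), and a synthetic
angiogram simulator that provides ground truth for all of it.  Patient
selection, angulation assessment and the visual grading itself are out
of scope: MBG enters only as an input label.

## Pipeline conventions

**Polarity.** Raw angiograms show contrast dark on bright.  Frames are
inverted once per sequence, `global_max − value`, so that contrast
density is positive and "brightest pixels" means highest contrast
density.  The blush curve is invariant to this global affine flip in
the panning estimator (normalized correlation), and the scoring is
shift-invariant, so the inversion only fixes a sign convention.

**Median filter.** Each output pixel is the order statistic at rank
`side² // 2` of its `side × side` neighbourhood — the exact median for
odd windows, the upper-middle value for even ones (20 px and 50 px
windows are part of the design).  Windows are centered at
`floor(side/2)` and the border is handled by edge replication, which
avoids artificial dark rims that would pollute the brightest-pixel
rule.  Integer-valued frames (any 8–16-bit acquisition) are filtered by
a sliding-histogram rank filter; arbitrary float frames take an exact
generic path with identical conventions.  Both paths are tested against
an explicit sorted-window oracle.

**Residual.** `frame − background` clipped below at 0: a background
brighter than the frame carries no contrast information, and clipping
prevents negative blush values.

**Blush value.** The residual is mean-smoothed with a 5 × 5 window and
the frame value is the mean of the `k = max(10, ceil(2% · ROI area))`
largest smoothed residuals inside the ROI.  The count, smoothing window
and fraction are explicit options (`BlushOptions`); the defaults were
chosen to be robust to single-pixel noise while remaining local, and are
not claims about any other implementation.  Because the mean of the `k`
largest values does not depend on which of several tied values at the
cut are taken, ties need no extra rule.

**Panning correction.** For every frame the integer offset within a
±20 px box maximizing the normalized cross-correlation with the first
frame over their overlap is found by exhaustive search (FFT cross term
plus integral-image moments; identical to the direct per-offset
computation).  Ties are broken by the smallest Euclidean norm, then
row-major order, making the output deterministic; degenerate
(constant-overlap) offsets rank below any defined correlation.  The ROI
is shifted by the estimated offset.  When a per-frame ROI track is
supplied the track already encodes motion and panning is skipped.

**Score.** `a = max_{i<j}(v_j − v_i)` and `b = max_{i<j}(v_i − v_j)`,
both floored at 0, `score = a + b`.  The extrema range over all ordered
frame pairs (global rise and fall), the only parameter-free reading of
"maximum increase plus maximum decrease"; no curve smoothing is applied
before scoring.  The implementation is O(T) via running extrema and is
tested against the all-pairs enumeration.

**ROI geometry.** Coordinates are 0-based `(row, col)` with pixel
centers on the integer grid.  A pixel belongs to a polygon iff its
center is inside by the even-odd rule, with boundary centers included —
a deterministic rule testable against an independent point-in-polygon
oracle.  Polygons must be simple; tracks are validated against the
sequence length at use time.

**Exact cropping.** `compute_blush_curve` filters only the ROI bounding
box dilated by `kernel + smoothing` pixels (clipped to the frame).
Every pixel contributing to the blush value then sees complete filter
windows, or windows cut by the true frame border where replication
applies identically, so the result equals whole-frame filtering bit for
bit (asserted in the tests).  This makes cohort-scale experiments
tractable on one CPU.

## Simulator

The scene is composed in a reference pose as
`background − vessels·v(t) − diaphragm − catheter − blush·h(t)`,
rigid-warped per frame, noise-corrupted, and quantized:

* **Blush**: spatial Gaussian of scale `blush_sigma_px` (default 45 px —
  a mid-spatial-frequency structure relative to the 35 px kernel) whose
  amplitude follows the gamma-variate bolus model
  `h(t) = A·x^α·e^{α(1−x)}`, `x = (t−t0)/tp`, normalized so
  `h(t0+tp) = A` exactly (defaults `t0 = 1 s`, `tp = 1.6 s`, `α = 3`).
  The gamma-variate is the standard indicator-dilution curve; the choice
  of functional form is the simulator's, made because a single-peaked
  parametric model with controllable arrival, peak and width is exactly
  what the recovery tests need.
* **Vessel tree**: 2–4 levels of quadratic Bézier branches with Gaussian
  cross-sections (widths 3–7 px) and a faster, earlier gamma-variate
  transit than the blush.  Any curvilinear dark structure suffices to
  exercise edge-artifact behaviour.  Random-tree control points are
  clamped 20 px clear of the reference ROI (Bézier curves stay in the
  convex hull of their control points), so that vessel kinetics only
  contaminate blush curves when an experiment deliberately places a
  vessel near the ROI — which `near_bifurcation_params()` does: a fork
  pinned 12 px outside the ROI's left edge, combined with 6° rotation
  and stronger translation, sweeps vessel pixels across the fixed ROI
  while the ground-truth track keeps its distance.
* **Motion**: rigid only — sinusoidal translation and rotation about the
  image center at the cardiac period (0.8 s) plus a linear panning
  drift, applied with bilinear interpolation and edge replication.
  Sub-pixel motion is intended; it stresses the integer panning
  correction.  Real cardiac motion also contracts and shears tissue;
  that non-rigidity is deliberately absent, so passing motion tests
  shows correctness of the correction machinery, not that rigid tracking
  suffices clinically.
* **Noise and depth**: additive Gaussian (default σ = 2 intensity
  units) followed by rounding to 8 bits (`bit_depth=None` disables
  quantization; 12-bit variants are used where sub-LSB accuracy is
  asserted).  Poisson noise and physical x-ray transport are out of
  scope.
* **Cohorts**: `associated` mode maps grade → blush amplitude
  `(0, 15, 30, 45)` intensity units with ±25% per-patient jitter —
  grade 0 has no blush by definition of the scale, higher grades step up
  to a clearly visible opacification; `null` mode draws every amplitude
  from `U(0, 45)` regardless of grade, a negative control in which any
  detected association is a false positive.  Per-patient seeds, phases
  and vessel trees derive deterministically from one master seed.

The simulator's defaults are chosen for testability on an 8-bit
intensity scale, not calibrated to clinical amplitudes or SNR, which no
suitable public reference quantifies.  Consequently absolute score
magnitudes are not comparable to clinical QuBE values; orderings,
correlations and calibration properties are the meaningful outputs.

## Statistics

Mid-ranks everywhere ties arise.  Spearman p-values use the t
approximation (recorded in the result's `method` field); Kruskal–Wallis
applies the tie correction with a chi-square reference, returning
`H = 0, p = 1` when every observation is identical; Lin's concordance
uses population (n-denominator) moments per the original estimator,
with the n−1 variant available as an option; the Wilcoxon signed-rank
test drops zero differences (count logged), uses exact enumeration of
all sign patterns for up to 25 retained pairs (dynamic programming over
doubled mid-ranks, so exactness survives ties) and a tie-corrected
normal approximation without continuity correction beyond.  Quartiles
use inclusive linear interpolation of order statistics.  Undefined
statistics (constant inputs) are flagged as missing NaN values, never
coerced to 0; aggregates skip them with a logged count.  The 0.05
significance threshold is reported alongside results and never used to
suppress them.

## Problem sizes

Default study conditions: 256 × 256 frames, 60 frames at 12.5 Hz,
blush scale 45 px, ROI 80 × 80 px, cohorts of 10 patients per MBG
grade (40 total).  The kernel-comparison and motion experiments run at
that scale.  The null-calibration experiment uses 20 master seeds of
20-patient null cohorts (5 per grade) — ample for a type-I check of a
rank correlation at n = 20 per cohort.  Unit tests use reduced scenes
(96–160 px, 8–24 frames) of identical structure.

## Known limitations

* Rigid motion and a single Gaussian blush blob are simplifications;
  non-isotropic contraction, breathing deformation and textured blush
  are not emulated.
* The brightest-pixel count, smoothing window and panning algorithm of
  the historical implementation are not published; this package's
  choices are explicit, documented parameters rather than a claim of
  bit-compatibility.
* DICOM support covers uncompressed multi-frame grayscale pixel data
  only (no overlays, no compressed transfer syntaxes).
* Scores scale linearly with intensity units and are uncalibrated
  across acquisition setups — a limitation inherent to the method
  itself.
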