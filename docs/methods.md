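# Methods

This note documents the models, estimators and numerical choices behind
`gazegrade`, and what the synthetic cohorts used in testing do and do not
establish about real data.

## Study design being modeled

Twenty raters grade the nuclei of twenty carcinomas. Each carcinoma
contributes two circular high-power fields (HPFs) with statistically
identical nuclei; one is shown embedded in a tubule-rich low-grade context
("tubular"), the other in a solid high-grade context ("solid"), each for
8 seconds while gaze is tracked at 50 Hz. Grades live on a 1–3 scale with
half steps. Afterwards every HPF contributes one isolated-nuclei trial:
ten of its nuclei shown out of context in a 2×5 matrix and graded as a
group. The analysis asks how much of the context-induced grade difference
is mediated by *which* nuclei the rater fixated.

## Nuclear morphometry

Nuclei arrive segmented as an integer label raster aligned with an 8-bit
grey (or RGB) intensity raster. Per nucleus:

| feature | definition | units / range |
|---|---|---|
| `size_px` | pixel count of the mask (exact integer) | px |
| `hyperchromasia` | mean grey level over the mask | 0–255, lower = darker |
| `heterochromasia` | SD of the grey histogram (population, ddof = 0) | grey units |
| `roundness` | form factor 4πA/P² | (0, 1] |

RGB inputs are reduced to luminance with BT.601 weights
(0.299, 0.587, 0.114) before histogram statistics. The perimeter in the
form factor uses the Crofton estimator with four directions
(`skimage.measure.perimeter_crofton`): on rasterized discs it is accurate
to a few parts in 10³ at radius 100 px, against a ~10% staircase bias for
a raw marching-squares polyline. Discretization can still push the ratio
a fraction of a percent above 1 for some radii (the error oscillates with
radius inside a shrinking envelope); values are clamped to 1.0 with a
debug log entry, since the scale is bounded by the perfect circle.
Regions below 20 px (configurable) are dropped with a logged count — a
form factor computed on a handful of pixels measures the raster, not the
shape. Disconnected masks are reduced to their largest component with a
warning. Coordinates are (row, col), 0-based, pixel-center convention.

## Fixation detection and nucleus assignment

Detection is dispersion-threshold identification (I-DT) over maximal runs
of valid samples: grow the window while bounding-box dispersion
(width + height) stays within `dispersion_px`; emit the maximal window as
a fixation if its duration reaches `min_duration_ms`, else advance the
anchor one sample. Duration is defined as last-minus-first timestamp plus
one nominal sample interval, so exactly five samples at 50 Hz equal the
100 ms floor. Invalid samples split candidate windows; nothing is
interpolated.

Defaults: `min_duration_ms = 100` (the recording criterion of the
emulated design), `sampling_hz = 50`, `assignment_radius_px = 14`
(≈ 0.4° tracker accuracy at ~35 px/°), and `dispersion_px = 40` (≈ 1° of
visual angle). The dispersion threshold is the one constant the emulated
design does not pin down — it is exposed in `GazeConfig`, and the
detector's exact agreement with an exhaustive-window oracle is tested so
that changing it cannot silently change semantics.

A fixation is assigned to the nucleus whose label lies under its centroid
pixel; failing that, to the nucleus with the nearest labeled pixel
(Euclidean, pixel centers, exact local search) within the assignment
radius; otherwise it stays unassigned. Fixations outside the HPF's
circular viewport are kept for detection but never assigned. Fixated
feature means count each distinct nucleus once per trial regardless of
dwell time (re-fixating a nucleus is evidence of interest, not of a
different nucleus); a dwell-time-weighted variant is available behind a
flag.

## Rater profiles

Per rater, over their isolated-nuclei trials (one grade per ten-nucleus
display, regressed on the display's *mean* features): Spearman rank
correlation (average ranks, two-sided p) per feature; a feature passes at
|ρ| > 0.3 and p < 0.05 — absolute value, so a darkness criterion
(negative ρ against grey level) qualifies; the passing feature with the
largest |ρ| becomes the preferred feature (exact ties broken in the fixed
order size, hyperchromasia, roundness, heterochromasia); OLS of grade on
that feature (statsmodels) supplies the slope. Raters with constant
grades yield a degenerate profile rather than an error. The regression is
univariate on the strongest feature even for raters correlating with two
features — the slope feeds a one-dimensional mediation estimate, and a
bivariate slope would double-count correlated features.

## Bias decomposition

Per rater: `observed_delta` = mean(solid grades) − mean(tubular grades);
`predicted_delta` = slope × (fixated mean of the preferred feature under
solid − under tubular), with the shift computed from the rater's
aggregate condition means (a per-case-pair mode is available via
`per_pair=True`; with equal trial counts per case the two agree);
`fraction_explained` = predicted/observed. Raters with no preferred
feature contribute a fraction of exactly 0; raters with a zero observed
delta are excluded from the cohort summary with a logged note. Fractions
are reported unclipped — under noise they can be negative or exceed
100% — and the summary counts values outside [0, 100]%.

Inference throughout uses the rater as the unit: the cohort bias is a
two-tailed paired t across raters (df = n − 1); the Gleason-gap contrast
is a paired t on within-rater stratum differences; experience-group and
prostate-reader comparisons are one-way fixed-effects ANOVAs on per-rater
deltas (reported with MSE). Zero-variance differences return flagged
degenerate results instead of raising, so edge-case cohorts run end to
end. No multiple-comparison correction is applied.

## Synthetic cohorts

The generator emulates the full experiment with known ground truth.

**Nuclei.** Per case, `nuclei_per_field = 80` nuclei are drawn once and
shared by the case's two fields (the emulated design verified the paired
HPFs were morphometrically identical; sharing the draws realizes that
exactly and is what makes the null calibration below exact). Size is
lognormal (mean 3200 px, CV 0.25, plus a case-level multiplier, CV 0.08);
mean grey is normal (135 ± 10 between nuclei, ± 3 between cases); pixel
texture SD is 45 ± 4; shapes are ellipses (axis ratio 1–1.3) with smooth
radial contour noise (relative amplitude 0.08, harmonics 2–5).

**Rendering (`render=True`).** Fields are 1704 px circular viewports;
nuclei are placed without overlap by rejection sampling and painted into
a uint16 label raster and a uint8 intensity raster (background
210 ± 6). The recorded per-nucleus "truth" features are computed from the
painted pixels, so morphometry on the written rasters recovers them
exactly. Gaze streams dwell 140–320 ms on each selected nucleus with
2 px jitter, bridged by two interpolated saccade samples; non-overlap
margins keep neighbouring dwells beyond the dispersion threshold, so
every generated dwell survives I-DT and lands on its nucleus.

**Feature-level mode (`render=False`)** skips rasters and gaze and reports
the generative feature values directly; roundness uses the analytic
ellipse form factor with a quadratic contour-noise penalty fitted to the
renderer. The two modes are distributionally matched, not
sample-identical (rendering truncates the extreme size tail via
placement rejection and adds quantization noise). Replicated statistical
studies in the test suite use this mode; the rendered path is validated
separately by exact end-to-end agreement with the ground truth on a
small cohort.

**Selection.** Fixation targets (15 per trial) are sampled without
replacement with weight exp(±s·z), where z is a composite atypia z-score
(size +, darkness +, texture +, roundness excluded) and the tilt sign
follows the condition. The default `selection_strength s = 0.15` was
calibrated once against the regime the design reports: a fixated-size
condition shift on the order of 100 px with shifts in chromasia but none
in roundness.

**Grades.** latent = intercept_r + slope_r · (fixated mean of the
rater's preferred feature) + offset_case · [solid] + N(0, 0.15), rounded
to the nearest half step (ties at .25 round up) and clamped to [1, 3].
Slopes are scaled to 0.6 grade units per nucleus-SD of the preferred
feature (log-normal rater scatter, CV 0.2); intercepts target a tubular
cohort mean of 2.02. The direct offset defaults to 0.36, modulated ±33%
by whether the case pair's context images differ by more than 1.5
Gleason points; with the selection-mediated ~0.04 on top, cohort
condition means land near 2.0 / 2.4. The rater panel mixes preferences
(11 size, 4 darkness, 5 none per 20) and experience groups (4 + 4 + 4 + 8,
with the 8 senior faculty flagged as routine prostate readers).

Named regimes fix everything but the seed: `pure_selection_config`
(no direct offset, tilt 1.0, all-size raters — the decomposition must
recover ~100%), `offset_dominated_config` (offset carries 90% of the
generative delta — must recover ~10%), and `noiseless_config` (pure
selection with no noise, no rounding, no rater/case scatter and a
moderate tilt so no latent grade touches the clamp — the fraction
explained is then exactly 1 per rater, and the tests require it to
1e-6).

Randomness is hierarchical: the cohort seed spawns independent per-case,
per-rater and per-trial generators, so enlarging the rater panel never
perturbs existing cases.

**What passing does not show.** The generator's nuclei are independent
ellipses on a clean background: no touching or overlapping nuclei, no
stain variation, no segmentation error (masks are exact), no head
movement or tracker drift beyond white jitter, and saccades are linear.
Results on real exports depend on segmentation quality and tracker
calibration in ways these tests cannot certify.

## Problem sizes used in testing

Statistical checks run on feature-level cohorts at the design's full
size (20 raters × 20 cases) — 100 seeds for the type-I calibration of
the fixated-feature tests, 50 seeds per recovery regime, 100 replicates
for preferred-feature recovery — while raster-backed checks use a
3-rater × 4-case rendered cohort plus single-field fixtures (including a
1000-nucleus render/extract round trip). These sizes make the whole
suite a few minutes of compute while keeping every estimator at the
cohort dimensions it is meant for.

## Known limitations

* The dispersion threshold is a stated convention, not an estimated
  quantity; sensitivity to it should be explored per dataset.
* The mediation estimate is a point decomposition: no confidence
  interval is attached to the fraction explained (per-rater fractions
  are ratios of noisy quantities and are reported unclipped for that
  reason).
* Grade rounding to half steps makes the linear grading model an
  approximation near the scale ends; the clamp can attenuate extreme
  latent grades.
* The per-rater aggregate shift (default) weights trials, not case
  pairs; with missing trials the `per_pair` mode is the safer choice.
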