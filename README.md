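# gazegrade

When pathologists assign a nuclear grade to a tumor, the surrounding
architecture biases them: the same high-power field (HPF) of a prostate
carcinoma receives systematically higher nuclear grades when it is shown in
the context of a solid, high-Gleason tumor than in the context of a
tubule-rich, low-Gleason one. Part of that bias could be *visual selection*:
under a "high grade" expectation the eye seeks out bigger, darker nuclei,
and grading those nuclei honestly would already raise the grade.
`gazegrade` implements the analysis that separates the two: it quantifies
the observed grading bias, reconstructs which nuclei each rater actually
fixated from eye-tracking data, identifies each rater's operative grading
criterion, and computes how much of the bias selective fixation can explain.

The package is aimed at researchers studying observer behavior in
diagnostic pathology (and, more generally, at anyone decomposing a
stimulus-context effect into a gaze-mediated and a residual component).

## The method

For each rater *r* and each carcinoma case shown under both architectural
conditions:

* **Observed bias** — Δ\_obs(r) = mean grade under *solid* − mean grade
  under *tubular*, tested across raters with a two-tailed paired *t*
  (rater is the unit of inference).
* **Morphometry** — every segmented nucleus gets four features: size
  (pixel count), hyperchromasia (mean grey level; lower = darker),
  heterochromasia (SD of the grey histogram), and roundness (form factor
  4πA/P², 1 for a circle).
* **Fixation mapping** — fixations are detected from 50 Hz gaze samples by
  dispersion-threshold identification (I-DT; ≥ 100 ms, bounding-box
  dispersion ≤ 40 px) and assigned to the nucleus under (or within 14 px
  of) their centroid; the mean features of each rater's fixated nuclei are
  compared between conditions.
* **Rater profile** — from trials that show ten nuclei stripped of
  architectural context, Spearman correlations between the rater's grades
  and the displays' mean features identify the preferred feature
  (|ρ| > 0.3, p < 0.05, strongest |ρ| wins), and OLS of grade on that
  feature yields the rater's grading slope β\_r.
* **Decomposition** — Δ\_pred(r) = β\_r · (fixated-feature mean under solid
  − under tubular), and the **fraction explained** is
  Δ\_pred(r)/Δ\_obs(r), summarized over the cohort as mean / median /
  range.

Because the human-subject data this design comes from were never deposited,
the package ships a fully ground-truthed synthetic cohort generator
(histology-like label/intensity rasters, 50 Hz gaze streams, half-step
grades on the 1–3 scale) whose every stage is verifiable: the generative
selection tilt and grading rules are known, so recovery of the mediated
fraction can be tested exactly.

## Worked example

```python
import gazegrade as gg

cohort = gg.simulate_cohort(gg.default_config(), seed=1)
results = gg.ArchitectureBiasModel.from_cohort(cohort).fit()
print(results.summary())
```

prints

```
Architecture-induced nuclear grading bias
==========================================================
raters: 20   cases: 20

Observed bias (grade units, solid - tubular)
  mean grade tubular:  1.984 +/- 0.177
  mean grade solid:    2.428 +/- 0.164
  mean delta:          0.444
  paired t(19) = 25.67, p = 3.3e-16

Fixated-nucleus feature shifts (per-rater paired t)
  size_px           3197.30 ->   3288.11  t(19) =   8.15, p = 1.3e-07
  hyperchromasia     137.15 ->    135.26  t(19) = -12.27, p = 1.8e-10
  heterochromasia     44.83 ->     45.53  t(19) =  14.21, p = 1.4e-11
  roundness            0.89 ->      0.89  t(19) =  -1.66, p = 0.11

Rater feature preferences
  size_px         12 rater(s)
  hyperchromasia   4 rater(s)
  none             3 rater(s)
  roundness        1 rater(s)

Fraction of bias explained by nucleus selection
  mean 12.4%   median 10.5%   range -11.6%-33.7%  (n = 20)
  note: 1 rater fraction(s) outside [0%, 100%]
```

Reading this: every rater grades the same nuclei about 0.44 grade units
higher in the solid context; they fixate larger (+91 px) and darker
(−1.9 grey units) nuclei there, but pushing those shifts through each
rater's own grading slope predicts only ~12% of the bias — the rest is the
architectural prime acting directly on the judgment, not on the eyes.
Stratified re-analyses are available as
`results.stratified("gleason_delta_class")` (bias is larger when the two
context images differ by more than 1.5 Gleason points),
`results.stratified("rater_group")` and
`results.stratified("prostate_reader")` (experience does not modulate the
bias). `results.plot_paired()` draws the classic paired-lines figure.

The same pipeline runs from the shell over on-disk cohorts (rasters, gaze
logs and grade tables in plain-text dialects):

```
gazegrade simulate --seed 1 --out cohort      # write a synthetic cohort
gazegrade analyze --out cohort                # morphometry -> fixations ->
                                              # profiles -> decomposition
```

`cohort/analysis/` then contains the per-nucleus feature table, the
fixation table, per-rater profiles, the decomposition table and a text
report; `features`, `fixations` and `profile` run individual stages.

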