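# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic-data results do and do not show about real breath-print data.

## Breath-print geometry and the AUBP index

A breath-print is an ordered vector of 28 non-negative sensor responses:
7 quartz-microbalance sensors × 4 desorption temperatures, stored
temperature-major (sensors 1–7 at 50 °C, then 100, 150, 200 °C) so that
radar plots show each temperature block as a contiguous run.  Responses
are frequency-shift magnitudes in arbitrary response units; units are
carried as metadata only and negative inputs are rejected rather than
absolute-valued, since the area semantics below require non-negative
radii and silent transformation would hide data errors.

On a radar plot with equal angular steps θ = 2π/n, the profile encloses
a polygon whose area is the triangle fan

    A_i = ½ s_i s_{i+1} sin θ   (i = 1…n−1),   A₀ = ½ s_n s_1 sin θ,
    AUBP = Σ_i A_i + A₀ = ½ sin θ (Σ_{i=1}^{n−1} s_i s_{i+1} + s_n s_1).

This equals the shoelace area of the vertices (s_i cos iθ, s_i sin iθ);
the equivalence is exercised in the tests on 1000 random profiles at
1e−9 relative tolerance, together with the closed-form regular-polygon
case (constant r ⇒ r²·(n/2)·sin 2π/n), quadratic homogeneity
(AUBP(c·s) = c²·AUBP(s)), monotonicity in every radius, and rotation
invariance (the start angle affects rendering only).  AUBP is *not*
permutation-invariant — it depends on the declared radius order — and a
test pins that property rather than hiding it.

## PLS-DA classification

Class indicators (one-hot over the sorted class labels) are regressed on
autoscaled predictors through L NIPALS latent variables; a subject is
assigned the argmax of its predicted indicator row, ties broken by class
order.  Autoscaling (mean-centre, unit variance) is standard chemometric
practice for quartz-microbalance arrays with heterogeneous response
magnitudes and is refit on training folds only.  A zero-variance
training column gets scale 1 (inert after centring) with a warning; a
matrix that is constant everywhere is rejected.

Validation is stratified k-fold cross-validation (default k = 10; the
fold count drops to the rarest class size when necessary).  The number
of latent variables is selected from a grid (default 1…min(10, rank)) by
pooled held-out misclassification, ties to the smallest L.  Because L is
chosen on the same held-out predictions that are reported, the pooled
accuracy is a best-of-grid statistic: on zero-effect cohorts it sits a
few points above chance (≈ 0.38 vs 1/3 for a 5-value grid, measured over
40 seeds).  Chance-calibration checks therefore fix L = 1, for which the
analytic binomial band is the correct null; signal estimates treat the
optimism as part of the declared model-selection procedure.

The permutation test shuffles class labels and reruns the *entire*
cross-validation pipeline per permutation, reporting the add-one
p-value (1 + #{null ≥ observed}) / (1 + B).  The replication default of
B = 10 bounds p below by 1/11; `--strict` raises B to 1000 when real
resolution is needed.  A `--features 7` switch collapses the
breath-print to per-sensor means over temperature blocks for analyses
run on the 7-sensor array rather than the full 28 responses.

## Diagnostic accuracy and ROC analysis

Confusion matrices keep actual classes on rows and predictions on
columns.  Collapsing to a 2×2 table takes declared positive/negative
label sets; the optional `restrict_predicted` argument drops predicted
columns outside a kept set *before* collapsing — the convention required
to reproduce two-class accuracies quoted within a disease subgroup when
a third predicted class exists (subjects routed to the outside class are
excluded from the two-class table).  Metrics use the standard
definitions; LR+ is reported as +∞ at specificity 1 (a legitimate
perfect-specificity table, not an error), and replication against
printed one-decimal values rounds half away from zero, the convention of
printed clinical tables.

AUROC is the average-rank Mann–Whitney probability (ties credited ½),
computed on oriented scores: the AUBP falls with disease, so its ROC
runs with `lower_is_positive` and cut-offs read "score < threshold ⇒
positive".  Operating points are enumerated at midpoints between
adjacent distinct scores, with open-ended extremes for the ROC corners.
Confidence intervals are percentile bootstrap (default B = 2000),
stratified within class so every replicate retains both classes;
replication stability uses stratified 90% subsamples without replacement
(the chosen reading of "10-fold resampling", configurable via
`--resample-frac`) and label permutations with the add-one p-value.
Cut-off selection supports the Youden index (ties to higher specificity)
and sensitivity/specificity-constrained criteria; the no-call and
all-call extremes are excluded from selection since they are clinically
meaningless as cut-offs and leave a predictive value undefined.

## Sensor–covariate correlation

Spearman's ρ is computed as Pearson correlation of average ranks on
pairwise-complete pairs (≥ 4 required), with a two-sided p from the
t-approximation on n−2 degrees of freedom.  The grid covers all 28
responses × {bilirubin, albumin, INR}; cells with p ≥ 0.05 are flagged
non-significant.  No multiple-testing correction is applied by default,
matching how such grids are conventionally reported; a
Benjamini–Hochberg option exists behind `--bh-correct` for honest reuse.

## Synthetic cohort generator

The generator encodes the study conditions the analysis assumes:

* **Concordant multiplicative disease effect.**  Each subject draws a
  global scale g ~ logNormal(log m_s, σ_s²) for its stratum s ∈ {CTRL,
  NC-CLD, LC·A, LC·B, LC·C}; the breath-print is g × baseline profile
  plus additive zero-mean sensor noise (SD 1.0 response units, ≈ 4% of a
  typical response), truncated at zero.  The multiplicative, concordant
  form reflects the observation that disease produces a quantitative
  shrinkage of the whole profile with no discordant directional changes.
* **Calibration.**  AUBP is quadratic, so a subject's area is
  A_base·g² (additive noise is independent across radii and does not
  bias the expected area).  The squared-log-normal moments give
  E[AUBP] = A_base·e^{2μ+2σ²} and CV² = e^{4σ²} − 1, inverted in
  closed form per stratum from the published group mean ± SD anchors;
  a Monte-Carlo test at n = 10⁵ confirms the inversion to 1%.  The
  published SDs imply stratum-specific dispersions (CV 0.26–0.73), which
  is why σ is per-stratum rather than global.  The baseline profile is a
  fixed smooth template (a sensor pattern repeated over four decreasing
  temperature-block levels, responses ≈ 16–33 units) scaled so its area
  equals the healthy-control anchor.
* **Aetiology as a shape effect.**  Non-infective subjects have sensors
  2, 4, 5 of the 50 °C block damped by a factor (default 0.8), then the
  whole profile rescaled to preserve its area — group AUBPs do not
  differ by aetiology in the reference results, so the effect must live
  in the profile shape, not its size.
* **Covariates.**  Bilirubin and INR follow log-linear links with
  negative slope on log g plus noise (sicker ⇒ smaller profile ⇒ higher
  marker), tuned to Spearman ρ ≈ −0.45 and ≈ −0.33 against sensor
  responses at n = 160; albumin has a weak positive linear link with
  large noise (ρ ≈ +0.2), reflecting that albumin is only loosely
  related to the breath signal.  ALT and eGFR are plausible but
  deliberately uncoupled — they are not part of the correlation
  analysis.  Hepatic encephalopathy occurs only within cirrhosis with
  probability 0.05/0.2/0.4 across Child-Pugh A/B/C (≈ 13 expected
  cases); aetiology composition follows the reference design's
  proportions (NC-CLD 19:20 infective:non-infective; LC 18:37:10 with
  mixed).
* **Default design.**  56 CTRL / 39 NC-CLD / 65 LC (Child-Pugh
  21/27/17), one seed driving all draws; identical config + seed yields
  an identical file.  A zero-effect variant (equal scales everywhere,
  balanced 50/50/50 groups) serves the chance-calibration checks.

**What passing tests show — and what they do not.**  The generator
produces a single latent severity axis with independent additive sensor
noise.  Real e-nose data have correlated sensor noise, drift,
temperature-block interactions, comorbidity effects and aetiology
signatures richer than a three-sensor damping; classification accuracy
on these cohorts therefore measures the pipeline's ability to recover a
known monotone structure at realistic effect sizes and sample sizes, not
the clinical accuracy of the instrument.  Published AUROCs, cut-offs and
their operating characteristics depend on the original patient scores
and are not reproducible from summary statistics; the pipeline instead
verifies the properties that *are* checkable — chance calibration under
permutation, anchor recovery, correlation-sign recovery, and the
expected difficulty ordering (detecting disease is easier than grading
decompensation).

## Problem sizes and numerical choices

Multi-seed checks use 20 cohorts at the reference design size (160
subjects), 10-fold cross-validation over a 1–5 latent-variable grid, 500
label permutations for null AUROC means, and 2000 bootstrap replicates
for interval checks — sizes at which every documented statistical bound
holds with margin while the full suite runs in well under a minute.
Ties in scores collapse into single ROC thresholds; permutation p-values
use the add-one rule and can never be 0; infinities and missing values
serialise as the fixed sentinels "inf"/"NA" so reports stay diff-able;
all randomness flows from explicit integer seeds, forked per stage via
`numpy.random.SeedSequence`.

## Known limitations

* The generator's single-axis structure makes 3-class PLS-DA accuracy on
  NC-CLD (the intermediate class) lower than the reference results,
  where profile *shape* also carried class information.
* "10-fold resampling" in the reference description is ambiguous
  (k-fold CV vs repeated subsampling); the package implements stratified
  10-fold CV for classification and 90% stratified subsampling for ROC
  stability, both configurable.
* Whether the reference models used all 28 responses or 7 per-sensor
  aggregates is ambiguous; the default is 28 with a documented switch.
* Exact-permutation Spearman p-values are not implemented; the
  t-approximation is used at all n (adequate at the cohort sizes here).
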