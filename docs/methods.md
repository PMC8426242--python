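# Methods

This note documents the models, parameter choices and numerical
conventions behind `petmtv`, and states what the synthetic validation
does and does not demonstrate.

## 1. Imaging substrate and quantification chain

Volumes are body-weight SUV grids with anisotropic spacing; the default
3.18 × 3.18 × 5.0 mm matches a common clinical whole-body
reconstruction, giving a voxel volume of 0.050562 ml. Axis order is
(x, y, z), coordinates are 0-based, and all volumes are reported in ml
(1 ml = 1000 mm³).

**Detection threshold.** `2·mean + 2·SD` of the SUV inside a
mediastinal blood-pool mask, recomputed per patient. Region statistics
use the population SD (divisor N): reference VOIs contain hundreds of
voxels, so the N vs N−1 distinction is negligible; fixing one
convention keeps results bit-reproducible and testable.

**Foci.** Connected components of strictly supra-threshold voxels.
Default connectivity is the 26-neighborhood — the permissive standard
for hot-spot components on coarse PET grids — configurable to 6; both
detection and half-max segmentation use the same setting. Components
whose detection-mask volume is below 0.5 ml are discarded *before* any
re-segmentation or classification; the half-max mask is therefore
allowed to end up smaller than 0.5 ml.

**SUVpeak.** Mean SUV over a 1.0-ml sphere, following the PERCIST
convention. Candidate sphere centres are restricted to the focus's own
voxels; membership is decided by voxel-centre distance in mm; for foci
smaller than the sphere, the sphere extends into the surroundings, and
at the grid boundary out-of-grid voxels are excluded from the mean.
The exhaustive centre search is exact, not a heuristic — the test
suite checks it against an independent brute-force scan.

**Measurability.** Strict inequality
`SUVpeak > 2·mean(liver) + 2·SD(liver)`; a focus exactly at the
threshold is not measurable.

**MTV.** Voxels with `SUV ≥ 0.5·SUVmax` (the focus's *local* maximum)
connected to the focus's maximum voxel. Seeding at the maximum and
growing by connectivity keeps adjacent structures that exceed half-max
but are not connected to this focus out of the mask.

**Organ-wise aggregation.** Region labels map onto five organ systems
(bone, lymph node, liver, lung, soft tissue) through an explicit
dictionary in `petmtv.anatomy`; an unmapped region label is a
configuration error, never silently dropped. Patients with no foci in
scope contribute 0 ml.

## 2. The synthetic phantom

Lesions are rendered as voxelized balls: the `ceil(V / v)` voxels
nearest the centre in the anisotropic mm metric (`v` = voxel volume),
with deterministic tie-breaking. The constructed volume is therefore
an exact voxel-count multiple, which is what makes *exact* MTV
recovery a meaningful test: lesion voxels carry the lesion's SUVmax
with no noise, background/compartment voxels get truncated-at-zero
Gaussian noise, so the half-max contour coincides with the constructed
voxel set in the unblurred case. With the optional Gaussian smoothing
(FWHM 5.0 mm by default when enabled — a typical effective
post-reconstruction resolution) recovery is checked against a
one-surface-layer quantization bound instead.

Default geometry: a 48 × 48 × 72 grid with background SUV 0.5
(noise SD 0.05), an ellipsoidal blood-pool compartment
(SUV 1.8 ± 0.2) and a box liver compartment (SUV 2.2 ± 0.3).
Compartments must not overlap; lesions are placed in organ-specific
zones with a one-voxel exclusion halo against other lesions and
against the reference compartments (liver lesions may — must — sit
inside the liver box), with bounded retries and a hard error naming
the lesion on failure. Physiological (unsuspicious) foci are rendered
with the same machinery and only differ in their classification label,
because the evaluation stage scores both kinds.

When no explicit lesion list is given, per-patient counts are Poisson
(mean 11 suspicious + 10 physiological ≈ 21 foci, the scale of a
metastasised-cancer read), volumes log-normal (median 1.5 ml,
σ_log = 1, truncated to 0.1–50 ml), SUVmax log-normal (median 7,
truncated below at 4.5 so every rendered lesion is detectable by the
blood-pool threshold). Liver lesions get a floor of 3× the liver mean
so their half-max contour stays clear of liver parenchyma — without
it, the 50% threshold of a faint liver lesion would flood the whole
compartment, which is a real failure mode of half-max segmentation,
not an artifact of this phantom.

## 3. The simulated detector

The candidate read flips each truly suspicious focus to "detected
suspicious" with probability
`expit(b0 + b_v·ln(volume_ml) + b_s·SUVmax)` (defaults −3.0, 1.2,
0.35), flags physiological foci at a false-positive rate (default
0.02), and corrupts anatomical labels with per-level confusion rates
(defaults 0.02 / 0.12 / 0.20 for body part / region / subregion).
Slopes are constrained non-negative so sensitivity is monotone in size
and uptake; the defaults make missed lesions smaller and fainter than
detected ones, the qualitative signature such evaluations report. A
`DetectorProfile.constant(s, fp)` constructor produces
volume-independent operating points for calibration tests.

## 4. Evaluation statistics

Per-focus metrics pool all foci; per-patient metrics are computed
within each patient and averaged over patients with a defined value.
Patients whose denominator is empty (e.g. no suspicious foci for
sensitivity) are excluded from the mean — exclusion, not imputation,
is the only choice that does not invent data; counts of exclusions are
carried in the result. Confidence intervals are percentile bootstrap
(default B = 1000, level 95%) resampling *patients* with replacement,
each patient carrying all its foci; replicates where the metric is
undefined are dropped and counted. Percentile (not BCa) is used as the
minimal, seed-reproducible construction. The bootstrap is vectorised
over replicates from per-patient count tables.

Subregion label accuracy is computed only over foci whose reference
read provides a subregion (absent ≠ wrong — absent labels are encoded
as an explicit null token in CSV, never as an empty string);
"most detailed" compares at the finest reference-provided level.
Missed-vs-detected comparisons use the two-sided Mann–Whitney U (exact
for small untied samples, otherwise normal approximation with tie
correction, via scipy).

## 5. Survival layer

**Transform.** All MTV covariates enter as `log2(x + 1)`; +1 keeps
zero volumes finite and base 2 makes a coefficient the log hazard
ratio per volume doubling.

**Cox fitting.** The partial likelihood with Efron tie handling is
maximised by damped Newton iterations (step halving on the
log-likelihood) to a gradient sup-norm of 1e-8; standard errors come
from the inverse observed information at the optimum. Efron rather
than Breslow because month-granularity follow-up ties often and Efron
is the less biased default; the general tied path is fully vectorised
over (tie-group, within-group-rank) pairs, and untied data takes a
leaner prefix-sum path. Monotone likelihood (a covariate that orders
the risk sets) is detected both by divergence during iteration and by
a |β| > 20 guard at convergence, and reported with the offending
covariate's name; a singular information matrix raises a collinearity
error. The test suite cross-checks coefficients and standard errors
against lifelines' independent implementation and against a
grid-search maximiser of the hand-written partial likelihood on tiny
fixtures.

**Stepwise selection.** Forward-LR in the SPSS sense: candidates enter
by the Rao score test (evaluated at the current fit extended with a
zero coefficient, where the current-model score vanishes) at
α_entry = 0.05, and selected covariates are removed by the
likelihood-ratio test at α_removal = 0.10, iterating to a fixed point.
Every tested entry and removal is recorded in a trace.

**Concordance.** The Gönen–Heller CPE is computed from fitted linear
predictors only: each unordered pair contributes the model-implied
probability that the higher-risk subject fails first,
`1/(1 + exp(−|η_i − η_j|))`, pairs with equal predictors contribute
1/2, and a fit with all-equal predictors returns 0.5 with a
degeneracy flag. Because no observed times enter, the estimate is
unaffected by censoring. A kernel-smoothed variant (normal-CDF
weights with a bandwidth) is available but off by default. Note the
estimator is bounded below by 0.5 by construction.

**Model comparison.** Two Cox models on the same patients are compared
by a paired patient-level bootstrap of the CPE difference:
`z = mean(Δ*) / SD(Δ*)` against a standard normal (a bootstrap Gauss
test). Replicates where either refit fails are dropped and counted
(more than 20% dropped is an error); a degenerate spread — comparing
a model with itself — returns p = 1. Calibration caveats: (i) when
*neither* model carries signal the CPE sits at its 0.5 boundary and
the test is strongly conservative (empirically near-zero rejections),
so a non-significant comparison of two near-null models is
uninformative rather than evidential; (ii) the normal reference is
asymptotic — in simulations with two equally informative covariates
the size is ≈5.5% at n = 100 patients but drifts to ≈7% at n = 60, so
small-cohort p-values near 0.05 should be read with that in mind.

**Kaplan–Meier / log-rank.** Product-limit estimation and the
multi-group log-rank test are delegated to lifelines; the median is
the earliest time with S(t) ≤ 0.5 and is undefined (reported as null)
when the curve never reaches 0.5. The optimized-cutoff scan evaluates
every midpoint between consecutive distinct covariate values (this
includes the 0-vs-positive split whenever zeros occur) with a fast
in-package two-group log-rank statistic, subject to each arm holding
at least 10% of patients (an arm-size floor preventing degenerate
splits; configurable), and ties in the maximal χ² resolve to the
smallest cutoff. The reported p-value is labelled *naive*: the scan
maximises the statistic, so its null rejection rate is far above
nominal (a property the test suite demonstrates), and the cutoff —
not the p-value — is the deliverable. Quartile grouping uses
linear-interpolation quantiles with boundary ties assigned to the
lower group; both conventions are stated because quartile boundaries
are convention-dependent.

**Agreement.** Paired MTV series are compared with the Wilcoxon
signed-rank test on raw differences (zero differences dropped; exact
for small untied samples, else normal approximation with tie
correction), squared Pearson correlation on the log2(x+1) scale, and
Bland–Altman bias with 1.96·SD limits of agreement.

## 6. The synthetic cohort

Per-organ MTV is zero-inflated log-normal (an organ is unaffected with
probability p₀, else log-normal), with defaults chosen to give
organ-wise means of roughly 5–15 ml and ranges reaching a few hundred
ml — the scale of advanced metastatic disease. Event times are
exponential with hazard
`h₀ · exp(Σ_k β_k · log2(MTV_k + 1))` (defaults: h₀ = 0.008/month,
β = 0.24 for lymph-node and 0.16 for liver MTV, zero elsewhere),
administratively censored at 84 months; with these defaults the event
fraction is roughly two thirds and mean survival sits near 40 months.
An all-censored draw warns rather than fails. The generating β is the
recoverable ground truth for every downstream Cox check.

## 7. Pipeline conventions

The end-to-end driver requires an explicit seed per stochastic stage
(phantom, detector, bootstrap, cohort) and refuses to run otherwise;
identical configurations reproduce every output bit for bit. In the
pipeline's reference read, truth lesions missed by thresholding
(dropped by the minimum-volume filter) are appended as "manually
added" foci carrying their constructed volume — they count against the
candidate read in the all-foci analysis, mirroring a reference
standard completed by a human reader. The pipeline's manual-vs-AI
agreement stage multiplies each patient's whole-body MTV by a
logit-normal recovered fraction (mean logit 0.3, SD 0.9), a one-knob
stand-in for partial lesion recovery that yields high log-scale
correlation with a low-biased automated read.

## 8. Validation sizes and runtime choices

The shipped checks use: 20-lesion phantoms spanning 0.5–200 ml on a
128 × 128 × 160 grid; 2000 simulated foci over 50 patients for
detector metrics (bootstrap B = 1000, CI coverage measured over 400
repeated simulations); Cox recovery at n = 2000 and Wald-CI coverage
over 200 cohorts of n = 200; 1000-rep null simulations for log-rank,
Wilcoxon, Mann–Whitney (and the CPE comparison at n = 100, B = 150).
These sizes were chosen so each property is measured with small
simulation error while the whole suite stays interactive.

## 9. What passing these checks shows — and what it does not

The synthetic phantom establishes *internal correctness*: thresholds,
connectivity, sphere geometry, half-max segmentation, bootstrap
resampling and likelihood maximisation do exactly what their
definitions say, because every expected value is either constructed or
recomputed by an independent brute-force oracle. It does **not**
establish performance on scanner data: real PET has non-Gaussian
correlated noise, reconstruction and partial-volume effects,
physiological uptake far more varied than two compartments, and
lesions that are neither spherical nor homogeneous. In particular,
exact MTV recovery is a property of whole-voxel homogeneous lesions;
on real data, half-max segmentation is known to depend on contrast and
lesion size. Claims about real-world detector accuracy or prognostic
value require real cohorts; this package supplies the verified
machinery for making such claims, not the claims themselves.

## 10. Known limitations

- No DICOM ingestion or SUV computation from raw activity; inputs are
  already SUV NIfTI volumes.
- Reference-region masks are inputs; there is no automatic blood-pool
  or liver VOI placement.
- No partial-volume correction; the half-max MTV of small blurred
  lesions is biased in the direction the blur dictates.
- The detector simulator models classification of threshold-found
  foci, not free-form segmentation; false positives can only arise on
  existing physiological foci (plus unmatched candidate rows when an
  external read supplies them).
- The bootstrap Gauss test's small-sample and boundary behaviour is as
  described in §5; prefer n ≳ 100 patients for calibrated CPE
  comparisons.
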