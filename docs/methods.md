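# Methods

This note documents the models and procedures implemented in `aoqc`, the
assumptions behind them, the defaults and their units, and the numerical
conventions that affect results. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Grading model

A *patch* is one 50 × 50 µm sampling window of an AO-FIO cone-mosaic image
(65 × 65 px at the default pixel scale of 50/65 ≈ 0.769 µm/px). Quality is
an ordinal category:

1. **truncated** — strictly more than 5% of the patch area lies outside
   the imaged mosaic (blank pixels). The bound is strict at 0.05: a patch
   with exactly 5% truncation falls through to the category-2/3 rules.
2. **poor** — within the 5% truncation bound, but cones are unresolvable
   in at least one quadrant of the patch.
3. **acceptable** — resolvable cones in all four quadrants.

Categories 1 and 2 are unusable for quantitative cone analysis; category 3
is usable. The category-1 rule exists to catch windows that were cropped
automatically from the edge of a stitched mosaic.

## LAPE focus metric

The energy-of-Laplacian score of a patch is

    LAPE = C · mean[ (K * I_norm)² ]   over valid response pixels,

where `K` is the 3 × 3 five-point Laplacian `[[0,1,0],[1,−4,1],[0,1,0]]`
(the 8-neighbour variant is available as a config option), `I_norm` is the
patch rescaled multiplicatively so its mean intensity equals 0.5, and `C`
is a fixed calibration constant. Conventions:

* **Boundary rule.** The energy mean runs over *valid* convolution
  positions only — no padded border responses. The same principle covers
  mosaic-blank regions: pixels at exactly the blank level (default 0) are
  excluded from the brightness statistics, and any 3 × 3 neighbourhood
  touching one is excluded from the energy. Without this, the artificial
  step edge between mosaic content and blank area dominates the score and
  truncated patches would paradoxically score *highest*; with it, a
  truncated patch is scored on its remaining mosaic content. On patches
  without blank pixels the masked and unmasked definitions coincide
  exactly.
* **Normalization.** Multiplicative mean-matching (not histogram
  equalization). This makes the score invariant to multiplying the input
  by any positive constant, so exposure differences between acquisitions
  cancel.
* **Calibration.** `C = 570` maps the mean per-pixel energy onto the
  instrument's 0–75 scale. The constant was frozen once against the
  default synthetic cohort: the 99th percentile of cohort scores sits at
  75. Sharp, low-eccentricity (dense) mosaics span the upper part of the
  range; mid-eccentricity pristine patches sit around 20–35. Scores above
  75 are possible for unusually dense, sharp mosaics and are not clipped.
  Only ordinal behaviour of the score is meaningful across
  implementations; the absolute scale is instrument- and
  convention-specific.

Under Gaussian defocus the score decreases monotonically on cone-mosaic
content (verified on seeded fixtures for sigmas 0–4 µm); additive noise
sets a score floor because white noise carries Laplacian energy.

## Threshold classifiers on the LAPE score

Both classifiers consume the scalar score only.

**Linear rounding.** Ordinary least squares of the numeric category
(1, 2, 3) on the score; prediction is the fitted value rounded to the
nearest category (ties x.5 round half-up — fixed for determinism) and
clamped to [1, 3]. The implied score-axis boundaries are
`(1.5 − b)/a` and `(2.5 − b)/a`; by construction they are equidistant
(spacing `1/a`), which is the model's structural limitation.

**Random forest + probability curves.** A 1,000-tree classification
forest (scikit-learn, seeded, single feature) provides class
probabilities on the grid 0–75 in 0.1 steps (751 points). Each class
curve is Loess-smoothed (span 0.3 of the grid, local linear, clipped to
[0, 1] but not renormalized so each curve stays a smooth function of its
raw curve). Cut points are the curve intersections: `t12` is the first
grid position where the class-2 curve rises above class-1's, `t23` the
last where class-3 rises above class-2's, linearly interpolated between
grid points; first/last keeps the bands contiguous when sampling noise
produces multiple crossings. A score equal to a cut point goes to the
middle band, consistent with strict outer bands ("< t12", "> t23").

**Threshold-recovery study design.** The recovery experiments draw
n = 3,000 scores as class-conditional Gaussians (sd 3) centered *inside*
planted bands [0, 8), [8, 35), [35, 75], with class mix
(0.30, 0.55, 0.15) and centers (3.5, 14.5, 54.0). The centers and mix are
not arbitrary: because the rounding classifier can only represent
equidistant cuts, the class geometry must make the planted cuts (8, 35)
expressible by both families. The chosen design was derived analytically
(closed-form OLS solution and Gaussian posterior-crossing formula) before
any recovery experiment was run; it puts the analytic Bayes crossings at
(8.50, 34.55) and the analytic OLS boundaries at (7.21, 35.54). Scores
are clipped to [0, 75] (the metric is nonnegative); the clip affects
~4% of class-1 draws and shifts the analytic values negligibly. The
Bayes-rate reference classifier for this design is banding at the
analytic crossings.

**Training discipline.** All train/validation splits are by *subject*,
never by patch, and cross-validation folds are subject-stratified:
patches within a subject share covariates and acquisition conditions, and
a patch-level split would leak that correlation into validation scores.

## Compact CNN

Architecture (config-driven): conv–ReLU–2×2-maxpool blocks followed by
dense layers and a 3-way softmax. The default stack is (32, 32, 64)
filters with 5 × 5 kernels and a dense-64 head — a standard small-image
classification baseline sized for 65 × 65 grayscale input. The validation
experiments use a lighter (16, 16, 32)/dense-32 variant of the same
family, which reaches the same decisions on the synthetic cohorts at a
fraction of the cost; problem sizes are listed below.

* **Input conditioning**: larger patches are center-cropped to 65 × 65
  (odd surpluses trimmed bottom/right); smaller ones mirror-padded
  (numpy `symmetric`, odd deficits padded bottom/right; padding iterates
  for patches smaller than half the target). The operation is idempotent
  at the target size.
* **Standardization**: per-patch z-score, so inter-clinic brightness and
  contrast offsets do not dominate the filters.
* **Optimization**: SGD with momentum 0.9, learning rate 0.01, batch 64,
  cross-entropy with inverse-frequency class weights (the default cohort
  is ~56% category 2), at most the configured number of epochs with early
  stopping on a held-back monitoring subset (10%, split by subject when
  subject ids are provided); the weights from the best-monitored epoch are
  restored.
* **Implementation**: pure numpy. Convolutions are im2col + BLAS matmul
  (float32), the input gradient is computed as a convolution with
  spatially flipped weights, and max-pool gradients are split across tied
  maxima so gradient mass is conserved. Training is deterministic given
  the config seed.

## Agreement machinery

* **Adjudication**: unanimity or majority decides; a full three-way split
  falls to the designated senior grader. This is a computational stand-in
  for the facilitated consensus discussion used with human graders, which
  is not computable; a `flag` mode raises instead so such patches can be
  routed to manual review.
* **Cohen's κ**: unweighted, `κ = (p_o − p_e)/(1 − p_e)` with chance
  agreement from marginal products. Unweighted is the deliberate default
  despite ordinal categories (a weighted variant would change reported
  agreement); the degenerate case `p_e = 1` (both raters constant and
  identical) is defined as κ = 1 when agreement is perfect and is an error
  otherwise. The implementation is cross-checked against
  scikit-learn's `cohen_kappa_score` in the tests.
* **Confusion/accuracy**: 3 × 3 counts, rows = reference standard;
  accuracy = 100 · trace/total.
* **Kruskal–Wallis**: tie-corrected H with the chi-square approximation
  (scipy), for testing score separation across categories.

## Quality-factor regression

Binary logistic regression of *poor* (category 2 = 1) versus *acceptable*
(category 3 = 0); category-1 patches carry no usable content and are
excluded before fitting. Covariates enter jointly: healthy-vs-diseased
indicator, eccentricity (degrees, one linear term pooling meridians), age
(years), axial length (mm), spherical equivalent (D), ETDRS letter score,
BCEA63 (deg²). Effects are odds ratios `exp(β)` with Wald 95% CIs
`exp(β ± 1.96 SE)`. The fit is plain maximum likelihood (statsmodels
Logit); subject-clustered robust standard errors are available via
`cov_type="cluster"` because patches within a subject are correlated, but
are off by default — in the synthetic cohorts outcomes are conditionally
independent given the covariates, so the plain Wald intervals attain
nominal coverage (verified by the 100-replicate coverage study).

Frequency summaries: per-(eccentricity, group) fraction of category 2
among categories {2, 3}, restricted to eccentricities ≤ 10°; and
per-subject fraction poor, with the cohort share of subjects at or above
0.5 ("half or more images poor" — the boundary is inclusive).

## Synthetic cone-mosaic generator

The generator stands in for clinical data that cannot be redistributed.
One patch is rendered as:

1. hexagonal cone lattice at the requested center-to-center spacing with
   uniform ±20%-of-spacing jitter per axis (candidates within 0.6 spacing
   of an accepted cone are re-drawn up to 3 times) — a cheap quasi-regular
   mosaic without a packing simulation;
2. cones as isotropic Gaussian reflexes (FWHM 0.6 × spacing), amplitudes
   lognormal with the requested CV — a phenomenological stand-in for
   Stiles–Crawford reflectance variability — over a diffuse background
   (0.15);
3. per-quadrant degradation: cone amplitude × 0.05 and doubled blur in
   that quadrant (the 0.05 suppression factor is a stand-in for
   "unresolvable to a grader" and is config-exposed);
4. global Gaussian blur (µm), additive Gaussian noise (sd relative to the
   maximum), clipping to [0, 1];
5. truncation as a blanked (exact zero) vertical strip from the left
   edge, making the blanked area fraction exact.

The planted category is a pure function of the parameters (the grading
rules above, with "blurred beyond resolvability" meaning psf sigma
> 2.5 µm, a Rayleigh-like limit for an instrument that cannot resolve
2 µm structure). `generate_patch` is bit-reproducible given its
parameters, which include the seed.

**Cohort defaults** (the study conditions for all validation
experiments): category mix (0.20, 0.56, 0.24); subject groups
healthy/DSM/HCQ in proportions (0.56, 0.22, 0.22) with group-specific
covariate distributions (age 55 ± 17 / 62 ± 18 / 59 ± 7 y; axial length
24.0 ± 0.9 / 23.3 ± 1.0 / 23.1 ± 0.8 mm; acuity 90 ± 5 / 83 ± 8 / 87 ± 5
letters; refraction 0 ± 1.8 / −0.5 ± 1.1 / 0.9 ± 1.8 D; BCEA63 around
1.1 / 1.2 / 2.9 deg²); cone spacing 2.5 + 0.55·eccentricity µm (≈3 µm
near the fovea to ≈8 µm at 10°); reflex CV 0.3; noise sd 0.03.
Degradations per category: category 1 = truncation U(0.08, 0.40) plus
defocus U(2.5, 4.0) µm (montage-edge acquisitions are both cut off and
poorly focused); category 2 = with probability 0.85 one to three
unresolvable quadrants on defocus U(1.2, 2.4) µm, otherwise global
defocus U(2.5, 3.0) µm, either way truncation U(0, 0.04); category 3 =
defocus U(0, 0.8) µm. These values were calibrated once, during generator
design, so that the synthetic cohort reproduces the qualitative behaviour
of graded clinical data — focus scores ordered by category with
substantial category-2/3 overlap, score banding achievable at roughly
70–75% accuracy, and a lower cut near 7 — and frozen thereafter. A
`scene_for_category_clear` sampler (≥2 degraded quadrants, near-pristine
category 3, ≥15% truncation) provides well-separated cohorts for recovery
experiments where the planted structure should dominate.

Among untruncated patches, the probability of category 2 follows a
planted logistic model in the covariates (defaults: disease OR 5.2,
eccentricity OR 1.03/degree, age OR 1.03/year, all others null), with the
intercept calibrated by root-finding so the realized category-2 share
matches the mix. Category 1 is assigned independently of covariates
(mosaic-edge windows are a geometry accident, not a biology effect).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: rod photoreceptors and vessel shadows; optical
wavefront structure (blur is isotropic Gaussian); spatially correlated
noise and frame-registration artifacts; within-subject correlation of
image quality beyond the planted covariate effects; drusen, debris or
RPE reflexes that mimic cones. Accuracies measured on synthetic cohorts
validate the *machinery* (metrics, classifiers, statistics), not clinical
performance.

## Validation experiment sizes

Chosen as the package's standard desk-scale study sizes:

* threshold recovery: n = 3,000 train + 3,000 held-out scores;
* grader comparison: 30 subjects × 30 patches (moderate-overlap sampler),
  60/40 subject-wise split, light CNN ≤ 8 epochs;
* CNN recovery: 50 subjects × 30 patches (clear sampler), 70/30
  subject-wise split, light CNN ≤ 6 epochs, plus a label-shuffled control
  evaluated as *balanced* accuracy (mean per-class recall) — on an
  unbalanced cohort plain accuracy of an uninformed predictor equals the
  prevalence of whichever class it collapses to, whereas balanced accuracy
  is 1/3 for any uninformed predictor;
* factor recovery: 40 subjects × 200 patches (8,000 rows, labels only),
  100 replicates for CI coverage;
* agreement null checks: n = 10,000 label pairs.

## Numerical choices and degenerate inputs

* Rounding ties in the linear classifier: half-up (`floor(x + 0.5)`).
* Loess span 0.3 over the 751-point grid; smoothing is applied to raw
  forest probabilities per class.
* Scores exactly at a threshold classify as category 2.
* All-blank patches cannot be focus-scored (error; callers should grade
  them category 1 via the truncation rule).
* Constant-score training data is a fit error; training data missing any
  category is a data error.
* `p_e = 1` kappa handling as above; empty confusion matrices are domain
  errors.
* Axial length must exceed 1.82 mm (the formula's zero point) — the
  magnification factor must be positive.
* Seeds: every stochastic routine takes an explicit integer seed;
  identical seeds give bit-identical outputs (the CNN is deterministic to
  float32 round-off).

## Known limitations

* The absolute LAPE scale depends on kernel, boundary and normalization
  conventions; only ordinal comparisons transfer between implementations.
* The linear rounding classifier cannot represent bands of unequal width
  relative to its slope; its implied boundaries are reported so the
  limitation is visible.
* The adjudication tie-break (senior grader) is a simplification of a
  human consensus process.
* Unweighted κ ignores the ordinal structure of the categories.
* The factor regression treats patches as independent given covariates;
  for real data with subject-level random effects the clustered-SE option
  should be preferred.
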