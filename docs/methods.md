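# Methods

This note records the models, conventions and numerical choices behind
`dkihabitat`, and what the synthetic-data tests do and do not demonstrate.

## Habitat partition

**Otsu thresholding.** For each map (MD, MK) the ROI voxels of the whole
cohort are pooled and the data range is split into 256 equal-width bins.
Every interior bin boundary is scored by the between-class variance of the
exact data split (values strictly below the boundary versus the rest) —
equivalent to minimizing within-class variance — and the maximizing boundary
is returned, ties broken toward the lowest threshold. Scoring the exact
split rather than histogram-bin approximations makes the output identical to
an exhaustive search over boundaries, which the test suite verifies. A
constant input has no threshold and raises a degenerate-input error.

Pooling uses ROI voxels only (configurable). The features are
ROI-restricted, so thresholds estimated from the same distribution keep the
partition and the features commensurable; whole-brain pooling would mix in
tissue the features never see.

**Quadrant rule.** Within the ROI: MD < t_MD and MK < t_MK → LL; MD < t_MD,
MK ≥ t_MK → LH; MD ≥ t_MD, MK < t_MK → HL; both ≥ → HH. Values exactly
equal to a threshold go to the "high" class; this matters because Otsu bin
edges can coincide with data values. The first letter of a label is the MD
level, the second the MK level. By construction the mean MK over LH voxels
is at least t_MK and exceeds the LL mean — the "cellular tumor" habitat is
the high-kurtosis one.

**Features.** Per subhabitat: arithmetic mean MD (10⁻³ mm²/s), mean MK
(dimensionless), volume in mL (voxel count × |det| of the affine's spatial
part / 1000), and percent of ROI voxels — 16 features per subject, in the
fixed order (LL, LH, HL, HH) × (MD, MK, volume, percent). An absent
subhabitat has volume and percent 0 and *missing* means; downstream
modelling imputes missing means with 0 and records an imputation mask, so
"no such tissue" is representable without inventing a diffusivity. Volume
percent always sums to 100 over the four labels when the ROI is non-empty.

**Reference thresholds.** MD 1.71 × 10⁻³ mm²/s and MK 0.58 are packaged as
`STUDY_THRESHOLDS` for scoring single subjects without a cohort. They are
documented constants from the source cohort, not reproducible from
synthetic data; 10⁻³ mm²/s is the only unit in which 1.71 is a physiologic
diffusivity.

**Inter-observer agreement.** `icc_agreement` computes, per feature, the
two-way random-effects absolute-agreement single-measure ICC (via pingouin),
with a 0.60 retention floor. A consistency variant (insensitive to a
constant rater offset) is available for diagnosing *why* agreement is low.

## Clinical statistics

Categorical signs are compared between IDH classes with the Pearson
chi-square test **without** continuity correction — the choice that
reproduces the reference characteristics table to three decimals — on the
levels actually present in the cohort. Quantitative variables use the
pooled-variance t test when both classes pass Shapiro–Wilk at α = 0.05,
otherwise the Mann–Whitney U test (exact null for ≤ 20 untied observations
per group, tie-corrected normal approximation with continuity correction
otherwise). p-values are formatted to three decimals, "<.001" below 0.0005.
The asymptotic chi-square p is checked against a permutation mid-p in the
suite with an absolute 0.02 tolerance: the permutation null is discrete, so
Monte-Carlo-precision agreement is not attainable on 100-subject tables, but
the check still rules out a misapplied correction.

## Correlation analysis

All 120 feature pairs get a product-moment coefficient with a two-sided p,
computed on pairwise-complete observations (absent subhabitats create
missingness); each cell records its effective n, and cells with fewer than
3 complete pairs or a zero-variance margin are missing. The
high-correlation rule flags |r| > 0.6 — magnitude, since strong negative
correlations are equally "high" — and non-significant cells (α = 0.05) are
classed "none".

## Model harness

Each of the 32 pipelines is scaler → reducer → selector → classifier, refit
from scratch on every LOOCV training fold (n−1 subjects); the held-out
subject receives a probability from a model its label never touched.
Training metrics come from the full-data fit, matching a design where all
subjects form the training group and LOOCV provides internal validation.

* scaling: per-fold z-score fit on training subjects only;
* reducers: PCA retaining 95% cumulative variance, or pairwise Pearson
  decorrelation dropping the later feature of any pair with |r| > 0.85
  (canonical feature order, so the earlier feature survives);
* selectors: one-way ANOVA F, Kruskal–Wallis H, ReliefF (k = 5 nearest
  hits/misses, range-normalized Manhattan distance), and RFE wrapping the
  pipeline's own linear classifier; the selected count k is capped at the
  post-reduction width, which varies per fold under PCA;
* classifiers: logistic (L2), L1 logistic, linear discriminant analysis,
  linear-kernel SVM with Platt-calibrated probabilities.

The best pipeline is the highest validation (LOOCV) AUC, ties broken by
fewer selected features, then enumeration order. The retained-feature count
is swept (default 1..min(p, 20)) jointly with the pipeline; the acceptance
script fixes k = 4 to keep a 103-subject, 32-pipeline run in minutes on one
CPU.

**Three models.** ClinicRad = best pipeline on the coded clinical and
morphology covariates; H-MRI = best pipeline on the 16 habitat features;
HANDINESS = near-unpenalized logistic regression (C = 10⁶) on {age,
necrosis, hemorrhage, location, calcification, H-MRI, edema}, where H-MRI
is each subject's **held-out** LOOCV probability — never an in-fold fit.
The suite verifies this with a leakage check: on label-free random features
and covariates the integrated model's held-out AUC stays at chance. The
HANDINESS logistic is itself validated by LOOCV over subjects, holding the
H-MRI inputs fixed.

**Covariate coding.** The published formula does not state its coding. The
package default — binary signs present/yes = 1; location ordinal
frontal/insula = 0, other = 1, basal nucleus/corpus callosum = 2 (ordered by
wild-type enrichment); edema ≤ 1.5 cm yes = 1 — is an explicit, configurable
convention, not an inference of the original one. Some published
coefficient signs (necrosis −0.65 despite necrosis being commoner in
wild-type tumors) hint that the original coding differed; this is why the
coding table is exposed rather than hard-wired.

**Youden threshold.** The operating threshold maximizes sensitivity +
specificity − 1 over observed probabilities, calls being prob ≥ threshold,
ties broken toward the lowest qualifying value. The published decision
cutoff 0.38 ships as a reference constant.

## Evaluation battery

* ROC AUC by the rank (Mann–Whitney) formulation with 0.5 credit for ties;
  it equals U/(n₁n₀) by construction, a cross-module identity the suite
  asserts on random data.
* PR-AUC as the area under the step curve traversed from the highest score
  (average precision).
* Bootstrap CIs: stratified per-class resampling, 1000 replicates,
  percentile 2.5/97.5 interval, seed recorded. Percentile rather than BCa:
  simpler, and its coverage on binormal AUC data (≈ 0.95–0.97 at n = 100)
  is verified by simulation in the suite.
* DeLong: classic structural-components covariance, two-sided normal p;
  identical score vectors return p = 1.
* IDI = difference in discrimination slopes; NRI defaults to the continuous
  (category-free) variant — no risk-category cut points are established for
  this problem — with a categorical option taking explicit cut points. Both
  are antisymmetric and carry stratified bootstrap CIs.
* Calibration: equal-frequency decile bins (duplicate quantile edges
  merged) of mean predicted vs observed rate, plus the Brier score.
* Decision curves: NB(pt) = TP/n − (FP/n)·pt/(1−pt) on a 0.01–0.99 grid
  (step 0.01) with treat-all and treat-none references.

## Synthetic cohort

The generator emulates the study conditions, not any particular tumor:

* **Cohort**: 103 subjects, IDH-mutant fraction 47/103. Clinical and
  morphology variables are drawn per class at the reference cohort's
  empirical prevalences; ages are normal (mutant 46.83 ± 10.70, wild-type
  57.29 ± 10.70 years). `table1_fixture()` instead reproduces every
  categorical cross-tabulation *exactly*, with ages affinely adjusted to the
  printed moments — categorical counts are exact, ages synthetic, and
  variables are assigned independently because a printed table constrains
  margins, not the joint distribution.
* **Geometry**: nested ellipsoids — LH core (6-voxel radius), LL shell (10),
  HL outer shell (14, defining the ROI) and a 3-voxel HH pocket offset into
  the shell — on a 40³ grid of 1.5 mm isotropic voxels. The spatial
  arrangement of real subhabitats is unknown; this layout is a stand-in that
  lets all four labels coexist and makes absence simulable by dropping a
  component. The HH pocket is absent with probability 15/47 (mutant) and
  8/56 (wild-type), the HL shell with 0/47 and 5/56.
* **Intensities**: per-habitat bivariate normals with means symmetric about
  MD 1.71 / MK 0.58 (LL 1.15/0.35, LH 1.15/0.81, HL 2.27/0.35, HH
  2.27/0.81), voxel SDs 0.15 (MD) and 0.07 (MK), and MD–MK correlations
  following the reported per-habitat pattern (LL ≈ 0, LH −0.666, HL 0.665,
  HH 0.999). Wild-type subjects get +0.06 on the high-density (LH/HH) MK
  means — a modest class signal consistent with denser wild-type tumors.
  Between-subject variation enters as a tumor-wide mean offset shared by all
  habitats (SD 0.06 MD / 0.04 MK) plus independent per-habitat offsets (SD
  0.05 / 0.04), so habitat means co-vary across subjects and no two
  subjects are identical.
* **Determinism**: every subject consumes an RNG stream keyed by
  (seed, subject index, stream), so cohorts are bit-identical given the
  seed and independent of generation order.

What passing tests on this cohort show: the partition, feature extraction,
correlation machinery, harness and statistics behave correctly on data with
the assumed structure, and cohort-level Otsu recovers the configured class
boundaries (within 0.1) when habitats are separated. What they do not show:
performance on real gliomas — real maps have partial-volume voxels, spatial
noise correlation, non-ellipsoidal anatomy, registration error and
rater-dependent ROIs, none of which are modelled. Published AUCs
(0.951/0.938 for the integrated model) require the original 103-subject
image cohort and are therefore reference documentation, not test targets.

The coefficient-recovery simulation draws covariates at the pooled
reference prevalences, H-MRI uniform on [0, 1], outcomes Bernoulli from the
packaged formula, and refits by maximum likelihood (statsmodels). At
n = 2000 each refit coefficient is expected within ~2 standard errors of
truth; with eight coefficients the maximum |z| hovers near 2 and is
seed-dependent, which is the expected sampling behaviour, not a defect.

## Problem sizes and runtime

The test suite runs desk-scale: 100-phantom property sweeps, n = 60 DeLong
comparisons, a 500-dataset bootstrap-coverage simulation (n = 100, 500
replicates per CI), the full 103-subject cohort for threshold recovery, and
n = 2000 for coefficient recovery — about two minutes on one CPU. The
acceptance script runs the 32-pipeline harness on the 103-subject synthetic
cohort at a fixed selector width (k = 4), roughly 100 seconds.

## Known limitations

* The ellipsoid geometry cannot probe partial-volume or topology effects.
* DKI fitting, registration, bias correction and ROI drawing are upstream
  of this package; it consumes finished parametric maps.
* The 0.85 decorrelation scan and ReliefF are order- and k-dependent by
  design; both conventions are documented above and fixed by default.
* `SVC(probability=True)` internal Platt calibration adds its own CV split;
  probabilities from the linear-SVM pipelines are therefore slightly
  seed-dependent in the third decimal, which the fixed seeds absorb.
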