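# Methods

This note documents the models and procedures implemented in `hemispan`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic data generator does and does not emulate.

## Voxel-level metrics

Both metrics operate on a masked `(n_voxels, n_timepoints)` series
matrix with per-voxel hemisphere labels and geometric-mirror indices.
Two hemisphere conventions exist: `index_midline` (first array axis
split in half; the convention of the synthetic grids, which are
symmetric by construction) and `world_x_sign` (left means world-space
x < 0 under the NIfTI affine; mirrors are nearest in-mask voxels of the
reflected coordinate; exact-midline voxels are excluded and counted).

**Autonomy Index.**  `AI(v) = Ni/Hi − Nc/Hc` with `Ni`/`Nc` the counts
of "significantly connected" ipsilateral/contralateral voxels and
`Hi`/`Hc` the hemisphere totals.  Two conventions are deliberately
configurable because common usage underdetermines them:

* *Significance threshold* (`sig_threshold`, default: the positive
  critical Pearson r for two-tailed p < 0.05 at the series length,
  ≈ 0.16 at 150 timepoints).  Per-pair significance is the most natural
  reading of "significantly connected"; an `use_absolute` variant counts
  strong negative correlations too.
* *Self-pair handling* (`exclude_self`, default True): the self voxel is
  excluded from both `Ni` and `Hi`.  Note that on an exactly
  mirror-symmetric volume this convention leaves a residue of at most
  `1/H` per voxel (the voxel's contralateral copy counts into `Nc` while
  the self is excluded ipsilaterally); with `exclude_self=False` the
  symmetric case is exactly zero.  Both behaviors are tested.

**CFH.**  The functionally homotopic partner of `v` is the contralateral
voxel with the highest functional connectivity; because connectivity is
itself the Pearson correlation, CFH equals the maximum contralateral
correlation and is implemented as such (the partner index is retained;
ties break to the smallest voxel index).  `CFH(v) ≥ r(v, mirror(v))`
always — the maximum dominates any single member, including the
geometric mirror.

**Normalization.**  CFH values pass through the Fisher r-to-z transform
(variance stabilization appropriate for correlations), then both metrics
are z-scored over the mask to mean 0, SD 1.  AI is not a correlation and
skips the Fisher step.  Normalization precedes all group comparison.

## Group statistics

Voxel-wise OLS of the normalized metric on
`[intercept, group, age, sex, education]`; the group t statistic is the
group coefficient over its standard error, df = n − rank(design).  With
no covariates and two groups this reduces exactly to the classical
pooled-variance two-sample t (tested).

**Smoothness.**  FWHM per axis is estimated from the variance `v` of
spatial derivatives of the unit-normalized residual images, with a
Gaussian-autocorrelation correction `λ = −2 ln(1 − v/2)` (for an exact
Gaussian kernel this inverts the finite-difference bias; a 2-voxel
kernel is recovered without bias, and unsmoothed white noise yields
sub-voxel estimates).

**GRF cluster correction.**  Voxels are thresholded at the two-tailed
critical |t|; positive and negative excursion sets are labelled
separately (26-connectivity, configurable to 6/18) and each tail is
analyzed one-tailed at half the nominal cluster level, consistent with
reporting signed peaks.  Cluster-level p uses the classical
random-field-theory approximation: expected cluster count from the 3D
Euler-characteristic density at the Gaussianized height threshold,
expected suprathreshold volume, and an exponential approximation of the
cluster-extent distribution,
`P = 1 − exp(−E[m] · exp(−β k^{2/3}))`.  The FWHM entering the resel
count is floored at one voxel: sampled fields carry no sub-voxel
smoothness information and the continuous approximation degenerates
below it (extent-1 clusters would otherwise become "significant" on
rough maps).  RFT cluster inference assumes smooth fields; the pipeline
therefore smooths metric maps by a 2-voxel-FWHM Gaussian before the
group GLM (`map_smoothing_fwhm`, set 0 to disable).  Measured
family-wise false-positive rate on 500 smooth null fields at nominal
0.05: ≈ 0.04–0.05.

A max-cluster-extent permutation procedure (group relabeling, both tails
pooled into one null) serves as the model-free oracle; GRF and
permutation decisions agree 20/20 on planted blobs of ~5× the smoothed
noise SD.

**Demographics and power.**  Group comparisons dispatch on Shapiro–Wilk
normality at 0.05 (t test vs Mann–Whitney U, branch reported);
categorical tables use the Pearson chi-square without continuity
correction (df = 1); post hoc power uses the noncentral t with
noncentrality `d·√(n1·n2/(n1+n2))` — at d = 0.5, α = 0.05, 42 vs 45 this
gives 0.6346 (cross-checked against statsmodels).  Clinical associations
use Spearman rank correlation (two-tailed t approximation).

## Transcriptome–neuroimaging association

Preprocessing mirrors the standard microarray-to-parcellation chain:
probes below background in more than half of the samples are dropped
(exactly 50% survives); one probe per gene is kept by maximum mean
inter-probe correlation of regional profiles (ties to the smallest probe
id); samples are assigned to the parcel of their containing voxel, else
the nearest labelled voxel within 2 mm Euclidean distance (equidistant
ties to the smaller label); expression is normalized by a scaled robust
sigmoid — `1/(1+exp(−(x−median)/IQR))` rescaled to [0, 1].

**PLS1.**  With a univariate response the first PLS weight vector is the
normalized covariance `X'y` of standardized predictors; scores are
`X·w`; explained variance equals corr(scores, y)² exactly (identity
tested to 1e-9); the sign convention fixes corr(scores, y) ≥ 0.  Only
the first component is computed.

**Spin permutation.**  Region centroids are projected radially onto a
unit sphere about their mean; each iteration applies a Haar-uniform 3D
rotation and reassigns regions greedily by ascending distance without
replacement, yielding a bijection that preserves the value multiset and
the broad spatial autocorrelation.  Coplanar centroid sets fall back to
plain label permutation with a warning.  p = (1 + #{null ≥ obs})/(1 + n)
one-tailed; the two-tailed variant doubles the smaller tail.  The
statistic function is injectable, so either the response map or the
score map can be spun.

**Bootstrap gene Z.**  Regions are resampled with replacement (resamples
with fewer than three distinct regions are redrawn); each replicate's
loading vector is sign-aligned to the original before the per-gene SD is
taken.  The bootstrap operates on the *unnormalized* covariance loadings
`X'y`: renormalizing inside every resample deflates the per-gene SE by
up to √2 under weak signal (the resampled norm absorbs part of the
fluctuation), which inflates null Z scores (SD ≈ 1.45 instead of ≈ 0.95)
and floods the FDR sets with false discoveries.  Z values share the sign
pattern of the sign-fixed PLS1 weights.  Two-tailed normal p values
under Benjamini–Hochberg FDR (q = 0.05) split significant genes into
positive and negative sets; the reported cutoffs are the smallest |Z|
per sign, treated as outputs of the procedure rather than constants.
At the planted benchmark (45 regions, 500 genes, 10 genes coupled at
r = 0.8, 1000 bootstrap iterations) the positive set attains median
recall 1.0 and median false-discovery proportion ≈ 0.09.

## Receptor-density correlation

A voxel-wise t map is averaged within atlas parcels; each regional
density map is compared by Spearman correlation (density units enter
only through ranks) with a two-tailed spin p.  Significance control
defaults to `bonferroni_mode="family"`: the 0.001 threshold is treated
as the already-adjusted per-test level.  Rationale: a finite spin null
of 5000 iterations has a minimum two-tailed p of 2/5001 ≈ 4×10⁻⁴, so a
divided threshold 0.001/39 could never be reached for a 39-map battery —
only the per-test reading is operable.  The `per_test` division is
available as a flag.  At 90 regions with four maps planted at Spearman
0.6 and six at 0, the battery detects ≈ 90% of planted maps with no
false flags (5000 spins).

## Discrimination

Subjects are classified from region-wise metric features by an RBF SVM.
Hyperparameters follow the libsvm powers-of-two convention
(C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, step 4× by default).  Every (C, γ) pair is
evaluated by leave-one-out cross-validation with feature
standardization refit inside each training fold (no leakage — the
training-fold mean/SD are applied to the held-out subject).  The best
configuration maximizes LOOCV accuracy, ties broken by AUC then smaller
C.  AUC uses the rank (Mann–Whitney) formulation with tie correction.
Single-feature classifiers (one per region) and the combined model are
both emitted.

Note a known small-sample artifact: under chance-level features a fixed
configuration yields LOOCV AUC systematically *below* 0.5 (each held-out
subject's class is the training minority and the underfit SVM behaves as
a majority vote); grid search's optimistic selection offsets this, and
the grid-searched permuted-label mean AUC sits near 0.5 (tested within
±0.1 at n = 50).

**Exact Shapley values.**  The value of a feature coalition S for a
subject is the mean decision output over the background set (all
training subjects — the interventional expectation) with the subject's
values substituted in the S columns; Shapley values enumerate all 2^d
coalitions with the standard combinatorial weights (d ≤ 12; the analysis
uses 4).  Efficiency (Σφ = decision − baseline), symmetry and the dummy
axiom hold to numerical precision; linear decision functions reproduce
the closed form `φ_j = w_j (x_j − mean background_j)`.  SHAP is computed
on a model refit to all subjects at the best hyperparameters (per-fold
attribution is available by calling `exact_shap` per fold).

## Synthetic data: what it emulates and what it does not

The generator plants exactly the structure the analysis assumes:

* **Homotopic coupling** via one shared latent per mirror pair with
  loading √ρ, giving expected mirror correlation ρ in closed form.
  Default baseline ρ = 0.5, the middle of the conventional 0.4–0.6 band
  for resting-state homotopic correlation (no empirical level is
  available for the emulated cohort).
* **Homotopic (CFH) effects**: the patient-group pair loading rises to
  ρ + shift in the flagged region.  Because the shift is a pair
  property, both the region and its mirror are elevated; the recorded
  truth lists both labels, and localization checks accept either.
* **Autonomy (AI) effects**: a region-wide latent added to one
  hemisphere only in patients raises within-hemisphere connectivity
  (Ni) without touching Nc.  This manipulation is near-deterministic at
  the default loading (0.25 variance share), so planted-AI group
  differences are far stronger than anything seen in real data — useful
  for recoverability testing, not for effect-size realism.
* **Clinical table**: vision and disease duration are log-normal
  (σ = 1), so Shapiro–Wilk rejects normality at n = 42 with high
  frequency and the nonparametric branch is exercised; controls carry
  missing values for the disease-specific fields.
* **Expression tables**: coupled gene columns are
  `r·z(target) + √(1−r²)·noise` (expected Pearson r exactly), placed at
  random positions, under gene-specific affine scaling.
* **Receptor maps**: rank-blending with weight `w = 2 sin(πρ/6)` (the
  bivariate-normal inversion of the Spearman/Pearson relation) gives an
  expected sample Spearman ≈ ρ, exact monotone transforms at ρ = ±1.

Defaults fix the study conditions: 42 patients vs 45 controls, 150
timepoints, a 16×16×12 grid (midline on the first axis) with 8 parcels
per hemisphere.  Data are born "preprocessed": no scanner physics, head
motion, nuisance structure, spatial autocorrelation within hemispheres,
or registration error is simulated.  Consequences worth keeping in mind
when reading test results: within-subject z-scoring of metric maps makes
a strong planted increase in one region induce apparent *decreases*
elsewhere (a relative-scale effect that also exists in real normalized
maps); and at the desk-scale 8 left parcels the PLS spin test is
essentially uninformative (with genes ≫ regions PLS1 fits any spun
response nearly perfectly), so spin-test calibration and power are
established at 45 regions in the module tests instead.

## Problem sizes and numerical choices

Simulations run at sizes chosen to keep the full suite in minutes on one
CPU: 12×12×10 grids for field-level calibration (500 null fields for the
GRF family-wise rate; 20 seeds for concordance checks), 45 regions × 500
genes × 1000 bootstrap iterations for gene recovery, 90 regions × 5000
spins for the receptor battery, and cohorts of 12 + 12 for
planted-effect recovery.  The pipeline defaults keep the printed
analysis constants (5000 spins, 10000 bootstrap iterations, voxel
p 0.001, cluster p 0.05, FDR q 0.05, Bonferroni α 0.001).

Degenerate inputs fail loudly: zero-variance series name the voxel,
empty hemispheres and constant maps are rejected, rank-deficient designs
name the collinear columns, zero-IQR sigmoid normalization and
sub-minimum region counts raise.  Ties break deterministically
everywhere (smallest voxel index, smallest label, lexicographically
smallest probe id, smallest C).  All randomness flows through
`numpy.random.default_rng` seeds carried in configuration objects;
identical configuration and seed reproduce byte-identical artifacts and
manifests (NIfTI outputs are written uncompressed so digests are
stable).

## Known limitations

* RFT cluster p values are approximate at desk-scale grids and low
  smoothness; the permutation oracle is the fallback authority.
* The spin null on a handful of parcels has very low resolution; spin
  inference is only meaningful from a few dozen regions upward.
* The homotopic latent construction gives every mirror pair the same
  coupling within a condition; real data show graded regional profiles.
* Donor-level aggregation of expression data is out of scope; the
  transcriptomics stage consumes one pooled sample table.
* The bootstrap gene Z is approximately, not exactly, standard normal
  under the null (measured SD ≈ 0.94); FDR control is correspondingly
  slightly conservative.
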