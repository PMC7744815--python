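# Methods

This note records the scientific and numerical choices behind the package:
what each stage computes, which knobs matter, what the synthetic generators
do and do not emulate, and the known limitations.

## Feature extraction

All extraction is label-mask driven on the voxel grid.  Images are assumed
spatially normalized, so world-space geometry beyond the voxel size is
ignored and coordinates are 0-based grid indices.  A 4D functional series is
reduced to a single 3D volume before extraction; the reducer is configurable
(temporal mean by default, median available) because a resting-state series
must be summarized into one scalar volume before region texture is
meaningful.

### Texture set (43 per region)

* **Quantization.** Uniform min-max binning into `Ng = 32` levels,
  `level = 1 + floor(Ng (x − min)/(max − min))` clamped to `Ng`; a constant
  region maps to level 1.  Equal-probability (quantile) binning is available.
  `Ng` and the rule are configurable; 32 uniform levels is the common
  radiomics default for MR intensity maps.  A consequence asserted by the
  tests: all matrix-based features are invariant under strictly increasing
  affine intensity transforms, while the three first-order moments transform
  as moments.
* **First-order:** population variance, skewness, and Pearson (non-excess)
  kurtosis of the raw region intensities.
* **GLCM (9):** pairs at distance 1 pooled over the 13 unique 3D directions
  and both orders (one merged symmetric matrix, not per-direction
  averaging), normalized to probabilities: energy, contrast, entropy (bits),
  homogeneity, correlation, sum average, variance, dissimilarity,
  autocorrelation.
* **GLRLM (13):** maximal same-level runs per direction, pooled over the 13
  directions.  Run percentage is runs / (voxels x directions) so that a
  single direction on a single run of length L gives RP = 1/L.  SRE, LRE,
  GLN, RLN, RP, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLV, RLV.
* **GLSZM (13):** zones are 26-connected components of equal level; the
  matrix is normalized by the zone count.  SZE, LZE, GLN, ZSN, ZP, LGZE,
  HGZE, SZLGE, SZHGE, LZLGE, LZHGE (Σ p·i²·j²), GLV, ZSV.
* **NGTDM (5):** s_i sums |level − mean of in-region 26-neighbors| over
  voxels of level i that have at least one in-region neighbor; coarseness,
  contrast, busyness, complexity, strength per the standard neighborhood
  gray-tone difference formulas.

Merged-direction pooling (rather than averaging per-direction features) was
chosen because it is rotation-robust and matches the behaviour of the widely
used MATLAB radiomics texture toolboxes this feature set descends from.

**Degenerate values.** Features whose denominator vanishes (single-voxel
region, constant region, one occupied gray level) emit a configured sentinel
(0.0 by default; 1e6 for NGTDM coarseness, which diverges as texture
flattens) and a log record instead of aborting a cohort extraction.  One
deliberate deviation from a mechanical reading of "drop undefined t":
a feature constant within both groups but differing between them is a
perfect separator and is retained with p = 0 in the t-filter; only features
constant across all subjects are removed.

### Wavelet band-pass block (172 per region)

Single-level 3D discrete wavelet transform (`sym8`, symmetric boundary
extension), eight sub-bands; LLL and HHH keep weight 1 while the six mixed
band-pass sub-bands are multiplied by R before inverse transformation.
R = 1 reproduces the input to machine precision (asserted); R < 1 suppresses
and R > 1 amplifies band-pass content, so for a pure high-frequency
checkerboard the post-filter energy is monotone in R (asserted).  The whole
volume is filtered before masking — filtering a masked fragment would
corrupt region boundaries, and the tests pin this ordering.  Features are
extracted at R ∈ {1/2, 2/3, 3/2, 2}: 172 wavelet columns per region, 215
with the unfiltered pass, hence 116 × 215 = 24,940 structural columns.

### Diffusion

FA, MD, AD and RD maps are summarized as arithmetic means over the 50
white-matter tracts of the tract atlas (an input; no tract reconstruction is
performed): 200 columns.

### Column identity and order

Every column is a canonical key `modality|region|R|family|name`.  The fixed
order — modality block, region-major, R ascending (1/2, 2/3, 1, 3/2, 2),
family, name — makes tallies comparable across runs and is the tie-break for
every ranking in the pipeline.

## Stability selection

Features are first residualized on age, sex and education by OLS fit on the
full cohort (the adjustment precedes resampling by design; the mild
train/validation leakage this creates is accepted as part of the protocol
and noted here).  Subjects missing an adjustment covariate are dropped with
a logged count; constant covariates are dropped with a warning.

Each of `folds × repetitions` training resamples (stratified splits so both
classes appear in every fold; a degenerate split is redrawn and logged) runs:

1. **t-filter:** two-sided equal-variance t-test, keep p < 0.05.
2. **Decorrelation:** greedy scan in ascending-p order; keep a feature iff
   |r| ≤ 0.8 against every kept feature.  The keep-rule (smaller p wins) is
   a determinism choice aligned with the preceding filter; the kept set's
   maximum pairwise |r| ≤ 0.8 is verified post hoc in the tests.
3. **Branches:** Fisher score top-50 (population variances; zero-denominator
   features rank first as infinite separation, with a warning); L1 logistic
   regression (liblinear) with the inverse penalty chosen by inner
   stratified 5-fold CV minimizing summed deviance over a 5-point log grid
   `10^{-2..1}`, ties to the sparser model; mRMR top-50 with the difference
   criterion on tercile-binned features (plug-in mutual information).

Occurrence tallies are bounded by `folds × repetitions` (= 500 at the
default 5 × 100).  High-frequency = top-10 per branch (canonical-order
tie-break); stable = intersection of the three top-10 sets; the >300-count
overlap is computed from raw counts, not from the top-10 lists.  Fold
assignments and per-run selections are persisted so the classification stage
reuses exactly the same resamples; the three branches share fold splits.

## Classification and association

SVMs use standardization by training statistics, C = 1, and bandwidth
`gamma = 1/(p · Var(X))` for the rbf kernel; the random forest uses 500
trees with √p candidate features per split, seeded.  None of these are
data-tuned.  Sensitivity is recall on the case class, specificity on the
controls; a metric whose denominator is empty (a single-class evaluation
fold) is reported missing and excluded from the mean with a printed count,
never coerced to zero.  AUC is the tie-corrected normalized Mann–Whitney U;
orientation is reported as a flag (AUC plus direction) rather than silently
inverting, since features legitimately correlate with outcome in either
sign.  The combination score for several stable features is the linear
predictor of an unpenalized logistic fit on the same subjects (ridge
fallback, flagged, under separation) — the simplest combination consistent
with reporting a single combined AUC.  Feature–SUVR association is Pearson
r, and partial r via double residualization on age, sex, education and MoCA
with degrees of freedom reduced by the covariate count.

## Longitudinal analysis

Paired two-sample t on follow-up minus baseline differences (df = n − 1);
identical pairs produce an exact-equality report instead of an undefined t.
The median split sends values strictly above the median to the high group
and the median itself (with any duplicates) to the low group, so 37 distinct
values split 18 high / 19 low.  Kaplan–Meier curves use lifelines'
product-limit estimator with exponential-Greenwood (log-log) 95% bands —
the variant stable near 0 and 1 — and groups are compared by the two-group
log-rank test (1 df).  Non-converters are censored at last follow-up; the
all-converter case needs no censoring but the machinery supports it for null
simulations.

## Synthetic data

Two tiers, both pure functions of (spec, seed):

* **Image tier:** Voronoi parcellations of an ellipsoidal foreground
  (convex cells, hence connected regions; a background shell is retained)
  and subject volumes built from region-mean offsets plus a smoothed
  Gaussian fluctuation field.  Cases receive the planted perturbation in the
  designated regions: a variance multiplier `1 + d/2` or a mean shift of
  d fluctuation-SDs.  Diffusion maps are per-tract constants plus noise.
  Default grids are 48³ — small enough for end-to-end extraction in seconds
  while every region keeps enough voxels for stable texture matrices.
* **Feature tier:** the subjects × features table directly, with
  block-correlated Gaussian noise (within-block r = 0.5, block size 10 —
  exercising the 0.8 decorrelation rule), planted columns shifted by
  Cohen's d between groups (drawn independently of their block so
  decorrelation cannot swap a planted feature for a noise sibling),
  covariates at cohort-like scales (age 66 ± 6 y, education 12 ± 3 y,
  MoCA ≈ 26 ± 3), and SUVR around 1.15 ± 0.06 constructed so its
  correlation with the standardized planted-feature mean equals the
  requested link (0.4 by default), with 1.18 as the conventional positivity
  cutoff.  The longitudinal generator adds a drifted follow-up copy and
  exponential conversion times whose hazard is log-linear in the designated
  feature's baseline level or group-proportional after a median split.

What the generators do **not** emulate: brain morphology, partial-volume and
smoothing-induced inter-region correlation, scanner/site effects, and
realistically correlated multi-feature signal structure.  Passing tests
therefore demonstrate that the machinery is correct and recovers planted
effects under controlled conditions — not that the pipeline attains any
particular accuracy on real cohorts.

## Validation design and problem sizes

Every texture matrix is checked for exact equality against independent
brute-force enumerations (pair loops, run walks, BFS flood fill, neighbor
scans) on sampled ROIs up to 4×4×4 with Ng ≤ 4, alongside closed-form toy
cases.  Statistical identities (AUC = U/(n₁n₀), partial-correlation closed
form, paired-t closed form) are pinned exactly; partial correlation is also
cross-checked against an independent implementation (pingouin).

The stochastic validations run at the study-scale conditions: tally
saturation uses the full 5 × 100 = 500 resamples on 2,000 features with
n = 90/90; the recovery study (3 planted features, d = 1.5, ≥90% of seeds
recovering all three; no feature stable in >10% of null seeds) uses 20 seeds
at 5 folds × 25 repetitions — the overlap rule operates on ranks, so the
tally depth affects only resolution, and 125 resamples per seed keeps the
two 20-seed studies tractable; log-rank size/power use 500/200 seeds.

## Known limitations

* The rbf SVM evaluated on each resample's own selected subset does not
  reach the accuracy of a signal-dominated subset at n = 180: the ~47
  selection-overfit noise features in a top-50 subset dilute three planted
  signals for an equal-weight kernel (the random forest is robust to this
  and the effect vanishes at larger n).  This is a property of
  selection-then-evaluate protocols under sparse true signal, measured and
  documented rather than patched.
* mRMR uses plug-in MI on terciles; with n ≈ 144 per resample the estimates
  are biased upward for all features equally, which leaves rankings usable
  but the MI values themselves uninterpretable.
* The covariate adjustment is fit once on the full cohort (protocol
  fidelity); a per-fold adjustment would remove the leakage at the cost of
  deviating from the analysis being reproduced.
* Feature extraction assumes spatially normalized inputs; no registration,
  smoothing or tensor fitting is performed here.
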