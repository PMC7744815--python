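# mpradiomics

Atlas-based radiomics for multiparametric brain MRI, aimed at the earliest
(preclinical) stage of Alzheimer's disease: cognitively normal individuals
whose amyloid-PET burden (mean cortical SUVR > 1.18) already marks them as
being on the Alzheimer's continuum.  The package implements the full
analysis pipeline as a tested Python library — high-dimensional texture
feature extraction from structural, functional and diffusion MRI; a
resampling *stability selection* scheme that tallies how often each feature
survives three independent selectors; SVM / random-forest evaluation of the
retained subsets; ROC and amyloid-correlation analyses of the stable
features; and longitudinal change / conversion-time survival analysis — plus
synthetic-cohort generators that let every stage run and be validated
without any imaging data.

Intended users are neuroimaging methods researchers who want a reproducible,
scriptable implementation of this selection-stability paradigm, either to
apply to their own preprocessed NIfTI data or to study the behaviour of the
method itself under controlled synthetic conditions.

## The method

**Features.** For each of 116 cortical/subcortical atlas regions (AAL-style)
the structural gray-matter map yields 43 texture features — 3 first-order
moments (variance, skewness, Pearson kurtosis) plus 9 GLCM, 13 GLRLM,
13 GLSZM and 5 NGTDM descriptors of the 32-level quantized region —
and 172 wavelet features: the same 43 after re-weighting the six band-pass
sub-bands of a single-level 3D `sym8` wavelet decomposition by
R ∈ {1/2, 2/3, 3/2, 2} and reconstructing.  That is 215 columns per region,
24,940 structural columns in total.  The functional temporal-summary volume
contributes 43 texture features per region (4,988 columns) and the four
diffusion scalar maps (FA/MD/AD/RD) contribute their means over 50
white-matter tracts (200 columns): 30,128 features per subject.

**Stability selection.**  After regressing out age, sex and education, every
training resample (stratified 5-fold split × 100 repetitions) passes through

1. two-sided two-sample t-test, keep p < 0.05;
2. greedy decorrelation at |Pearson r| ≤ 0.8, scanning in ascending-p order;
3. three selectors: Fisher score F = [n₁(μ₁−μ)² + n₂(μ₂−μ)²] / [n₁σ₁² + n₂σ₂²]
   (top 50), L1-penalized logistic regression (inner-CV penalty), and greedy
   mRMR, maximizing MI(f; y) − mean MI(f; selected) (top 50).

Each selector branch tallies per-feature occurrences in 0..500.  The top-10
counts per branch are *high-frequency* features; features high-frequency in
all three branches are *stable*; a looser overlap collects features with
counts > 300 everywhere.

**Evaluation.**  SVMs (sigmoid / linear / rbf kernels) and random forests
train on each resample's selected subset and score the held-out fold (and an
optional external cohort), aggregated as mean ± SD over the 500 runs.  Stable
features are assessed singly and combined (logistic score) by AUC — the
normalized Mann–Whitney U — and correlated with SUVR, plain and partial
(residualized on age, sex, education, MoCA).  For converter cohorts, paired
t-tests compare the two time points and a median split of the baseline level
feeds Kaplan–Meier curves and the log-rank test.

## Worked example

`examples/` holds one short script per capability.  Extraction
(`examples/extract_features.py`) prints:

```
feature columns per modality block:
  structural   24940
  functional    4988
  diffusion      200
  total        30128

example column  structural|region_001|1/2|GLSZM|LZHGE = 1224.096
```

i.e. the structural block is exactly 116 regions × 215 columns, and each
column is addressed by a canonical key `modality|region|R|family|name`.
Stability selection (`examples/stability_selection.py`) on a synthetic
cohort with three planted effects (Cohen's d = 1.5 among 2,000 features,
90 cases / 90 controls) prints:

```
stable features (in the top-10 of all three branches):
  synth_00000  mean count 50 <- planted
  synth_00010  mean count 50 <- planted
  synth_00020  mean count 50 <- planted
  synth_01934  mean count 41
```

— all three planted features saturate the tally (50 of 50 resamples here)
and are recovered as stable.  `examples/roc_and_correlation.py` shows the
combined logistic score improving on the best single feature
(AUC 0.913 vs 0.807) and the generator's planted feature–SUVR link of 0.4
recovered as r = 0.403; `examples/longitudinal_survival.py` reproduces the
18 high / 19 low median split of 37 converters and runs the log-rank
comparison.

A YAML-configured end-to-end run is available both as a library call
(`mpradiomics.run_pipeline`) and a thin CLI
(`mpradiomics simulate|extract|select|classify|roc|correlate|longitudinal`,
with `--seed`, `--config`, `--out`, `--log-level`).

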