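"""ROC / AUC of single features, their logistic combination, and the
correlation of features with amyloid burden (mean cortical SUVR).

The generator links SUVR to the planted features with a target correlation
of 0.4; the plain and covariate-adjusted Pearson correlations should both
recover it, and combining features should not degrade the best single AUC.
"""

import numpy as np

from mpradiomics import EffectSpec, roc_auc, suvr_correlation, synth_feature_cohort
from mpradiomics.classify import combined_score

cohort = synth_feature_cohort(
    100, EffectSpec(n_cases=90, n_controls=90, n_planted=3, effect_size_d=1.0,
                    suvr_link=0.4, seed=5)
)
labels = cohort.labels
columns = np.column_stack([cohort.features.column(k) for k in cohort.planted_keys])

print("single-feature AUC for amyloid status:")
for key, col in zip(cohort.planted_keys, columns.T):
    res = roc_auc(col, labels)
    print(f"  {key.region}: AUC = {res['auc_oriented']:.3f} (direction {res['direction']:+d})")

combo = combined_score(columns, labels)
print(f"combined (logistic) AUC = {roc_auc(combo['score'], labels)['auc']:.3f}")

suvr = np.array([r.suvr for r in cohort.records])
covs = np.column_stack([[r.age for r in cohort.records],
                        [r.sex for r in cohort.records],
                        [r.education for r in cohort.records],
                        [r.moca for r in cohort.records]])
res = suvr_correlation(columns[:, 0], suvr, covariates=covs)
print(f"\nfeature-SUVR correlation: r = {res['r']:.3f} (p = {res['p']:.2e}); "
      f"adjusted r = {res['r_adjusted']:.3f} (p = {res['p_adjusted']:.2e})")
print("(the generator plants r = 0.4; adjustment for age/sex/education/MoCA "
      "should barely move it because the covariates are independent here)")
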