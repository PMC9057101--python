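"""Relate seizure dissimilarity to band-power fluctuations.

Per-IMF seizure distance matrices (plus residue and temporal distances)
explain the DTW dissimilarity of seizure evolutions through a
cross-validated nonnegative LASSO with an OLS refit, and two permutation
tests assess significance.
"""

import numpy as np

import seizmod
from seizmod.pipeline import RunConfig, analyze_recording

rec = seizmod.generate_subject(
    n_channels=2, fs=180.0, duration_days=2.0, n_seizures=8, seed=11
)
cfg = RunConfig(k_min=2, k_max=5, n_permutations=200, seed=11)
res = analyze_recording(rec, cfg)

print(f"k = {res.factorization.k} NMF components, {res.imfset.M} IMFs")
print(f"circadian IMF: {res.circadian_imf + 1 if res.circadian_imf is not None else 'absent'}")
reg = res.regression
print(f"selected predictors: {reg.selected}")
print(f"lambda = {reg.lambda_selected:.3g}, adjusted R^2 = {reg.adjusted_R2:.3f}")
for lab, coef, (lo, hi) in zip(reg.selected, reg.coefficients, reg.conf_int):
    print(f"  {lab:8s} beta = {coef:6.3f}  95% CI [{lo:6.3f}, {hi:6.3f}]")
print(f"p (random onset times):  {res.perm_random_times.p_value:.3f}")
print(f"p (shuffled seizure order): {res.perm_shuffled_order.p_value:.3f}")
# Small p-values say the explained variance cannot be reproduced once the
# link between seizure timing and the band-power fluctuations is broken.
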