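"""The three reference expanders: MS, SMOTE and DA.

MS resamples each stage from a Gaussian with the stage mean and half the
stage standard deviation; SMOTE balances every stage to the majority count
by interpolating between same-stage neighbours; DA expands each sample into
floor(m/5) window-corrupted copies restored by a denoising autoencoder.
"""

import omixaug as oa

cohort, _ = oa.make_synthetic_cohort(oa.SyntheticConfig(
    stage_counts=(11, 38, 15, 6), n_genes=20, n_informative=6, seed=3))
X, y = cohort.expression, cohort.stages
print(f"training counts: {cohort.stage_counts()}")

ms = oa.augment_ms(X, y, seed=0)
print(f"MS:    {len(ms.expression):4d} samples {ms.stage_counts()}")

sm = oa.augment_smote(X, y, k_neighbors=5, seed=0)
print(f"SMOTE: {len(sm.expression):4d} samples {sm.stage_counts()}")

da = oa.augment_da(X, y, seed=0, epochs=50)
n, m = X.shape
print(f"DA:    {len(da.expression):4d} samples "
      f"(= n*floor(m/5)+n = {n}*{m // 5}+{n} = {oa.da_sample_count(n, m)})")

# MS mirrors the training counts, SMOTE balances all stages to the majority
# (38 each), and DA multiplies every sample by its corruption-window count.
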