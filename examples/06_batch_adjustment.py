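"""Remove a planted batch effect while keeping the stage signal.

Two batches of a synthetic cohort differ by an additive expression shift;
parametric empirical-Bayes adjustment removes the between-batch gap while
the planted stage-4 vs stage-1 expression difference survives.
"""

import numpy as np

import omixaug as oa

cohort, truth = oa.make_synthetic_cohort(oa.SyntheticConfig(
    stage_counts=(50, 50, 50, 50), n_genes=60, n_informative=6,
    n_batches=2, batch_shift=2.0, seed=1))
expr, batch, stages = cohort.expression, cohort.batch, cohort.stages
adjusted = oa.combat_adjust(expr, batch)


def batch_gap(df):
    m = df.groupby(batch).mean()
    return float(np.abs(m.iloc[1] - m.iloc[0]).mean())


def stage_gap(df):
    m = df[truth.informative_genes].groupby(stages).mean()
    return float((m.loc[4] - m.loc[1]).mean())


print(f"between-batch mean gap: {batch_gap(expr):.3f} -> {batch_gap(adjusted):.3f} "
      f"({100 * (1 - batch_gap(adjusted) / batch_gap(expr)):.1f}% removed)")
print(f"stage 4 - stage 1 signal on informative genes: "
      f"{stage_gap(expr):.3f} -> {stage_gap(adjusted):.3f}")

# The planted 2.0 batch shift all but vanishes; the planted ~3.0 stage
# contrast is essentially untouched.
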