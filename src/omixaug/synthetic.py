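"""Synthetic paired mutation/expression cohorts with planted stage structure.

Real stage-annotated tumour cohorts are small and access-controlled; this
module generates cohorts whose statistical shape mirrors them closely enough
to exercise every pipeline step: four stage classes with configurable (and
possibly severely imbalanced) counts, a subset of genes whose mutation
frequency and expression mean rise with stage, optional additive batch
structure, and Gaussian noise.

The planted signal is ordinal: an informative gene's expression mean is
``stage * effect_size`` (in units of the within-stage standard deviation) and
its mutation probability is ``min(1, rate * gradient * stage)``.  By default
the same genes carry both signals, encoding the premise that mutation-selected
genes have stage-relevant expression; ``coupled=False`` plants them in
disjoint gene sets to test the pipeline when that premise fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import CohortDataset

#: Stage counts mirroring a severely imbalanced rectal-cancer cohort.
READ_LIKE_COUNTS = (12, 24, 29, 12)
#: Training-set stage counts of a large breast-cancer cohort.
BRCA_LIKE_COUNTS = (110, 383, 152, 12)


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults define the standard test-bench cohort."""

    stage_counts: Sequence[int] = (60, 60, 60, 60)
    n_genes: int = 200
    n_informative: int = 10
    effect_size: float = 1.0        # per-stage expression mean shift, units of noise_sd
    mutation_rate: float = 0.05     # baseline (non-informative) mutation probability
    mutation_gradient: float = 4.0  # informative gene: P(mut | stage s) = rate*gradient*s
    n_batches: int = 1
    batch_shift: float = 0.0        # additive expression offset per batch index
    noise_sd: float = 1.0
    coupled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.stage_counts) != 4:
            raise ValueError("stage_counts must list counts for stages 1-4")
        if any(int(c) < 2 for c in self.stage_counts):
            raise ValueError("every stage needs at least 2 samples")
        need = self.n_informative if self.coupled else 2 * self.n_informative
        if need > self.n_genes:
            raise ValueError("n_informative exceeds n_genes for the requested coupling")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be a probability")
        if self.noise_sd < 0 or self.n_batches < 1:
            raise ValueError("noise_sd must be >= 0 and n_batches >= 1")


@dataclass
class GroundTruth:
    """What was planted, for scoring recovery."""

    informative_genes: list[str]            # expression-informative gene ids
    informative_mut_genes: list[str]        # mutation-informative gene ids
    stage_means: dict[int, float]           # per-stage informative expression mean
    batch_assignments: pd.Series | None


def make_synthetic_cohort(config: SyntheticConfig | None = None,
                          **overrides) -> tuple[CohortDataset, GroundTruth]:
    """Generate a cohort plus its ground truth; deterministic given the seed."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)

    counts = [int(c) for c in config.stage_counts]
    n = sum(counts)
    stages = np.repeat([1, 2, 3, 4], counts)
    sample_ids = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    gene_ids = pd.Index([f"G{j:04d}" for j in range(config.n_genes)], name="gene_id")

    k = config.n_informative
    expr_inf = np.arange(k)
    mut_inf = expr_inf if config.coupled else np.arange(k, 2 * k)

    # expression: informative mean = stage * effect * sd; others centred at 0
    mean = np.zeros((n, config.n_genes))
    shift = stages[:, None] * config.effect_size * config.noise_sd
    mean[:, expr_inf] = shift
    expression = mean + rng.normal(0.0, config.noise_sd, size=(n, config.n_genes))

    # mutation: Bernoulli with a per-stage gradient on informative genes
    prob = np.full((n, config.n_genes), config.mutation_rate)
    prob[:, mut_inf] = np.minimum(
        1.0, config.mutation_rate * config.mutation_gradient * stages[:, None]
    )
    mutation = (rng.random((n, config.n_genes)) < prob).astype(np.int8)

    batch = None
    if config.n_batches > 1:
        batch_idx = np.arange(n) % config.n_batches
        expression += batch_idx[:, None] * config.batch_shift
        batch = pd.Series([f"B{b}" for b in batch_idx], index=sample_ids, name="batch")

    cohort = CohortDataset(
        expression=pd.DataFrame(expression, index=sample_ids, columns=gene_ids),
        mutation=pd.DataFrame(mutation, index=sample_ids, columns=gene_ids),
        stages=pd.Series(stages, index=sample_ids, name="stage"),
        batch=batch,
    )
    truth = GroundTruth(
        informative_genes=gene_ids[expr_inf].tolist(),
        informative_mut_genes=gene_ids[mut_inf].tolist(),
        stage_means={s: s * config.effect_size * config.noise_sd for s in (1, 2, 3, 4)},
        batch_assignments=batch,
    )
    return cohort, truth


_PRESETS = {
    "balanced": dict(),
    "read-like": dict(stage_counts=READ_LIKE_COUNTS),
    "brca-like": dict(stage_counts=BRCA_LIKE_COUNTS),
    # Bench scale for the full experiment harness: fewer genes, but enough
    # informative ones that the selected-gene set clears the 1D-CNN's minimum
    # input length of 13.
    "bench": dict(n_genes=100, n_informative=20),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    """Named cohort presets: balanced, read-like, brca-like, bench."""
    try:
        base = dict(_PRESETS[name])
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
    base.update(overrides)
    return SyntheticConfig(seed=seed, **base)
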