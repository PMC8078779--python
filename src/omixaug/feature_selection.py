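"""Stage-informative gene selection from binary mutation profiles.

A random forest is fitted to the mutation matrix against the stage labels and
genes are ranked by mean-decrease-in-impurity importance.  Significance is
assessed by a label-permutation null: the forest is refitted under shuffled
stage labels and each gene's p-value is the add-one tail probability of its
observed importance, p = (1 + #{permuted >= observed}) / (1 + B).  Genes with
p below the threshold (default 0.004, strict inequality) are selected, ordered
by decreasing importance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier


@dataclass
class FeatureSelectionConfig:
    p_threshold: float = 0.004
    n_trees: int = 100
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must be in (0, 1]")
        if self.p_threshold <= 0.01 and self.n_permutations < 100:
            raise ValueError(
                "n_permutations must be >= 100 when p_threshold <= 0.01 "
                "(permutation resolution must support the threshold)"
            )
        # the smallest achievable p is 1/(B+1); a stricter threshold can never fire
        if 1.0 / (1 + self.n_permutations) >= self.p_threshold:
            raise ValueError(
                f"minimum achievable p-value 1/{1 + self.n_permutations} is not below "
                f"p_threshold={self.p_threshold}; increase n_permutations"
            )


@dataclass
class FeatureRanking:
    gene_ids: list[str]
    importance: np.ndarray
    p_value: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.importance):
            raise ValueError("gene_ids and importance lengths differ")
        if self.p_value is not None and len(self.p_value) != len(self.gene_ids):
            raise ValueError("p_value length differs from gene_ids")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene_id": self.gene_ids, "importance": self.importance})
        if self.p_value is not None:
            df["p_value"] = self.p_value
        return df.set_index("gene_id")


def _validate(mutation: pd.DataFrame, stages: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(mutation, dtype=float)
    y = np.asarray(stages)
    if len(np.unique(y)) < 2:
        raise ValueError("stage vector is constant; need >= 2 distinct stages")
    vals = np.unique(X)
    if not np.all(np.isin(vals, (0.0, 1.0))):
        raise ValueError("mutation matrix must be binary {0,1}")
    return X, y


def _fit_importances(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int) -> np.ndarray:
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    return rf.feature_importances_


def rank_features_rf(mutation: pd.DataFrame, stages: pd.Series,
                     config: FeatureSelectionConfig | None = None) -> FeatureRanking:
    """Impurity-importance ranking of mutation genes against stage."""
    config = config or FeatureSelectionConfig()
    X, y = _validate(mutation, stages)
    imp = _fit_importances(X, y, config.n_trees, config.seed)
    return FeatureRanking(gene_ids=list(mutation.columns), importance=imp)


def permutation_pvalues(mutation: pd.DataFrame, stages: pd.Series,
                        config: FeatureSelectionConfig | None = None) -> FeatureRanking:
    """Ranking with label-permutation p-values.

    Each permutation replicate shuffles the stage labels and refits the forest
    with a replicate-specific seed; ties count against significance (add-one
    estimator), so p-values lie in (0, 1].
    """
    config = config or FeatureSelectionConfig()
    X, y = _validate(mutation, stages)
    observed = _fit_importances(X, y, config.n_trees, config.seed)
    rng = np.random.default_rng(config.seed)
    exceed = np.zeros_like(observed, dtype=np.int64)
    for b in range(config.n_permutations):
        y_perm = rng.permutation(y)
        perm_imp = _fit_importances(X, y_perm, config.n_trees, config.seed + 1 + b)
        exceed += perm_imp >= observed
    p = (1.0 + exceed) / (1.0 + config.n_permutations)
    return FeatureRanking(gene_ids=list(mutation.columns), importance=observed, p_value=p)


def select_features(ranking: FeatureRanking, p_threshold: float = 0.004) -> list[str]:
    """Genes with p < p_threshold (strict), ordered by decreasing importance."""
    if not 0.0 < p_threshold <= 1.0:
        raise ValueError("p_threshold must be in (0, 1]")
    if ranking.p_value is None:
        raise ValueError("ranking has no p-values; run permutation_pvalues first")
    keep = np.flatnonzero(ranking.p_value < p_threshold)
    order = keep[np.argsort(-ranking.importance[keep], kind="stable")]
    return [ranking.gene_ids[i] for i in order]
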