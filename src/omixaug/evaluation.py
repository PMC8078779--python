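"""Repeated-split experiment harness, significance tests and PCA diagnostics.

One experiment cycle: draw a fresh stratified 70/30 split, build the
variant-specific training set (original genes, selected genes, or one of the
augmentation methods applied to the selected-gene training data), train each
classifier, and score accuracy and macro-F1 on the untouched 30%.  Cycles are
repeated with seeds ``base_seed + r`` and aggregated as mean +/- sd.

Test-set hygiene is asserted on every cycle: no test sample ever enters an
augmenter's or classifier's training inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .augmentation import (GanConfig, augment_da, augment_gan, augment_ms,
                           augment_smote)
from .classifiers import (CnnConfig, DnnConfig, RfConfig, evaluate_classifier,
                          train_classifier)
from .datasets import CohortDataset, stratified_split
from .feature_selection import (FeatureSelectionConfig, permutation_pvalues,
                                select_features)

logger = logging.getLogger(__name__)

VARIANTS = ("Ori", "FS", "MS", "SMOTE", "DA", "GAN1", "GAN5", "GAN20", "GAN100")
CLASSIFIERS = ("1DCNN", "DNN", "RF")


@dataclass
class ExperimentConfig:
    variants: tuple[str, ...] = VARIANTS
    classifiers: tuple[str, ...] = CLASSIFIERS
    repeats: int = 10
    base_seed: int = 0
    train_fraction: float = 0.7
    fs: FeatureSelectionConfig = field(default_factory=FeatureSelectionConfig)
    gan: GanConfig = field(default_factory=GanConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    dnn: DnnConfig = field(default_factory=DnnConfig)
    rf: RfConfig = field(default_factory=RfConfig)
    smote_k: int = 5
    da_epochs: int = 200

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.variants:
            raise ValueError("variant set must be non-empty")
        unknown = [v for v in self.variants
                   if v not in VARIANTS and not _gan_fold(v)]
        if unknown:
            raise ValueError(f"unknown variants: {unknown}")
        unknown = set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")


def _gan_fold(variant: str) -> int | None:
    if variant.startswith("GAN") and variant[3:].isdigit():
        return int(variant[3:])
    return None


@dataclass
class ResultsTable:
    """Per-repeat metrics, one row per (variant, classifier, repeat)."""

    rows: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Mean +/- sd per (variant, classifier), recomputed from the rows."""
        g = self.rows.groupby(["variant", "classifier"])[["accuracy", "macro_f1"]]
        out = g.agg(["mean", "std"])
        out.columns = ["_".join(c) for c in out.columns]
        return out.reset_index()

    def metric_vector(self, variant: str, classifier: str,
                      metric: str = "accuracy") -> np.ndarray:
        sel = self.rows.query("variant == @variant and classifier == @classifier")
        return sel.sort_values("repeat")[metric].to_numpy()


def _classifier_config(kind: str, config: ExperimentConfig, seed: int):
    if kind == "1DCNN":
        return replace(config.cnn, seed=seed)
    if kind == "DNN":
        return replace(config.dnn, seed=seed)
    if kind == "RF":
        return config.rf
    raise ValueError(f"unknown classifier {kind!r}")


def _variant_training_set(variant: str, train_expr: pd.DataFrame,
                          train_stages: pd.Series, selected: list[str] | None,
                          config: ExperimentConfig, seed: int):
    if variant == "Ori":
        return train_expr, train_stages
    fs_X = train_expr.loc[:, selected]
    if variant == "FS":
        return fs_X, train_stages
    if variant == "MS":
        a = augment_ms(fs_X, train_stages, seed=seed)
    elif variant == "SMOTE":
        a = augment_smote(fs_X, train_stages, k_neighbors=config.smote_k, seed=seed)
    elif variant == "DA":
        a = augment_da(fs_X, train_stages, seed=seed, epochs=config.da_epochs)
    else:
        fold = _gan_fold(variant)
        a = augment_gan(fs_X, train_stages, fold, replace(config.gan, seed=seed))
    return a.expression, a.stages


def select_cohort_genes(cohort: CohortDataset,
                        fs: FeatureSelectionConfig) -> list[str]:
    """Mutation-based gene selection for the experiment harness."""
    ranking = permutation_pvalues(cohort.mutation, cohort.stages, fs)
    genes = select_features(ranking, fs.p_threshold)
    if not genes:
        raise ValueError(
            "no gene passed the permutation p-value threshold; lower the "
            "threshold or check the mutation signal"
        )
    return genes


def _assert_hygiene(train_index: pd.Index, test_ids: set) -> None:
    leaked = set(train_index) & test_ids
    assert not leaked, f"test samples leaked into training: {sorted(leaked)[:5]}"


def run_experiment(cohort: CohortDataset, config: ExperimentConfig | None = None,
                   selected_genes: list[str] | None = None) -> ResultsTable:
    """The dataset-variant x classifier x repeat grid."""
    config = config or ExperimentConfig()
    needs_fs = any(v != "Ori" for v in config.variants)
    if needs_fs and selected_genes is None:
        selected_genes = select_cohort_genes(cohort, config.fs)
        logger.info("selected %d genes for the FS/augmented variants", len(selected_genes))

    records = []
    for r in range(config.repeats):
        seed = config.base_seed + r
        split = stratified_split(cohort, config.train_fraction, seed=seed)
        test_ids = set(split.test.sample_ids)
        for variant in config.variants:
            try:
                tr_X, tr_y = _variant_training_set(
                    variant, split.train.expression, split.train.stages,
                    selected_genes, config, seed)
            except Exception:
                logger.exception("variant %s failed on repeat %d", variant, r)
                for kind in config.classifiers:
                    records.append((variant, kind, r, np.nan, np.nan))
                continue
            _assert_hygiene(tr_X.index, test_ids)
            te_X = (split.test.expression if variant == "Ori"
                    else split.test.expression.loc[:, selected_genes])
            for kind in config.classifiers:
                try:
                    model = train_classifier(tr_X, tr_y,
                                             _classifier_config(kind, config, seed))
                    res = evaluate_classifier(model, te_X, split.test.stages)
                    records.append((variant, kind, r, res.accuracy, res.macro_f1))
                except Exception:
                    logger.exception("%s/%s failed on repeat %d", variant, kind, r)
                    records.append((variant, kind, r, np.nan, np.nan))
    return ResultsTable(rows=pd.DataFrame(
        records, columns=["variant", "classifier", "repeat", "accuracy", "macro_f1"]))


# --------------------------------------------------------------------------
# statistics

def compare_ttest(results_a, results_b) -> float:
    """Welch two-sample t-test p-value between two per-repeat metric vectors."""
    a = np.asarray(results_a, dtype=float)
    b = np.asarray(results_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def compare_friedman(metric_matrix: np.ndarray) -> float:
    """Friedman test over matched repeats (rows: variants, columns: repeats)."""
    M = np.asarray(metric_matrix, dtype=float)
    if M.shape[0] < 3:
        raise ValueError("Friedman test needs >= 3 matched groups")
    return float(stats.friedmanchisquare(*M).pvalue)


# --------------------------------------------------------------------------
# PCA diagnostics

@dataclass
class PcaEmbedding:
    """Sample-level and gene-level 2-D views of original vs generated data."""

    original_coords: np.ndarray
    generated_coords: np.ndarray
    explained_variance_ratio: np.ndarray
    gene_coords_original: np.ndarray
    gene_coords_generated: np.ndarray
    gene_explained_variance_ratio: np.ndarray


def pca_embed(original_expression, generated_expression,
              n_components: int = 2) -> PcaEmbedding:
    """Fit PCA on the pooled samples and embed both datasets.

    The gene-level view summarises each gene by its expression quantiles so
    genes from datasets with different sample counts share one feature basis;
    it visualises whether generation altered per-gene distributions.
    """
    X_o = np.asarray(original_expression, dtype=float)
    X_g = np.asarray(generated_expression, dtype=float)
    if len(X_o) + len(X_g) < 3:
        raise ValueError("need at least 3 samples in total")
    pooled = np.vstack([X_o, X_g])
    k = min(n_components, min(pooled.shape))
    pca = PCA(n_components=k)
    coords = pca.fit_transform(pooled)

    qs = np.linspace(0.0, 1.0, 21)
    gene_rows = np.vstack([np.quantile(X_o, qs, axis=0).T,
                           np.quantile(X_g, qs, axis=0).T])
    kg = min(n_components, min(gene_rows.shape))
    gene_pca = PCA(n_components=kg)
    gene_coords = gene_pca.fit_transform(gene_rows)
    n_genes = X_o.shape[1]
    return PcaEmbedding(
        original_coords=coords[:len(X_o)],
        generated_coords=coords[len(X_o):],
        explained_variance_ratio=pca.explained_variance_ratio_,
        gene_coords_original=gene_coords[:n_genes],
        gene_coords_generated=gene_coords[n_genes:],
        gene_explained_variance_ratio=gene_pca.explained_variance_ratio_,
    )


# --------------------------------------------------------------------------
# scaling experiments

def subsample_experiment(cohort: CohortDataset,
                         fractions: tuple[float, ...] = (1.0, 0.5, 0.3, 0.1),
                         fold: int = 5,
                         config: ExperimentConfig | None = None,
                         selected_genes: list[str] | None = None) -> ResultsTable:
    """Stage-stratified subsampling with un-augmented (O) vs GAN-fold (G) arms.

    For each fraction and repeat: subsample the cohort stratified by stage,
    split 70/30, then train the 1D-CNN on the selected-gene training data
    (O arm) and on its GAN-`fold` expansion (G arm).  Variants are labelled
    '100O', '100G', '50O', ... by the percentage kept.
    """
    config = config or ExperimentConfig()
    if selected_genes is None:
        selected_genes = select_cohort_genes(cohort, config.fs)
    counts = cohort.stage_counts()
    for frac in fractions:
        bad = [s for s, n in counts.items() if round(frac * n) < 2]
        if bad:
            raise ValueError(f"fraction {frac} leaves <2 samples for stages {bad}")

    records = []
    for frac in fractions:
        tag = f"{int(round(frac * 100))}"
        for r in range(config.repeats):
            seed = config.base_seed + r
            rng = np.random.default_rng(seed)
            keep = []
            for s in sorted(counts):
                ids = np.asarray(sorted(cohort.sample_ids[cohort.stages == s]))
                take = int(np.floor(frac * len(ids) + 0.5))
                keep.extend(rng.choice(ids, size=take, replace=False))
            sub = cohort.subset(sorted(keep))
            split = stratified_split(sub, config.train_fraction, seed=seed)
            test_ids = set(split.test.sample_ids)
            fs_train = split.train.expression.loc[:, selected_genes]
            te_X = split.test.expression.loc[:, selected_genes]
            arms = {
                f"{tag}O": (fs_train, split.train.stages),
                f"{tag}G": None,
            }
            for arm, data in arms.items():
                try:
                    if data is None:
                        a = augment_gan(fs_train, split.train.stages, fold,
                                        replace(config.gan, seed=seed))
                        tr_X, tr_y = a.expression, a.stages
                    else:
                        tr_X, tr_y = data
                    _assert_hygiene(tr_X.index, test_ids)
                    model = train_classifier(
                        tr_X, tr_y, _classifier_config("1DCNN", config, seed))
                    res = evaluate_classifier(model, te_X, split.test.stages)
                    records.append((arm, "1DCNN", r, res.accuracy, res.macro_f1))
                except Exception:
                    logger.exception("arm %s failed on repeat %d", arm, r)
                    records.append((arm, "1DCNN", r, np.nan, np.nan))
    return ResultsTable(rows=pd.DataFrame(
        records, columns=["variant", "classifier", "repeat", "accuracy", "macro_f1"]))


def fold_sweep(cohort: CohortDataset,
               folds: tuple[int, ...] = (1, 5, 10, 20, 30, 50, 70, 100),
               config: ExperimentConfig | None = None,
               selected_genes: list[str] | None = None) -> ResultsTable:
    """Accuracy of the 1D-CNN across GAN augmentation folds (10 repeats each)."""
    config = config or ExperimentConfig()
    sweep = replace(config, variants=tuple(f"GAN{f}" for f in folds),
                    classifiers=("1DCNN",))
    return run_experiment(cohort, sweep, selected_genes=selected_genes)
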