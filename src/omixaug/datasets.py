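"""Cohort containers, TSV readers and stratified splitting.

A cohort pairs a continuous expression matrix with a binary mutation matrix
over the same samples, plus a pathologic stage label (I-IV) per sample and an
optional batch label.  Samples are rows everywhere; readers normalise any
genes-in-rows input to that orientation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}
_STAGE_RE = re.compile(r"^(?:STAGE[\s_]*)?(I{1,3}|IV|[1-4])[AB]?$", re.IGNORECASE)


def parse_stage_label(label: object) -> int | None:
    """Map a stage label ('III', '3', 'Stage IIIA', ...) to an integer 1-4.

    Returns None for labels that do not encode a stage I-IV.
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return None
    if isinstance(label, (int, np.integer)):
        return int(label) if 1 <= int(label) <= 4 else None
    m = _STAGE_RE.match(str(label).strip())
    if m is None:
        return None
    token = m.group(1).upper()
    return int(token) if token.isdigit() else _ROMAN[token]


def _check_unique(ids: Sequence, what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dups[:5]}")


@dataclass
class CohortDataset:
    """Aligned expression/mutation matrices with stage labels.

    expression : DataFrame, samples x genes, continuous (log-scale) values
    mutation   : DataFrame, samples x genes, entries in {0, 1}
    stages     : Series of ints in {1,2,3,4}, indexed like the matrices
    batch      : optional Series of batch identifiers
    """

    expression: pd.DataFrame
    mutation: pd.DataFrame
    stages: pd.Series
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        n = len(self.expression)
        if len(self.mutation) != n or len(self.stages) != n:
            raise ValueError(
                f"row-count mismatch: expression {n}, mutation "
                f"{len(self.mutation)}, stages {len(self.stages)}"
            )
        _check_unique(self.expression.index, "sample ids")
        _check_unique(self.expression.columns, "expression gene ids")
        _check_unique(self.mutation.columns, "mutation gene ids")
        if not (self.expression.index.equals(self.mutation.index)
                and self.expression.index.equals(self.stages.index)):
            raise ValueError("expression, mutation and stages must share the same sample index")
        bad = set(np.unique(self.stages)) - {1, 2, 3, 4}
        if bad:
            raise ValueError(f"stage values outside 1-4: {sorted(bad)}")
        if self.batch is not None and not self.expression.index.equals(self.batch.index):
            raise ValueError("batch labels must share the sample index")

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.expression.index

    @property
    def n_samples(self) -> int:
        return len(self.expression)

    def stage_counts(self) -> dict[int, int]:
        vc = self.stages.value_counts()
        return {int(s): int(vc[s]) for s in sorted(vc.index)}

    def subset(self, sample_ids: Sequence) -> "CohortDataset":
        ids = pd.Index(sample_ids)
        return CohortDataset(
            expression=self.expression.loc[ids],
            mutation=self.mutation.loc[ids],
            stages=self.stages.loc[ids],
            batch=None if self.batch is None else self.batch.loc[ids],
        )

    def restrict_genes(self, genes: Sequence) -> "CohortDataset":
        """Restrict the expression matrix to the given genes (mutation kept)."""
        return CohortDataset(
            expression=self.expression.loc[:, list(genes)],
            mutation=self.mutation,
            stages=self.stages,
            batch=self.batch,
        )


@dataclass
class SplitDataset:
    """A stratified 70/30-style partition of a cohort."""

    train: CohortDataset
    test: CohortDataset
    train_fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = self.train.sample_ids.intersection(self.test.sample_ids)
        if len(overlap):
            raise ValueError(f"train/test overlap: {overlap[:5].tolist()}")


def read_matrix_tsv(path: str | Path, orientation: str = "samples_in_rows") -> pd.DataFrame:
    """Read a TSV matrix with an identifier header row and identifier first column.

    Returns a samples-in-rows DataFrame regardless of the file's orientation.
    """
    if orientation not in ("samples_in_rows", "genes_in_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], f"header identifiers in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r} in {path}")
        df[col] = pd.to_numeric(df[col])
    if orientation == "genes_in_rows":
        df = df.T
    _check_unique(df.index, f"row identifiers in {path}")
    _check_unique(df.columns, f"column identifiers in {path}")
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_labels_tsv(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample_id, label) into a Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected exactly two columns (sample_id, label)")
    _check_unique(df.index, f"sample ids in {path}")
    return df.iloc[:, 0]


def match_and_filter(
    expr: pd.DataFrame,
    mut: pd.DataFrame,
    stages: Mapping | pd.Series,
    batch: Mapping | pd.Series | None = None,
) -> CohortDataset:
    """Keep exactly the samples present in all inputs with a parseable stage.

    Mirrors the matched-ID rule used when pairing DNA and RNA assays: a sample
    survives only if it has expression, mutation and stage information.  Stage
    labels are parsed with :func:`parse_stage_label`; unmappable labels are
    dropped with a warning.  Output sample order is the sorted intersection.
    """
    stages = pd.Series(dict(stages) if not isinstance(stages, pd.Series) else stages)
    parsed = stages.map(parse_stage_label)
    dropped = stages.index[parsed.isna()]
    if len(dropped):
        logger.warning("dropping %d samples with unmappable stage labels: %s",
                       len(dropped), dropped[:5].tolist())
    parsed = parsed.dropna().astype(int)
    ids = sorted(set(expr.index) & set(mut.index) & set(parsed.index))
    if not ids:
        raise ValueError("no samples shared by expression, mutation and stage inputs")
    b = None
    if batch is not None:
        batch = pd.Series(dict(batch) if not isinstance(batch, pd.Series) else batch)
        b = batch.reindex(ids)
    return CohortDataset(
        expression=expr.loc[ids],
        mutation=mut.loc[ids],
        stages=parsed.loc[ids],
        batch=b,
    )


def stratified_split(cohort: CohortDataset, train_fraction: float = 0.7,
                     seed: int = 0) -> SplitDataset:
    """Random stage-stratified split.

    Per stage s with n_s samples, round(train_fraction * n_s) go to train,
    clamped so both partitions keep at least one sample of every stage.
    Deterministic given the seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    counts = cohort.stage_counts()
    thin = [s for s, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"stages with fewer than 2 samples cannot be split: {thin}")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for s in sorted(counts):
        ids = np.asarray(sorted(cohort.sample_ids[cohort.stages == s]))
        rng.shuffle(ids)
        n_train = int(np.floor(train_fraction * len(ids) + 0.5))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
    return SplitDataset(
        train=cohort.subset(train_ids),
        test=cohort.subset(test_ids),
        train_fraction=train_fraction,
        seed=seed,
    )


def write_cohort(cohort: CohortDataset, outdir: str | Path) -> None:
    """Write a cohort directory (expression.tsv, mutation.tsv, stages.tsv[, batch.tsv])."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_tsv(cohort.expression, out / "expression.tsv")
    write_matrix_tsv(cohort.mutation, out / "mutation.tsv")
    cohort.stages.rename("stage").to_csv(out / "stages.tsv", sep="\t", index_label="sample_id")
    if cohort.batch is not None:
        cohort.batch.rename("batch").to_csv(out / "batch.tsv", sep="\t", index_label="sample_id")


def read_cohort(indir: str | Path) -> CohortDataset:
    """Read a cohort directory written by :func:`write_cohort`."""
    ind = Path(indir)
    expr = read_matrix_tsv(ind / "expression.tsv")
    mut = read_matrix_tsv(ind / "mutation.tsv")
    stages = read_labels_tsv(ind / "stages.tsv")
    batch = read_labels_tsv(ind / "batch.tsv") if (ind / "batch.tsv").exists() else None
    return match_and_filter(expr, mut, stages, batch)
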