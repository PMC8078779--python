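"""Batch-effect adjustment via parametric empirical-Bayes (ComBat-style).

The classic location/scale model: each gene is standardised against its
batch-free fit, per-batch location (gamma) and scale (delta) estimates are
shrunk toward their across-gene priors with the parametric empirical-Bayes
iteration, and the data are back-transformed.  Only the parametric variant is
provided.  With a single batch the adjustment is skipped and the input is
returned unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class BatchModel:
    """Fitted adjustment parameters (genes indexed as in the input)."""

    batches: list
    grand_mean: np.ndarray          # per gene
    pooled_var: np.ndarray          # per gene
    gamma_star: np.ndarray          # n_batch x n_gene shrunken locations
    delta_star: np.ndarray          # n_batch x n_gene shrunken scales
    gamma_bar: np.ndarray           # per batch prior mean
    t2: np.ndarray                  # per batch prior variance
    a_prior: np.ndarray
    b_prior: np.ndarray
    skipped_genes: list[str]


def _eb_iterate(s_b: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
                g_bar: float, t2: float, a: float, b: float,
                conv: float = 1e-4, max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Joint posterior-mode iteration for one batch's (gamma*, delta*)."""
    n_b = s_b.shape[0]
    g_new, d_new = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_old, d_old = g_new, d_new
        g_new = (t2 * n_b * g_hat + d_old * g_bar) / (t2 * n_b + d_old)
        sum2 = ((s_b - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n_b / 2.0 + a - 1.0)
        change = max((np.abs(g_new - g_old) / g_old).max(initial=0.0),
                     (np.abs(d_new - d_old) / d_old).max(initial=0.0))
        if change < conv:
            break
    return g_new, d_new


def fit_batch_model(expression: pd.DataFrame, batch: pd.Series,
                    covariates: pd.Series | None = None) -> BatchModel:
    """Fit the location/scale adjustment; raises on singleton batches."""
    batch = batch.loc[expression.index]
    levels = sorted(pd.unique(batch))
    sizes = batch.value_counts()
    singletons = [b for b in levels if sizes[b] < 2]
    if singletons:
        raise ValueError(f"batches with a single sample cannot be adjusted: {singletons}")

    X = np.asarray(expression, dtype=float)          # samples x genes
    n, p = X.shape
    onehot = np.stack([(batch == b).to_numpy(float) for b in levels], axis=1)
    design = onehot
    if covariates is not None:
        cov = pd.get_dummies(covariates.loc[expression.index], drop_first=True)
        design = np.column_stack([onehot, cov.to_numpy(float)])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    n_batch = len(levels)
    props = np.array([sizes[b] for b in levels], dtype=float) / n
    grand_mean = props @ beta[:n_batch]
    stand_mean = np.tile(grand_mean, (n, 1))
    if covariates is not None:
        stand_mean = stand_mean + design[:, n_batch:] @ beta[n_batch:]
    resid = X - design @ beta
    pooled_var = (resid ** 2).sum(axis=0) / n

    ok = pooled_var > 0
    skipped = list(expression.columns[~ok])
    if skipped:
        logger.warning("passing %d zero-variance genes through unadjusted", len(skipped))
    scale = np.sqrt(np.where(ok, pooled_var, 1.0))
    s_data = (X - stand_mean) / scale

    gamma_star = np.zeros((n_batch, p))
    delta_star = np.ones((n_batch, p))
    gamma_bar = np.zeros(n_batch)
    t2 = np.zeros(n_batch)
    a_prior = np.zeros(n_batch)
    b_prior = np.zeros(n_batch)
    for k, b in enumerate(levels):
        s_b = s_data[(batch == b).to_numpy()]
        g_hat = s_b.mean(axis=0)
        d_hat = s_b.var(axis=0, ddof=1)
        gamma_bar[k] = g_hat.mean()
        t2[k] = g_hat.var() if p > 1 else 0.0
        m, s2 = d_hat.mean(), (d_hat.var(ddof=1) if p > 1 else 0.0)
        if t2[k] > 0 and s2 > 0:
            a_prior[k] = (2 * s2 + m ** 2) / s2
            b_prior[k] = (m * s2 + m ** 3) / s2
            g_star, d_star = _eb_iterate(s_b, g_hat, d_hat, gamma_bar[k], t2[k],
                                         a_prior[k], b_prior[k])
        else:
            # degenerate prior (e.g. a single gene): no shrinkage
            g_star, d_star = g_hat, np.maximum(d_hat, np.finfo(float).tiny)
        gamma_star[k] = g_star
        delta_star[k] = d_star

    return BatchModel(
        batches=levels, grand_mean=grand_mean, pooled_var=pooled_var,
        gamma_star=gamma_star, delta_star=delta_star, gamma_bar=gamma_bar,
        t2=t2, a_prior=a_prior, b_prior=b_prior, skipped_genes=skipped,
    )


def combat_adjust(expression: pd.DataFrame, batch: pd.Series | None,
                  covariates: pd.Series | None = None,
                  return_model: bool = False):
    """Adjust an expression matrix for batch effects.

    Parameters
    ----------
    expression
        Samples x genes matrix (selected genes, log scale).
    batch
        Batch label per sample.  ``None`` or a single level means there is
        nothing to correct: the input is returned unchanged with a notice.
    covariates
        Optional biological covariate (e.g. stage) whose signal should be
        protected during standardisation.  Off by default.
    """
    if batch is None or len(pd.unique(batch.loc[expression.index])) < 2:
        logger.info("single batch (or no batch labels): adjustment skipped")
        out = expression.copy()
        return (out, None) if return_model else out

    model = fit_batch_model(expression, batch, covariates)
    batch = batch.loc[expression.index]
    X = np.asarray(expression, dtype=float)
    n = X.shape[0]
    ok = model.pooled_var > 0
    scale = np.sqrt(np.where(ok, model.pooled_var, 1.0))
    stand_mean = np.tile(model.grand_mean, (n, 1))
    if covariates is not None:
        cov = pd.get_dummies(covariates.loc[expression.index], drop_first=True)
        onehot = np.stack([(batch == b).to_numpy(float) for b in model.batches], axis=1)
        design = np.column_stack([onehot, cov.to_numpy(float)])
        beta, *_ = np.linalg.lstsq(design, X, rcond=None)
        stand_mean = stand_mean + design[:, len(model.batches):] @ beta[len(model.batches):]
    s_data = (X - stand_mean) / scale

    adjusted = s_data.copy()
    for k, b in enumerate(model.batches):
        rows = (batch == b).to_numpy()
        adjusted[rows] = (s_data[rows] - model.gamma_star[k]) / np.sqrt(model.delta_star[k])
    out = adjusted * scale + stand_mean
    out[:, ~ok] = X[:, ~ok]
    out_df = pd.DataFrame(out, index=expression.index, columns=expression.columns)
    return (out_df, model) if return_model else out_df
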