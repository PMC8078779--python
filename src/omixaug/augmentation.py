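"""Training-set augmentation: per-stage GANs and three reference expanders.

The GAN route trains one generator/discriminator pair per stage on that
stage's training expression (selected genes only).  Both networks have a
single 256-unit hidden layer; the generator's latent vectors are drawn from a
per-gene normal whose mean and standard deviation are those of the training
data fed to it, so latent dimensionality equals the gene count.  Generating
``fold * n_s`` samples per stage preserves the stage ratio of the training
set exactly.

Reference expanders:

* MS — per-stage Gaussian sampling with the stage mean and half the stage
  standard deviation;
* SMOTE — classic minority interpolation up to the majority-class count;
* DA — denoising-autoencoder expansion: every sample is corrupted in
  disjoint 5-gene windows and reconstructed, yielding n*floor(m/5)+n samples
  (originals included).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from ._nn import MLP, Adam, ResidualMLP, sigmoid

logger = logging.getLogger(__name__)


@dataclass
class GanConfig:
    """Hyperparameters of one stage GAN (identical across stages).

    The discriminator takes `d_steps` Adam updates at `learning_rate` per
    generator update at `generator_lr`; generated samples come from a Polyak
    (exponential moving) average of the generator weights, which stabilises
    the matched distribution.
    """

    hidden_units: int = 256
    epochs: int = 1000          # the reference setting varies 900-1100 by cohort
    batch_size: int = 32
    learning_rate: float = 2e-4   # discriminator
    generator_lr: float = 1e-4
    d_steps: int = 2
    ema_decay: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("hidden_units, epochs and batch_size must be >= 1")
        if self.d_steps < 1 or not 0.0 <= self.ema_decay < 1.0:
            raise ValueError("d_steps must be >= 1 and ema_decay in [0, 1)")


@dataclass
class LatentStats:
    """Per-gene latent normal parameters (computed on the standardised data)."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sd < 0) or len(self.mean) != len(self.sd):
            raise ValueError("latent sd must be >= 0 and match mean length")


@dataclass
class TrainedGenerator:
    stage: int
    generator: MLP
    latent: LatentStats
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    gene_ids: list[str]
    n_train: int
    discriminator: MLP | None = None
    history: dict[str, list[float]] = field(default_factory=dict)


@dataclass
class AugmentedTrainingSet:
    """Synthetic (or expanded) training samples with stage labels."""

    expression: pd.DataFrame
    stages: pd.Series
    method: str                 # GAN | MS | SMOTE | DA
    fold: int | None = None     # GAN only
    history: dict | None = None

    def stage_counts(self) -> dict[int, int]:
        vc = self.stages.value_counts()
        return {int(s): int(vc[s]) for s in sorted(vc.index)}


def _stage_arrays(expression: pd.DataFrame, stages: pd.Series):
    X = np.asarray(expression, dtype=float)
    y = np.asarray(stages)
    out = {}
    for s in sorted(np.unique(y)):
        out[int(s)] = X[y == s]
    return X, y, out


# --------------------------------------------------------------------------
# GAN

def fit_stage_gan(train_expression, config: GanConfig | None = None,
                  stage: int = 0) -> TrainedGenerator:
    """Adversarially train one stage's generator.

    Non-saturating BCE objective with Adam (beta1 0.5); the generator is a
    residual net starting near the identity, so its initial output already
    follows the latent marginals.  Data are standardised per gene before
    training and the scaler is inverted at generation time.
    """
    config = config or GanConfig()
    gene_ids = (list(train_expression.columns)
                if isinstance(train_expression, pd.DataFrame) else None)
    X = np.asarray(train_expression, dtype=float)
    if X.ndim != 2:
        raise ValueError("training expression must be 2-D (samples x genes)")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in training expression")
    n, m = X.shape
    if n < 2:
        raise ValueError(
            "a stage with a single sample cannot train a GAN; pool it with a "
            "neighbouring stage or skip augmentation for it"
        )
    batch = min(config.batch_size, n)
    if batch < config.batch_size:
        logger.warning("stage %s: batch size clamped to its %d training samples",
                       stage, n)

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / scale
    latent = LatentStats(mean=Xs.mean(axis=0), sd=Xs.std(axis=0))

    rng = np.random.default_rng(config.seed)
    h = config.hidden_units
    G = ResidualMLP([m, h, m], ["relu", "linear"], rng)
    D = MLP([m, h, 1], ["leaky", "linear"], rng)
    optG = Adam(G.params, lr=config.generator_lr, beta1=0.5)
    optD = Adam(D.params, lr=config.learning_rate, beta1=0.5)
    ema = [p.copy() for p in G.params]

    d_hist, g_hist = [], []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        d_ep, g_ep, nb = 0.0, 0.0, 0
        for start in range(0, n, batch):
            xb = Xs[order[start:start + batch]]
            B = len(xb)
            for _k in range(config.d_steps):
                # discriminator: push real -> 1, fake -> 0
                z = rng.normal(latent.mean, latent.sd, size=(B, m))
                fake = G.forward(z)
                logit_r = D.forward(xb, cache=True)
                p_r = sigmoid(logit_r)
                grads_r, _ = D.backward((p_r - 1.0) / B)
                logit_f = D.forward(fake, cache=True)
                p_f = sigmoid(logit_f)
                grads_f, _ = D.backward(p_f / B)
                optD.step([a + b for a, b in zip(grads_r, grads_f)])
            d_ep += float(-(np.log(p_r + 1e-12).mean() + np.log(1 - p_f + 1e-12).mean()))
            # generator: non-saturating, push D(fake) -> 1
            z = rng.normal(latent.mean, latent.sd, size=(B, m))
            fake = G.forward(z, cache=True)
            logit = D.forward(fake, cache=True)
            p = sigmoid(logit)
            _, dfake = D.backward((p - 1.0) / B)
            gradsG, _ = G.backward(dfake)
            optG.step(gradsG)
            decay = config.ema_decay
            for e, q in zip(ema, G.params):
                e *= decay
                e += (1.0 - decay) * q
            g_ep += float(-np.log(p + 1e-12).mean())
            nb += 1
        d_hist.append(d_ep / nb)
        g_hist.append(g_ep / nb)
    for q, e in zip(G.params, ema):
        q[...] = e

    return TrainedGenerator(
        stage=stage, generator=G, latent=latent, scaler_mean=mu,
        scaler_scale=scale, gene_ids=gene_ids, n_train=n, discriminator=D,
        history={"d_loss": d_hist, "g_loss": g_hist},
    )


def sample_generator(gen: TrainedGenerator, count: int, seed: int = 0) -> np.ndarray:
    """Draw `count` latent vectors, map through the generator, un-standardise."""
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = np.random.default_rng(seed)
    m = len(gen.scaler_mean)
    z = rng.normal(gen.latent.mean, gen.latent.sd, size=(count, m))
    out = gen.generator.forward(z)
    return out * gen.scaler_scale + gen.scaler_mean


def discriminate(gen: TrainedGenerator, X: np.ndarray) -> np.ndarray:
    """Probability-real scores from the stage's discriminator (diagnostics).

    Input is on the raw expression scale; the training standardisation is
    applied before scoring.
    """
    if gen.discriminator is None:
        raise ValueError("generator was stored without its discriminator")
    Xs = (np.asarray(X, dtype=float) - gen.scaler_mean) / gen.scaler_scale
    return sigmoid(gen.discriminator.forward(Xs)).ravel()


def augment_gan(expression: pd.DataFrame, stages: pd.Series, fold: int,
                config: GanConfig | None = None) -> AugmentedTrainingSet:
    """Per-stage GAN augmentation keeping the stage ratio exactly.

    One generator is trained per stage and emits ``fold * n_s`` samples
    labelled with its stage, so the augmented set's stage proportions equal
    the training set's.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    config = config or GanConfig()
    _, _, per_stage = _stage_arrays(expression, stages)
    blocks, labels, histories = [], [], {}
    for s, Xs_raw in per_stage.items():
        cfg = GanConfig(hidden_units=config.hidden_units, epochs=config.epochs,
                        batch_size=config.batch_size,
                        learning_rate=config.learning_rate,
                        seed=config.seed + 17 * s)
        gen = fit_stage_gan(pd.DataFrame(Xs_raw, columns=expression.columns),
                            cfg, stage=s)
        n_out = fold * len(Xs_raw)
        blocks.append(sample_generator(gen, n_out, seed=config.seed + 1000 + s))
        labels.extend([s] * n_out)
        histories[s] = gen.history
    ids = pd.Index([f"GAN{fold}_{i:05d}" for i in range(len(labels))], name="sample_id")
    out = AugmentedTrainingSet(
        expression=pd.DataFrame(np.vstack(blocks), index=ids, columns=expression.columns),
        stages=pd.Series(labels, index=ids, name="stage"),
        method="GAN", fold=fold, history=histories,
    )
    want = {s: fold * len(Xs) for s, Xs in per_stage.items()}
    assert out.stage_counts() == want, "stage-ratio rule violated"
    return out


# --------------------------------------------------------------------------
# reference expanders

def augment_ms(expression: pd.DataFrame, stages: pd.Series,
               seed: int = 0) -> AugmentedTrainingSet:
    """Gaussian resampling: per stage, n_s draws of N(mean, sd/2) per gene."""
    rng = np.random.default_rng(seed)
    _, _, per_stage = _stage_arrays(expression, stages)
    blocks, labels = [], []
    for s, Xs in per_stage.items():
        mu = Xs.mean(axis=0)
        half_sd = Xs.std(axis=0, ddof=1) / 2.0 if len(Xs) > 1 else np.zeros(Xs.shape[1])
        blocks.append(rng.normal(mu, half_sd, size=Xs.shape))
        labels.extend([s] * len(Xs))
    ids = pd.Index([f"MS_{i:05d}" for i in range(len(labels))], name="sample_id")
    return AugmentedTrainingSet(
        expression=pd.DataFrame(np.vstack(blocks), index=ids, columns=expression.columns),
        stages=pd.Series(labels, index=ids, name="stage"),
        method="MS",
    )


def augment_smote(expression: pd.DataFrame, stages: pd.Series,
                  k_neighbors: int = 5, seed: int = 0) -> AugmentedTrainingSet:
    """Oversample every stage to the majority count by SMOTE interpolation.

    New points are x_i + u (x_nn - x_i) with u ~ Uniform(0,1) and x_nn one of
    the k nearest same-stage neighbours (Euclidean).  Originals are kept, so
    per-class counts all equal the majority count.
    """
    rng = np.random.default_rng(seed)
    X, y, per_stage = _stage_arrays(expression, stages)
    majority = max(len(v) for v in per_stage.values())
    blocks = [X]
    labels = list(y)
    for s, Xs in per_stage.items():
        need = majority - len(Xs)
        if need == 0:
            continue
        if len(Xs) < 2:
            raise ValueError(f"stage {s} has a single sample; SMOTE needs >= 2")
        k_eff = min(k_neighbors, len(Xs) - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xs)
        neigh = nn.kneighbors(Xs, return_distance=False)[:, 1:]
        base = rng.integers(0, len(Xs), size=need)
        pick = rng.integers(0, k_eff, size=need)
        u = rng.random(need)
        partner = Xs[neigh[base, pick]]
        blocks.append(Xs[base] + u[:, None] * (partner - Xs[base]))
        labels.extend([s] * need)
    ids = pd.Index([f"SM_{i:05d}" for i in range(len(labels))], name="sample_id")
    return AugmentedTrainingSet(
        expression=pd.DataFrame(np.vstack(blocks), index=ids, columns=expression.columns),
        stages=pd.Series(labels, index=ids, name="stage"),
        method="SMOTE",
    )


def da_sample_count(n: int, m: int) -> int:
    """DA expansion size: n * floor(m / 5) + n."""
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    return n * (m // 5) + n


def corrupt_windows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All window-corrupted copies: copy j of a sample zeroes genes [5j, 5j+5).

    Returns (corrupted, source_index); copies are grouped per source sample.
    """
    n, m = X.shape
    n_win = m // 5
    if n_win == 0:
        return np.empty((0, m)), np.empty(0, dtype=int)
    src = np.repeat(np.arange(n), n_win)
    out = X[src].copy()
    win = np.tile(np.arange(n_win), n)
    for j in range(n_win):
        rows = win == j
        out[rows, 5 * j:5 * j + 5] = 0.0
    return out, src


def augment_da(expression: pd.DataFrame, stages: pd.Series, seed: int = 0,
               hidden_units: int = 256, epochs: int = 200) -> AugmentedTrainingSet:
    """Denoising-autoencoder expansion.

    A single-hidden-layer autoencoder learns to restore window-corrupted
    samples; the output is the originals plus one reconstruction per
    corrupted copy, n * floor(m/5) + n samples in total, each labelled with
    its source sample's stage.
    """
    from sklearn.neural_network import MLPRegressor

    X, y, _ = _stage_arrays(expression, stages)
    n, m = X.shape
    corrupted, src = corrupt_windows(X)
    if len(corrupted) == 0:
        logger.warning("fewer than 5 genes: DA expansion degenerates to the originals")
        return AugmentedTrainingSet(expression=expression.copy(),
                                    stages=stages.copy(), method="DA")
    model = MLPRegressor(hidden_layer_sizes=(hidden_units,), max_iter=epochs,
                         random_state=seed, solver="adam")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # plateau warnings at small epoch budgets
        model.fit(corrupted, X[src])
    recon = model.predict(corrupted)
    out_X = np.vstack([X, recon])
    labels = np.concatenate([y, y[src]])
    assert len(out_X) == da_sample_count(n, m)
    ids = pd.Index([f"DA_{i:06d}" for i in range(len(out_X))], name="sample_id")
    return AugmentedTrainingSet(
        expression=pd.DataFrame(out_X, index=ids, columns=expression.columns),
        stages=pd.Series(labels, index=ids, name="stage"),
        method="DA", history={"loss": list(model.loss_curve_)},
    )
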