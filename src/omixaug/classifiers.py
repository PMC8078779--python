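"""The three stage classifiers behind one train/predict/evaluate interface.

* 1DCNN — two convolution layers (20 and 40 filters, kernel 5), max pools of
  size 2, a 64-unit dense layer, softmax over the four stages; Adam, batch 32.
  Genes are convolved in their selection order (the order is recorded on the
  trained model; for expression vectors it is semantically arbitrary, so
  reproducibility requires fixing it).
* DNN — three hidden layers of 64, 32 and 4 ReLU units with a softmax head.
* RF — 100 trees, out-of-bag scoring on, random_state 123456.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.neural_network import MLPClassifier

from ._nn import Adam, Conv1DNet, softmax

STAGES = (1, 2, 3, 4)


@dataclass
class CnnConfig:
    filters: tuple[int, int] = (20, 40)
    kernel_size: int = 5
    pool_size: int = 2
    dense_units: int = 64
    batch_size: int = 32
    epochs: int = 1000
    learning_rate: float = 1e-3
    n_classes: int = 4
    seed: int = 0


@dataclass
class DnnConfig:
    hidden_sizes: tuple[int, ...] = (64, 32, 4)
    batch_size: int = 32
    epochs: int = 500
    seed: int = 0


@dataclass
class RfConfig:
    n_estimators: int = 100
    oob_score: bool = True
    random_state: int = 123456

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass
class TrainedClassifier:
    kind: str                      # "1DCNN" | "DNN" | "RF"
    model: object
    feature_names: list[str]
    config: object
    classes: np.ndarray
    history: list[float] | None = None


def _as_xy(expression, stages):
    if isinstance(expression, pd.DataFrame):
        features = list(expression.columns)
    else:
        features = [f"f{i}" for i in range(np.asarray(expression).shape[1])]
    X = np.asarray(expression, dtype=float)
    y = np.asarray(stages)
    if len(np.unique(y)) < 2:
        raise ValueError("training set has a single class; need >= 2 stages")
    return X, y, features


def _train_cnn(X: np.ndarray, y: np.ndarray, cfg: CnnConfig):
    rng = np.random.default_rng(cfg.seed)
    net = Conv1DNet(X.shape[1], rng, filters=cfg.filters,
                    kernel_size=cfg.kernel_size, pool=cfg.pool_size,
                    dense_units=cfg.dense_units, n_classes=cfg.n_classes)
    opt = Adam(net.params, lr=cfg.learning_rate)
    targets = (y[:, None] == np.arange(1, cfg.n_classes + 1)).astype(float)
    n = len(X)
    batch = min(cfg.batch_size, n)
    history = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            logits = net.forward(X[idx], cache=True)
            p = softmax(logits)
            ep_loss += float(-(targets[idx] * np.log(p + 1e-12)).sum(axis=1).mean())
            opt.step(net.backward((p - targets[idx]) / len(idx)))
            nb += 1
        history.append(ep_loss / nb)
    return net, history


def train_classifier(expression, stages,
                     config: CnnConfig | DnnConfig | RfConfig) -> TrainedClassifier:
    """Fit one of the three classifiers on a (possibly augmented) training set."""
    X, y, features = _as_xy(expression, stages)
    if isinstance(config, CnnConfig):
        need = Conv1DNet.min_input_length(config.kernel_size, config.pool_size)
        if X.shape[1] < need:
            raise ValueError(
                f"1DCNN needs at least {need} input genes for two "
                f"conv(k={config.kernel_size})+pool stages; got {X.shape[1]}"
            )
        net, history = _train_cnn(X, y, config)
        return TrainedClassifier("1DCNN", net, features, config,
                                 classes=np.arange(1, config.n_classes + 1),
                                 history=history)
    if isinstance(config, DnnConfig):
        model = MLPClassifier(hidden_layer_sizes=config.hidden_sizes,
                              activation="relu", solver="adam",
                              batch_size=min(config.batch_size, len(X)),
                              max_iter=config.epochs,
                              random_state=config.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        return TrainedClassifier("DNN", model, features, config,
                                 classes=model.classes_,
                                 history=list(model.loss_curve_))
    if isinstance(config, RfConfig):
        model = RandomForestClassifier(n_estimators=config.n_estimators,
                                       oob_score=config.oob_score,
                                       random_state=config.random_state,
                                       n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # OOB warnings on tiny sets
            model.fit(X, y)
        return TrainedClassifier("RF", model, features, config, classes=model.classes_)
    raise TypeError(f"unknown config type: {type(config).__name__}")


def _check_features(model: TrainedClassifier, expression) -> np.ndarray:
    if isinstance(expression, pd.DataFrame):
        got = list(expression.columns)
        if got != model.feature_names:
            missing = [g for g in model.feature_names if g not in got]
            extra = [g for g in got if g not in model.feature_names]
            if missing or extra:
                raise ValueError(
                    f"feature mismatch: missing {missing[:5]}, extra {extra[:5]}"
                )
            expression = expression.loc[:, model.feature_names]
    X = np.asarray(expression, dtype=float)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {X.shape[1]}"
        )
    return X


def predict_proba(model: TrainedClassifier, expression) -> np.ndarray:
    """Class probabilities over stages 1-4 (rows sum to 1)."""
    X = _check_features(model, expression)
    if model.kind == "1DCNN":
        p = softmax(model.model.forward(X))
    else:
        p = model.model.predict_proba(X)
    out = np.zeros((len(X), len(STAGES)))
    for j, c in enumerate(model.classes):
        out[:, int(c) - 1] = p[:, j]
    return out


def predict(model: TrainedClassifier, expression) -> np.ndarray:
    """Predicted stage (1-4) per sample."""
    p = predict_proba(model, expression)
    return p.argmax(axis=1) + 1


@dataclass
class EvalResult:
    accuracy: float
    macro_f1: float
    confusion: pd.DataFrame


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalResult:
    """Accuracy and macro-F1; stages absent from both truth and prediction
    are excluded from the macro average."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    labels = sorted(set(y_true) | set(y_pred))
    acc = accuracy_score(y_true, y_pred)
    f1 = f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    conf = pd.DataFrame(cm, index=pd.Index(labels, name="true"),
                        columns=pd.Index(labels, name="predicted"))
    return EvalResult(accuracy=float(acc), macro_f1=float(f1), confusion=conf)


def evaluate_classifier(model: TrainedClassifier, expression, stages) -> EvalResult:
    if len(expression) == 0:
        raise ValueError("empty test set")
    return evaluate_predictions(np.asarray(stages), predict(model, expression))
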