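"""A single-layer perceptron (one hidden layer) for key-day classification.

The network maps an M-vector of histogram statistics to K key-day scores
through one ReLU hidden layer of N neurons:

    M = m × I   (m features per index, I indices)
    N = I + A   (one hidden neuron per index plus A reserved, A = 5)
    Nw = M·N + N·K   weights (1005 for M=60, N=15, K=7)

Hidden and output weights are drawn from the Kaiming-He normal distribution
(zero mean, variance 2/fan_in); biases start at zero.  Training minimizes
softmax cross-entropy with full-batch Adam.  Because a freshly initialized
shallow net is itself a random variable, reported accuracy is the average
over many independent trials, each with a fresh stratified train/test split
and fresh initial weights.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit

from .errors import ValidationError
from .io_formats import FeatureTable

RESERVE_NEURONS = 5  # A: hidden neurons beyond one-per-index


@dataclass(frozen=True)
class SLPConfig:
    n_inputs: int
    n_hidden: int
    n_outputs: int
    learning_rate: float = 1e-2
    max_epochs: int = 500
    batch_size: int | None = None  # None = full batch for <=1000 rows
    init: str = "kaiming"
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise ValidationError("layer sizes must be >= 1")
        if self.init != "kaiming":
            raise ValidationError(f"unknown init scheme {self.init!r}")


def count_weights(config: SLPConfig) -> int:
    """Number of connection weights: M·N + N·K (biases not counted)."""
    return config.n_inputs * config.n_hidden + config.n_hidden * config.n_outputs


def init_weights(config: SLPConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Kaiming-He normal weights (variance 2/fan_in), zero biases."""
    w1 = rng.normal(0.0, np.sqrt(2.0 / config.n_inputs), size=(config.n_inputs, config.n_hidden))
    w2 = rng.normal(0.0, np.sqrt(2.0 / config.n_hidden), size=(config.n_hidden, config.n_outputs))
    return {
        "w1": w1,
        "b1": np.zeros(config.n_hidden),
        "w2": w2,
        "b2": np.zeros(config.n_outputs),
    }


@dataclass
class SLPModel:
    config: SLPConfig
    params: dict[str, np.ndarray]
    loss_history: list[float] = field(default_factory=list)
    # standardization learned from the training split
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None

    def scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_std
        h = np.maximum(X @ self.params["w1"] + self.params["b1"], 0.0)
        return h @ self.params["w2"] + self.params["b2"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.scores(X), axis=1)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: SLPConfig,
    rng: np.random.Generator,
    standardize: bool = True,
) -> SLPModel:
    """Fit the SLP with full-batch Adam on softmax cross-entropy.

    Features are z-scored column-wise from the training data (raw index
    scales differ by orders of magnitude).  Stops at ``max_epochs`` or when
    the epoch-to-epoch loss improvement drops below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] != config.n_inputs:
        raise ValidationError(f"feature matrix must be (n, {config.n_inputs})")
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain non-finite values")
    if y.min() < 0 or y.max() >= config.n_outputs:
        raise ValidationError("labels must lie in 0..K-1")

    mean = std = None
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std == 0, 1.0, std)
        X = (X - mean) / std

    params = init_weights(config, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    onehot = np.eye(config.n_outputs)[y]
    n = len(X)
    batch = n if (config.batch_size is None and n <= 1000) else (config.batch_size or 256)

    losses: list[float] = []
    step = 0
    for epoch in range(config.max_epochs):
        if batch >= n:
            order = np.arange(n)
        else:
            order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb, tb = X[idx], onehot[idx]
            h_pre = xb @ params["w1"] + params["b1"]
            h = np.maximum(h_pre, 0.0)
            p = _softmax(h @ params["w2"] + params["b2"])
            epoch_loss += float(-(tb * np.log(p + 1e-12)).sum())
            # backprop
            dz2 = (p - tb) / len(xb)
            grads = {
                "w2": h.T @ dz2,
                "b2": dz2.sum(axis=0),
            }
            dh = dz2 @ params["w2"].T
            dh[h_pre <= 0] = 0.0
            grads["w1"] = xb.T @ dh
            grads["b1"] = dh.sum(axis=0)
            step += 1
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                params[k] = params[k] - config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        losses.append(epoch_loss / n)
        if epoch > 0 and abs(losses[-2] - losses[-1]) < config.tol:
            break
    return SLPModel(config=config, params=params, loss_history=losses,
                    feature_mean=mean, feature_std=std)


def evaluate(model: SLPModel, X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Accuracy and the row-normalized K×K confusion matrix.

    Row r, column c holds the fraction of true-class-r samples predicted as
    c; rows of classes absent from the test set are left at zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) == 0:
        raise ValidationError("empty test set")
    pred = model.predict(X)
    k = model.config.n_outputs
    counts = np.zeros((k, k))
    np.add.at(counts, (y, pred), 1.0)
    row_tot = counts.sum(axis=1, keepdims=True)
    confusion = np.divide(counts, row_tot, out=np.zeros_like(counts), where=row_tot > 0)
    return float((pred == y).mean()), confusion


@dataclass
class TrainResult:
    mean_accuracy: float
    accuracy_per_trial: list[float]
    mean_confusion: np.ndarray
    training_time_s: float
    n_trials: int
    day_labels: list[int]
    config: SLPConfig

    def __post_init__(self) -> None:
        if self.accuracy_per_trial and not np.isclose(
            self.mean_accuracy, np.mean(self.accuracy_per_trial)
        ):
            raise ValidationError("mean_accuracy must equal the per-trial mean")


def trial_average(
    table: FeatureTable,
    feature_subset: Sequence[tuple[str, str]],
    n_trials: int = 100,
    train_fraction: float = 0.7,
    seed: int = 0,
    config: SLPConfig | None = None,
    shuffle_labels: bool = False,
) -> TrainResult:
    """Mean accuracy/confusion over independent training trials.

    ``feature_subset`` is a list of (index_name, feature_name) pairs; the
    input layer is sized to exactly that subset (M = m × I_used), the hidden
    layer to I_used + 5, and the output layer to the number of distinct day
    labels.  Each trial draws a fresh stratified train/test split and fresh
    Kaiming weights.  ``shuffle_labels`` permutes labels once per trial — the
    chance-level control.
    """
    if n_trials < 1:
        raise ValidationError("n_trials must be >= 1")
    if not feature_subset:
        raise ValidationError("feature subset is empty")
    X, days, cols = table.to_matrix(feature_subset)
    day_labels = sorted(set(days.tolist()))
    y = np.searchsorted(day_labels, days)
    n_indices = len({idx for idx, _ in cols})
    base = SLPConfig(
        n_inputs=len(cols),
        n_hidden=n_indices + RESERVE_NEURONS,
        n_outputs=len(day_labels),
    )
    if config is not None:
        base = replace(
            config,
            n_inputs=len(cols),
            n_hidden=n_indices + RESERVE_NEURONS,
            n_outputs=len(day_labels),
        )

    master = np.random.SeedSequence([int(seed)])
    accs: list[float] = []
    confusions = np.zeros((base.n_outputs, base.n_outputs))
    t0 = time.perf_counter()
    for trial_ss in master.spawn(n_trials):
        rng = np.random.default_rng(trial_ss)
        y_t = y if not shuffle_labels else rng.permutation(y)
        splitter = StratifiedShuffleSplit(
            n_splits=1,
            train_size=train_fraction,
            random_state=int(rng.integers(2**31)),
        )
        (tr, te), = splitter.split(X, y_t)
        if len(set(y_t[tr])) < base.n_outputs or len(set(y_t[te])) < base.n_outputs:
            raise ValidationError("a class is absent from the train or test split")
        model = train(X[tr], y_t[tr], base, rng)
        acc, conf = evaluate(model, X[te], y_t[te])
        accs.append(acc)
        confusions += conf
    elapsed = time.perf_counter() - t0
    return TrainResult(
        mean_accuracy=float(np.mean(accs)),
        accuracy_per_trial=accs,
        mean_confusion=confusions / n_trials,
        training_time_s=elapsed,
        n_trials=n_trials,
        day_labels=day_labels,
        config=base,
    )
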