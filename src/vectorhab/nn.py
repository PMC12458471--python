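"""Feedforward suitability classifier.

A fully connected network maps a flattened climate feature sequence
(seq_len x n_vars) to a single habitat-suitability logit. The architecture
is three ReLU hidden layers of 128, 64 and 32 units plus a linear output
unit, trained with Adam (learning rate 1e-3) on binary cross-entropy with
logits against presence / pseudo-absence labels. Early stopping monitors
validation AUC and restores the best — not last — epoch's weights.

The implementation is plain numpy, single-threaded and fully seeded, so a
(seed, data) pair reproduces weights bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigurationError, InsufficientDataError, InvalidInputError

log = logging.getLogger(__name__)

DEFAULT_HIDDEN = (128, 64, 32)


@dataclass
class ModelSpec:
    """Architecture and optimizer hyperparameters."""

    input_dim: int
    hidden: tuple[int, ...] = DEFAULT_HIDDEN
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 1000
    patience: int = 100

    def __post_init__(self) -> None:
        if self.input_dim < 1 or any(h < 1 for h in self.hidden):
            raise ConfigurationError("layer widths must be positive")
        if self.patience < 1:
            raise ConfigurationError("patience must be >= 1 epoch")
        self.hidden = tuple(int(h) for h in self.hidden)


@dataclass
class Scaler:
    """Per-input-dimension z-score parameters fitted on training data only.

    Population (1/n) standard deviation convention; zero-variance
    dimensions get sd 1 so they map to a constant zero column.
    """

    mean: np.ndarray
    std: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.mean.size:
            raise InvalidInputError(
                f"expected {self.mean.size} input dims, received {X.shape[-1]}"
            )
        return (X - self.mean) / self.std


def fit_scaler(X: np.ndarray) -> Scaler:
    """Fit column means/standard deviations on the training matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InsufficientDataError("need at least 2 training rows to fit a scaler")
    mean = X.mean(axis=0)
    std = X.std(axis=0)  # population convention
    degenerate = std == 0.0
    if degenerate.any():
        log.warning("fit_scaler: %d zero-variance dimensions set to sd 1", degenerate.sum())
        std = np.where(degenerate, 1.0, std)
    return Scaler(mean=mean, std=std)


# ---------------------------------------------------------------------------
# Network internals
# ---------------------------------------------------------------------------


def _init_weights(spec: ModelSpec, rng: np.random.Generator):
    """Seeded uniform (He-style fan-in scaled) initialization."""
    dims = (spec.input_dim, *spec.hidden, 1)
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        bound = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward(weights, biases, X):
    """Return the logit vector and per-layer activations for backprop."""
    acts = [X]
    h = X
    for W, b in zip(weights[:-1], biases[:-1]):
        h = np.maximum(h @ W + b, 0.0)
        acts.append(h)
    logits = (h @ weights[-1] + biases[-1]).ravel()
    return logits, acts


def _sigmoid(z):
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC (ties counted half) used as the early-stopping monitor."""
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = labels.sum(), (~labels).sum()
    if n_pos == 0 or n_neg == 0:
        raise InvalidInputError("AUC undefined: validation set has a single class")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class TrainedModel:
    """Frozen weights + scaler + provenance; prediction is a pure function."""

    spec: ModelSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    scaler: Scaler
    seed: int
    val_auc_trace: list[float] = field(default_factory=list)
    best_epoch: int = -1
    variable_names: tuple[str, ...] = ()
    seq_len: int = 0

    def predict_logits(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(np.asarray(X, dtype=float).reshape(len(X), -1))
        logits, _ = _forward(self.weights, self.biases, Z)
        return logits

    def save(self, path) -> None:
        """Single-file .npz checkpoint plus a JSON metadata sidecar."""
        arrays = {f"W{i}": W for i, W in enumerate(self.weights)}
        arrays |= {f"b{i}": b for i, b in enumerate(self.biases)}
        arrays["scaler_mean"] = self.scaler.mean
        arrays["scaler_std"] = self.scaler.std
        np.savez(path, **arrays)
        meta = {
            "spec": asdict(self.spec),
            "seed": self.seed,
            "best_epoch": self.best_epoch,
            "val_auc_trace": self.val_auc_trace,
            "variable_names": list(self.variable_names),
            "seq_len": self.seq_len,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        data = np.load(path if str(path).endswith(".npz") else str(path))
        n_layers = len(meta["spec"]["hidden"]) + 1
        return cls(
            spec=ModelSpec(**{**meta["spec"], "hidden": tuple(meta["spec"]["hidden"])}),
            weights=[data[f"W{i}"] for i in range(n_layers)],
            biases=[data[f"b{i}"] for i in range(n_layers)],
            scaler=Scaler(mean=data["scaler_mean"], std=data["scaler_std"]),
            seed=meta["seed"],
            val_auc_trace=meta["val_auc_trace"],
            best_epoch=meta["best_epoch"],
            variable_names=tuple(meta["variable_names"]),
            seq_len=meta["seq_len"],
        )


def train(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    rng_seed: int = 0,
    scaler: Scaler | None = None,
) -> TrainedModel:
    """Train the classifier with early stopping on validation AUC.

    The scaler is fitted on ``X_train`` only (unless supplied) and applied
    frozen to the validation set. Training stops once ``spec.patience``
    epochs pass without a validation-AUC improvement, or at
    ``spec.max_epochs``; the returned weights are the best epoch's snapshot.
    """
    X_train = np.asarray(X_train, dtype=float).reshape(len(X_train), -1)
    X_val = np.asarray(X_val, dtype=float).reshape(len(X_val), -1)
    y_train = np.asarray(y_train, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    if len(X_train) == 0 or len(X_val) == 0:
        raise InsufficientDataError("empty train or validation set")
    if len(set(y_val.tolist())) < 2:
        raise InvalidInputError("AUC undefined: validation set has a single class")

    rng = np.random.default_rng(rng_seed)
    if scaler is None:
        scaler = fit_scaler(X_train)
    Zt, Zv = scaler.transform(X_train), scaler.transform(X_val)

    weights, biases = _init_weights(spec, rng)
    mW = [np.zeros_like(W) for W in weights]
    vW = [np.zeros_like(W) for W in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t_step = 0

    best_auc, best_epoch, since_best = -np.inf, -1, 0
    best_W = [W.copy() for W in weights]
    best_b = [b.copy() for b in biases]
    trace: list[float] = []
    n = len(Zt)

    for epoch in range(spec.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            Xb, yb = Zt[idx], y_train[idx]
            logits, acts = _forward(weights, biases, Xb)
            # BCE-with-logits gradient: sigmoid(z) - y
            delta = (_sigmoid(logits) - yb)[:, None] / len(idx)
            grads_W, grads_b = [], []
            for li in range(len(weights) - 1, -1, -1):
                grads_W.append(acts[li].T @ delta)
                grads_b.append(delta.sum(axis=0))
                if li > 0:
                    delta = (delta @ weights[li].T) * (acts[li] > 0)
            grads_W.reverse()
            grads_b.reverse()
            t_step += 1
            for li in range(len(weights)):
                for params, grads, m, v in (
                    (weights, grads_W, mW, vW),
                    (biases, grads_b, mb, vb),
                ):
                    m[li] = beta1 * m[li] + (1 - beta1) * grads[li]
                    v[li] = beta2 * v[li] + (1 - beta2) * grads[li] ** 2
                    m_hat = m[li] / (1 - beta1**t_step)
                    v_hat = v[li] / (1 - beta2**t_step)
                    params[li] = params[li] - spec.learning_rate * m_hat / (
                        np.sqrt(v_hat) + eps
                    )
        val_logits, _ = _forward(weights, biases, Zv)
        auc = _rank_auc(val_logits, y_val.astype(bool))
        trace.append(auc)
        if auc > best_auc:
            best_auc, best_epoch, since_best = auc, epoch, 0
            best_W = [W.copy() for W in weights]
            best_b = [b.copy() for b in biases]
        else:
            since_best += 1
            if since_best >= spec.patience:
                break

    log.info(
        "train: stopped after %d epochs, best val AUC %.4f at epoch %d",
        len(trace),
        best_auc,
        best_epoch,
    )
    return TrainedModel(
        spec=spec,
        weights=best_W,
        biases=best_b,
        scaler=scaler,
        seed=rng_seed,
        val_auc_trace=trace,
        best_epoch=best_epoch,
    )


def predict_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Sigmoid suitability scores in (0, 1), order-preserving with the logit."""
    return _sigmoid(model.predict_logits(np.asarray(X, dtype=float)))


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    fold_labels: np.ndarray,
    spec: ModelSpec,
    rng_seed: int = 0,
    patience: int = 10,
) -> list[float]:
    """k-fold cross-validation; each fold is held out once (patience 10).

    ``fold_labels`` assigns every row an integer fold index; returns the
    held-out AUC per fold in fold-index order.
    """
    X = np.asarray(X, dtype=float).reshape(len(X), -1)
    y = np.asarray(y, dtype=float).ravel()
    fold_labels = np.asarray(fold_labels)
    aucs = []
    for fold in sorted(set(fold_labels.tolist())):
        val = fold_labels == fold
        fold_spec = ModelSpec(**{**asdict(spec), "patience": patience})
        model = train(fold_spec, X[~val], y[~val], X[val], y[val], rng_seed=rng_seed)
        aucs.append(_rank_auc(model.predict_logits(X[val]), y[val].astype(bool)))
    return aucs


def sequences_to_matrix(sequences) -> np.ndarray:
    """Stack FeatureSequence objects into a flattened design matrix."""
    return np.stack([seq.matrix.ravel() for seq in sequences])
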