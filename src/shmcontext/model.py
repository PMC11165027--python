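"""A small convolutional regressor: one-hot 15-mer -> predicted mutation
frequency of the central nucleotide, in [0, 1].

The network is one 1-D convolution over the 15 positions (4 input
channels), ReLU, a flattening of the position-resolved feature map into a
dense ReLU layer, and a sigmoid output unit; trained with mean-squared
error and Adam.  Forward and backward passes are written directly in
numpy, which also yields exact gradients of the prediction with respect
to the input matrix — the quantity integrated-gradients attribution
needs.  The feature map is flattened rather than pooled because the
target is position-specific: mutability of the *central* base depends on
where in the window a motif sits, and global pooling discards that.

All stochasticity (weight initialisation, minibatch shuffling) is keyed
to ``config.seed``; training twice with the same data and config gives
identical predictions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np


@dataclass(frozen=True)
class ModelConfig:
    conv_filters: int = 32
    conv_width: int = 5
    dense_units: int = 16
    learning_rate: float = 0.003
    epochs: int = 100
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_width > 15:
            raise ValueError("conv_width must be <= 15")
        for name in ("conv_filters", "conv_width", "dense_units", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))), np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))


def _as_batch(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None, :, :]
    if X.ndim != 3 or X.shape[1] != 4:
        raise ValueError(f"expected (N, 4, k) one-hot input, got shape {X.shape}")
    return X


@dataclass
class TrainedModel:
    """Weights + config; prediction is deterministic once trained."""

    weights: dict[str, np.ndarray]
    config: ModelConfig
    training_loss_history: list[float] = field(default_factory=list)

    # ----- forward ---------------------------------------------------
    def _forward(self, X: np.ndarray):
        W1, b1 = self.weights["W1"], self.weights["b1"]
        W2, b2 = self.weights["W2"], self.weights["b2"]
        w3, b3 = self.weights["w3"], self.weights["b3"]
        F, _, w = W1.shape
        N, _, k = X.shape
        T = k - w + 1
        z1 = np.zeros((N, F, T))
        for j in range(w):
            z1 += np.einsum("nct,fc->nft", X[:, :, j : j + T], W1[:, :, j])
        z1 += b1[None, :, None]
        a1 = np.maximum(z1, 0.0)
        flat = a1.reshape(N, F * T)
        z2 = flat @ W2.T + b2
        a2 = np.maximum(z2, 0.0)
        z3 = a2 @ w3 + b3
        y = _sigmoid(z3)
        return X, z1, a1, z2, a2, z3, y

    def predict_batch(self, X) -> np.ndarray:
        """Predicted mutation frequencies, shape (N,), each in [0, 1]."""
        return self._forward(_as_batch(X))[-1]

    def predict(self, x) -> float:
        return float(self.predict_batch(x)[0])

    # ----- gradients -------------------------------------------------
    def _backward_to_input(self, cache, dy: np.ndarray) -> np.ndarray:
        """Backpropagate an upstream d(loss-or-output)/dy to the input."""
        X, z1, a1, z2, a2, z3, y = cache
        W1, W2, w3 = self.weights["W1"], self.weights["W2"], self.weights["w3"]
        F, _, w = W1.shape
        N, _, k = X.shape
        T = k - w + 1
        dz3 = dy * y * (1.0 - y)
        da2 = dz3[:, None] * w3[None, :]
        dz2 = da2 * (z2 > 0)
        dflat = dz2 @ W2
        dz1 = dflat.reshape(N, F, T) * (z1 > 0)
        dX = np.zeros_like(X)
        for j in range(w):
            dX[:, :, j : j + T] += np.einsum("nft,fc->nct", dz1, W1[:, :, j])
        return dX

    def input_gradients(self, X) -> np.ndarray:
        """d prediction / d input for each sample, shape (N, 4, k)."""
        Xb = _as_batch(X)
        cache = self._forward(Xb)
        return self._backward_to_input(cache, np.ones(Xb.shape[0]))

    def input_gradient(self, x) -> np.ndarray:
        return self.input_gradients(x)[0]

    # ----- persistence ----------------------------------------------
    def save(self, path) -> None:
        np.savez(
            path,
            config=json.dumps(asdict(self.config)),
            loss_history=np.asarray(self.training_loss_history),
            **self.weights,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path, allow_pickle=False)
        config = ModelConfig(**json.loads(str(data["config"])))
        weights = {k: data[k] for k in ("W1", "b1", "W2", "b2", "w3", "b3")}
        return cls(weights, config, list(data["loss_history"]))


def _init_weights(config: ModelConfig, k: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    F, w, D = config.conv_filters, config.conv_width, config.dense_units
    T = k - w + 1
    return {
        "W1": rng.normal(0.0, np.sqrt(2.0 / (4 * w)), size=(F, 4, w)),
        "b1": np.zeros(F),
        "W2": rng.normal(0.0, np.sqrt(2.0 / (F * T)), size=(D, F * T)),
        "b2": np.zeros(D),
        "w3": rng.normal(0.0, np.sqrt(1.0 / D), size=D),
        "b3": np.zeros(()),
    }


def train_model(dataset, config: ModelConfig = ModelConfig()) -> TrainedModel:
    """Fit the regressor with Adam on mean-squared error.

    ``dataset`` is either a list of ``(one_hot_matrix, mut_freq)`` pairs
    or a tuple ``(X, y)`` with X of shape (N, 4, k) and y in [0, 1].
    """
    if isinstance(dataset, tuple) and len(dataset) == 2:
        X, y = dataset
    else:
        dataset = list(dataset)
        if not dataset:
            raise ValueError("training dataset is empty")
        X = np.stack([np.asarray(m, dtype=float) for m, _ in dataset])
        y = np.array([t for _, t in dataset], dtype=float)
    X = _as_batch(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("training dataset is empty")
    if (y < 0).any() or (y > 1).any():
        raise ValueError("targets must lie in [0, 1]")

    rng = np.random.default_rng(config.seed)
    k = X.shape[2]
    model = TrainedModel(_init_weights(config, k, rng), config)

    # Adam state
    m = {key: np.zeros_like(v) for key, v in model.weights.items()}
    v = {key: np.zeros_like(val) for key, val in model.weights.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    n = X.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, config.batch_size):
            batch = order[lo : lo + config.batch_size]
            Xb, yb = X[batch], y[batch]
            cache = model._forward(Xb)
            pred = cache[-1]
            resid = pred - yb
            epoch_loss += float((resid**2).sum())
            dy = 2.0 * resid / len(batch)
            grads = _param_grads(model, cache, dy)
            step += 1
            for key in model.weights:
                g = grads[key]
                m[key] = beta1 * m[key] + (1 - beta1) * g
                v[key] = beta2 * v[key] + (1 - beta2) * g**2
                mhat = m[key] / (1 - beta1**step)
                vhat = v[key] / (1 - beta2**step)
                model.weights[key] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        model.training_loss_history.append(epoch_loss / n)
    return model


def _param_grads(model: TrainedModel, cache, dy: np.ndarray) -> dict[str, np.ndarray]:
    X, z1, a1, z2, a2, z3, y = cache
    W1, W2, w3 = model.weights["W1"], model.weights["W2"], model.weights["w3"]
    F, _, w = W1.shape
    N, _, k = X.shape
    T = k - w + 1
    dz3 = dy * y * (1.0 - y)
    grads: dict[str, np.ndarray] = {}
    grads["b3"] = np.asarray(dz3.sum())
    grads["w3"] = a2.T @ dz3
    da2 = dz3[:, None] * w3[None, :]
    dz2 = da2 * (z2 > 0)
    grads["b2"] = dz2.sum(axis=0)
    flat = a1.reshape(N, F * T)
    grads["W2"] = dz2.T @ flat
    dflat = dz2 @ W2
    dz1 = dflat.reshape(N, F, T) * (z1 > 0)
    grads["b1"] = dz1.sum(axis=(0, 2))
    gW1 = np.zeros_like(W1)
    for j in range(w):
        gW1[:, :, j] = np.einsum("nft,nct->fc", dz1, X[:, :, j : j + T])
    grads["W1"] = gW1
    return grads


def evaluate_correlation(predicted, observed) -> tuple[float, float]:
    """Pearson r between predicted and observed frequencies, with the
    Wald p-value of the regression slope (delegates to the stats layer)."""
    from .stats import pearson_with_wald

    return pearson_with_wald(np.asarray(predicted, float), np.asarray(observed, float))
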