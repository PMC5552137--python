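"""Back-propagation multilayer perceptron with an adaptive learning rate.

A fully connected feed-forward network (default 173 -> 20 -> 1, logistic
sigmoid throughout) trained by full-batch gradient descent on mean squared
error:

    theta_{m+1} = theta_m - gamma_m * grad K(theta_m)

The learning rate adapts to progress: a step that lowers the loss is
accepted and gamma is multiplied by an increase factor (> 1); a step that
raises it is rejected — the weights are discarded — and gamma is multiplied
by a decrease factor in (0, 1) before retrying.  The accepted-loss sequence
K(theta_0) >= K(theta_1) >= ... is therefore non-increasing by construction.

Everything is seeded and deterministic: same seed + same data = identical
trained weights.  A trained model (network + feature scaler) serializes to
versioned JSON so predictions are reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import ScalerParams, apply_scaler, fit_scaler

MODEL_FORMAT_VERSION = 1


@dataclass
class NetworkParams:
    """Weight matrices and bias vectors of a feed-forward sigmoid network."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("one bias vector per weight matrix required")
        for W, b in zip(self.weights, self.biases):
            if W.shape[0] != b.shape[0]:
                raise ValueError("bias length must match layer output size")
        for W1, W2 in zip(self.weights, self.weights[1:]):
            if W2.shape[1] != W1.shape[0]:
                raise ValueError("inconsistent consecutive layer shapes")

    @property
    def layout(self) -> tuple[int, ...]:
        return (self.weights[0].shape[1],) + tuple(W.shape[0]
                                                   for W in self.weights)

    def copy(self) -> "NetworkParams":
        return NetworkParams([W.copy() for W in self.weights],
                             [b.copy() for b in self.biases])


@dataclass
class TrainConfig:
    """Gradient-descent settings; all exposed, all with documented defaults."""

    lr0: float = 0.5
    lr_increase: float = 1.05
    lr_decrease: float = 0.7
    max_epochs: int = 1000
    tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("initial learning rate must be positive")
        if self.lr_increase <= 1:
            raise ValueError("increase factor must exceed 1")
        if not 0 < self.lr_decrease < 1:
            raise ValueError("decrease factor must lie in (0, 1)")


@dataclass
class TrainState:
    """Progress of one training run."""

    epochs: int = 0
    lr: float = 0.0
    loss_history: list[float] = field(default_factory=list)
    n_rejected: int = 0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_network(layout: Sequence[int], seed: int = 0) -> NetworkParams:
    """Seeded initialization: weights uniform in ±1/sqrt(fan_in), biases 0."""
    layout = tuple(int(s) for s in layout)
    if len(layout) < 2 or any(s <= 0 for s in layout):
        raise ValueError(f"invalid layout {layout}")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(layout, layout[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return NetworkParams(weights, biases)


def _forward_all(params: NetworkParams, X: np.ndarray) -> list[np.ndarray]:
    """Activations of every layer; X is (n_samples, n_inputs)."""
    acts = [X]
    a = X
    for W, b in zip(params.weights, params.biases):
        a = _sigmoid(a @ W.T + b)
        acts.append(a)
    return acts


def forward(params: NetworkParams, fv: np.ndarray) -> float | np.ndarray:
    """Network score(s) in (0, 1) for one feature vector or a matrix."""
    fv = np.asarray(fv, dtype=float)
    single = fv.ndim == 1
    X = fv[None, :] if single else fv
    if X.shape[1] != params.layout[0]:
        raise ValueError(
            f"input size {X.shape[1]} != network input {params.layout[0]}")
    out = _forward_all(params, X)[-1][:, 0]
    return float(out[0]) if single else out


def loss(params: NetworkParams, X: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error K(theta) over the batch."""
    return float(np.mean((forward(params, X) - y) ** 2))


def _gradients(params: NetworkParams, X: np.ndarray, y: np.ndarray
               ) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Backprop gradients of the MSE and the loss at theta."""
    n = X.shape[0]
    acts = _forward_all(params, X)
    out = acts[-1][:, 0]
    K = float(np.mean((out - y) ** 2))
    # delta at output: dK/dz = 2(out - y)/n * out(1-out)
    delta = (2.0 / n) * (out - y)[:, None] * acts[-1] * (1 - acts[-1])
    gW: list[np.ndarray] = [None] * len(params.weights)  # type: ignore
    gb: list[np.ndarray] = [None] * len(params.biases)  # type: ignore
    for layer in range(len(params.weights) - 1, -1, -1):
        gW[layer] = delta.T @ acts[layer]
        gb[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ params.weights[layer]) \
                * acts[layer] * (1 - acts[layer])
    return gW, gb, K


def train_epoch(params: NetworkParams, X: np.ndarray, y: np.ndarray,
                lr: float) -> tuple[NetworkParams, float]:
    """One full-batch gradient step; returns (candidate params, loss before)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot train on empty data")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X/y length mismatch")
    gW, gb, K = _gradients(params, X, y)
    cand = NetworkParams(
        [W - lr * g for W, g in zip(params.weights, gW)],
        [b - lr * g for b, g in zip(params.biases, gb)],
    )
    return cand, K


def train(params: NetworkParams, X: np.ndarray, y: np.ndarray,
          config: TrainConfig) -> tuple[NetworkParams, TrainState]:
    """Adaptive-learning-rate gradient descent.

    Accept a step (and raise gamma) only when it does not increase the loss;
    otherwise restore the previous weights and lower gamma, reusing the same
    gradient for the shorter retry step.  Stops at ``max_epochs``, when an
    accepted improvement falls below ``tol``, or when gamma underflows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("cannot train on empty data")
    params = params.copy()
    lr = config.lr0
    gW, gb, K = _gradients(params, X, y)
    if not np.isfinite(K):
        raise FloatingPointError(f"non-finite initial loss {K}")
    state = TrainState(lr=lr, loss_history=[K])
    for _ in range(config.max_epochs):
        state.epochs += 1
        cand = NetworkParams(
            [W - lr * g for W, g in zip(params.weights, gW)],
            [b - lr * g for b, g in zip(params.biases, gb)],
        )
        K_cand = loss(cand, X, y)
        if not np.isfinite(K_cand):
            raise FloatingPointError(
                f"non-finite loss at epoch {state.epochs} (lr={lr:g})")
        if K_cand <= K:
            improvement = K - K_cand
            params, K = cand, K_cand
            state.loss_history.append(K)
            lr *= config.lr_increase
            gW, gb, _ = _gradients(params, X, y)
            if improvement < config.tol:
                break
        else:
            state.n_rejected += 1
            lr *= config.lr_decrease
            if lr < 1e-15:
                break
    state.lr = lr
    return params, state


def predict(params: NetworkParams, fv: np.ndarray,
            threshold: float = 0.5) -> int | np.ndarray:
    """Hard label(s): positive iff score >= threshold."""
    score = forward(params, fv)
    if isinstance(score, float):
        return int(score >= threshold)
    return (score >= threshold).astype(np.int64)


# ---------------------------------------------------------------------------
# Trained model = scaler + network, serializable
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted feature scaler plus a trained network."""

    scaler: ScalerParams
    network: NetworkParams
    config: TrainConfig
    threshold: float = 0.5

    def scores(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_1d(forward(self.network, apply_scaler(self.scaler, X)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.scores(X) >= self.threshold).astype(np.int64)


def fit_model(X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None,
              hidden: Sequence[int] = (20,)) -> tuple[TrainedModel, TrainState]:
    """Standardize features (on this data only), then train the network."""
    config = config or TrainConfig()
    scaler = fit_scaler(X)
    Xs = apply_scaler(scaler, X)
    layout = (X.shape[1], *hidden, 1)
    net = init_network(layout, seed=config.seed)
    net, state = train(net, Xs, y, config)
    return TrainedModel(scaler, net, config), state


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model to versioned JSON."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "layout": list(model.network.layout),
        "weights": [W.tolist() for W in model.network.weights],
        "biases": [b.tolist() for b in model.network.biases],
        "scaler_mean": model.scaler.mean.tolist(),
        "scaler_scale": model.scaler.scale.tolist(),
        "threshold": model.threshold,
        "config": {
            "lr0": model.config.lr0,
            "lr_increase": model.config.lr_increase,
            "lr_decrease": model.config.lr_decrease,
            "max_epochs": model.config.max_epochs,
            "tol": model.config.tol,
            "seed": model.config.seed,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path: str | Path) -> TrainedModel:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {doc.get('format_version')}")
    net = NetworkParams([np.array(W, dtype=float) for W in doc["weights"]],
                        [np.array(b, dtype=float) for b in doc["biases"]])
    scaler = ScalerParams(np.array(doc["scaler_mean"]),
                          np.array(doc["scaler_scale"]))
    return TrainedModel(scaler, net, TrainConfig(**doc["config"]),
                        threshold=doc["threshold"])
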