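"""Back-propagation neural network with momentum.

A single-hidden-layer feed-forward net: sigmoid hidden units, a linear
output unit, trained by classic incremental (per-sample) gradient descent
with a momentum term,

    dw(t) = eta * dE/dw(t-1) + mom * dw(t-1),      w(t) = w(t-1) - dw(t)

where E = e^2 / 2 is the single-pattern squared error.  Presentation order
is reshuffled every epoch with a generator derived from the configured
seed — without shuffling, slowly trending components make the weights chase
the drifting target and never settle.  The full-batch mean squared error is
evaluated at the top of every epoch and training stops once it falls below
``goal_mse`` or after ``max_epochs`` passes.  Weight initialization is
uniform in [-0.5, 0.5] from the same seed, so runs are exactly
reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..series import SlidingWindowDataset

__all__ = ["BPNNConfig", "TrainedBPNN", "bpnn_train", "bpnn_predict"]


@dataclass(frozen=True)
class BPNNConfig:
    """Architecture and training hyperparameters.

    Defaults follow the usual setup for daily concentration series: 4 lag
    inputs, 9 hidden nodes, 1 output; learning rate 0.01; training goal
    4e-5 on [0, 1]-scaled targets; at most 1000 epochs.  The momentum
    coefficient has no canonical printed value; 0.9 is the conventional
    choice.
    """

    n_input: int = 4
    n_hidden: int = 9
    n_output: int = 1
    learning_rate: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 1000
    goal_mse: float = 0.00004
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if min(self.n_input, self.n_hidden, self.n_output) < 1:
            raise ValueError("layer sizes must be positive")


@dataclass
class TrainedBPNN:
    """Fitted network parameters plus the per-epoch training-error trace."""

    w_hidden: np.ndarray  # (n_input, n_hidden)
    b_hidden: np.ndarray  # (n_hidden,)
    w_output: np.ndarray  # (n_hidden, n_output)
    b_output: np.ndarray  # (n_output,)
    error_trace: np.ndarray
    config: BPNNConfig

    @property
    def n_input(self) -> int:
        return self.w_hidden.shape[0]

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        return bpnn_predict(self, inputs)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _init_params(config: BPNNConfig):
    rng = np.random.default_rng(config.seed)
    w1 = rng.uniform(-0.5, 0.5, size=(config.n_input, config.n_hidden))
    b1 = rng.uniform(-0.5, 0.5, size=config.n_hidden)
    w2 = rng.uniform(-0.5, 0.5, size=(config.n_hidden, config.n_output))
    b2 = rng.uniform(-0.5, 0.5, size=config.n_output)
    return w1, b1, w2, b2


def bpnn_train(data: SlidingWindowDataset, config: BPNNConfig = BPNNConfig()) -> TrainedBPNN:
    """Train the network by incremental gradient descent with momentum.

    Raises on an empty dataset, on an input-width mismatch, and on a
    non-finite gradient (reported with the epoch at which it appeared).
    """
    X = np.asarray(data.inputs, dtype=float)
    y = np.asarray(data.targets, dtype=float).reshape(-1, 1)
    if len(X) == 0:
        raise ValueError("cannot train on an empty dataset")
    if X.shape[1] != config.n_input:
        raise ValueError(f"dataset lag {X.shape[1]} != configured n_input {config.n_input}")

    w1, b1, w2, b2 = _init_params(config)
    vw1 = np.zeros_like(w1)
    vb1 = np.zeros_like(b1)
    vw2 = np.zeros_like(w2)
    vb2 = np.zeros_like(b2)
    eta, mom = config.learning_rate, config.momentum
    order_rng = np.random.default_rng(config.seed + 1)
    trace = []

    for epoch in range(config.max_epochs):
        h = _sigmoid(X @ w1 + b1)
        out = h @ w2 + b2
        mse = float(np.mean((out - y) ** 2))
        trace.append(mse)
        if mse < config.goal_mse:
            break
        for i in order_rng.permutation(len(X)):
            x = X[i: i + 1]
            target = y[i]
            h = _sigmoid(x @ w1 + b1)
            o = h @ w2 + b2
            e = o - target  # dE/do for E = e^2 / 2
            gw2 = h.T @ e
            gb2 = e.ravel()
            g_h = (e @ w2.T) * h * (1.0 - h)
            gw1 = x.T @ g_h
            gb1 = g_h.ravel()
            vw1 = eta * gw1 + mom * vw1
            vb1 = eta * gb1 + mom * vb1
            vw2 = eta * gw2 + mom * vw2
            vb2 = eta * gb2 + mom * vb2
            w1 = w1 - vw1
            b1 = b1 - vb1
            w2 = w2 - vw2
            b2 = b2 - vb2
        if not (np.all(np.isfinite(w1)) and np.all(np.isfinite(w2))):
            raise FloatingPointError(f"non-finite gradient at epoch {epoch}")

    return TrainedBPNN(
        w_hidden=w1,
        b_hidden=b1,
        w_output=w2,
        b_output=b2,
        error_trace=np.asarray(trace),
        config=config,
    )


def bpnn_predict(model: TrainedBPNN, inputs: np.ndarray) -> np.ndarray:
    """One output per input row; a pure function of (model, inputs)."""
    X = np.asarray(inputs, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[0] == 0:
        return np.empty(0)
    if X.shape[1] != model.n_input:
        raise ValueError(f"input width {X.shape[1]} != model n_input {model.n_input}")
    h = _sigmoid(X @ model.w_hidden + model.b_hidden)
    return (h @ model.w_output + model.b_output).ravel()
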