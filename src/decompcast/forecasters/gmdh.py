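"""Group method of data handling: a self-organizing polynomial network.

Each layer forms one candidate neuron per unordered pair (u, v) of the
current inputs, fitting the quadratic polynomial

    y = a0 + a1 u + a2 v + a3 u^2 + a4 v^2 + a5 u v

by least squares on a training portion.  Candidates are ranked by an
external criterion — RMSE on a held-out validation portion — and the best
``max_neurons`` survive as the next layer's inputs.  Growth stops as soon
as a new layer fails to improve the best external criterion ("survival of
the fittest"); the final model is the chain of neurons feeding the overall
best neuron.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ..series import SlidingWindowDataset

__all__ = ["GMDHConfig", "GMDHNeuron", "GMDHModel", "gmdh_fit", "gmdh_predict"]

_RIDGE = 1e-8


@dataclass(frozen=True)
class GMDHConfig:
    max_layers: int = 5
    max_neurons: int | None = None  # default: n_input of the dataset
    validation_fraction: float = 0.3
    seed: int = 0


@dataclass(frozen=True)
class GMDHNeuron:
    """One quadratic unit: parent column indices in the previous layer,
    6 polynomial coefficients, and its external-criterion score."""

    parents: tuple[int, int]
    coefficients: np.ndarray  # (6,)
    score: float

    def evaluate(self, prev: np.ndarray) -> np.ndarray:
        u = prev[:, self.parents[0]]
        v = prev[:, self.parents[1]]
        a = self.coefficients
        return a[0] + a[1] * u + a[2] * v + a[3] * u**2 + a[4] * v**2 + a[5] * u * v


@dataclass(frozen=True)
class GMDHModel:
    """Selected neurons per layer plus the index of the final output neuron
    in the last layer."""

    layers: tuple  # tuple of tuples of GMDHNeuron
    output_index: int
    n_input: int

    @property
    def criterion(self) -> float:
        return self.layers[-1][self.output_index].score

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        return gmdh_predict(self, inputs)


def _design(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(u), u, v, u**2, v**2, u * v])


def _fit_neuron(u, v, y) -> np.ndarray:
    A = _design(u, v)
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < 6:
        warnings.warn("degenerate candidate design; using ridge fallback", RuntimeWarning)
        coef = np.linalg.solve(A.T @ A + _RIDGE * np.eye(6), A.T @ y)
    return coef


def gmdh_fit(data: SlidingWindowDataset, config: GMDHConfig = GMDHConfig()) -> GMDHModel:
    """Grow the polynomial network until the external criterion stops
    improving.

    The training segment is split chronologically: the last
    ``validation_fraction`` of rows is the held-out part scored by the
    external criterion; coefficients are fitted on the rest.
    """
    X = np.asarray(data.inputs, dtype=float)
    y = np.asarray(data.targets, dtype=float)
    n, d = X.shape
    if n < 10:
        raise ValueError("GMDH needs at least 10 samples")
    if d < 2:
        raise ValueError("GMDH needs at least 2 inputs")
    max_neurons = config.max_neurons or d
    n_val = max(1, int(round(config.validation_fraction * n)))
    n_fit = n - n_val
    if n_fit < 6:
        raise ValueError("too few fitting rows after validation split")
    fit_idx = slice(0, n_fit)
    val_idx = slice(n_fit, n)

    layers: list[tuple[GMDHNeuron, ...]] = []
    current_fit = X[fit_idx]
    current_val = X[val_idx]
    best_so_far = np.inf

    for _ in range(config.max_layers):
        width = current_fit.shape[1]
        candidates = []
        for i, j in combinations(range(width), 2):
            coef = _fit_neuron(current_fit[:, i], current_fit[:, j], y[fit_idx])
            neuron = GMDHNeuron(parents=(i, j), coefficients=coef, score=np.nan)
            pred_val = neuron.evaluate(current_val)
            score = float(np.sqrt(np.mean((pred_val - y[val_idx]) ** 2)))
            candidates.append(GMDHNeuron(parents=(i, j), coefficients=coef, score=score))
        candidates.sort(key=lambda nrn: nrn.score)
        survivors = tuple(candidates[:max_neurons])
        layer_best = survivors[0].score
        if layer_best >= best_so_far:
            break  # new generation no better than the previous one
        best_so_far = layer_best
        layers.append(survivors)
        current_fit = np.column_stack([nrn.evaluate(current_fit) for nrn in survivors])
        current_val = np.column_stack([nrn.evaluate(current_val) for nrn in survivors])
        if current_fit.shape[1] < 2:
            break

    if not layers:
        raise RuntimeError("GMDH could not construct any improving layer")
    return GMDHModel(layers=tuple(layers), output_index=0, n_input=d)


def gmdh_predict(model: GMDHModel, inputs: np.ndarray) -> np.ndarray:
    """Propagate inputs through every layer; output of the best final neuron."""
    X = np.asarray(inputs, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[0] == 0:
        return np.empty(0)
    if X.shape[1] != model.n_input:
        raise ValueError(f"input width {X.shape[1]} != model n_input {model.n_input}")
    current = X
    for layer in model.layers[:-1]:
        current = np.column_stack([nrn.evaluate(current) for nrn in layer])
    return model.layers[-1][model.output_index].evaluate(current)
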