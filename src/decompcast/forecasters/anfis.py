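"""Adaptive network-based fuzzy inference system (Takagi-Sugeno type).

Five layers: (1) Gaussian memberships mu(x) = exp(-(x - c)^2 / (2 s^2)) per
input per rule; (2) rule firing strength by the product t-norm over the
rule's premise memberships; (3) normalization w_bar_i = w_i / sum_j w_j;
(4) per-rule first-order linear consequent f_i = a_i . x + b_i; (5) output
sum_i w_bar_i f_i.

Training is the classic hybrid scheme: per epoch the consequent parameters
are solved exactly by linear least squares on the normalized firings (with
a small ridge fallback if the system is singular), then premise centers and
spreads take one gradient-descent step on the squared error.  Stops at the
goal MSE or the epoch cap.

Two constructors are provided: a full grid partition (``anfis_init_grid``,
mfs_per_input^n_input rules) and a fuzzy-c-means seeding
(``anfis_fcm_build``, one rule per cluster) — the latter is the "ANFIS-FCM"
ensemble member.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from itertools import product

import numpy as np

from ..series import SlidingWindowDataset
from .fcm import fcm_cluster

__all__ = [
    "ANFISModel",
    "anfis_init_grid",
    "anfis_forward",
    "anfis_predict",
    "anfis_train",
    "anfis_fcm_build",
]

_RIDGE = 1e-8


@dataclass(frozen=True)
class ANFISModel:
    """Rule base: per-rule per-input Gaussian premises and linear consequents.

    centers, spreads: (n_rules, n_input); consequents: (n_rules, n_input + 1)
    with the constant term last.
    """

    centers: np.ndarray
    spreads: np.ndarray
    consequents: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.spreads <= 0):
            raise ValueError("all membership spreads must be positive")
        if self.consequents.shape != (self.n_rules, self.n_input + 1):
            raise ValueError("consequents must be (n_rules, n_input + 1)")

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_input(self) -> int:
        return self.centers.shape[1]

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        return anfis_predict(self, inputs)


def anfis_init_grid(
    n_input: int = 4,
    mfs_per_input: int = 2,
    spread: float = 0.5,
    input_range: tuple[float, float] = (0.0, 1.0),
) -> ANFISModel:
    """Grid-partition rule base: MF centers evenly spaced over
    ``input_range``, one rule per combination (mfs_per_input^n_input rules),
    zero-initialized consequents."""
    if mfs_per_input < 1:
        raise ValueError("mfs_per_input must be >= 1")
    lo, hi = input_range
    if mfs_per_input == 1:
        mf_centers = np.array([(lo + hi) / 2.0])
    else:
        mf_centers = np.linspace(lo, hi, mfs_per_input)
    combos = np.array(list(product(mf_centers, repeat=n_input)))
    n_rules = len(combos)
    return ANFISModel(
        centers=combos,
        spreads=np.full((n_rules, n_input), float(spread)),
        consequents=np.zeros((n_rules, n_input + 1)),
    )


def _firing(model: ANFISModel, X: np.ndarray) -> np.ndarray:
    """Rule firing strengths, shape (n_samples, n_rules); product t-norm."""
    z = (X[:, None, :] - model.centers[None, :, :]) / model.spreads[None, :, :]
    log_mu = -0.5 * z**2
    return np.exp(log_mu.sum(axis=2))


def anfis_forward(model: ANFISModel, x: np.ndarray):
    """Evaluate one input vector through all five layers.

    Returns (output, firing strengths w_i, normalized firings w_bar_i);
    the normalized firings always sum to 1.  Raises if every rule fires
    with strength zero (input outside the fuzzy support).
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) != model.n_input:
        raise ValueError(f"input width {len(x)} != model n_input {model.n_input}")
    w = _firing(model, x.reshape(1, -1)).ravel()
    total = w.sum()
    if total == 0.0:
        raise ValueError("input outside fuzzy support: all firing strengths are zero")
    w_bar = w / total
    f_rules = model.consequents[:, :-1] @ x + model.consequents[:, -1]
    return float(w_bar @ f_rules), w, w_bar


def anfis_predict(model: ANFISModel, inputs: np.ndarray) -> np.ndarray:
    """Vectorized layer-5 output, one value per input row."""
    X = np.asarray(inputs, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[0] == 0:
        return np.empty(0)
    if X.shape[1] != model.n_input:
        raise ValueError(f"input width {X.shape[1]} != model n_input {model.n_input}")
    w = _firing(model, X)
    totals = w.sum(axis=1, keepdims=True)
    if np.any(totals == 0.0):
        bad = int(np.flatnonzero(totals.ravel() == 0.0)[0])
        raise ValueError(f"input outside fuzzy support at row {bad}")
    w_bar = w / totals
    f_rules = X @ model.consequents[:, :-1].T + model.consequents[:, -1]
    return np.sum(w_bar * f_rules, axis=1)


def _lse_consequents(model: ANFISModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve the layer-4 parameters by least squares on normalized firings."""
    n, d = X.shape
    w = _firing(model, X)
    totals = w.sum(axis=1, keepdims=True)
    if np.any(totals == 0.0):
        raise ValueError("input outside fuzzy support during consequent fit")
    w_bar = w / totals
    Xa = np.hstack([X, np.ones((n, 1))])
    # design: column block per rule, w_bar_i * [x, 1]
    A = (w_bar[:, :, None] * Xa[:, None, :]).reshape(n, model.n_rules * (d + 1))
    coef, residuals, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("singular consequent system; using ridge fallback", RuntimeWarning)
        AtA = A.T @ A + _RIDGE * np.eye(A.shape[1])
        coef = np.linalg.solve(AtA, A.T @ y)
    return coef.reshape(model.n_rules, d + 1)


def _premise_gradients(model: ANFISModel, X: np.ndarray, y: np.ndarray):
    """Gradients of the mean squared error w.r.t. centers and spreads."""
    n = len(X)
    w = _firing(model, X)
    totals = w.sum(axis=1, keepdims=True)
    w_bar = w / totals
    f_rules = X @ model.consequents[:, :-1].T + model.consequents[:, -1]
    out = np.sum(w_bar * f_rules, axis=1)
    err = out - y  # (n,)
    # dE/dw_i = 2 err (f_i - out) / total ; chain to centers and spreads
    dE_dw = (2.0 / n) * err[:, None] * (f_rules - out[:, None]) / totals
    diff = X[:, None, :] - model.centers[None, :, :]
    inv_s2 = 1.0 / model.spreads**2
    dw_dc = w[:, :, None] * diff * inv_s2[None, :, :]
    dw_ds = w[:, :, None] * diff**2 * (inv_s2 / model.spreads)[None, :, :]
    g_c = np.einsum("nr,nrd->rd", dE_dw, dw_dc)
    g_s = np.einsum("nr,nrd->rd", dE_dw, dw_ds)
    return g_c, g_s, float(np.mean(err**2))


def anfis_train(
    model: ANFISModel,
    data: SlidingWindowDataset,
    epochs: int = 50,
    lr: float = 0.01,
    goal_mse: float = 0.00004,
) -> ANFISModel:
    """Hybrid training: exact LSE for consequents, one premise gradient step
    per epoch.  Returns a new model; the input model is not modified."""
    X = np.asarray(data.inputs, dtype=float)
    y = np.asarray(data.targets, dtype=float)
    if len(X) == 0:
        raise ValueError("cannot train on an empty dataset")
    if X.shape[1] != model.n_input:
        raise ValueError(f"dataset lag {X.shape[1]} != model n_input {model.n_input}")

    current = model
    for _ in range(epochs):
        current = replace(current, consequents=_lse_consequents(current, X, y))
        g_c, g_s, mse = _premise_gradients(current, X, y)
        if mse < goal_mse:
            break
        new_spreads = np.maximum(current.spreads - lr * g_s, 1e-4)
        current = replace(
            current,
            centers=current.centers - lr * g_c,
            spreads=new_spreads,
        )
    return current


def anfis_fcm_build(
    data: SlidingWindowDataset,
    c: int = 9,
    m: float = 2.0,
    spread_scale: float = 0.15,
    seed: int = 0,
    epochs: int = 50,
    lr: float = 0.01,
    goal_mse: float = 0.00004,
) -> ANFISModel:
    """Build and train an ANFIS whose rules are seeded by fuzzy c-means.

    One rule per cluster: each rule's premise Gaussian is centered at the
    cluster center's coordinates with spread = spread_scale x the per-input
    data range.  Consequents (and premises) are then refined by
    ``anfis_train``.
    """
    X = np.asarray(data.inputs, dtype=float)
    if c > len(X):
        raise ValueError(f"c={c} exceeds n_samples={len(X)}")
    result = fcm_cluster(X, c=c, m=m, seed=seed)
    ranges = X.max(axis=0) - X.min(axis=0)
    ranges = np.where(ranges > 0, ranges, 1.0)
    spreads = np.tile(spread_scale * ranges, (c, 1))
    model = ANFISModel(
        centers=result.centers.copy(),
        spreads=spreads,
        consequents=np.zeros((c, X.shape[1] + 1)),
    )
    return anfis_train(model, data, epochs=epochs, lr=lr, goal_mse=goal_mse)
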