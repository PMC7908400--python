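"""Fuzzy c-means clustering.

Soft k-means with fuzzified memberships: point j belongs to cluster i with
degree mu_ij in [0, 1], columns of the membership matrix summing to 1.  The
algorithm alternates

    mu_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1))        (membership update)
    c_i   = sum_j mu_ij^m x_j / sum_j mu_ij^m        (center update)

minimizing the cost J = sum_ij mu_ij^m d_ij^2, which is non-increasing
across iterations.  A point exactly coincident with a center gets crisp
membership 1 there.  Used here to seed fuzzy rule premises for the
ANFIS-FCM ensemble member.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FCMResult", "fcm_cluster"]


@dataclass(frozen=True)
class FCMResult:
    """Cluster centers (c, d), membership matrix U of shape (c, n) with
    column sums 1, the fuzziness exponent m, and the per-iteration cost."""

    centers: np.ndarray
    membership: np.ndarray
    fuzziness: float
    cost_trace: np.ndarray


def _distances(centers: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix d_ij between center i and point j."""
    diff = centers[:, None, :] - points[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=2))


def _memberships(d: np.ndarray, m: float) -> np.ndarray:
    coincident = d == 0.0
    U = np.zeros_like(d)
    any_zero = coincident.any(axis=0)
    if any_zero.any():
        # crisp assignment where a point sits exactly on a center
        cols = np.flatnonzero(any_zero)
        for j in cols:
            hits = np.flatnonzero(coincident[:, j])
            U[hits, j] = 1.0 / len(hits)
    ok = ~any_zero
    if ok.any():
        power = 2.0 / (m - 1.0)
        ratio = (d[:, ok][None, :, :] / d[:, ok][:, None, :]) ** power
        U[:, ok] = 1.0 / ratio.sum(axis=0)
    return U


def fcm_cluster(
    points: np.ndarray,
    c: int,
    m: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
) -> FCMResult:
    """Cluster ``points`` (n rows) into ``c`` fuzzy groups.

    Initial centers are drawn without replacement from the data (seeded).
    Iteration stops when the cost decreases by less than ``tol`` or at
    ``max_iter``.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    n = len(X)
    if not (1 <= c <= n):
        raise ValueError(f"need 1 <= c <= n, got c={c}, n={n}")
    if m <= 1:
        raise ValueError("fuzziness m must be > 1")

    rng = np.random.default_rng(seed)
    centers = X[rng.choice(n, size=c, replace=False)].copy()
    costs = []
    prev_cost = np.inf
    for _ in range(max_iter):
        d = _distances(centers, X)
        U = _memberships(d, m)
        Um = U**m
        cost = float(np.sum(Um * d**2))
        costs.append(cost)
        weights = Um.sum(axis=1, keepdims=True)
        weights = np.where(weights > 0, weights, 1.0)
        centers = (Um @ X) / weights
        if abs(prev_cost - cost) < tol:
            break
        prev_cost = cost

    d = _distances(centers, X)
    U = _memberships(d, m)
    return FCMResult(
        centers=centers,
        membership=U,
        fuzziness=m,
        cost_trace=np.asarray(costs),
    )
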