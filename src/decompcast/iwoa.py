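"""Whale optimization algorithm with chaotic local search (IWOA).

A population metaheuristic for box-constrained minimization.  Each agent
updates by one of three moves per iteration:

- encircling:    X(t+1) = X* - A . |C X* - X|        (exploit the best)
- random search: X(t+1) = X_r - A . |C X_r - X|      (explore, |A| >= 1)
- spiral:        X(t+1) = |X* - X| e^{b l} cos(2 pi l) + X*

where a decays linearly 2 -> 0 over iterations, A = 2 a r - a, C = 2 r with
r ~ U[0,1] per dimension, l ~ U[-1,1], and the move is picked by a fair
coin p (spiral when p >= 0.5, otherwise encircling/search by |A|).

After the swarm moves, a chaotic local search (CLS) probes for a better
solution: a position is mapped to the unit box, pushed once through the
logistic map cx' = 4 cx (1 - cx) (chaotic at mu = 4), mapped back, and
accepted only if strictly better — so fitness never worsens and the
best-so-far trace is non-increasing.  By default the probe starts from the
best solution only (``cls_mode="best"``): searching close to the incumbent
is what lets the hybrid escape shallow local optima without disturbing the
swarm's convergence.  ``cls_mode="population"`` instead pushes every agent
through the map each iteration; empirically the accepted long-range jumps
then disrupt the late-stage collapse onto the optimum on multimodal
objectives, so it is not the default.  Positions are clamped to the box
after every move.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IWOAConfig",
    "Population",
    "OptResult",
    "draw_coefficients",
    "position_update",
    "logistic_step",
    "chaotic_local_search",
    "iwoa_minimize",
]

# Fixed points / absorbing seeds of the mu=4 logistic map; nudged before stepping
_UNSTABLE = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class IWOAConfig:
    """Optimizer parameters.

    ``bounds`` is a (dim, 2) array of per-dimension [lo, hi]; the default
    box is [-2, 2] in every dimension (the range imposed on ensemble weight
    coefficients).  ``mu`` is fixed at 4 whenever the chaotic local search
    is enabled — that is the chaotic regime of the logistic map.
    ``init_positions`` optionally injects known-good starting agents
    (e.g. selector weight vectors); remaining agents are drawn uniformly.
    """

    dim: int
    bounds: np.ndarray | None = None
    pop_size: int = 30
    max_iter: int = 500
    spiral_constant: float = 1.0
    mu: float = 4.0
    seed: int = 0
    cls_enabled: bool = True
    cls_mode: str = "best"
    init_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        b = self.bounds
        if b is None:
            b = np.tile(np.array([-2.0, 2.0]), (self.dim, 1))
        b = np.asarray(b, dtype=float)
        if b.shape != (self.dim, 2):
            raise ValueError("bounds must have shape (dim, 2)")
        if np.any(b[:, 1] <= b[:, 0]):
            raise ValueError("each bound must satisfy hi > lo")
        object.__setattr__(self, "bounds", b)
        if self.cls_enabled and self.mu != 4.0:
            raise ValueError("chaotic local search requires mu = 4")
        if self.cls_mode not in ("best", "population"):
            raise ValueError(f"unknown cls_mode {self.cls_mode!r}")


@dataclass
class Population:
    positions: np.ndarray  # (I, dim)
    fitnesses: np.ndarray  # (I,)
    best_position: np.ndarray
    best_fitness: float
    iteration: int = 0


@dataclass(frozen=True)
class OptResult:
    best_position: np.ndarray
    best_fitness: float
    trace: np.ndarray  # best fitness after each iteration
    evaluations: int


def draw_coefficients(t: int, max_iter: int, rng: np.random.Generator, dim: int):
    """Per-agent random coefficients for iteration t.

    a decays linearly from 2 to 0; A = 2 a r - a and C = 2 r elementwise;
    l is uniform in [-1, 1]; p uniform in [0, 1].
    """
    if not (0 <= t < max_iter):
        raise ValueError("t must satisfy 0 <= t < max_iter")
    a = 2.0 * (1.0 - t / max_iter)
    r1 = rng.random(dim)
    r2 = rng.random(dim)
    A = 2.0 * a * r1 - a
    C = 2.0 * r2
    l = rng.uniform(-1.0, 1.0)
    p = rng.random()
    return a, A, C, l, p


def position_update(
    x: np.ndarray,
    x_star: np.ndarray,
    x_rand: np.ndarray,
    A: np.ndarray,
    C: np.ndarray,
    l: float,
    p: float,
    bounds: np.ndarray,
    b: float = 1.0,
) -> np.ndarray:
    """One whale move, clamped to the box."""
    if p < 0.5:
        if np.linalg.norm(A) < 1.0:
            D = np.abs(C * x_star - x)
            new = x_star - A * D
        else:
            D = np.abs(C * x_rand - x)
            new = x_rand - A * D
    else:
        D_prime = np.abs(x_star - x)
        new = D_prime * np.exp(b * l) * np.cos(2.0 * np.pi * l) + x_star
    return np.clip(new, bounds[:, 0], bounds[:, 1])


def logistic_step(cx: float) -> float:
    """One iteration of the logistic map at mu = 4: cx -> 4 cx (1 - cx)."""
    if not (0.0 < cx < 1.0):
        raise ValueError("chaotic variable must lie strictly inside (0, 1)")
    return 4.0 * cx * (1.0 - cx)


def _logistic_vec(cx: np.ndarray) -> np.ndarray:
    # nudge coordinates off the map's fixed/absorbing points before stepping
    for bad in _UNSTABLE:
        cx = np.where(cx == bad, bad + 1e-6, cx)
    return 4.0 * cx * (1.0 - cx)


def _chaotic_probe_best(pop: Population, bounds: np.ndarray, objective) -> int:
    """One chaotic jump from the best solution; greedy acceptance."""
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    cx = (pop.best_position - lo) / span
    candidate = lo + _logistic_vec(cx) * span
    fit = float(objective(candidate))
    if fit < pop.best_fitness:
        pop.best_fitness = fit
        pop.best_position = candidate.copy()
    return 1


def chaotic_local_search(pop: Population, bounds: np.ndarray, objective) -> int:
    """Refine every agent by one chaotic jump; greedy acceptance.

    Mutates ``pop`` in place; returns the number of objective evaluations
    performed.  No agent's fitness ever worsens.
    """
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    cx = (pop.positions - lo) / span
    candidates = lo + _logistic_vec(cx) * span
    evals = 0
    for i in range(len(pop.positions)):
        fit = float(objective(candidates[i]))
        evals += 1
        if fit < pop.fitnesses[i]:
            pop.positions[i] = candidates[i]
            pop.fitnesses[i] = fit
            if fit < pop.best_fitness:
                pop.best_fitness = fit
                pop.best_position = candidates[i].copy()
    return evals


def iwoa_minimize(objective, config: IWOAConfig) -> OptResult:
    """Minimize ``objective`` over the configured box.

    Fully seeded: identical config (including seed) gives an identical
    result.  Raises if the objective returns a non-finite value, naming
    the offending point.
    """
    rng = np.random.default_rng(config.seed)
    bounds = config.bounds
    lo, hi = bounds[:, 0], bounds[:, 1]
    I = config.pop_size

    positions = rng.uniform(lo, hi, size=(I, config.dim))
    if config.init_positions is not None:
        seeds = np.clip(np.atleast_2d(np.asarray(config.init_positions, float)), lo, hi)
        positions[: len(seeds)] = seeds[:I]

    def _eval(x: np.ndarray) -> float:
        v = float(objective(x))
        if not np.isfinite(v):
            raise FloatingPointError(f"objective returned non-finite value at {x!r}")
        return v

    fitnesses = np.array([_eval(x) for x in positions])
    evals = I
    best_idx = int(np.argmin(fitnesses))
    pop = Population(
        positions=positions,
        fitnesses=fitnesses,
        best_position=positions[best_idx].copy(),
        best_fitness=float(fitnesses[best_idx]),
    )

    trace = []
    for t in range(config.max_iter):
        for i in range(I):
            _, A, C, l, p = draw_coefficients(t, config.max_iter, rng, config.dim)
            x_rand = pop.positions[rng.integers(I)]
            pop.positions[i] = position_update(
                pop.positions[i],
                pop.best_position,
                x_rand,
                A,
                C,
                l,
                p,
                bounds,
                b=config.spiral_constant,
            )
        pop.fitnesses = np.array([_eval(x) for x in pop.positions])
        evals += I
        idx = int(np.argmin(pop.fitnesses))
        if pop.fitnesses[idx] < pop.best_fitness:
            pop.best_fitness = float(pop.fitnesses[idx])
            pop.best_position = pop.positions[idx].copy()
        if config.cls_enabled:
            if config.cls_mode == "population":
                evals += chaotic_local_search(pop, bounds, _eval)
            else:
                evals += _chaotic_probe_best(pop, bounds, _eval)
        pop.iteration = t + 1
        trace.append(pop.best_fitness)

    return OptResult(
        best_position=pop.best_position,
        best_fitness=pop.best_fitness,
        trace=np.asarray(trace),
        evaluations=evals,
    )
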