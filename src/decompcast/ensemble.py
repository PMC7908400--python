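"""Weighted forecast combination with optimizer-fitted coefficients.

Per decomposed component, the four member forecasts are combined as

    combined_t = sum_i w_i * P_i,t

with each weight boxed to [-2, 2] (no sum-to-one constraint — negative and
super-unit weights are allowed, which lets the combination cancel
correlated member errors).  Weights are fitted by minimizing RMSE against
the weight-optimization segment with the chaotic whale optimizer; the final
forecast is the elementwise sum of the combined component forecasts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .iwoa import IWOAConfig, iwoa_minimize

__all__ = ["ForecastMatrix", "WeightVector", "combine_forecasts", "optimize_vm_weights", "assemble_final"]

MEMBER_NAMES = ("bpnn", "anfis", "anfis_fcm", "gmdh")


@dataclass(frozen=True)
class ForecastMatrix:
    """Per-member forecasts for one component: one column per member model
    (fixed order: BPNN, ANFIS, ANFIS-FCM, GMDH), one row per time point."""

    values: np.ndarray
    model_names: tuple = MEMBER_NAMES
    vm_label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 2:
            raise ValueError("forecast matrix must be 2-D (time x members)")
        if vals.shape[1] != len(self.model_names):
            raise ValueError("one column per member model required")
        if not np.all(np.isfinite(vals)):
            raise ValueError("forecast matrix contains non-finite entries")

    @property
    def n_members(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class WeightVector:
    """Fitted combination coefficients for one component, all in [-2, 2],
    plus the RMSE achieved on the fitting segment."""

    w: np.ndarray
    fitness: float = float("nan")
    vm_label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        if w.ndim != 1:
            raise ValueError("weights must be a vector")
        if np.any(np.abs(w) > 2.0 + 1e-12):
            raise ValueError("weights must lie in [-2, 2]")


def combine_forecasts(F: ForecastMatrix, w: WeightVector | np.ndarray) -> np.ndarray:
    """Elementwise weighted sum of the member columns."""
    weights = w.w if isinstance(w, WeightVector) else np.asarray(w, dtype=float)
    if len(weights) != F.n_members:
        raise ValueError(f"{len(weights)} weights for {F.n_members} member columns")
    return F.values @ weights


def optimize_vm_weights(
    F: ForecastMatrix,
    actual,
    opt_config: IWOAConfig | None = None,
    seed: int = 0,
) -> WeightVector:
    """Fit combination weights by RMSE minimization over the [-2, 2] box.

    The optimizer population is warm-started with the per-member selector
    vectors (1 in one coordinate, 0 elsewhere), so the fitted combination
    can never score worse on the fitting segment than the best single
    member: feasible-point dominance holds by construction.
    """
    y = np.asarray(getattr(actual, "values", actual), dtype=float)
    if len(y) != len(F.values):
        raise ValueError("actuals must align with forecast rows")
    n_members = F.n_members
    if opt_config is None:
        opt_config = IWOAConfig(dim=n_members, seed=seed)
    if opt_config.dim != n_members:
        raise ValueError("optimizer dimension must equal the member count")
    if opt_config.init_positions is None:
        selectors = np.eye(n_members)
        opt_config = IWOAConfig(
            **{
                **{f: getattr(opt_config, f) for f in (
                    "dim", "bounds", "pop_size", "max_iter", "spiral_constant",
                    "mu", "seed", "cls_enabled", "cls_mode",
                )},
                "init_positions": selectors,
            }
        )

    M = F.values

    def objective(w: np.ndarray) -> float:
        return float(np.sqrt(np.mean((y - M @ w) ** 2)))

    result = iwoa_minimize(objective, opt_config)
    return WeightVector(w=result.best_position, fitness=result.best_fitness, vm_label=F.vm_label)


def assemble_final(per_vm_combined, residual_forecast) -> np.ndarray:
    """Sum the combined component forecasts and the residual forecast into
    the final series, in original (unscaled) units."""
    parts = [np.asarray(p, dtype=float) for p in per_vm_combined]
    parts.append(np.asarray(residual_forecast, dtype=float))
    lengths = {len(p) for p in parts}
    if len(lengths) != 1:
        raise ValueError(f"component forecasts differ in length: {sorted(lengths)}")
    return np.sum(parts, axis=0)
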