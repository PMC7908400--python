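"""Forecast-accuracy metrics and benchmark-improvement percentages.

For actuals y_n and forecasts yhat_n, n = 1..N:

    MAE  = mean |y - yhat|
    RMSE = sqrt(mean (y - yhat)^2)
    MAPE = mean |(y - yhat) / y| * 100          (percent; requires y != 0)
    TIC  = RMSE / (sqrt(mean y^2) + sqrt(mean yhat^2))   in [0, 1]

Errors follow the convention e = actual - predicted, so a model that
over-predicts has a negative error mean.  ``error_std`` uses the sample
(N-1) divisor, which ties RMSE, error mean and error std together via
RMSE^2 = mean(e)^2 + ((N-1)/N) std(e)^2.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MetricsReport", "compute_metrics", "improvement"]


@dataclass(frozen=True)
class MetricsReport:
    mae: float
    rmse: float
    mape: float  # percent
    tic: float
    error_mean: float
    error_std: float
    n: int

    def as_dict(self) -> dict:
        return {
            "MAE": self.mae,
            "RMSE": self.rmse,
            "MAPE": self.mape,
            "TIC": self.tic,
            "error_mean": self.error_mean,
            "error_std": self.error_std,
            "N": self.n,
        }


def compute_metrics(actual, predicted) -> MetricsReport:
    """Score a forecast against actuals of equal length.

    MAPE requires every actual value to be nonzero; the first offending
    index is named otherwise.
    """
    y = np.asarray(getattr(actual, "values", actual), dtype=float)
    yhat = np.asarray(getattr(predicted, "values", predicted), dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValueError(f"length mismatch: actual {y.shape}, predicted {yhat.shape}")
    n = len(y)
    if n < 1:
        raise ValueError("need at least one observation")
    zero = np.flatnonzero(y == 0.0)
    if len(zero) > 0:
        raise ValueError(f"MAPE undefined: actual value is zero at index {int(zero[0])}")
    e = y - yhat
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    mape = float(np.mean(np.abs(e / y)) * 100.0)
    tic_den = float(np.sqrt(np.mean(y**2)) + np.sqrt(np.mean(yhat**2)))
    tic = rmse / tic_den if tic_den > 0 else 0.0
    return MetricsReport(
        mae=mae,
        rmse=rmse,
        mape=mape,
        tic=tic,
        error_mean=float(np.mean(e)),
        error_std=float(np.std(e, ddof=1)) if n > 1 else 0.0,
        n=n,
    )


def improvement(bench: float, proposed: float) -> float:
    """Percentage reduction of a (positive) benchmark metric:
    (bench - proposed) / bench * 100."""
    if bench <= 0:
        raise ValueError("benchmark metric must be positive")
    return (bench - proposed) / bench * 100.0
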