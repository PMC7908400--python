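"""Time-series containers, CSV I/O, chronological splitting, lag windows, scaling.

Everything downstream (decomposition, the four learners, the weight
optimizer) consumes the small value types defined here.  The series carrier
is deliberately minimal: an ordered float vector plus optional timestamp
labels.  Timestamps are carried through for reporting but never enter any
computation — daily, regular spacing is assumed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "SlidingWindowDataset",
    "SplitSpec",
    "ScalerState",
    "load_series",
    "write_series",
    "chronological_split",
    "make_lag_matrix",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
]


@dataclass(frozen=True)
class TimeSeries:
    """An ordered, finite, univariate series with optional timestamp labels."""

    values: np.ndarray
    timestamps: tuple | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1:
            raise ValueError("series values must be one-dimensional")
        if len(vals) < 1:
            raise ValueError("series must contain at least one observation")
        if not np.all(np.isfinite(vals)):
            bad = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise ValueError(f"non-finite value at position {bad}")
        if self.timestamps is not None:
            ts = tuple(self.timestamps)
            object.__setattr__(self, "timestamps", ts)
            if len(ts) != len(vals):
                raise ValueError("timestamps and values must have equal length")
            if any(a >= b for a, b in zip(ts, ts[1:])):
                raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SlidingWindowDataset:
    """Supervised one-step-ahead pairs: row i holds ``lag`` consecutive values,
    target i is the value immediately following that window."""

    inputs: np.ndarray
    targets: np.ndarray
    lag: int

    def __post_init__(self) -> None:
        inputs = np.asarray(self.inputs, dtype=float)
        targets = np.asarray(self.targets, dtype=float)
        object.__setattr__(self, "inputs", inputs)
        object.__setattr__(self, "targets", targets)
        if inputs.ndim != 2 or inputs.shape[1] != self.lag:
            raise ValueError("inputs must be (n_samples, lag)")
        if len(targets) != len(inputs):
            raise ValueError("targets must align with input rows")

    @property
    def n_samples(self) -> int:
        return len(self.targets)


@dataclass(frozen=True)
class SplitSpec:
    """Lengths of the three contiguous chronological segments.

    ``n_train`` fits the learners, ``n_weight_opt`` fits the ensemble
    weights, ``n_test`` is held out for final scoring.  The shipped default
    (572, 95, 96) keeps ~75% of a 763-point series for training and splits
    the remaining 191 points roughly in half so that weight fitting and
    final testing never see the same data.
    """

    n_train: int
    n_weight_opt: int = 0
    n_test: int = 0

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_weight_opt, self.n_test) < 0:
            raise ValueError("segment lengths must be non-negative")

    @property
    def total(self) -> int:
        return self.n_train + self.n_weight_opt + self.n_test


DEFAULT_SPLIT = SplitSpec(n_train=572, n_weight_opt=95, n_test=96)


@dataclass(frozen=True)
class ScalerState:
    """Min-max scaler fitted on a training segment: maps [lower, upper] -> [0, 1].

    Values outside the fitted range extrapolate linearly.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.upper > self.lower):
            raise ValueError("scaler requires upper > lower")


def load_series(
    path: str | Path,
    value_column: str = "value",
    timestamp_column: str | None = None,
) -> TimeSeries:
    """Read a univariate series from a headered CSV file.

    Missing or non-numeric cells are rejected with the offending row index
    (0-based data row); imputation is deliberately unsupported.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"series file not found: {path}")
    frame = pd.read_csv(path, skip_blank_lines=False)
    if len(frame) == 0:
        raise ValueError(f"empty series file: {path}")
    if value_column not in frame.columns:
        raise ValueError(f"column {value_column!r} not present in {path}")
    raw = frame[value_column]
    numeric = pd.to_numeric(raw, errors="coerce")
    bad = numeric.index[numeric.isna()]
    if len(bad) > 0:
        raise ValueError(f"missing value at row {int(bad[0])} of {path}")
    timestamps = None
    if timestamp_column is not None:
        if timestamp_column not in frame.columns:
            raise ValueError(f"column {timestamp_column!r} not present in {path}")
        timestamps = tuple(frame[timestamp_column].astype(str))
    return TimeSeries(values=numeric.to_numpy(dtype=float), timestamps=timestamps)


def write_series(
    series: TimeSeries,
    path: str | Path,
    value_column: str = "value",
    timestamp_column: str = "timestamp",
) -> None:
    """Write a series as CSV with the same dialect ``load_series`` reads."""
    data: dict = {}
    if series.timestamps is not None:
        data[timestamp_column] = list(series.timestamps)
    data[value_column] = series.values
    pd.DataFrame(data).to_csv(path, index=False)


def chronological_split(
    series: TimeSeries, spec: SplitSpec
) -> tuple[TimeSeries, TimeSeries, TimeSeries]:
    """Slice a series into (train, weight-opt, test) without reordering.

    Segments declared with length 0 come back as ``None`` (a ``TimeSeries``
    is never empty); concatenating the non-empty segments reproduces the
    input exactly.
    """
    if spec.total != len(series):
        raise ValueError(
            f"split lengths sum to {spec.total}, series has {len(series)} points"
        )

    a = spec.n_train
    b = a + spec.n_weight_opt
    parts = []
    for lo, hi in ((0, a), (a, b), (b, spec.total)):
        if hi == lo:
            parts.append(None)
        else:
            ts = series.timestamps[lo:hi] if series.timestamps is not None else None
            parts.append(TimeSeries(values=series.values[lo:hi], timestamps=ts))
    return tuple(parts)  # type: ignore[return-value]


def make_lag_matrix(series: TimeSeries | Sequence[float], lag: int) -> SlidingWindowDataset:
    """Build rolling one-step supervised pairs from a series.

    Row ``i`` of the input matrix is ``values[i : i + lag]`` and target ``i``
    is ``values[i + lag]``; there are exactly ``len(series) - lag`` rows.
    """
    values = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    n = len(values)
    if n <= lag:
        raise ValueError(f"series of length {n} too short for lag {lag}")
    idx = np.arange(n - lag)[:, None] + np.arange(lag)[None, :]
    return SlidingWindowDataset(inputs=values[idx], targets=values[lag:], lag=lag)


def fit_scaler(segment: TimeSeries | Sequence[float]) -> ScalerState:
    """Fit a min-max scaler on a segment (typically the training slice only)."""
    values = segment.values if isinstance(segment, TimeSeries) else np.asarray(segment, float)
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        raise ValueError("cannot fit scaler on a constant segment")
    return ScalerState(lower=lo, upper=hi)


def apply_scaler(state: ScalerState, values: np.ndarray | Sequence[float]) -> np.ndarray:
    return (np.asarray(values, dtype=float) - state.lower) / (state.upper - state.lower)


def invert_scaler(state: ScalerState, values: np.ndarray | Sequence[float]) -> np.ndarray:
    return np.asarray(values, dtype=float) * (state.upper - state.lower) + state.lower
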