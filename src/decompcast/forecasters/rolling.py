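"""Rolling one-step-ahead forecasting.

Each horizon point is predicted from the ``lag`` most recent *observed*
values: after a prediction is made, the actual observation rolls into the
window — predictions are never fed back.  This matches how an operational
daily early-warning forecast would be issued.
"""
from __future__ import annotations

import numpy as np

from ..series import TimeSeries, make_lag_matrix

__all__ = ["rolling_forecast"]


def rolling_forecast(model, history, horizon, lag: int) -> np.ndarray:
    """Predict every point of ``horizon`` one step ahead.

    ``model`` is anything with a ``predict(inputs) -> outputs`` method (all
    four trained learners qualify).  ``history`` supplies the initial
    window; as the loop advances, actual horizon values replace the oldest
    window entries.
    """
    hist = np.asarray(getattr(history, "values", history), dtype=float)
    hor = np.asarray(getattr(horizon, "values", horizon), dtype=float)
    if lag < 1:
        raise ValueError("lag must be positive")
    if len(hist) < lag:
        raise ValueError(f"history of length {len(hist)} shorter than lag {lag}")
    if len(hor) == 0:
        return np.empty(0)
    # window i for horizon point i is the last `lag` values of hist + hor[:i]
    joined = np.concatenate([hist[-lag:], hor])
    windows = make_lag_matrix(joined, lag).inputs  # exactly len(hor) rows
    return np.asarray(model.predict(windows), dtype=float).ravel()
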