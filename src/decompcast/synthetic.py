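"""Seeded generators emulating the structure of a daily PM2.5 record.

The series generator produces a strictly positive sequence of (by default)
763 points — a slow trend, several narrowband oscillations at well-separated
frequencies, and autocorrelated AR(1) noise — which is exactly the
structure the decomposition-ensemble pipeline assumes: the oscillations are
separable by VMD and every component is forecastable from its own lags.
Ground-truth components are returned alongside the series so decomposition
fidelity is directly testable.

The weight fixture generates four linearly independent pseudo-member
forecast columns and an actual series that is a known weighted combination
of them plus noise, exercising the weight optimizer against a closed-form
least-squares oracle.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import ForecastMatrix
from .series import TimeSeries

__all__ = ["SyntheticSpec", "generate_series", "generate_weight_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Stated world for the synthetic concentration series.

    Defaults: 763 daily points; mean level 60 (a typical Jing-Jin-Ji
    daily PM2.5 concentration in ug/m3); seasonal-to-weekly oscillations at
    {0.004, 0.03, 0.12} cycles/sample, separated by more than an octave so
    narrowband decomposition is well-posed; AR(1) noise with coefficient
    0.6 so the irregular part is itself lag-forecastable, as real
    concentration noise is.
    """

    n: int = 763
    offset: float = 60.0
    trend_amplitude: float = 10.0
    components: tuple = (
        (0.004, 18.0, 0.0),
        (0.03, 9.0, 1.0),
        (0.12, 5.0, 2.0),
    )
    noise_sd: float = 2.0
    ar_coefficient: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = [f for f, _, _ in self.components]
        if len(set(freqs)) != len(freqs):
            raise ValueError("component frequencies must be distinct")
        if any(not (0 < f < 0.5) for f in freqs):
            raise ValueError("component frequencies must lie in (0, 0.5)")
        if not (0 <= self.ar_coefficient < 1):
            raise ValueError("AR coefficient must be in [0, 1)")


def generate_series(spec: SyntheticSpec = SyntheticSpec()) -> tuple[TimeSeries, dict]:
    """Generate the series plus its ground-truth components.

    Returns ``(series, truth)`` where ``truth`` maps component names
    ("trend", "component_0"..., "noise") to their additive parts; the parts
    sum to ``series.values`` exactly.
    """
    t = np.arange(spec.n, dtype=float)
    rng = np.random.default_rng(spec.seed)
    truth: dict[str, np.ndarray] = {}
    trend = spec.offset + spec.trend_amplitude * (t / max(spec.n - 1, 1))
    truth["trend"] = trend
    total = trend.copy()
    for k, (freq, amp, phase) in enumerate(spec.components):
        comp = amp * np.sin(2.0 * np.pi * freq * t + phase)
        truth[f"component_{k}"] = comp
        total += comp
    noise = np.zeros(spec.n)
    if spec.noise_sd > 0:
        innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar_coefficient**2)
        innovations = rng.normal(0.0, innov_sd, size=spec.n)
        noise[0] = rng.normal(0.0, spec.noise_sd)
        for i in range(1, spec.n):
            noise[i] = spec.ar_coefficient * noise[i - 1] + innovations[i]
    truth["noise"] = noise
    total = total + noise
    return TimeSeries(values=total), truth


def generate_weight_fixture(
    n: int = 200,
    true_weights=(0.3, -0.2, 0.5, 0.4),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ForecastMatrix, np.ndarray]:
    """Four well-conditioned pseudo-member columns and a known combination.

    Columns are distinct smooth signals (orthogonal-phase sinusoids plus a
    trend and a constant offset) whose Gram matrix is verified to be
    well-conditioned at generation time; ``actual`` is the true weighted sum
    plus optional Gaussian noise.
    """
    w = np.asarray(true_weights, dtype=float)
    if np.any(np.abs(w) > 2.0):
        raise ValueError("true weights must lie in [-2, 2]")
    t = np.arange(n, dtype=float)
    rng = np.random.default_rng(seed)
    cols = np.column_stack(
        [
            1.0 + np.sin(2.0 * np.pi * 0.01 * t),
            1.0 + np.cos(2.0 * np.pi * 0.05 * t),
            1.0 + np.sin(2.0 * np.pi * 0.11 * t + 0.7),
            1.0 + 0.5 * t / max(n - 1, 1) + 0.3 * np.cos(2.0 * np.pi * 0.002 * t),
        ]
    )
    gram = cols.T @ cols
    cond = float(np.linalg.cond(gram))
    if cond >= 1e6:
        raise RuntimeError(f"fixture Gram matrix ill-conditioned: {cond:.3g}")
    actual = cols @ w
    if noise_sd > 0:
        actual = actual + rng.normal(0.0, noise_sd, size=n)
    return ForecastMatrix(values=cols, vm_label="fixture"), actual
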