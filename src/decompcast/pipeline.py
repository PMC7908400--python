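"""Config-driven end-to-end experiment runner.

Three stages: (1) decompose the series into banded components plus a
residual; (2) scale each component to the training segment's [0, 1] range,
train the four learners on lag windows, roll one-step forecasts over the
weight-optimization and test segments, and fit per-component combination
weights on the weight-optimization segment; (3) reassemble the combined
component forecasts into the final series and score it on the held-out test
segment.

Optional comparison arms mirror the usual ablations: each single learner on
the raw (undecomposed) series, and each decomposition-based single learner
(one model forecasting every component, summed).  Reports are written as
CSV plus a JSON manifest recording every seed and parameter.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import ForecastMatrix, WeightVector, combine_forecasts, optimize_vm_weights, assemble_final
from .forecasters import (
    BPNNConfig,
    GMDHConfig,
    anfis_init_grid,
    anfis_train,
    anfis_fcm_build,
    bpnn_train,
    gmdh_fit,
    rolling_forecast,
    MEMBER_ORDER,
)
from .iwoa import IWOAConfig
from .metrics import compute_metrics, improvement
from .series import (
    SplitSpec,
    TimeSeries,
    apply_scaler,
    chronological_split,
    fit_scaler,
    invert_scaler,
    load_series,
    make_lag_matrix,
)
from .synthetic import SyntheticSpec, generate_series
from .vmd import VMDConfig, restructure_modes, vmd_decompose

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment"]

log = logging.getLogger("decompcast")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything one experiment needs, with field defaults matching the
    standard setup: lag 4, split (572, 95, 96) on a 763-point series,
    3 banded components + residual, weight box [-2, 2]."""

    input_path: str | None = None
    value_column: str = "value"
    timestamp_column: str | None = None
    synthetic: SyntheticSpec | None = None
    split: SplitSpec | None = None
    lag: int = 4
    vmd: VMDConfig = field(default_factory=VMDConfig)
    n_groups: int = 3
    bpnn: BPNNConfig = field(default_factory=BPNNConfig)
    anfis_epochs: int = 50
    anfis_lr: float = 0.01
    anfis_spread: float = 0.5
    anfis_mfs_per_input: int = 2
    fcm_clusters: int = 9
    fcm_spread_scale: float = 0.15
    gmdh: GMDHConfig = field(default_factory=GMDHConfig)
    iwoa_pop_size: int = 30
    iwoa_max_iter: int = 500
    cls_enabled: bool = True
    goal_mse: float = 0.00004
    seed: int = 0
    run_single_models: bool = False
    run_vmd_single_models: bool = True
    output_dir: str | None = None


@dataclass
class ExperimentResult:
    """In-memory run record; ``write_reports`` serializes it."""

    config: ExperimentConfig
    weights: dict  # component label -> WeightVector
    forecasts: pd.DataFrame  # test-segment actual + per-arm forecasts
    metrics: pd.DataFrame  # one row per arm
    improvements: pd.DataFrame  # ensemble vs comparison arms
    manifest: dict

    def write_reports(self, output_dir: str | Path) -> dict:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "forecasts": out / "forecasts.csv",
            "metrics": out / "metrics.csv",
            "improvements": out / "improvements.csv",
            "weights": out / "weights.json",
            "manifest": out / "manifest.json",
        }
        self.forecasts.to_csv(paths["forecasts"], index=False)
        self.metrics.to_csv(paths["metrics"], index=False)
        self.improvements.to_csv(paths["improvements"], index=False)
        weights_doc = {
            label: {
                "weights": dict(zip(MEMBER_ORDER, wv.w.tolist())),
                "fitness_rmse": wv.fitness,
            }
            for label, wv in self.weights.items()
        }
        paths["weights"].write_text(json.dumps(weights_doc, indent=2))
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2, default=str))
        return {k: str(v) for k, v in paths.items()}


def _default_split(n: int) -> SplitSpec:
    """Training ~75%, remaining tail split near-evenly between weight
    fitting and final testing."""
    n_train = int(round(0.75 * n))
    rest = n - n_train
    n_w = rest // 2
    return SplitSpec(n_train=n_train, n_weight_opt=n_w, n_test=rest - n_w)


def _train_members(train_scaled: np.ndarray, cfg: ExperimentConfig, seed: int) -> dict:
    """Fit all four learners on one scaled component's training segment."""
    data = make_lag_matrix(train_scaled, cfg.lag)
    models = {}
    t0 = time.perf_counter()
    models["bpnn"] = bpnn_train(
        data,
        BPNNConfig(
            n_input=cfg.lag,
            n_hidden=cfg.bpnn.n_hidden,
            learning_rate=cfg.bpnn.learning_rate,
            momentum=cfg.bpnn.momentum,
            max_epochs=cfg.bpnn.max_epochs,
            goal_mse=cfg.goal_mse,
            seed=seed,
        ),
    )
    grid = anfis_init_grid(
        n_input=cfg.lag,
        mfs_per_input=cfg.anfis_mfs_per_input,
        spread=cfg.anfis_spread,
    )
    models["anfis"] = anfis_train(
        grid, data, epochs=cfg.anfis_epochs, lr=cfg.anfis_lr, goal_mse=cfg.goal_mse
    )
    models["anfis_fcm"] = anfis_fcm_build(
        data,
        c=min(cfg.fcm_clusters, data.n_samples),
        spread_scale=cfg.fcm_spread_scale,
        seed=seed,
        epochs=cfg.anfis_epochs,
        lr=cfg.anfis_lr,
        goal_mse=cfg.goal_mse,
    )
    models["gmdh"] = gmdh_fit(
        data,
        GMDHConfig(
            max_layers=cfg.gmdh.max_layers,
            max_neurons=cfg.gmdh.max_neurons,
            validation_fraction=cfg.gmdh.validation_fraction,
            seed=seed,
        ),
    )
    log.info("trained 4 members in %.2fs", time.perf_counter() - t0)
    return models


def _component_forecasts(component: np.ndarray, split: SplitSpec, cfg: ExperimentConfig, seed: int):
    """Scale, train, and roll forecasts for one decomposed component.

    Returns (models, forecasts on weight-opt segment, forecasts on test
    segment), both forecast blocks in original units.
    """
    train = component[: split.n_train]
    wopt = component[split.n_train: split.n_train + split.n_weight_opt]
    test = component[split.n_train + split.n_weight_opt:]
    scaler = fit_scaler(train)
    train_s = apply_scaler(scaler, train)
    wopt_s = apply_scaler(scaler, wopt)
    test_s = apply_scaler(scaler, test)

    models = _train_members(train_s, cfg, seed)
    fc_w = {}
    fc_t = {}
    hist_for_test = np.concatenate([train_s, wopt_s])
    for name, model in models.items():
        fc_w[name] = invert_scaler(scaler, rolling_forecast(model, train_s, wopt_s, cfg.lag))
        fc_t[name] = invert_scaler(scaler, rolling_forecast(model, hist_for_test, test_s, cfg.lag))
    return models, fc_w, fc_t


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full decomposition-ensemble pipeline per the config."""
    t_start = time.perf_counter()
    stage = "load"
    try:
        if config.input_path is not None:
            series = load_series(
                config.input_path,
                value_column=config.value_column,
                timestamp_column=config.timestamp_column,
            )
            source = {"kind": "csv", "path": str(config.input_path)}
        else:
            spec = config.synthetic or SyntheticSpec(seed=config.seed)
            series, _ = generate_series(spec)
            source = {"kind": "synthetic", **asdict(spec)}
        n = len(series)
        split = config.split or _default_split(n)
        if split.total != n:
            raise ValueError(f"split {split} does not sum to series length {n}")

        stage = "decompose"
        log.info("decomposing %d points into %d modes", n, config.vmd.K)
        raw = vmd_decompose(series.values, config.vmd)
        grouped = restructure_modes(raw, n_groups=config.n_groups)
        components = grouped.components()
        labels = grouped.component_labels()

        stage = "train+forecast"
        actual_wopt = series.values[split.n_train: split.n_train + split.n_weight_opt]
        actual_test = series.values[split.n_train + split.n_weight_opt:]
        per_comp_w: dict[str, dict] = {}
        per_comp_t: dict[str, dict] = {}
        for k, (label, comp) in enumerate(zip(labels, components)):
            log.info("component %s", label)
            _, fc_w, fc_t = _component_forecasts(comp, split, config, seed=config.seed + k)
            per_comp_w[label] = fc_w
            per_comp_t[label] = fc_t

        stage = "optimize-weights"
        weights: dict[str, WeightVector] = {}
        combined_w: dict[str, np.ndarray] = {}
        combined_t: dict[str, np.ndarray] = {}
        for k, label in enumerate(labels):
            comp = components[k]
            comp_actual_w = comp[split.n_train: split.n_train + split.n_weight_opt]
            F_w = ForecastMatrix(
                values=np.column_stack([per_comp_w[label][m] for m in MEMBER_ORDER]),
                vm_label=label,
            )
            F_t = ForecastMatrix(
                values=np.column_stack([per_comp_t[label][m] for m in MEMBER_ORDER]),
                vm_label=label,
            )
            wv = optimize_vm_weights(
                F_w,
                comp_actual_w,
                IWOAConfig(
                    dim=len(MEMBER_ORDER),
                    pop_size=config.iwoa_pop_size,
                    max_iter=config.iwoa_max_iter,
                    cls_enabled=config.cls_enabled,
                    seed=config.seed + 100 + k,
                ),
            )
            weights[label] = wv
            combined_w[label] = combine_forecasts(F_w, wv)
            combined_t[label] = combine_forecasts(F_t, wv)

        stage = "assemble"
        final_test = assemble_final(
            [combined_t[lb] for lb in labels[:-1]], combined_t[labels[-1]]
        )

        stage = "score"
        metric_rows = []
        forecast_cols = {"actual": actual_test, "ensemble": final_test}
        rep = compute_metrics(actual_test, final_test)
        metric_rows.append({"arm": "ensemble", **rep.as_dict()})

        if config.run_vmd_single_models:
            for m in MEMBER_ORDER:
                pred = np.sum([per_comp_t[lb][m] for lb in labels], axis=0)
                forecast_cols[f"vmd_{m}"] = pred
                metric_rows.append(
                    {"arm": f"vmd_{m}", **compute_metrics(actual_test, pred).as_dict()}
                )

        if config.run_single_models:
            _, _, fc_t_raw = _component_forecasts(series.values, split, config, seed=config.seed + 50)
            for m in MEMBER_ORDER:
                forecast_cols[f"single_{m}"] = fc_t_raw[m]
                metric_rows.append(
                    {"arm": f"single_{m}", **compute_metrics(actual_test, fc_t_raw[m]).as_dict()}
                )

        metrics_df = pd.DataFrame(metric_rows)
        ens = metrics_df[metrics_df["arm"] == "ensemble"].iloc[0]
        imp_rows = []
        for _, row in metrics_df.iterrows():
            if row["arm"] == "ensemble":
                continue
            imp_rows.append(
                {
                    "versus": row["arm"],
                    **{
                        f"I{metric} (%)": improvement(row[metric], ens[metric])
                        for metric in ("MAE", "RMSE", "MAPE", "TIC")
                        if row[metric] > 0
                    },
                }
            )
        improvements_df = pd.DataFrame(imp_rows)

        manifest = {
            "source": source,
            "n": n,
            "split": asdict(split),
            "lag": config.lag,
            "vmd": asdict(config.vmd),
            "n_groups": config.n_groups,
            "seed": config.seed,
            "component_seeds": {lb: config.seed + k for k, lb in enumerate(labels)},
            "weight_opt_seeds": {lb: config.seed + 100 + k for k, lb in enumerate(labels)},
            "iwoa": {
                "pop_size": config.iwoa_pop_size,
                "max_iter": config.iwoa_max_iter,
                "cls_enabled": config.cls_enabled,
                "bounds": [-2.0, 2.0],
            },
            "members": list(MEMBER_ORDER),
            "runtime_seconds": round(time.perf_counter() - t_start, 3),
        }
        result = ExperimentResult(
            config=config,
            weights=weights,
            forecasts=pd.DataFrame(forecast_cols),
            metrics=metrics_df,
            improvements=improvements_df,
            manifest=manifest,
        )
        if config.output_dir is not None:
            result.write_reports(config.output_dir)
        return result
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc
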