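"""End-to-end experiment: simulate/load -> fuse -> tune -> forecast -> compare.

The experiment mirrors the standard protocol for this kind of pond study:

1. A multi-sensor frame is simulated (or loaded from CSV). The first
   ``fusion_train`` rows train the RBF fusion network, the next
   ``fusion_test`` rows are fused out-of-sample.
2. The fused test block becomes the forecasting dataset: features are the
   five meteorological covariates at time t plus the previous fused DO value,
   the target is the fused DO at t (one-step-ahead at the native sampling
   interval). The lag-1 construction drops the first row, so 200 fused rows
   yield 199 supervised rows, split 120 train / 79 test by default.
3. Each model in the roster picks (gamma, sigma) on the training block only
   — 5-fold CV over a grid for the baseline, swarm search (standard or
   improved) for the tuned variants — then forecasts the test block.
4. All models are scored with the same metrics module, and the improvement
   of the improved-swarm model over each baseline is reported as relative
   percentage differences in MAE/RMSE/MSE.

Everything is deterministic under a fixed seed; per-stage seeds are derived
from the global one. No stage ever sees data from a later split (scaling
statistics, K-means centers and tuned hyperparameters all come from training
partitions only).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fusion import RBFNetFusion
from .lssvm import LSSVM, cv_grid_search
from .metrics import compute_metrics, relative_difference
from .pso import DEFAULT_LOG_BOUNDS, PSOConfig, tune_lssvm
from .synthetic import COVARIATE_COLUMNS, SensorFrame, SyntheticConfig, simulate

__all__ = ["ExperimentConfig", "build_forecast_table", "run_experiment"]

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = COVARIATE_COLUMNS + ["prev_do"]

#: Default (gamma, sigma) grid for the cross-validated baseline.
DEFAULT_CV_GRID = tuple(
    (g, s) for g in (0.1, 1.0, 10.0, 100.0, 1000.0) for s in (0.25, 0.5, 1.0, 2.0, 4.0)
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of the full fusion-plus-forecasting experiment."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    input_csv: Optional[str] = None
    fusion_train: int = 500
    fusion_test: int = 200
    forecast_train: int = 120
    forecast_test: Optional[int] = None  # default: the remaining usable rows
    n_centers: int = 10
    reference_sensor: int = 0
    include_covariates_in_fusion: bool = False
    roster: Sequence[str] = ("cv-lssvm", "pso-lssvm", "ipso-lssvm")
    external_predictions: Optional[str] = None
    cv_grid: Sequence[tuple[float, float]] = DEFAULT_CV_GRID
    cv_folds: int = 5
    pso_particles: int = 50
    pso_iters: int = 200
    pso_folds: Optional[int] = 5  # swarm fitness: k-fold CV RMSE; None = 20% holdout
    holdout_fraction: float = 0.2
    seed: int = 0
    outdir: Optional[str] = None

    def resolved_forecast_test(self) -> int:
        usable = self.fusion_test - 1  # lag-1 table drops the first fused row
        if self.forecast_test is not None:
            return self.forecast_test
        return usable - self.forecast_train

    def validate(self) -> None:
        known = {"cv-lssvm", "pso-lssvm", "ipso-lssvm", "external"}
        for name in self.roster:
            if name not in known:
                raise ValueError(f"unknown roster model {name!r}; choose from {sorted(known)}")
        n_test = self.resolved_forecast_test()
        if n_test < 1 or self.forecast_train < 5:
            raise ValueError("forecast splits too small")
        if self.forecast_train + n_test > self.fusion_test - 1:
            raise ValueError(
                "fusion test block must cover the forecast train+test rows "
                f"(have {self.fusion_test - 1} usable rows, need "
                f"{self.forecast_train + n_test})"
            )
        if "external" in self.roster and not self.external_predictions:
            raise ValueError("roster includes 'external' but no predictions CSV given")


def build_forecast_table(frame: SensorFrame, fused: np.ndarray) -> pd.DataFrame:
    """Supervised one-step-ahead table from a frame slice and its fused DO.

    Row t has the five covariates at time t, the fused DO at t-1
    (``prev_do``) and the fused DO at t as ``target``; the first row is
    dropped (no previous value). N fused rows in -> N-1 supervised rows out.
    """
    fused = np.asarray(fused, dtype=float).ravel()
    if len(fused) != len(frame):
        raise ValueError(
            f"fused series length {len(fused)} does not match frame length {len(frame)}"
        )
    if len(fused) < 2:
        raise ValueError("need at least 2 rows for a lag-1 table")
    table = frame.covariates.iloc[1:].copy()
    table["prev_do"] = fused[:-1]
    table["target"] = fused[1:]
    table.index = range(len(table))
    return table


def _slice_frame(frame: SensorFrame, start: int, stop: int) -> SensorFrame:
    return SensorFrame(
        timestamps=frame.timestamps[start:stop],
        covariates=frame.covariates.iloc[start:stop].reset_index(drop=True),
        sensor_do=None if frame.sensor_do is None else frame.sensor_do[start:stop],
        truth_do=None if frame.truth_do is None else frame.truth_do[start:stop],
        valid_mask=None if frame.valid_mask is None else frame.valid_mask[start:stop],
    )


def _rmse(a, b) -> float:
    return float(np.sqrt(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2)))


def _fit_forecaster(name: str, y_tr, X_tr, config: ExperimentConfig):
    """Select (gamma, sigma) on the training block and fit; returns
    (results, info-dict, gbest_history-or-None)."""
    if name == "cv-lssvm":
        gamma, sigma = cv_grid_search(y_tr, X_tr, config.cv_grid, folds=config.cv_folds)
        history = None
    else:
        improved = name == "ipso-lssvm"
        pso_cfg = PSOConfig(
            bounds=DEFAULT_LOG_BOUNDS,
            n_particles=config.pso_particles,
            max_iter=config.pso_iters,
            improved=improved,
            seed=config.seed + (2 if improved else 1),
        )
        tuned = tune_lssvm(y_tr, X_tr, config=pso_cfg, folds=config.pso_folds,
                           holdout_fraction=config.holdout_fraction)
        gamma, sigma, history = tuned.gamma, tuned.sigma, tuned.gbest_history
    results = LSSVM(y_tr, X_tr, gamma=gamma, sigma=sigma).fit()
    return results, {"gamma": gamma, "sigma": sigma}, history


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full experiment; returns the comparison report as a dict.

    When ``config.outdir`` is set, every stage's artifacts are persisted
    there: the fused frame, the supervised table, per-model parameter files
    and predictions, swarm fitness histories and the metrics report.
    """
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # ---- stage 1: data -------------------------------------------------
    try:
        if config.input_csv:
            frame = SensorFrame.from_csv(config.input_csv)
            if frame.sensor_do is None:
                raise ValueError("input CSV has no do_s* sensor columns")
        else:
            frame = simulate(config.synthetic.replace(seed=config.seed))
    except Exception as exc:
        raise RuntimeError(f"[stage: data] {exc}") from exc

    n_fuse = config.fusion_train + config.fusion_test
    if len(frame) < n_fuse:
        raise RuntimeError(
            f"[stage: data] frame has {len(frame)} rows; fusion splits need {n_fuse}"
        )

    # ---- stage 2: fusion ----------------------------------------------
    try:
        X_sens = frame.sensor_do[:n_fuse]
        if config.include_covariates_in_fusion:
            X_fuse = np.column_stack([X_sens, frame.covariates.iloc[:n_fuse].to_numpy(float)])
        else:
            X_fuse = X_sens
        y_ref = frame.sensor_do[:n_fuse, config.reference_sensor]
        fusion_model = RBFNetFusion(
            y_ref[: config.fusion_train],
            X_fuse[: config.fusion_train],
            n_centers=config.n_centers,
        )
        fusion_res = fusion_model.fit(seed=config.seed)
        fused = fusion_res.predict(X_fuse)
    except Exception as exc:
        raise RuntimeError(f"[stage: fusion] {exc}") from exc

    fusion_report: dict = {
        "n_centers": config.n_centers,
        "train_rmse": fusion_res.train_rmse,
        "width_sigma": float(fusion_res.widths[0]),
    }
    test_slice = slice(config.fusion_train, n_fuse)
    if frame.truth_do is not None:
        truth_test = frame.truth_do[test_slice]
        fusion_report["test_rmse_vs_truth"] = _rmse(fused[test_slice], truth_test)
        fusion_report["sensor_rmse_vs_truth"] = [
            _rmse(frame.sensor_do[test_slice, j], truth_test)
            for j in range(frame.sensor_do.shape[1])
        ]
        best_sensor = min(fusion_report["sensor_rmse_vs_truth"])
        fusion_report["improvement_vs_best_sensor_pct"] = relative_difference(
            best_sensor, fusion_report["test_rmse_vs_truth"]
        )

    # ---- stage 3: forecasting table ------------------------------------
    try:
        test_frame = _slice_frame(frame, config.fusion_train, n_fuse)
        table = build_forecast_table(test_frame, fused[test_slice])
        n_tr = config.forecast_train
        n_te = config.resolved_forecast_test()
        X_all = table[FEATURE_COLUMNS].to_numpy(float)
        y_all = table["target"].to_numpy(float)
        X_tr, y_tr = X_all[:n_tr], y_all[:n_tr]
        X_te, y_te = X_all[n_tr : n_tr + n_te], y_all[n_tr : n_tr + n_te]
    except Exception as exc:
        raise RuntimeError(f"[stage: table] {exc}") from exc

    # ---- stage 4: models ----------------------------------------------
    model_reports: dict = {}
    predictions: dict = {}
    histories: dict = {}
    for name in config.roster:
        try:
            if name == "external":
                ext = pd.read_csv(config.external_predictions)
                col = "prediction" if "prediction" in ext.columns else ext.columns[-1]
                pred = ext[col].to_numpy(float)
                if len(pred) != n_te:
                    raise ValueError(
                        f"external predictions have {len(pred)} rows, expected {n_te}"
                    )
                info = {"source": str(config.external_predictions)}
                results = None
            else:
                results, info, history = _fit_forecaster(name, y_tr, X_tr, config)
                pred = results.predict(X_te)
                if history is not None:
                    histories[name] = history
            report = compute_metrics(y_te, pred)
            model_reports[name] = {**info, "metrics": report.to_dict()}
            predictions[name] = pred
            if outdir and results is not None:
                results.to_json(outdir / f"model_{name}.json")
        except Exception as exc:
            raise RuntimeError(f"[stage: model {name}] {exc}") from exc

    # ---- stage 5: comparison -------------------------------------------
    comparison: dict = {}
    if "ipso-lssvm" in model_reports:
        champ = model_reports["ipso-lssvm"]["metrics"]
        for name, rep in model_reports.items():
            if name == "ipso-lssvm":
                continue
            ref = rep["metrics"]
            comparison[name] = {
                m: relative_difference(ref[m], champ[m]) for m in ("mae", "rmse", "mse")
            }

    report = {
        "seed": config.seed,
        "splits": {
            "fusion_train": config.fusion_train,
            "fusion_test": config.fusion_test,
            "forecast_train": n_tr,
            "forecast_test": n_te,
        },
        "fusion": fusion_report,
        "models": model_reports,
        "relative_differences_vs_ipso": comparison,
    }

    # ---- stage 6: artifacts --------------------------------------------
    if outdir:
        fused_df = _slice_frame(frame, 0, n_fuse).to_dataframe()
        fused_df["do_fused"] = fused
        fused_df.to_csv(outdir / "fused.csv", index=False)
        table.to_csv(outdir / "forecast_table.csv", index=False)
        pred_df = pd.DataFrame({"observed": y_te})
        for name, pred in predictions.items():
            pred_df[name] = pred
        pred_df.to_csv(outdir / "predictions.csv", index=False)
        for name, history in histories.items():
            pd.DataFrame({"iteration": range(len(history)), "gbest_fitness": history}).to_csv(
                outdir / f"fitness_history_{name}.csv", index=False
            )
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        logger.info("experiment artifacts written to %s", outdir)
    return report
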