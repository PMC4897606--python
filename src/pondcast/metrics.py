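"""Forecast-accuracy metrics and model-comparison arithmetic.

Definitions (o = observed, p = predicted, n values):

    MAE  = mean |o - p|                          [mg/L]
    MSE  = mean (o - p)^2                        [(mg/L)^2]
    RMSE = sqrt(MSE)                             [mg/L]
    MAPE = 100 * mean |o - p| / |o|              [%]
    NSC  = 1 - sum (o - p)^2 / sum (o - obar)^2  [Nash-Sutcliffe efficiency]
    R^2  = squared Pearson correlation of o and p

NSC compares the model against the constant-mean predictor on the same
evaluation block: 1 is a perfect forecast, 0 no better than the mean.
MAPE terms with a zero observation are undefined; they are excluded with a
warning. A constant observed series leaves NSC and R^2 undefined (NaN, with
a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["MetricsReport", "compute_metrics", "relative_difference"]


@dataclass(frozen=True)
class MetricsReport:
    """Error statistics of one model on one evaluation set."""

    mae: float
    rmse: float
    mse: float
    mape: float
    nsc: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        return (
            f"n={self.n}  MAE={self.mae:.4f}  RMSE={self.rmse:.4f}  "
            f"MSE={self.mse:.4f}  MAPE={self.mape:.2f}%  "
            f"NSC={self.nsc:.4f}  R2={self.r2:.4f}"
        )


def compute_metrics(observed, predicted) -> MetricsReport:
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.shape != p.shape or o.size == 0:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    if not (np.isfinite(o).all() and np.isfinite(p).all()):
        raise ValueError("observed/predicted contain non-finite values")

    err = o - p
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))

    nonzero = o != 0
    if not nonzero.all():
        warnings.warn(
            f"{int((~nonzero).sum())} zero observation(s) excluded from MAPE",
            stacklevel=2,
        )
    if nonzero.any():
        mape = float(100.0 * np.mean(np.abs(err[nonzero] / o[nonzero])))
    else:
        mape = float("nan")

    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("constant observed series: NSC and R2 undefined", stacklevel=2)
        nsc = float("nan")
        r2 = float("nan")
    else:
        nsc = float(1.0 - np.sum(err**2) / ss_tot)
        sp = float(np.sum((p - p.mean()) ** 2))
        if sp == 0.0:
            r2 = 1.0 if mse == 0.0 else float("nan")
            if mse > 0.0:
                warnings.warn("constant predictions: R2 undefined", stacklevel=2)
        else:
            c = np.corrcoef(o, p)[0, 1]
            r2 = float(c * c)
    return MetricsReport(mae=mae, rmse=rmse, mse=mse, mape=mape, nsc=nsc, r2=r2,
                         n=int(o.size))


def relative_difference(reference_metric: float, candidate_metric: float) -> float:
    """Percentage improvement of a candidate model over a reference model,

        100 * (reference - candidate) / reference,

    rounded to 2 decimals for reporting (positive = candidate is better on an
    error metric)."""
    if reference_metric <= 0:
        raise ValueError("reference metric must be positive")
    return round(100.0 * (reference_metric - candidate_metric) / reference_metric, 2)
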