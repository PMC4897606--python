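"""Least-squares support vector machine regression with an RBF kernel.

The LSSVM replaces the standard SVM's inequality constraints and
epsilon-insensitive loss with equality constraints and a squared-error loss,
so training collapses to one symmetric linear system (the KKT conditions of
the Lagrangian) in the dual variables:

    [ 0      1^T          ] [ b     ]   [ 0 ]
    [ 1   K + I / gamma   ] [ alpha ] = [ y ]

with K_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)). Predictions are the dual
expansion f(x) = sum_i alpha_i K(x, x_i) + b. ``gamma`` trades training error
against smoothness; ``sigma`` sets the kernel's similarity length scale.

Inputs are z-scored per feature using training-block statistics before any
kernel evaluation: the covariates mix units (degrees C, W/m^2, mm, %), and an
isotropic RBF kernel on raw mixed units would let one feature dominate. The
scaling parameters are stored in the results object and re-applied at
prediction time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold

__all__ = ["rbf_kernel", "LSSVM", "LSSVMResults", "cv_grid_search"]


def rbf_kernel(x: np.ndarray, z: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel K(x, z) = exp(-||x - z||^2 / (2 sigma^2)).

    Accepts single vectors or 2-D arrays; returns a scalar or the Gram
    matrix accordingly. Values lie in (0, 1] with K(x, x) = 1.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    scalar = x.ndim == 1 and z.ndim == 1
    X = np.atleast_2d(x)
    Z = np.atleast_2d(z)
    if X.shape[1] != Z.shape[1]:
        raise ValueError("x and z have different dimensions")
    K = np.exp(-cdist(X, Z, "sqeuclidean") / (2.0 * sigma**2))
    return float(K[0, 0]) if scalar else K


class LSSVM:
    """LSSVM regression model.

    Parameters
    ----------
    endog : (N,) array
        Targets.
    exog : (N, M) array
        Inputs; z-scored internally unless ``standardize=False``.
    gamma : float
        Regularization parameter (larger = closer fit to the training data).
    sigma : float
        RBF kernel width, on the standardized scale.
    """

    def __init__(self, endog, exog, gamma: float = 10.0, sigma: float = 1.0,
                 standardize: bool = True):
        if gamma <= 0:
            raise ValueError(f"gamma must be positive, got {gamma}")
        if sigma <= 0:
            raise ValueError(f"sigma must be positive, got {sigma}")
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog have different numbers of rows")
        if self.endog.shape[0] < 1:
            raise ValueError("need at least one training row")
        if not np.isfinite(self.endog).all() or not np.isfinite(self.exog).all():
            raise ValueError("endog/exog contain non-finite values")
        self.gamma = float(gamma)
        self.sigma = float(sigma)
        self.standardize = bool(standardize)
        if standardize:
            self._mean = self.exog.mean(axis=0)
            sd = self.exog.std(axis=0)
            self._scale = np.where(sd > 0, sd, 1.0)
        else:
            self._mean = np.zeros(self.exog.shape[1])
            self._scale = np.ones(self.exog.shape[1])

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self._mean) / self._scale

    def fit(self) -> "LSSVMResults":
        """Solve the KKT system for (b, alpha) by a dense symmetric solve."""
        y = self.endog
        n = len(y)
        Xs = self._transform(self.exog)
        K = rbf_kernel(Xs, Xs, self.sigma)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + np.eye(n) / self.gamma
        rhs = np.concatenate([[0.0], y])
        try:
            sol = scipy.linalg.solve(A, rhs, assume_a="sym")
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - numerical edge
            raise np.linalg.LinAlgError(f"KKT system solve failed: {exc}") from exc
        resid = np.linalg.norm(A @ sol - rhs)
        if not np.isfinite(sol).all() or resid > 1e-8 * max(1.0, np.linalg.norm(rhs)):
            # fall back to minimum-norm solve before declaring failure
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            resid = np.linalg.norm(A @ sol - rhs)
            if resid > 1e-8 * max(1.0, np.linalg.norm(rhs)):
                raise np.linalg.LinAlgError(
                    f"KKT system numerically singular (residual {resid:.3e})"
                )
        return LSSVMResults(model=self, bias=float(sol[0]), alpha=sol[1:],
                            kkt_residual=float(resid))


@dataclass
class LSSVMResults:
    """Fitted LSSVM: dual coefficients, bias and solve diagnostics."""

    model: LSSVM
    bias: float
    alpha: np.ndarray
    kkt_residual: float

    def predict(self, exog=None) -> np.ndarray:
        """Evaluate f(x) = sum_i alpha_i K(x, x_i) + b."""
        X = self.model.exog if exog is None else np.atleast_2d(np.asarray(exog, float))
        if X.shape[1] != self.model.exog.shape[1]:
            raise ValueError(
                f"input dimension {X.shape[1]} does not match training dimension "
                f"{self.model.exog.shape[1]}"
            )
        K = rbf_kernel(self.model._transform(X),
                       self.model._transform(self.model.exog), self.model.sigma)
        return K @ self.alpha + self.bias

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def train_rmse(self) -> float:
        return float(np.sqrt(np.mean(self.resid**2)))

    def summary(self) -> str:
        lines = [
            "LSSVM regression (RBF kernel)",
            "=============================",
            f"training rows:        {len(self.model.endog)}",
            f"gamma (regulariz.):   {self.model.gamma:.6g}",
            f"sigma (kernel width): {self.model.sigma:.6g}",
            f"bias b:               {self.bias:.6g}",
            f"sum(alpha):           {float(self.alpha.sum()):.3e}",
            f"KKT residual:         {self.kkt_residual:.3e}",
            f"training RMSE:        {self.train_rmse:.6g}",
        ]
        return "\n".join(lines)

    # ---- serialization (plain-text JSON, CLI round-tripping) ----

    def to_dict(self) -> dict:
        return {
            "gamma": self.model.gamma,
            "sigma": self.model.sigma,
            "standardize": self.model.standardize,
            "scale_mean": self.model._mean.tolist(),
            "scale_sd": self.model._scale.tolist(),
            "bias": self.bias,
            "alpha": self.alpha.tolist(),
            "X_train": self.model.exog.tolist(),
            "y_train": self.model.endog.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "LSSVMResults":
        model = LSSVM(d["y_train"], d["X_train"], gamma=d["gamma"], sigma=d["sigma"],
                      standardize=d["standardize"])
        model._mean = np.asarray(d["scale_mean"], dtype=float)
        model._scale = np.asarray(d["scale_sd"], dtype=float)
        return cls(model=model, bias=float(d["bias"]),
                   alpha=np.asarray(d["alpha"], dtype=float), kkt_residual=float("nan"))

    @classmethod
    def from_json(cls, path) -> "LSSVMResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def cv_grid_search(endog, exog, grid, folds: int = 5,
                   standardize: bool = True) -> tuple[float, float]:
    """Pick (gamma, sigma) minimizing mean k-fold CV RMSE over a grid.

    Folds are contiguous and unshuffled, so the result is deterministic.
    Ties break toward smaller gamma, then smaller sigma.
    """
    y = np.asarray(endog, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(exog, dtype=float))
    candidates = sorted((float(g), float(s)) for g, s in grid)
    if not candidates:
        raise ValueError("empty parameter grid")
    if len(y) < folds:
        raise ValueError(f"need at least {folds} rows for {folds}-fold CV")
    kf = KFold(n_splits=folds, shuffle=False)
    splits = list(kf.split(X))
    best, best_score = None, np.inf
    for gamma, sigma in candidates:
        errs = []
        for train_idx, test_idx in splits:
            res = LSSVM(y[train_idx], X[train_idx], gamma=gamma, sigma=sigma,
                        standardize=standardize).fit()
            pred = res.predict(X[test_idx])
            errs.append(np.sqrt(np.mean((y[test_idx] - pred) ** 2)))
        score = float(np.mean(errs))
        if score < best_score:
            best, best_score = (gamma, sigma), score
    return best
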