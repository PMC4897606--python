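"""Multi-sensor fusion with a three-layer radial-basis-function network.

Several dissolved-oxygen sensors observe the same pond; individual readings
carry noise, dropouts (exact zeros) and spikes. The fusion network maps the
vector of simultaneous readings to one credible value: a hidden layer of
Gaussian units whose centers come from K-means clustering of the training
inputs, and a linear output layer fitted by least squares. Because the
hidden-to-output map is linear, the output weights have a closed-form
least-squares solution — no gradient descent is needed.

Fault suppression is geometric: a reading vector contaminated by a zero or a
spike lies far from every K-means center, so all hidden activations are small
and the network output falls back toward its bias (roughly the mean DO),
rather than reproducing the corrupted value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

__all__ = [
    "kmeans_centers",
    "rbf_widths",
    "hidden_activations",
    "RBFNetFusion",
    "RBFNetFusionResults",
]


def kmeans_centers(X: np.ndarray, k: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Cluster rows of ``X`` into ``k`` groups; return (centers, assignments).

    Lloyd's algorithm run to convergence (or 300 iterations), with empty
    clusters re-seeded from high-inertia points.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D array")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n_samples, got k={k}, n={n}")
    km = KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=seed).fit(X)
    return km.cluster_centers_, km.labels_


def rbf_widths(centers: np.ndarray, k: int | None = None) -> np.ndarray:
    """Receptive-field widths from the classical heuristic.

    sigma = d_max / sqrt(2K) with ``d_max`` the largest pairwise center
    distance; shared across units. Degenerate geometries (one center, or all
    centers coincident) fall back to sigma = 1.
    """
    centers = np.asarray(centers, dtype=float)
    k = centers.shape[0] if k is None else k
    if centers.shape[0] < 2:
        return np.ones(centers.shape[0])
    d_max = cdist(centers, centers).max()
    sigma = d_max / np.sqrt(2.0 * k) if d_max > 0 else 1.0
    return np.full(centers.shape[0], sigma)


def hidden_activations(centers: np.ndarray, widths: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Gaussian hidden-layer activations phi_j(x) = exp(-||x - c_j||^2 / (2 sigma_j^2)).

    Returns an (N, K) matrix with entries in (0, 1]; an entry equals 1 exactly
    when the input coincides with the center.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != centers.shape[1]:
        raise ValueError(
            f"input dimension {X.shape[1]} does not match center dimension {centers.shape[1]}"
        )
    widths = np.asarray(widths, dtype=float)
    if (widths <= 0).any():
        raise ValueError("widths must be positive")
    sq = cdist(X, centers, "sqeuclidean")
    return np.exp(-sq / (2.0 * widths[None, :] ** 2))


class RBFNetFusion:
    """RBF fusion network model: sensor readings in, one fused DO value out.

    Parameters
    ----------
    endog : (N,) array
        Fusion target — the reference sensor's reading.
    exog : (N, M) array
        Simultaneous sensor readings (optionally plus covariates).
    n_centers : int
        Hidden-layer size K. The network interpolates when K = N.
    drop_zero_targets : bool
        Exclude training rows whose target is an exact 0.00 mg/L — a zero
        reference reading is itself a dropout fault, not a value worth
        fitting. Prediction still runs on every row.
    """

    def __init__(self, endog, exog, n_centers: int = 10, drop_zero_targets: bool = True):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog have different numbers of rows")
        if not np.isfinite(self.endog).all() or not np.isfinite(self.exog).all():
            raise ValueError("endog/exog contain non-finite values")
        self.n_centers = int(n_centers)
        self.drop_zero_targets = bool(drop_zero_targets)
        keep = self.endog != 0.0 if drop_zero_targets else np.ones(len(self.endog), bool)
        if keep.sum() < self.n_centers:
            raise ValueError(
                f"n_centers={self.n_centers} exceeds the {int(keep.sum())} usable training rows"
            )
        self._keep = keep

    def fit(self, seed: int = 0) -> "RBFNetFusionResults":
        """K-means centers, heuristic widths, least-squares output weights."""
        Xfit = self.exog[self._keep]
        yfit = self.endog[self._keep]
        centers, _ = kmeans_centers(Xfit, self.n_centers, seed=seed)
        widths = rbf_widths(centers)
        phi = hidden_activations(centers, widths, Xfit)
        design = np.column_stack([phi, np.ones(len(phi))])
        # minimum-norm least squares: rank-deficient designs are fine
        coef, *_ = np.linalg.lstsq(design, yfit, rcond=None)
        return RBFNetFusionResults(self, centers, widths, coef[:-1], coef[-1])


@dataclass
class RBFNetFusionResults:
    """Fitted fusion network: centers, widths, output weights and bias."""

    model: RBFNetFusion
    centers: np.ndarray
    widths: np.ndarray
    out_weights: np.ndarray
    bias: float

    def predict(self, exog=None) -> np.ndarray:
        """Fused values: linear combination of hidden activations plus bias."""
        X = self.model.exog if exog is None else np.atleast_2d(np.asarray(exog, float))
        phi = hidden_activations(self.centers, self.widths, X)
        return phi @ self.out_weights + self.bias

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog[self.model._keep])

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog[self.model._keep] - self.fittedvalues

    @property
    def train_rmse(self) -> float:
        return float(np.sqrt(np.mean(self.resid**2)))

    def summary(self) -> str:
        lines = [
            "RBF fusion network",
            "==================",
            f"hidden units (K):      {self.model.n_centers}",
            f"input dimension:       {self.model.exog.shape[1]}",
            f"training rows used:    {int(self.model._keep.sum())} of {len(self.model.endog)}",
            f"shared width sigma:    {self.widths[0]:.6g}",
            f"training RMSE (mg/L):  {self.train_rmse:.6g}",
        ]
        return "\n".join(lines)
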