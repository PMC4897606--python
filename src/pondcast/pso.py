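"""Particle swarm optimization, standard and improved, for LSSVM tuning.

The standard swarm moves each particle under inertia plus attraction to its
personal best and the global best:

    v <- w*v + c1*r1*(pbest - x) + c2*r2*(gbest - x),    x <- x + v

with r1, r2 fresh U[0,1] draws per particle per dimension, velocities capped
at vmax and positions clipped to box bounds.

The improved variant adds two independent mechanisms:

* **adaptive inertia** — particles at or below the swarm's average fitness
  are deemed close to the optimum and get a weight interpolated linearly
  between ``w_min`` (at the best fitness) and ``w_max`` (at the average);
  particles above average keep ``w_max`` so they can still move far;
* **mutation** — with probability ``pm`` a particle's position is re-drawn
  uniformly inside the bounds, an escape hatch from local minima.

``tune_lssvm`` specializes the swarm to 2-D hyperparameter search for the
LSSVM: particles live in (log10 gamma, log10 sigma) space, so decoded
parameters are always positive, and fitness is the RMSE between predicted
and actual values on a held-out slice of the training block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .lssvm import LSSVM

__all__ = [
    "PSOConfig",
    "SwarmState",
    "PSOResult",
    "adapt_inertia",
    "mutate",
    "pso_step",
    "run_pso",
    "tune_lssvm",
    "TuneResult",
]

logger = logging.getLogger(__name__)

#: Default (log10 gamma, log10 sigma) search box for LSSVM tuning.
DEFAULT_LOG_BOUNDS = ((-2.0, 6.0), (-2.0, 2.0))


@dataclass(frozen=True)
class PSOConfig:
    """Swarm settings. Defaults follow common practice for the classical
    values (c1 = c2 = 2, inertia in [0.4, 0.9]); swarm size 50 and 200
    generations match the reference experimental setup for 2-D tuning."""

    bounds: Sequence[tuple[float, float]]
    n_particles: int = 50
    max_iter: int = 200
    c1: float = 2.0
    c2: float = 2.0
    w_init: float = 0.9
    w_min: float = 0.4
    w_max: float = 0.9
    pm: float = 0.05
    vmax: Optional[Sequence[float]] = None
    seed: int = 0
    improved: bool = True
    fitness_floor: float = 0.0

    @property
    def dim(self) -> int:
        return len(self.bounds)

    def validate(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if len(self.bounds) == 0:
            raise ValueError("bounds are mandatory (unbounded search not supported)")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"bounds must satisfy low < high, got ({lo}, {hi})")
        if not 0.0 <= self.pm <= 1.0:
            raise ValueError("pm must lie in [0, 1]")
        if self.w_min > self.w_max:
            raise ValueError("w_min must be <= w_max")

    def velocity_cap(self) -> np.ndarray:
        if self.vmax is not None:
            return np.asarray(self.vmax, dtype=float)
        b = np.asarray(self.bounds, dtype=float)
        return 0.2 * (b[:, 1] - b[:, 0])


@dataclass
class SwarmState:
    """Positions, velocities and bests at one iteration."""

    positions: np.ndarray
    velocities: np.ndarray
    fitness: np.ndarray
    pbest_pos: np.ndarray
    pbest_fit: np.ndarray
    gbest_pos: np.ndarray
    gbest_fit: float
    iteration: int
    gbest_history: list[float] = field(default_factory=list)


@dataclass
class PSOResult:
    best_position: np.ndarray
    best_fitness: float
    gbest_history: list[float]
    n_iter: int


def adapt_inertia(particle_fit: float, fit_min: float, fit_avg: float,
                  config: PSOConfig) -> float:
    """Fitness-proportional inertia weight.

    Particles at or below the swarm average are close to the optimum and get
    a weight growing linearly from ``w_min`` (best particle) to ``w_max``
    (average particle); worse-than-average particles keep ``w_max``. The
    degenerate case fit_avg == fit_min maps to ``w_min``.
    """
    if not np.isfinite(particle_fit) or not np.isfinite(fit_avg):
        # failed evaluations (fitness +inf) are far from the optimum
        return config.w_max
    if particle_fit > fit_avg:
        return config.w_max
    if fit_avg == fit_min:
        return config.w_min
    frac = (particle_fit - fit_min) / (fit_avg - fit_min)
    return float(np.clip(config.w_min + (config.w_max - config.w_min) * frac,
                         config.w_min, config.w_max))


def mutate(position: np.ndarray, pm: float, bounds, rng: np.random.Generator) -> np.ndarray:
    """With probability ``pm``, re-draw the position uniformly in the bounds."""
    if rng.random() < pm:
        b = np.asarray(bounds, dtype=float)
        return rng.uniform(b[:, 0], b[:, 1])
    return position


def _safe_eval(objective: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    val = float(objective(x))
    if not np.isfinite(val):
        logger.warning("objective returned non-finite value at %s; treating as +inf", x)
        return np.inf
    return val


def _init_swarm(objective, config: PSOConfig, rng: np.random.Generator) -> SwarmState:
    b = np.asarray(config.bounds, dtype=float)
    pos = rng.uniform(b[:, 0], b[:, 1], size=(config.n_particles, config.dim))
    vel = np.zeros_like(pos)
    fit = np.array([_safe_eval(objective, p) for p in pos])
    gi = int(np.argmin(fit))
    state = SwarmState(
        positions=pos, velocities=vel, fitness=fit,
        pbest_pos=pos.copy(), pbest_fit=fit.copy(),
        gbest_pos=pos[gi].copy(), gbest_fit=float(fit[gi]),
        iteration=0,
    )
    state.gbest_history.append(state.gbest_fit)
    return state


def pso_step(state: SwarmState, objective, config: PSOConfig,
             rng: np.random.Generator) -> SwarmState:
    """Advance the swarm one generation in place and return it."""
    b = np.asarray(config.bounds, dtype=float)
    vcap = config.velocity_cap()
    n, d = state.positions.shape
    fit_min = float(state.fitness.min())
    fit_avg = float(state.fitness.mean())

    if config.improved:
        w = np.array([adapt_inertia(f, fit_min, fit_avg, config) for f in state.fitness])
    else:
        w = np.full(n, config.w_init)

    r1 = rng.random((n, d))
    r2 = rng.random((n, d))
    state.velocities = (
        w[:, None] * state.velocities
        + config.c1 * r1 * (state.pbest_pos - state.positions)
        + config.c2 * r2 * (state.gbest_pos[None, :] - state.positions)
    )
    state.velocities = np.clip(state.velocities, -vcap, vcap)
    state.positions = np.clip(state.positions + state.velocities, b[:, 0], b[:, 1])

    if config.improved and config.pm > 0:
        for i in range(n):
            state.positions[i] = mutate(state.positions[i], config.pm, config.bounds, rng)

    state.fitness = np.array([_safe_eval(objective, p) for p in state.positions])
    better = state.fitness < state.pbest_fit
    state.pbest_pos[better] = state.positions[better]
    state.pbest_fit[better] = state.fitness[better]
    gi = int(np.argmin(state.pbest_fit))
    if state.pbest_fit[gi] < state.gbest_fit:
        state.gbest_fit = float(state.pbest_fit[gi])
        state.gbest_pos = state.pbest_pos[gi].copy()
    state.iteration += 1
    state.gbest_history.append(state.gbest_fit)
    return state


def run_pso(objective, config: PSOConfig) -> PSOResult:
    """Run the swarm from a uniform initialization to termination.

    Terminates after ``max_iter`` generations or as soon as the global best
    reaches ``fitness_floor``. ``gbest_history`` holds the best fitness after
    initialization and after each executed generation (length n_iter + 1)
    and is non-increasing. Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = _init_swarm(objective, config, rng)
    while state.iteration < config.max_iter and state.gbest_fit > config.fitness_floor:
        pso_step(state, objective, config, rng)
    return PSOResult(
        best_position=state.gbest_pos.copy(),
        best_fitness=state.gbest_fit,
        gbest_history=list(state.gbest_history),
        n_iter=state.iteration,
    )


@dataclass
class TuneResult:
    gamma: float
    sigma: float
    fitness: float
    gbest_history: list[float]


def holdout_fitness(endog, exog, holdout_fraction: float = 0.2,
                    standardize: bool = True) -> Callable[[np.ndarray], float]:
    """Fitness for 2-D (log10 gamma, log10 sigma) particles: RMSE on the last
    ``holdout_fraction`` of the training block (temporal order respected)."""
    y = np.asarray(endog, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(exog, dtype=float))
    n_val = max(1, int(round(holdout_fraction * len(y))))
    n_fit = len(y) - n_val
    if n_fit < 2:
        raise ValueError(
            f"training block of {len(y)} rows is too small for a "
            f"{holdout_fraction:.0%} holdout"
        )

    def fitness(p: np.ndarray) -> float:
        gamma, sigma = 10.0 ** p[0], 10.0 ** p[1]
        res = LSSVM(y[:n_fit], X[:n_fit], gamma=gamma, sigma=sigma,
                    standardize=standardize).fit()
        pred = res.predict(X[n_fit:])
        return float(np.sqrt(np.mean((y[n_fit:] - pred) ** 2)))

    return fitness


def kfold_fitness(endog, exog, folds: int = 5,
                  standardize: bool = True) -> Callable[[np.ndarray], float]:
    """k-fold CV RMSE fitness (contiguous unshuffled folds), mirroring the
    baseline model-selection protocol."""
    from sklearn.model_selection import KFold

    y = np.asarray(endog, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(exog, dtype=float))
    if len(y) < folds:
        raise ValueError(f"training block of {len(y)} rows is too small for {folds} folds")
    splits = list(KFold(n_splits=folds, shuffle=False).split(X))

    def fitness(p: np.ndarray) -> float:
        gamma, sigma = 10.0 ** p[0], 10.0 ** p[1]
        errs = []
        for tr, te in splits:
            res = LSSVM(y[tr], X[tr], gamma=gamma, sigma=sigma,
                        standardize=standardize).fit()
            errs.append(np.sqrt(np.mean((y[te] - res.predict(X[te])) ** 2)))
        return float(np.mean(errs))

    return fitness


def tune_lssvm(endog, exog, config: Optional[PSOConfig] = None,
               holdout_fraction: float = 0.2, folds: Optional[int] = None,
               standardize: bool = True) -> TuneResult:
    """Tune (gamma, sigma) for an LSSVM by particle swarm search.

    Particles encode (log10 gamma, log10 sigma); the default box spans
    gamma in [1e-2, 1e6] and sigma in [1e-2, 1e2]. Fitness is holdout RMSE
    by default or k-fold CV RMSE when ``folds`` is given.
    """
    if config is None:
        config = PSOConfig(bounds=DEFAULT_LOG_BOUNDS)
    if config.dim != 2:
        raise ValueError("LSSVM tuning needs 2-D particles (log10 gamma, log10 sigma)")
    if folds is not None:
        fitness = kfold_fitness(endog, exog, folds=folds, standardize=standardize)
    else:
        fitness = holdout_fitness(endog, exog, holdout_fraction=holdout_fraction,
                                  standardize=standardize)
    result = run_pso(fitness, config)
    gamma = float(10.0 ** result.best_position[0])
    sigma = float(10.0 ** result.best_position[1])
    return TuneResult(gamma=gamma, sigma=sigma, fitness=result.best_fitness,
                      gbest_history=result.gbest_history)
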