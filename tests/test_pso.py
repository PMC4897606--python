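"""Particle swarm: update rules, adaptive inertia, mutation, tuning."""

import numpy as np
import pytest

from pondcast import LSSVM, PSOConfig, SwarmState, adapt_inertia, mutate, pso_step, run_pso, tune_lssvm
from pondcast.pso import DEFAULT_LOG_BOUNDS, holdout_fitness

BOUNDS2 = ((-5.0, 5.0), (-5.0, 5.0))


def sphere(x):
    return float(np.dot(x, x))


def make_state(positions, fitness):
    positions = np.asarray(positions, dtype=float)
    fitness = np.asarray(fitness, dtype=float)
    gi = int(np.argmin(fitness))
    return SwarmState(
        positions=positions.copy(), velocities=np.zeros_like(positions),
        fitness=fitness.copy(), pbest_pos=positions.copy(), pbest_fit=fitness.copy(),
        gbest_pos=positions[gi].copy(), gbest_fit=float(fitness[gi]),
        iteration=0, gbest_history=[float(fitness[gi])],
    )


class TestAdaptInertia:
    cfg = PSOConfig(bounds=BOUNDS2, w_min=0.4, w_max=0.9)

    def test_best_particle_gets_w_min(self):
        assert adapt_inertia(1.0, 1.0, 2.0, self.cfg) == pytest.approx(0.4)

    def test_worse_than_average_gets_w_max(self):
        assert adapt_inertia(3.0, 1.0, 2.0, self.cfg) == pytest.approx(0.9)

    def test_degenerate_all_equal_gets_w_min(self):
        assert adapt_inertia(1.0, 1.0, 1.0, self.cfg) == pytest.approx(0.4)

    def test_linear_interpolation_in_between(self):
        w = adapt_inertia(1.5, 1.0, 2.0, self.cfg)
        assert w == pytest.approx(0.4 + 0.5 * 0.5)
        assert 0.4 <= w <= 0.9


class TestMutate:
    def test_pm_zero_never_mutates(self, rng):
        x = np.array([1.0, -2.0])
        for _ in range(100):
            assert np.array_equal(mutate(x, 0.0, BOUNDS2, rng), x)

    def test_pm_one_always_redraws(self, rng):
        x = np.array([1.0, -2.0])
        out = mutate(x, 1.0, BOUNDS2, rng)
        assert not np.array_equal(out, x)
        assert (out >= -5).all() and (out <= 5).all()

    def test_mutation_count_binomial(self):
        rng = np.random.default_rng(99)
        n, p = 10000, 0.05
        x = np.zeros(2)
        count = sum(not np.array_equal(mutate(x, p, BOUNDS2, rng), x) for _ in range(n))
        assert abs(count - n * p) < 3 * np.sqrt(n * p * (1 - p))


class TestPSOStep:
    def test_swarm_at_optimum_is_fixed_point(self):
        # all particles at the optimum with zero velocity: update is identity
        cfg = PSOConfig(bounds=BOUNDS2, n_particles=3, improved=False, seed=0)
        state = make_state(np.zeros((3, 2)), np.zeros(3))
        rng = np.random.default_rng(0)
        for _ in range(5):
            state = pso_step(state, sphere, cfg, rng)
        np.testing.assert_array_equal(state.positions, np.zeros((3, 2)))
        assert state.gbest_fit == 0.0

    def test_zero_coefficients_static_swarm(self, rng):
        cfg = PSOConfig(bounds=BOUNDS2, n_particles=4, c1=0.0, c2=0.0,
                        w_init=0.7, improved=False, seed=1)
        pos = rng.uniform(-5, 5, size=(4, 2))
        state = make_state(pos, np.array([sphere(p) for p in pos]))
        state = pso_step(state, sphere, cfg, np.random.default_rng(1))
        np.testing.assert_array_equal(state.positions, pos)

    def test_gbest_monotone_and_positions_bounded(self, rng):
        cfg = PSOConfig(bounds=BOUNDS2, n_particles=8, improved=True, seed=2)
        pos = rng.uniform(-5, 5, size=(8, 2))
        state = make_state(pos, np.array([sphere(p) for p in pos]))
        step_rng = np.random.default_rng(2)
        for _ in range(20):
            before = state.gbest_fit
            state = pso_step(state, sphere, cfg, step_rng)
            assert state.gbest_fit <= before
            assert (state.positions >= -5).all() and (state.positions <= 5).all()

    def test_non_finite_objective_treated_as_inf(self):
        def bad(x):
            return float("nan") if x[0] > 0 else sphere(x)

        cfg = PSOConfig(bounds=BOUNDS2, n_particles=6, seed=3, max_iter=10)
        result = run_pso(bad, cfg)
        assert np.isfinite(result.best_fitness)


class TestRunPSO:
    def test_sphere_convergence_reference_settings(self):
        cfg = PSOConfig(bounds=BOUNDS2, n_particles=50, max_iter=200,
                        improved=True, seed=0)
        result = run_pso(sphere, cfg)
        assert result.best_fitness < 1e-3

    def test_analytic_optimum_located(self):
        cfg = PSOConfig(bounds=BOUNDS2, n_particles=50, max_iter=200,
                        improved=True, seed=7)
        result = run_pso(lambda x: (x[0] - 2) ** 2 + (x[1] + 1) ** 2, cfg)
        assert np.linalg.norm(result.best_position - [2.0, -1.0]) < 0.05

    def test_history_non_increasing_both_variants(self):
        for improved in (False, True):
            cfg = PSOConfig(bounds=BOUNDS2, n_particles=10, max_iter=40,
                            improved=improved, seed=5)
            h = run_pso(sphere, cfg).gbest_history
            assert all(a >= b for a, b in zip(h, h[1:]))

    def test_max_iter_zero_returns_initial_best(self):
        cfg = PSOConfig(bounds=BOUNDS2, n_particles=10, max_iter=0, seed=4)
        result = run_pso(sphere, cfg)
        assert result.n_iter == 0 and len(result.gbest_history) == 1
        assert np.isfinite(result.best_fitness)

    def test_reproducible_from_seed(self):
        cfg = PSOConfig(bounds=BOUNDS2, n_particles=12, max_iter=30, seed=9)
        a, b = run_pso(sphere, cfg), run_pso(sphere, cfg)
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.gbest_history == b.gbest_history

    def test_improved_beats_standard_on_rastrigin(self):
        def rastrigin(x):
            return float(20 + np.sum(x * x - 10 * np.cos(2 * np.pi * x)))

        finals = {True: [], False: []}
        for seed in range(20):
            for improved in (False, True):
                cfg = PSOConfig(bounds=((-5.12, 5.12),) * 2, n_particles=30,
                                max_iter=60, improved=improved, seed=seed)
                finals[improved].append(run_pso(rastrigin, cfg).best_fitness)
        assert np.median(finals[True]) <= np.median(finals[False])

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            run_pso(sphere, PSOConfig(bounds=()))
        with pytest.raises(ValueError, match="n_particles"):
            run_pso(sphere, PSOConfig(bounds=BOUNDS2, n_particles=1))
        with pytest.raises(ValueError, match="low < high"):
            run_pso(sphere, PSOConfig(bounds=((1.0, 1.0),)))


class TestTuneLSSVM:
    @staticmethod
    def planted_problem(seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-2, 2, size=(50, 2))
        base = LSSVM(np.sin(X[:, 0]) + 0.5 * X[:, 1], X, gamma=100.0, sigma=1.0).fit()
        return X, base.predict(X)  # noiseless, exactly representable targets

    def test_recovery_or_better_on_planted_data(self):
        X, y = self.planted_problem(17)
        planted_fitness = holdout_fitness(y, X)(np.log10([100.0, 1.0]))
        cfg = PSOConfig(bounds=DEFAULT_LOG_BOUNDS, n_particles=20, max_iter=30,
                        improved=True, seed=17)
        tuned = tune_lssvm(y, X, config=cfg)
        assert tuned.fitness <= planted_fitness + 1e-6
        assert tuned.gamma > 0 and tuned.sigma > 0

    def test_constant_targets_trivially_fit(self, rng):
        X = rng.normal(size=(25, 2))
        y = np.full(25, 3.5)
        cfg = PSOConfig(bounds=DEFAULT_LOG_BOUNDS, n_particles=10, max_iter=5, seed=1)
        tuned = tune_lssvm(y, X, config=cfg)
        assert tuned.fitness == pytest.approx(0.0, abs=1e-6)
        model = LSSVM(y, X, gamma=tuned.gamma, sigma=tuned.sigma).fit()
        np.testing.assert_allclose(model.predict(X), 3.5, atol=1e-4)

    def test_deterministic_under_seed(self):
        X, y = self.planted_problem(3)
        cfg = PSOConfig(bounds=DEFAULT_LOG_BOUNDS, n_particles=8, max_iter=10, seed=3)
        a, b = tune_lssvm(y, X, config=cfg), tune_lssvm(y, X, config=cfg)
        assert (a.gamma, a.sigma) == (b.gamma, b.sigma)

    def test_too_small_training_block_rejected(self, rng):
        with pytest.raises(ValueError, match="too small"):
            tune_lssvm(rng.normal(size=2), rng.normal(size=(2, 2)))

    def test_non_2d_config_rejected(self, rng):
        cfg = PSOConfig(bounds=((0.0, 1.0),))
        with pytest.raises(ValueError, match="2-D"):
            tune_lssvm(rng.normal(size=30), rng.normal(size=(30, 2)), config=cfg)
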