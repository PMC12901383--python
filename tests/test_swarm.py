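"""Unit tests for the swarm core: updates, schedules, boundaries, runs."""

import numpy as np
import pytest

from opso.exceptions import ConfigurationError, DimensionError, ScheduleError
from opso.problems import BoundedProblem
from opso.swarm import (
    OPSOParams,
    PSOParams,
    apply_boundary_absorption,
    classical_delta,
    constriction_factor,
    inertia_weight,
    initialize_swarm,
    maybe_reseed,
    position_update,
    run_opso,
    run_pso,
    velocity_update,
)


class _OnesRng:
    """Stub generator whose uniform draws are all ones (pins r1 = r2 = 1)."""

    def random(self, shape=None):
        return np.ones(shape) if shape is not None else 1.0


class TestInitialization:
    def test_seeded_determinism(self, unit_problem):
        a = initialize_swarm(unit_problem, 5, seed=7)
        b = initialize_swarm(unit_problem, 5, seed=7)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.pbest_fitness, b.pbest_fitness)
        assert a.gbest_fitness == b.gbest_fitness

    def test_gbest_is_min_of_pbest(self, unit_problem):
        s = initialize_swarm(unit_problem, 5, seed=3)
        assert s.gbest_fitness == s.pbest_fitness.min()

    def test_positions_inside_box(self, sphere5):
        s = initialize_swarm(sphere5, 100, seed=0)
        assert np.all(s.positions >= sphere5.lower)
        assert np.all(s.positions <= sphere5.upper)
        assert np.all(s.velocities == 0.0)

    def test_too_small_swarm_rejected(self, unit_problem):
        with pytest.raises(ConfigurationError):
            initialize_swarm(unit_problem, 1, seed=0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            BoundedProblem(2, [0.0, 1.0], [1.0, 1.0], lambda x: 0.0)


class TestClassicalDelta:
    def test_zero_when_at_both_attractors(self):
        x = np.array([0.3, -0.7])
        d = classical_delta(x, x, x, 2.0, 2.0, np.random.default_rng(0))
        assert np.array_equal(d, np.zeros(2))

    def test_zero_coefficients(self):
        rng = np.random.default_rng(1)
        d = classical_delta(np.zeros(3), np.ones(3), np.ones(3), 0.0, 0.0, rng)
        assert np.array_equal(d, np.zeros(3))

    def test_pinned_draws_give_sum_of_attractions(self):
        d = classical_delta(np.array([0.0]), np.array([1.0]), np.array([1.0]),
                            1.0, 1.0, _OnesRng())
        assert d == pytest.approx([2.0])

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            classical_delta(np.zeros(2), np.zeros(3), np.zeros(2), 1, 1,
                            np.random.default_rng(0))


class TestSchedulesAndFactors:
    def test_constriction_complex_at_2_05(self):
        assert constriction_factor(2.05) == pytest.approx(1.0, abs=5e-5)

    def test_constriction_at_discriminant_zero(self):
        assert constriction_factor(4.0) == pytest.approx(1.0, abs=1e-12)

    def test_constriction_real_clerc_value(self):
        assert constriction_factor(4.1, mode="real") == pytest.approx(0.7298, abs=5e-5)

    def test_real_mode_rejects_small_phi(self):
        with pytest.raises(ConfigurationError):
            constriction_factor(2.05, mode="real")

    @pytest.mark.parametrize("t,expected", [(0, 0.7), (500, 0.5), (1000, 0.3)])
    def test_inertia_linear_schedule(self, t, expected):
        assert inertia_weight(t, 1000, 0.7, 0.3) == pytest.approx(expected)

    def test_inertia_outside_schedule(self):
        with pytest.raises(ScheduleError):
            inertia_weight(11, 10, 0.7, 0.3)


class TestVelocityPosition:
    def test_velocity_update_formula(self):
        v = velocity_update(np.array([1.0, 0.0]), np.array([0.0, 1.0]), 0.5, 1.0)
        assert np.allclose(v, [0.5, 1.0])

    def test_zero_chi_kills_velocity(self):
        v = velocity_update(np.array([3.0, -2.0]), np.array([5.0, 5.0]), 0.9, 0.0)
        assert np.array_equal(v, np.zeros(2))

    def test_position_update_is_sum_and_invertible(self):
        x = np.array([1.0, 2.0])
        v = np.array([-1.0, 3.0])
        moved = position_update(x, v)
        assert np.array_equal(moved, [0.0, 5.0])
        assert np.array_equal(position_update(moved, -v), x)


class TestBoundaryAbsorption:
    def test_inside_untouched(self, unit_problem):
        x, v = apply_boundary_absorption(np.array([0.4]), np.array([0.2]), unit_problem)
        assert x == pytest.approx([0.4]) and v == pytest.approx([0.2])

    def test_clamp_and_zero_velocity(self, unit_problem):
        x, v = apply_boundary_absorption(np.array([1.5]), np.array([0.9]), unit_problem)
        assert np.array_equal(x, [1.0]) and np.array_equal(v, [0.0])

    def test_per_coordinate(self):
        p = BoundedProblem(2, [0.0, 0.0], [1.0, 1.0], lambda x: 0.0)
        x, v = apply_boundary_absorption(np.array([-0.2, 0.5]),
                                         np.array([-1.0, 2.0]), p)
        assert np.array_equal(x, [0.0, 0.5])
        assert np.array_equal(v, [0.0, 2.0])


class TestReseeding:
    def test_p_zero_never_reseeds(self, unit_problem):
        s = initialize_swarm(unit_problem, 2, seed=0)
        part = s.particle(0)
        rng = np.random.default_rng(5)
        for _ in range(50):
            out = maybe_reseed(part, unit_problem, 0.0, rng)
            assert np.array_equal(out.position, part.position)

    def test_p_one_redraws_but_keeps_pbest(self, unit_problem):
        s = initialize_swarm(unit_problem, 2, seed=0)
        part = s.particle(0)
        out = maybe_reseed(part, unit_problem, 1.0, np.random.default_rng(5))
        assert np.array_equal(out.pbest_position, part.pbest_position)
        assert out.pbest_fitness == part.pbest_fitness
        assert np.all(out.velocity == 0.0)

    def test_reseed_rate_is_binomial(self, unit_problem):
        s = initialize_swarm(unit_problem, 2, seed=0)
        part = s.particle(0)
        rng = np.random.default_rng(11)
        count = sum(
            not np.array_equal(maybe_reseed(part, unit_problem, 0.03, rng).position,
                               part.position)
            for _ in range(10_000)
        )
        sd = np.sqrt(10_000 * 0.03 * 0.97)
        assert abs(count - 300) < 5 * sd


class TestRuns:
    def test_pso_converges_on_sphere(self, sphere5):
        params = PSOParams(population=50, t_max=300)
        finals = [run_pso(sphere5, params, seed=s).best_fitness for s in range(5)]
        assert all(f < 1e-3 for f in finals)

    def test_opso_converges_on_sphere(self, sphere5):
        params = OPSOParams(population=100, t_max=200)
        finals = [run_opso(sphere5, params, seed=s).best_fitness for s in range(5)]
        assert sum(f < 1e-3 for f in finals) >= 4

    @pytest.mark.parametrize("runner,params", [
        (run_pso, PSOParams(population=20, t_max=50)),
        (run_opso, OPSOParams(population=20, t_max=50)),
    ])
    def test_history_monotone_and_reproducible(self, sphere5, runner, params):
        r1 = runner(sphere5, params, seed=42)
        r2 = runner(sphere5, params, seed=42)
        assert len(r1.history) == params.t_max
        assert np.all(np.diff(r1.history) <= 0)
        assert r1.best_fitness == r1.history[-1]
        assert np.array_equal(r1.history, r2.history)
        assert np.array_equal(r1.best_position, r2.best_position)
        assert r1.evaluations == params.population * (params.t_max + 1)

    def test_zero_iterations_returns_initial_best(self, sphere5):
        r = run_pso(sphere5, PSOParams(population=30, t_max=0), seed=3)
        s = initialize_swarm(sphere5, 30, seed=3)
        assert r.best_fitness == s.gbest_fitness
        assert len(r.history) == 0

    def test_degenerate_swarm_at_optimum_never_worsens(self, sphere5):
        at_opt = np.zeros((100, 10))
        r = run_opso(sphere5, OPSOParams(population=100, t_max=30), seed=0,
                     init_positions=at_opt)
        assert r.best_fitness == 0.0
        assert np.all(np.asarray(r.history) == 0.0)

    def test_positions_stay_in_bounds_randomized(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            lo = rng.uniform(-10, 0, 4)
            hi = lo + rng.uniform(0.5, 10, 4)
            prob = BoundedProblem(4, lo, hi,
                                  lambda x: float(np.sum(np.sin(x) + x * x)))
            for params, runner in [(OPSOParams(population=10, t_max=20), run_opso),
                                   (PSOParams(population=10, t_max=20), run_pso)]:
                res = runner(prob, params, seed=int(rng.integers(1000)))
                assert np.all(res.best_position >= lo - 1e-12)
                assert np.all(res.best_position <= hi + 1e-12)


def _reference_constricted_pso(problem, params, seed):
    """Independent constricted-PSO oracle replaying the run's draw order."""
    rng = np.random.default_rng(seed)
    n, d = params.population, problem.dimension
    pos = rng.uniform(problem.lower, problem.upper, (n, d))
    vel = np.zeros((n, d))
    fit = problem.evaluate(pos)
    pbest, pbest_f = pos.copy(), fit.copy()
    g = int(np.argmin(fit))
    gbest, gbest_f = pos[g].copy(), float(fit[g])
    import cmath

    # phi = 2.05 under the complex-modulus reading: |2 - phi - sqrt(phi^2-4phi)| = 2
    phi = params.phi_stability
    chi = 2.0 / abs(2.0 - phi - cmath.sqrt(complex(phi * phi - 4.0 * phi)))
    history = []
    for t in range(params.t_max):
        r1 = rng.random((n, d))
        r2 = rng.random((n, d))
        delta = params.C1 * r1 * (pbest - pos) + params.C2 * r2 * (gbest - pos)
        w = params.w_hi + (params.w_lo - params.w_hi) * (t / params.t_max)
        vel = chi * (w * vel + delta)
        pos = pos + vel
        out = (pos < problem.lower) | (pos > problem.upper)
        pos = np.clip(pos, problem.lower, problem.upper)
        vel = np.where(out, 0.0, vel)
        fit = problem.evaluate(pos)
        better = fit < pbest_f
        pbest[better] = pos[better]
        pbest_f[better] = fit[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest = pbest[g].copy()
        history.append(gbest_f)
    return np.asarray(history), gbest


class TestReductionToClassicalPSO:
    def test_opso_without_optical_equals_constricted_pso(self, sphere5):
        params = OPSOParams(population=25, t_max=60, mbeta0=0.0, reseed_p=0.0)
        res = run_opso(sphere5, params, seed=123)
        hist, gbest = _reference_constricted_pso(sphere5, params, seed=123)
        assert np.array_equal(res.history, hist)
        assert np.array_equal(res.best_position, gbest)
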