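import numpy as np
import pytest

from bcdnet.jellyfish import (JsoConfig, active_move, logistic_init, logistic_step,
                              ocean_current_move, optimize, passive_move, time_control)


class FixedRng:
    """Stand-in RNG returning a scripted sequence of uniform draws."""

    def __init__(self, values):
        self.values = list(values)

    def random(self, size=None):
        v = self.values.pop(0)
        return np.full(size, v) if size is not None else v


class TestLogisticInit:
    def test_chaotic_step_values(self):
        assert logistic_step(0.2) == pytest.approx(0.64)
        assert logistic_step(0.5) == pytest.approx(1.0)  # why 0.5 starts are excluded

    def test_init_within_bounds(self):
        cfg = JsoConfig(population=30, bounds=(-5.0, 5.0), seed=3)
        pos = logistic_init(10, cfg)
        assert pos.shape == (30, 10)
        assert np.all(pos >= -5.0) and np.all(pos <= 5.0)

    def test_init_deterministic(self):
        cfg = JsoConfig(population=6, bounds=(0.0, 1.0), seed=9)
        np.testing.assert_array_equal(logistic_init(4, cfg), logistic_init(4, cfg))


class TestTimeControl:
    def test_zero_at_final_iteration(self):
        assert time_control(100, 100, np.random.default_rng(0)) == 0.0

    def test_plugin_midpoint(self):
        assert time_control(50, 100, FixedRng([1.0])) == pytest.approx(0.5)

    def test_moments(self):
        # E|2r - 1| = 1/2, so the mean at iteration 1 of N=100 is 0.495
        rng = np.random.default_rng(5)
        draws = np.array([time_control(1, 100, rng) for _ in range(10_000)])
        assert np.all((0.0 <= draws) & (draws <= 0.99))
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.495) < 3 * se


class TestMoves:
    cfg = JsoConfig(bounds=(-10.0, 10.0))

    def test_ocean_current_zero_step_unchanged(self):
        pos = np.array([1.0, 2.0])
        out = ocean_current_move(pos, np.array([3.0, 3.0]), np.array([0.5, 0.5]),
                                 self.cfg, FixedRng([0.7, 0.0]))
        np.testing.assert_array_equal(out, pos)

    def test_ocean_current_zero_mean_plugin(self):
        pos = np.array([1.0, 1.0])
        best = np.array([2.0, -1.0])
        out = ocean_current_move(pos, best, np.zeros(2), self.cfg, FixedRng([0.3, 1.0]))
        np.testing.assert_allclose(out, pos + best)

    def test_ocean_current_origin_fixed_point(self):
        out = ocean_current_move(np.zeros(3), np.zeros(3), np.zeros(3),
                                 self.cfg, FixedRng([0.4, 0.9]))
        np.testing.assert_array_equal(out, np.zeros(3))

    def test_passive_zero_draw_or_zero_chi_unchanged(self):
        pos = np.array([5.0])
        np.testing.assert_array_equal(passive_move(pos, self.cfg, FixedRng([0.0])), pos)
        cfg0 = JsoConfig(bounds=(-10.0, 10.0), chi=0.0)
        np.testing.assert_array_equal(passive_move(pos, cfg0, FixedRng([1.0])), pos)

    def test_passive_plugin(self):
        cfg = JsoConfig(bounds=(0.0, 10.0))
        out = passive_move(np.array([5.0]), cfg, FixedRng([1.0]))
        np.testing.assert_allclose(out, [6.0])

    def test_active_moves_toward_better_peer(self):
        # minimization: s has the worse (larger) fitness, so it moves toward q
        s, q = np.array([0.0]), np.array([4.0])
        out = active_move(s, q, 2.0, 1.0, self.cfg, FixedRng([0.5]))
        assert 0.0 < out[0] <= 4.0

    def test_active_identical_positions_unchanged(self):
        s = np.array([1.0, 2.0])
        np.testing.assert_array_equal(active_move(s, s.copy(), 3.0, 1.0, self.cfg,
                                                  FixedRng([0.8])), s)

    def test_active_else_branch_plugin(self):
        s, q = np.array([1.0]), np.array([3.0])
        out = active_move(s, q, 1.0, 2.0, self.cfg, FixedRng([1.0]))
        np.testing.assert_allclose(out, 2 * s - q)


def sphere(x):
    return float(np.sum(np.square(x)))


class TestOptimize:
    def test_1d_quadratic_converges(self):
        cfg = JsoConfig(population=30, iterations=200, bounds=(0.0, 5.0), seed=0)
        res = optimize(lambda x: float((x[0] - 3.0) ** 2), 1, cfg)
        assert abs(res.best_position[0] - 3.0) < 0.1

    def test_single_iteration_bookkeeping(self):
        cfg = JsoConfig(population=2, iterations=1, bounds=(-1.0, 1.0), seed=1)
        res = optimize(sphere, 3, cfg)
        assert res.history.shape == (1,)
        assert res.history[0] == res.best_fitness

    def test_history_monotone_and_final_best(self):
        cfg = JsoConfig(population=10, iterations=50, bounds=(-5.0, 5.0), seed=2)
        seen = []

        def tracked(x):
            f = sphere(x)
            seen.append(f)
            return f

        res = optimize(tracked, 4, cfg)
        assert np.all(np.diff(res.history) <= 0)
        assert res.best_fitness == min(seen)

    def test_seed_determinism(self):
        cfg = JsoConfig(population=8, iterations=30, bounds=(-2.0, 2.0), seed=5)
        r1 = optimize(sphere, 3, cfg)
        r2 = optimize(sphere, 3, cfg)
        np.testing.assert_array_equal(r1.history, r2.history)
        np.testing.assert_array_equal(r1.best_position, r2.best_position)

    def test_all_evaluations_feasible(self):
        lo, hi = -1.5, 0.5

        def check(x):
            assert np.all(x >= lo) and np.all(x <= hi)
            return sphere(x)

        cfg = JsoConfig(population=10, iterations=40, bounds=(lo, hi), seed=3)
        optimize(check, 5, cfg)

    def test_nonfinite_fitness_reports_position(self):
        cfg = JsoConfig(population=4, iterations=5, bounds=(-1.0, 1.0), seed=0)
        with pytest.raises(FloatingPointError, match="non-finite"):
            optimize(lambda x: float("nan"), 2, cfg)

    def test_batch_fitness_matches_scalar_path(self):
        cfg = JsoConfig(population=6, iterations=20, bounds=(-3.0, 3.0), seed=7)
        r1 = optimize(sphere, 3, cfg)
        r2 = optimize(sphere, 3, cfg,
                      batch_fitness=lambda P: np.sum(np.square(P), axis=1))
        np.testing.assert_array_equal(r1.history, r2.history)


def test_config_validation():
    with pytest.raises(ValueError, match="population"):
        JsoConfig(population=1)
    with pytest.raises(ValueError, match="bounds"):
        JsoConfig(bounds=(1.0, 1.0))
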