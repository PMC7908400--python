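import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from decompcast.iwoa import (
    IWOAConfig,
    Population,
    chaotic_local_search,
    draw_coefficients,
    iwoa_minimize,
    logistic_step,
    position_update,
)

BOX = np.tile(np.array([-2.0, 2.0]), (2, 1))


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestCoefficients:
    def test_linear_decay_schedule(self):
        rng = np.random.default_rng(0)
        a0, *_ = draw_coefficients(0, 100, rng, 3)
        assert a0 == pytest.approx(2.0)
        a_last, *_ = draw_coefficients(99, 100, rng, 3)
        assert a_last <= 2.0 / 100 + 1e-12

    @given(st.integers(0, 499), st.integers(0, 50))
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_A_bounded_by_a(self, t, seed):
        rng = np.random.default_rng(seed)
        a, A, C, l, p = draw_coefficients(t, 500, rng, 4)
        assert np.all(np.abs(A) <= a + 1e-12)
        assert -1.0 <= l <= 1.0
        assert 0.0 <= p <= 1.0
        assert np.all((0.0 <= C) & (C <= 2.0))

    def test_bad_iteration_rejected(self):
        with pytest.raises(ValueError):
            draw_coefficients(500, 500, np.random.default_rng(0), 2)


class TestPositionUpdate:
    def test_encircling_with_zero_A_returns_best(self):
        x_star = np.array([0.5, -1.0])
        out = position_update(
            np.array([1.0, 1.0]), x_star, np.zeros(2),
            A=np.zeros(2), C=np.ones(2), l=0.0, p=0.2, bounds=BOX,
        )
        np.testing.assert_allclose(out, x_star)

    def test_spiral_at_best_stays_at_best(self):
        x_star = np.array([0.3, 0.7])
        out = position_update(
            x_star.copy(), x_star, np.zeros(2),
            A=np.zeros(2), C=np.ones(2), l=0.4, p=0.9, bounds=BOX,
        )
        np.testing.assert_allclose(out, x_star)

    def test_spiral_unit_offset(self):
        # D' = (1, 0), b = 1, l = 0 -> X* + (1, 0)
        x_star = np.array([0.0, 0.0])
        x = np.array([-1.0, 0.0])
        out = position_update(
            x, x_star, np.zeros(2), A=np.zeros(2), C=np.ones(2),
            l=0.0, p=0.9, bounds=BOX, b=1.0,
        )
        np.testing.assert_allclose(out, [1.0, 0.0])

    @given(st.integers(0, 60))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_always_clamped_to_box(self, seed):
        rng = np.random.default_rng(seed)
        a, A, C, l, p = draw_coefficients(rng.integers(0, 500), 500, rng, 2)
        out = position_update(
            rng.uniform(-2, 2, 2), rng.uniform(-2, 2, 2), rng.uniform(-2, 2, 2),
            A=A, C=C, l=l, p=p, bounds=BOX,
        )
        assert np.all(out >= -2.0) and np.all(out <= 2.0)


class TestLogisticStep:
    @pytest.mark.parametrize(
        "cx, expected",
        [(0.3, 0.84), (0.25, 0.75), (0.75, 0.75), (0.5, 1.0)],
    )
    def test_map_values(self, cx, expected):
        assert logistic_step(cx) == pytest.approx(expected)

    @pytest.mark.parametrize("cx", [0.0, 1.0, -0.1, 1.5])
    def test_domain_enforced(self, cx):
        with pytest.raises(ValueError):
            logistic_step(cx)

    def test_chaos_space_round_trip_is_identity(self):
        lo, hi = -2.0, 2.0
        x = np.linspace(-1.9, 1.9, 11)
        cx = (x - lo) / (hi - lo)
        back = lo + cx * (hi - lo)
        np.testing.assert_allclose(back, x, atol=1e-12)


class TestChaoticLocalSearch:
    def _pop(self, positions, objective):
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        fits = np.array([objective(x) for x in positions])
        best = int(np.argmin(fits))
        return Population(
            positions=positions.copy(),
            fitnesses=fits,
            best_position=positions[best].copy(),
            best_fitness=float(fits[best]),
        )

    def test_no_improvement_leaves_population_unchanged(self):
        bounds = np.array([[-2.0, 2.0]])
        pop = self._pop([[0.0]], sphere)  # at the optimum; any jump is worse
        before = pop.positions.copy()
        chaotic_local_search(pop, bounds, sphere)
        np.testing.assert_array_equal(pop.positions, before)

    def test_never_worsens_any_agent(self):
        bounds = np.tile(np.array([-2.0, 2.0]), (3, 1))
        rng = np.random.default_rng(1)
        pop = self._pop(rng.uniform(-2, 2, size=(12, 3)), sphere)
        before = pop.fitnesses.copy()
        chaotic_local_search(pop, bounds, sphere)
        assert np.all(pop.fitnesses <= before)

    def test_hand_computed_jump_in_1d(self):
        # chaos coordinate 0.3 on [-2, 2] -> candidate -2 + 0.84 * 4 = 1.36
        bounds = np.array([[-2.0, 2.0]])
        x0 = -2.0 + 0.3 * 4.0  # = -0.8, sphere fitness 0.64
        pop = self._pop([[x0]], sphere)
        chaotic_local_search(pop, bounds, sphere)
        # 1.36^2 = 1.8496 > 0.64 -> rejected
        np.testing.assert_allclose(pop.positions, [[x0]])
        pop2 = self._pop([[-2.0 + 0.3 * 4.0]], lambda x: -sphere(x))
        chaotic_local_search(pop2, bounds, lambda x: -sphere(x))
        # now the larger-magnitude candidate improves (more negative fitness)
        np.testing.assert_allclose(pop2.positions, [[1.36]])


class TestMinimize:
    def test_constant_objective_flat_trace(self):
        result = iwoa_minimize(lambda x: 3.5, IWOAConfig(dim=2, max_iter=20, seed=0))
        assert result.best_fitness == 3.5
        assert np.all(result.trace == 3.5)

    def test_seeded_determinism(self):
        a = iwoa_minimize(sphere, IWOAConfig(dim=3, max_iter=40, seed=9))
        b = iwoa_minimize(sphere, IWOAConfig(dim=3, max_iter=40, seed=9))
        np.testing.assert_array_equal(a.best_position, b.best_position)
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_trace_non_increasing(self):
        result = iwoa_minimize(sphere, IWOAConfig(dim=4, max_iter=100, seed=2))
        assert np.all(np.diff(result.trace) <= 0.0 + 1e-15)

    def test_visited_points_stay_in_box(self):
        seen = []

        def probe(x):
            seen.append(x.copy())
            return sphere(x)

        iwoa_minimize(probe, IWOAConfig(dim=2, max_iter=30, seed=4))
        allx = np.array(seen)
        assert np.all(allx >= -2.0) and np.all(allx <= 2.0)

    def test_nan_objective_reported(self):
        def bad(x):
            return float("nan")

        with pytest.raises(FloatingPointError, match="non-finite"):
            iwoa_minimize(bad, IWOAConfig(dim=2, max_iter=5, seed=0))

    def test_mu_constraint_enforced(self):
        with pytest.raises(ValueError, match="mu = 4"):
            IWOAConfig(dim=2, mu=3.9, cls_enabled=True)
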