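"""Grasshopper-optimizer core: social force, schedule, update, loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq, minimize_scalar

from goafs.goa import (
    GoaConfig,
    SwarmState,
    social_force,
    comfort_coefficient,
    map_distance,
    update_positions,
    optimize,
)

COMFORT = 3 * np.log(2)  # unique positive root of S for f=0.5, l=1.5


class TestSocialForce:
    def test_root_at_comfort_distance(self):
        assert social_force(COMFORT, 0.5, 1.5) == pytest.approx(0.0, abs=1e-12)
        # printed three-decimal boundary of the repulsion range
        assert abs(social_force(2.079, 0.5, 1.5)) < 1e-3

    def test_value_at_origin(self):
        # S(0) = f - 1
        assert social_force(0.0, 0.5, 1.5) == pytest.approx(-0.5)

    def test_global_maximum_matches_grid_oracle(self):
        """Dense grid + bounded refinement locates the argmax at 3 ln 3."""
        grid = np.arange(1e-3, 10, 1e-3)
        i = np.argmax(social_force(grid, 0.5, 1.5))
        res = minimize_scalar(
            lambda r: -social_force(r, 0.5, 1.5),
            bounds=(grid[i] - 1e-2, grid[i] + 1e-2),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.x == pytest.approx(3 * np.log(3), abs=1e-5)
        assert social_force(res.x, 0.5, 1.5) == pytest.approx(1 / 54, abs=1e-10)

    def test_sign_structure(self):
        r = np.linspace(1e-6, 15, 2000)
        s = social_force(r, 0.5, 1.5)
        assert np.all(s[r < COMFORT - 1e-9] < 0)
        assert np.all(s[r > COMFORT + 1e-9] > 0)
        assert abs(social_force(15.0, 0.5, 1.5)) < 1e-3

    @given(st.floats(min_value=0.0, max_value=50.0))
    @settings(derandomize=True, max_examples=50)
    def test_sign_by_region_property(self, r):
        s = social_force(r, 0.5, 1.5)
        if r < COMFORT - 1e-9:
            assert s < 0
        elif r > COMFORT + 1e-9:
            assert s > 0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            social_force(-0.1, 0.5, 1.5)


class TestComfortCoefficient:
    @pytest.fixture
    def cfg(self):
        return GoaConfig(max_iterations=80, c_max=1.0, c_min=1e-5)

    def test_endpoints_exact(self, cfg):
        assert comfort_coefficient(0, cfg) == cfg.c_max
        assert comfort_coefficient(80, cfg) == cfg.c_min

    def test_midpoint(self, cfg):
        assert comfort_coefficient(40, cfg) == pytest.approx(0.500005)

    def test_strictly_decreasing(self, cfg):
        vals = [comfort_coefficient(t, cfg) for t in range(81)]
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("t", [-1, 81])
    def test_out_of_range_rejected(self, cfg, t):
        with pytest.raises(ValueError):
            comfort_coefficient(t, cfg)


class TestMapDistance:
    def test_endpoints(self):
        assert map_distance(2.0, 2.0, 9.0) == pytest.approx(1.0)
        assert map_distance(9.0, 2.0, 9.0) == pytest.approx(4.0)

    def test_degenerate_all_equal(self):
        assert map_distance(3.3, 3.3, 3.3) == pytest.approx(2.5)

    def test_affine_in_between(self):
        # halfway distance maps to the range midpoint
        assert map_distance(5.5, 2.0, 9.0) == pytest.approx(2.5)


class TestUpdatePositions:
    def _state(self, positions, objective):
        positions = np.asarray(positions, dtype=float)
        fit = np.array([objective(x) for x in positions])
        i = int(np.argmin(fit))
        return SwarmState(positions, fit, positions[i].copy(), float(fit[i]))

    def test_single_grasshopper_copies_target(self):
        cfg = GoaConfig(population_size=1, lower_bounds=[-5, -5], upper_bounds=[5, 5])
        obj = lambda x: float((x ** 2).sum())
        st_ = self._state([[2.0, -3.0]], obj)
        new = update_positions(st_, 0.7, cfg, obj, np.random.default_rng(0))
        np.testing.assert_array_equal(new.positions[0], st_.target_position)

    def test_mirror_symmetry_about_target(self):
        """Two grasshoppers symmetric about the target move as mirror images.

        Hand evaluation: the single pairwise distance maps to the
        degenerate midpoint 2.5, so each update is
        c^2 * half_width * S(2.5) * (+-1) + T.
        """
        cfg = GoaConfig(
            population_size=2, lower_bounds=[-10.0], upper_bounds=[10.0]
        )
        obj = lambda x: float(x[0] ** 2)
        st_ = self._state([[-1.0], [1.0]], obj)
        st_.target_position = np.array([0.0])
        st_.target_fitness = 0.0
        c = 0.7
        new = update_positions(st_, c, cfg, obj, np.random.default_rng(0))
        expected = c * c * 10.0 * social_force(2.5, 0.5, 1.5)
        assert new.positions[0, 0] == pytest.approx(expected)
        assert new.positions[1, 0] == pytest.approx(-expected)

    def test_positions_always_clamped(self):
        cfg = GoaConfig(
            population_size=8, lower_bounds=[-1, -1], upper_bounds=[1, 1]
        )
        rng = np.random.default_rng(3)
        obj = lambda x: float((x ** 2).sum())
        st_ = self._state(rng.uniform(-1, 1, (8, 2)), obj)
        lb, ub = cfg.bounds_arrays()
        for c in [1.0, 0.5, 0.01]:
            st_ = update_positions(st_, c, cfg, obj, rng)
            assert np.all(st_.positions >= lb) and np.all(st_.positions <= ub)

    def test_coincident_grasshoppers_no_nan(self):
        cfg = GoaConfig(population_size=3, lower_bounds=[-5, -5], upper_bounds=[5, 5])
        obj = lambda x: float((x ** 2).sum())
        st_ = self._state([[1.0, 1.0], [1.0, 1.0], [-2.0, 0.5]], obj)
        new = update_positions(st_, 0.9, cfg, obj, np.random.default_rng(1))
        assert np.all(np.isfinite(new.positions))

    def test_target_fitness_never_increases(self):
        cfg = GoaConfig(population_size=5, lower_bounds=[-3] * 3, upper_bounds=[3] * 3)
        rng = np.random.default_rng(9)
        obj = lambda x: float(np.cos(x).sum())
        st_ = self._state(rng.uniform(-3, 3, (5, 3)), obj)
        prev = st_.target_fitness
        for c in np.linspace(1.0, 0.01, 10):
            st_ = update_positions(st_, float(c), cfg, obj, rng)
            assert st_.target_fitness <= prev
            prev = st_.target_fitness


class TestOptimize:
    def test_trace_shape_and_monotone(self):
        cfg = GoaConfig(
            population_size=10, max_iterations=30,
            lower_bounds=[-4] * 3, upper_bounds=[4] * 3, seed=0,
        )
        _, best, trace = optimize(lambda x: float((x ** 2).sum()), cfg)
        assert trace.shape == (31,)
        assert np.all(np.diff(trace) <= 0)
        assert best == trace[-1]

    def test_monotone_on_constant_objective(self):
        cfg = GoaConfig(
            population_size=5, max_iterations=15,
            lower_bounds=[0, 0], upper_bounds=[1, 1], seed=2,
        )
        _, best, trace = optimize(lambda x: 7.0, cfg)
        assert best == 7.0
        assert np.all(trace == 7.0)

    def test_seeded_determinism_bitwise(self):
        cfg = GoaConfig(
            population_size=12, max_iterations=25,
            lower_bounds=[-2] * 4, upper_bounds=[2] * 4, seed=11,
        )
        obj = lambda x: float(np.abs(x).sum())
        p1, f1, t1 = optimize(obj, cfg)
        p2, f2, t2 = optimize(obj, cfg)
        assert np.array_equal(p1, p2) and f1 == f2 and np.array_equal(t1, t2)

    def test_sphere_convergence(self):
        """Sphere on D = 5 driven below 1e-2 within the default budget."""
        for seed in range(3):
            cfg = GoaConfig(
                population_size=25, max_iterations=80,
                lower_bounds=[-10] * 5, upper_bounds=[10] * 5, seed=seed,
            )
            _, best, _ = optimize(lambda x: float((x ** 2).sum()), cfg)
            assert best < 1e-2

    def test_non_finite_objective_aborts(self):
        cfg = GoaConfig(
            population_size=4, max_iterations=5,
            lower_bounds=[0], upper_bounds=[1], seed=0,
        )
        with pytest.raises(FloatingPointError, match="non-finite"):
            optimize(lambda x: float("nan"), cfg)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"population_size": 0},
            {"max_iterations": 0},
            {"attraction_intensity": -1.0},
            {"attractive_length_scale": 0.0},
            {"c_max": 1e-6, "c_min": 1e-5},
            {"lower_bounds": [0, 0], "upper_bounds": [1]},
            {"lower_bounds": [2], "upper_bounds": [1]},
            {"distance_map_range": (4.0, 1.0)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GoaConfig(**kwargs)
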