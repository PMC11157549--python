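"""Sinh-cosh optimizer: closed-form pieces, move algebra, run invariants."""

import math

import numpy as np
import pytest

from gaitopt.optimizer import (
    Agent,
    ConfigurationError,
    SchoParams,
    SearchSpace,
    exploitation_move_1,
    exploitation_move_2,
    exploration_move_1,
    exploration_move_2,
    init_population,
    phase_boundary,
    quasi_reflect,
    random_search,
    run,
    weight_w1,
    weight_w2,
    weight_w3,
)


def box(lb, ub, kinds=()):
    return SearchSpace(np.atleast_1d(np.asarray(lb, float)), np.atleast_1d(np.asarray(ub, float)), kinds)


SPHERE = lambda x: float(np.sum(np.square(x)))


class TestSearchSpace:
    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            box([0.0], [0.0])

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            box([1.0, 0.0], [0.0, 1.0])

    def test_integer_decode_rounds_within_bounds(self):
        space = box([1.0, 0.0], [10.0, 1.0], ("integer", "continuous"))
        decoded = space.decode(np.array([6.7, 0.33]))
        assert decoded[0] == 7.0 and decoded[1] == 0.33


class TestPhaseBoundary:
    @pytest.mark.parametrize("T,ct,expected", [(15, 3.6, 4), (36, 3.6, 10), (0, 3.6, 0), (7, 2.0, 3)])
    def test_floor_arithmetic(self, T, ct, expected):
        assert phase_boundary(T, ct) == expected

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ConfigurationError):
            phase_boundary(10, 0.0)


class TestWeights:
    def test_w1_zero_cases(self):
        assert weight_w1(0.0, 0.7, 2.0, 0.5) == 0.0
        assert weight_w1(0.9, 0.0, 2.0, 0.5) == pytest.approx(0.0)

    def test_w1_closed_form_at_one(self):
        # cosh 1 + sinh 1 = e, so w1 = e - 1
        assert weight_w1(1.0, 1.0, 1.0, 1.0) == pytest.approx(math.e - 1.0, abs=1e-12)

    def test_w2_is_product(self):
        assert weight_w2(0.0, 2.0) == 0.0
        assert weight_w2(0.5, 2.0) == 1.0
        assert weight_w2(1.0, 1.5) == 1.5

    def test_w3_closed_form(self):
        assert weight_w3(0.0, 0.3, 2.0, 0.5) == 0.0
        assert weight_w3(1.0, 0.0, 1.0, 0.5) == pytest.approx(1.0)  # cosh 0 = 1
        assert weight_w3(1.0, 1.0, 1.0, 1.0) == pytest.approx(math.e, abs=1e-12)


class TestMoves:
    space = box([0.0], [10.0])

    def test_exploration_1_branches_and_clip(self):
        a, best = np.array([3.0]), np.array([2.0])
        assert exploration_move_1(a, best, 0.0, 0.9, 1.0, self.space)[0] == 2.0
        assert exploration_move_1(a, best, 1.0, 0.9, 1.0, self.space)[0] == 5.0
        # negative branch lands at -1 and clips to the lower bound 0
        assert exploration_move_1(a, best, 1.0, 0.1, 1.0, self.space)[0] == 0.0

    def test_exploration_2_substitution(self):
        a, best = np.array([3.0]), np.array([5.0])
        up = exploration_move_2(a, best, 0.9, 1.0, 0.003, self.space)
        dn = exploration_move_2(a, best, 0.1, 1.0, 0.003, self.space)
        assert up[0] == pytest.approx(5.0 + abs(0.015 - 3.0))  # 7.985
        assert dn[0] == pytest.approx(5.0 - abs(0.015 - 3.0))  # 2.015

    def test_exploitation_1_branches(self):
        a, best = np.array([1.0]), np.array([1.0])
        assert exploitation_move_1(a, best, 0.0, 1.0, 2.0, self.space)[0] == 1.0
        assert exploitation_move_1(a, best, 1.0, 1.0, 2.0, self.space)[0] == 3.0
        assert exploitation_move_1(a, best, 1.0, 0.0, 2.0, self.space)[0] == 0.0  # clipped

    def test_exploitation_2_tanh_contraction(self):
        a, best = np.array([1.0]), np.array([3.0])
        assert exploitation_move_2(a, best, 0.0, 0.7, 1.0, self.space)[0] == 1.0
        assert exploitation_move_2(a, best, 1.0, 0.0, 1.0, self.space)[0] == 1.0
        got = exploitation_move_2(a, best, 1.0, 0.5, 1.0, self.space)[0]
        assert got == pytest.approx(1.0 + math.tanh(0.5) * 2.0, abs=1e-9)


class TestQuasiReflect:
    def test_midpoint_is_fixed_point(self, rng):
        space = box([0.0, -2.0], [10.0, 2.0])
        mid = (space.lower + space.upper) / 2
        assert np.allclose(quasi_reflect(mid, space, rng), mid)

    def test_out_of_bounds_rejected(self, rng):
        space = box([0.0], [10.0])
        with pytest.raises(ValueError):
            quasi_reflect(np.array([11.0]), space, rng)

    @pytest.mark.parametrize("x,lo,hi", [(10.0, 5.0, 10.0), (2.0, 2.0, 5.0), (8.0, 5.0, 8.0)])
    def test_interval_containment_monte_carlo(self, x, lo, hi, rng):
        space = box([0.0], [10.0])
        draws = np.array([quasi_reflect(np.array([x]), space, rng)[0] for _ in range(10_000)])
        assert draws.min() >= lo and draws.max() <= hi
        # the draw actually spans the interval, not a point mass
        assert np.ptp(draws) > 0.9 * (hi - lo)


class TestInitPopulation:
    def test_bound_containment(self):
        space = box([0.0, 0.0], [1.0, 1.0])
        agents = init_population(space, 5, np.random.default_rng(0))
        assert len(agents) == 5
        assert all(space.contains(a.position) for a in agents)

    def test_qrl_draws_concentrate_toward_midpoint(self):
        space = box([0.0], [10.0])
        rng = np.random.default_rng(1)
        plain = np.array([a.position[0] for a in init_population(space, 2000, np.random.default_rng(1))])
        qrl = np.array([a.position[0] for a in init_population(space, 2000, rng, use_qrl=True)])
        assert np.all(qrl >= 0) and np.all(qrl <= 10)
        assert np.abs(qrl - 5.0).mean() < np.abs(plain - 5.0).mean()

    def test_population_too_small(self):
        with pytest.raises(ConfigurationError):
            init_population(box([0.0], [1.0]), 1, np.random.default_rng(0))


class TestRun:
    space = box([-5.0, -5.0], [5.0, 5.0])

    def test_history_nonincreasing_and_best_consistent(self):
        res = run(SPHERE, self.space, SchoParams(n_agents=10, max_iter=15, seed=4), "mscho")
        assert np.all(np.diff(res.history) <= 0)
        assert res.best.fitness == res.history[-1]
        assert self.space.contains(res.best.position)

    def test_bit_identical_under_same_seed(self):
        a = run(SPHERE, self.space, SchoParams(n_agents=8, max_iter=10, seed=9), "mscho")
        b = run(SPHERE, self.space, SchoParams(n_agents=8, max_iter=10, seed=9), "mscho")
        assert np.array_equal(a.history, b.history)
        assert np.array_equal(a.best.position, b.best.position)
        assert a.evaluations == b.evaluations

    def test_mscho_reduces_to_scho_when_modifications_disabled(self):
        reduced = SchoParams(n_agents=10, max_iter=12, seed=5, use_qrl=False, trial_limit=None)
        a = run(SPHERE, self.space, reduced, "mscho")
        b = run(SPHERE, self.space, SchoParams(n_agents=10, max_iter=12, seed=5), "scho")
        assert np.array_equal(a.history, b.history)
        assert np.array_equal(a.best.position, b.best.position)

    def test_constant_objective_triggers_qrl_replacement(self):
        params = SchoParams(n_agents=6, max_iter=6, seed=2, trial_limit=2)
        res = run(lambda x: 1.0, self.space, params, "mscho")
        assert np.all(res.history == 1.0)
        # evaluations: init + per-iteration moves + a base/reflected pair
        # per agent every second iteration (trials hit the limit of 2)
        base = 6 + 6 * 6
        replacements = 2 * 6 * 3  # iterations 2, 4, 6
        assert res.evaluations == base + replacements

    def test_nonfinite_objective_aborts_with_position(self):
        with pytest.raises(RuntimeError, match="non-finite"):
            run(lambda x: float("nan"), self.space, SchoParams(n_agents=4, max_iter=3, seed=0))

    def test_target_fitness_stops_early_but_keeps_history_length(self):
        res = run(SPHERE, self.space, SchoParams(n_agents=10, max_iter=15, seed=3), "mscho", target_fitness=1.0)
        assert res.history.size == 15
        assert res.best.fitness <= 1.0
        assert res.evaluations < 10 + 15 * 10

    def test_random_search_monotone_history(self):
        res = random_search(SPHERE, self.space, 100, seed=0)
        assert res.evaluations == 100
        assert np.all(np.diff(res.history) <= 0)


def test_bounds_respected_throughout_a_run():
    """Every evaluated position stays inside the box."""
    seen = []
    space = box([-1.0, 2.0, -3.0], [1.0, 4.0, 0.0])

    def objective(x):
        seen.append(x.copy())
        return float(np.sum(x))

    run(objective, space, SchoParams(n_agents=6, max_iter=10, seed=7), "mscho")
    assert seen and all(space.contains(x) for x in seen)
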