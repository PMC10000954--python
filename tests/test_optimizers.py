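"""Unit and property tests for the AOA/HGS numeric primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aoahg.optimizers import (
    ContinuousSolution,
    HungerState,
    OptimizerParams,
    SearchBounds,
    aoa_exploit_rule,
    aoa_explore_rule,
    aoahg_hgs_rule,
    energy_E,
    hgs_position_update,
    hunger_weights,
    init_population,
    make_rng,
    moa,
    mop,
    sech,
    update_bounds,
    update_hunger,
    variation_R,
    weight_w1,
    weight_w2,
)

PARAMS = OptimizerParams()


class TestSchedules:
    @pytest.mark.parametrize(
        "t, T, expected",
        [(20, 20, 1.0), (0, 20, 0.2), (10, 20, 0.6)],
    )
    def test_moa_endpoints_and_midpoint(self, t, T, expected):
        assert moa(t, T, PARAMS) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "t, T, alpha, expected",
        [(20, 20, 5.0, 0.0), (0, 20, 5.0, 1.0), (1, 32, 5.0, 0.5)],
    )
    def test_mop_endpoints_and_power_of_two(self, t, T, alpha, expected):
        # 32 = 2^5 makes t=1 land exactly on 1 - 1/2
        assert mop(t, T, alpha) == pytest.approx(expected, abs=1e-15)

    def test_moa_nondecreasing_mop_nonincreasing(self):
        T = 37
        moas = [moa(t, T, PARAMS) for t in range(T + 1)]
        mops = [mop(t, T, PARAMS.alpha) for t in range(T + 1)]
        assert all(a <= b for a, b in zip(moas, moas[1:]))
        assert all(a >= b for a, b in zip(mops, mops[1:]))
        assert all(PARAMS.min_acc <= v <= PARAMS.max_acc for v in moas)
        assert all(0.0 <= v <= 1.0 for v in mops)

    def test_zero_iteration_budget_rejected(self):
        with pytest.raises(ValueError):
            moa(0, 0, PARAMS)
        with pytest.raises(ValueError):
            mop(0, 0, PARAMS.alpha)
        with pytest.raises(ValueError):
            variation_R(0, 0, 0.5)


class TestArithmeticRules:
    def test_explore_divide_branch(self):
        # 0.5 / 0.5 * (1*0.5 + 0) = 0.5
        assert aoa_explore_rule(0.5, 0.5, 0.0, 1.0, PARAMS, 0.9) == pytest.approx(0.5)

    def test_explore_multiply_branch(self):
        assert aoa_explore_rule(0.5, 0.5, 0.0, 1.0, PARAMS, 0.1) == pytest.approx(0.125)

    def test_explore_vanishing_mop_clips_to_one(self):
        assert aoa_explore_rule(0.5, 0.0, 0.0, 1.0, PARAMS, 0.9) == 1.0

    def test_exploit_subtract_branch(self):
        assert aoa_exploit_rule(0.5, 0.5, 0.0, 1.0, PARAMS, 0.9) == pytest.approx(0.25)

    def test_exploit_add_branch(self):
        assert aoa_exploit_rule(0.5, 0.5, 0.0, 1.0, PARAMS, 0.1) == pytest.approx(0.75)

    def test_exploit_zero_step(self):
        for r3 in (0.1, 0.9):
            assert aoa_exploit_rule(0.5, 0.0, 0.0, 1.0, PARAMS, r3) == pytest.approx(0.5)

    @given(
        best=st.floats(0, 1),
        mop_val=st.floats(0, 1),
        r=st.floats(0, 1),
        lo=st.floats(0, 1),
        hi=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_rules_stay_in_unit_box(self, best, mop_val, r, lo, hi):
        lo, hi = min(lo, hi), max(lo, hi)
        for rule in (aoa_explore_rule, aoa_exploit_rule):
            out = rule(best, mop_val, lo, hi, PARAMS, r)
            assert 0.0 <= out <= 1.0


class TestHyperbolicAndEnergy:
    def test_sech_of_zero_is_one(self):
        assert sech(0.0) == 1.0

    def test_sech_at_one(self):
        # 2 / (e + 1/e)
        assert sech(1.0) == pytest.approx(0.6480542736638855, abs=1e-12)

    @given(x=st.floats(-50, 50))
    @settings(max_examples=100, deadline=None)
    def test_sech_even_and_bounded(self, x):
        assert sech(x) == pytest.approx(sech(-x), rel=1e-12)
        assert 0.0 < sech(x) <= 1.0

    def test_energy_one_only_at_equal_fitness(self):
        assert energy_E(0.3, 0.3) == 1.0
        assert energy_E(1.3, 0.3) == pytest.approx(0.6480542736638855, abs=1e-12)
        gaps = [0.1, 0.5, 1.0, 3.0]
        vals = [energy_E(0.3 + g, 0.3) for g in gaps]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestVariationR:
    def test_zero_at_final_iteration(self):
        for rand in (0.0, 0.3, 1.0):
            assert variation_R(10, 10, rand) == 0.0

    def test_zero_at_midpoint_draw(self):
        for t in (0, 3, 7):
            assert variation_R(t, 10, 0.5) == pytest.approx(0.0)

    def test_maximal_spread_at_start(self):
        assert variation_R(0, 10, 1.0) == pytest.approx(2.0)

    @given(t=st.integers(0, 50), rand=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_bounded_by_shrink_factor(self, t, rand):
        T = 50
        s = 2.0 * (1.0 - t / T)
        assert abs(variation_R(t, T, rand)) <= s + 1e-12


class TestHunger:
    def test_best_solution_hunger_reset(self):
        fits = np.array([0.1, 0.5, 0.9])
        h = HungerState(np.array([7.0, 3.0, 2.0]))
        out = update_hunger(fits, 0.1, 0.9, h, SearchBounds.unit(4), PARAMS, make_rng(0))
        assert out.H[0] == 0.0
        assert out.H[1] > 3.0 and out.H[2] > 2.0
        assert out.SH == pytest.approx(out.H.sum())

    def test_th_above_floor_taken_verbatim(self):
        # worst solution, r6 = 1, bound span 100, LH = 100 -> TH = 200
        fits = np.array([0.0, 1.0])
        b = SearchBounds(np.zeros(3), np.full(3, 100.0))

        class FixedRng:
            def __init__(self):
                self.calls = 0

            def random(self, n=None):
                self.calls += 1
                return np.ones(n) if self.calls == 1 else np.zeros(n)  # r6=1, r=0

        out = update_hunger(fits, 0.0, 1.0, HungerState.zeros(2), b, PARAMS, FixedRng())
        assert out.H[1] == pytest.approx(200.0)

    def test_th_below_floor_uses_lh_branch(self):
        fits = np.array([0.0, 1.0])

        class FixedRng:
            def __init__(self):
                self.calls = 0

            def random(self, n=None):
                self.calls += 1
                return np.zeros(n) if self.calls == 1 else np.full(n, 0.25)  # r6=0, r=0.25

        out = update_hunger(
            fits, 0.0, 1.0, HungerState.zeros(2), SearchBounds.unit(3), PARAMS, FixedRng()
        )
        assert out.H[1] == pytest.approx(PARAMS.lh * 1.25)

    def test_degenerate_equal_fitness_population(self):
        fits = np.full(3, 0.4)
        out = update_hunger(
            fits, 0.4, 0.4, HungerState.zeros(3), SearchBounds.unit(2), PARAMS, make_rng(1)
        )
        assert np.all(out.H == 0.0)  # everyone matches the best


class TestHungerWeights:
    def test_w1_not_hungry_branch(self):
        assert weight_w1(5.0, 10.0, 4, PARAMS, r3=0.9, r4=0.5) == 1.0

    def test_w1_zero_hunger(self):
        assert weight_w1(0.0, 10.0, 4, PARAMS, r3=0.01, r4=0.5) == 0.0

    def test_w1_single_hungry_solution(self):
        # H_i = SH, N = 50, r4 = 0.02 -> 50 * 0.02 = 1
        assert weight_w1(1.0, 1.0, 50, PARAMS, r3=0.01, r4=0.02) == pytest.approx(1.0)

    def test_w1_all_zero_hunger_guard(self):
        assert weight_w1(0.0, 0.0, 4, PARAMS, r3=0.01, r4=0.7) == 0.0

    def test_w2_zero_at_equal_hunger(self):
        assert weight_w2(3.0, 3.0, r5=0.8) == 0.0

    def test_w2_half_saturation_at_log_two(self):
        assert weight_w2(np.log(2.0), 0.0, r5=1.0) == pytest.approx(1.0)

    @given(h=st.floats(0, 1e6), sh=st.floats(0, 1e6), r5=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_w2_range(self, h, sh, r5):
        # open upper bound 2 is attained only through float rounding of 1-e^-x
        assert 0.0 <= weight_w2(h, sh, r5) <= 2.0

    def test_weights_attach_to_state(self):
        h = hunger_weights(HungerState(np.array([0.0, 100.0, 200.0])), PARAMS, make_rng(3))
        assert h.W1.shape == (3,) and h.W2.shape == (3,)
        assert np.all((h.W2 >= 0) & (h.W2 < 2))


class TestPositionUpdates:
    def test_hgs_collapse_to_best_with_zero_perturbation(self):
        # W1=1, R=0 and r1 > l: both signs send the solution onto the best
        x = ContinuousSolution(np.array([0.1, 0.9, 0.4]))
        best = ContinuousSolution(np.array([0.6, 0.2, 0.8]))

        class FixedRng:
            def __init__(self, draws):
                self.draws = list(draws)

            def random(self, n=None):
                return self.draws.pop(0)

        out = hgs_position_update(x, best, 1.0, 0.0, 0.0, 0.5, PARAMS, FixedRng([0.9, 0.9]))
        assert np.allclose(out.position, best.position)

    def test_hgs_self_branch_with_zero_rand(self):
        x = ContinuousSolution(np.array([0.3, 0.7]))

        class FixedRng:
            def __init__(self, draws):
                self.draws = list(draws)

            def random(self, n=None):
                return self.draws.pop(0)

        out = hgs_position_update(
            x, x, 1.0, 1.0, 1.0, 0.5, PARAMS, FixedRng([0.0, 0.0])  # r1 < l, rand = 0
        )
        assert np.allclose(out.position, x.position)

    def test_hgs_attraction_clipped(self):
        x = ContinuousSolution(np.array([0.4]))
        best = ContinuousSolution(np.array([0.8]))

        class FixedRng:
            def __init__(self, draws):
                self.draws = list(draws)

            def random(self, n=None):
                return self.draws.pop(0)

        # r1 > l, r2 > E: 1*0.8 + 1*1*(0.8-0.4) = 1.2 -> 1.0
        out = hgs_position_update(x, best, 1.0, 1.0, 1.0, 0.5, PARAMS, FixedRng([0.9, 0.9]))
        assert out.position[0] == 1.0

    def test_hybrid_rule_zero_step(self):
        for ph in (0.1, 0.9):
            assert aoahg_hgs_rule(0.37, 0.8, 1.0, 1.0, 0.0, ph) == pytest.approx(0.37)

    def test_hybrid_rule_branch_arithmetic(self):
        assert aoahg_hgs_rule(0.4, 0.8, 1.0, 1.0, 1.0, 0.9) == pytest.approx(0.0)
        assert aoahg_hgs_rule(0.4, 0.8, 1.0, 1.0, 1.0, 0.1) == pytest.approx(0.8)

    @given(
        x=st.floats(0, 1),
        best=st.floats(0, 1),
        w1=st.floats(0, 2),
        w2=st.floats(0, 2),
        r=st.floats(-2, 2),
        ph=st.floats(0, 1),
    )
    @settings(max_examples=200, deadline=None)
    def test_hybrid_rule_stays_in_unit_box(self, x, best, w1, w2, r, ph):
        assert 0.0 <= aoahg_hgs_rule(x, best, w1, w2, r, ph) <= 1.0


class TestPopulation:
    def test_init_within_bounds(self):
        pop = init_population(3, 2, SearchBounds.unit(2), make_rng(0))
        P = pop.positions()
        assert P.shape == (3, 2)
        assert np.all((P >= 0) & (P <= 1))

    def test_init_degenerate_interval(self):
        b = SearchBounds(np.full(4, 0.5), np.full(4, 0.5))
        pop = init_population(3, 4, b, make_rng(0))
        assert np.all(pop.positions() == 0.5)

    def test_init_seed_reproducibility(self):
        a = init_population(5, 6, SearchBounds.unit(6), make_rng(11)).positions()
        b = init_population(5, 6, SearchBounds.unit(6), make_rng(11)).positions()
        assert np.array_equal(a, b)

    def test_init_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            init_population(1, 3, SearchBounds.unit(3), make_rng(0))
        with pytest.raises(ValueError):
            init_population(3, 0, SearchBounds.unit(0), make_rng(0))

    def test_update_bounds_min_max(self):
        P = np.array([[0.2, 0.5], [0.7, 0.1], [0.4, 0.9]])
        b = update_bounds(P)
        assert np.allclose(b.lower, [0.2, 0.1])
        assert np.allclose(b.upper, [0.7, 0.9])
        assert np.all((P >= b.lower) & (P <= b.upper))

    def test_update_bounds_single_solution(self):
        b = update_bounds(np.array([[0.3, 0.6]]))
        assert np.allclose(b.lower, b.upper)

    def test_update_bounds_empty_rejected(self):
        with pytest.raises(ValueError):
            update_bounds(np.empty((0, 3)))


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"min_acc": 0.9, "max_acc": 0.5},
            {"alpha": 0.0},
            {"mu": 1.5},
            {"epsilon": 0.0},
            {"lam": 0.0},
            {"l_hgs": 1.0},
            {"lh": -1.0},
            {"pop_size": 1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            OptimizerParams(**kwargs)

    def test_bounds_ordering_enforced(self):
        with pytest.raises(ValueError):
            SearchBounds(np.array([0.5]), np.array([0.2]))
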