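"""The hybrid ant-grey-wolf selector: ACO algebra, wolf moves, full runs."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hagwo import (AcoParams, HagwoConfig, PheromoneState, PlantedOracle,
                   TableSpec, WolfState, adaptive_A, construct_subset,
                   hybrid_score, make_feature_table, optimize, planted_fitness,
                   run, select_elite, selection_probabilities, update_pheromone,
                   wolf_step)
from hagwo.optimize import TAU_MIN


class TestSelectionProbabilities:
    def test_symmetric_inputs_give_uniform(self):
        state = PheromoneState(tau=np.ones(2), eta=np.ones(2))
        p = selection_probabilities(state, AcoParams())
        np.testing.assert_allclose(p, [0.5, 0.5])

    def test_heuristic_squared_weighting(self):
        # tau=(1,1), eta=(2,1), alpha=1, beta=2 -> weights (4,1) -> (0.8, 0.2)
        state = PheromoneState(tau=np.ones(2), eta=np.array([2.0, 1.0]))
        p = selection_probabilities(state, AcoParams(alpha=1.0, beta=2.0))
        np.testing.assert_allclose(p, [0.8, 0.2])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=30),
           st.lists(st.floats(0.0, 10), min_size=2, max_size=30))
    def test_normalization_property(self, tau, eta):
        n = min(len(tau), len(eta))
        state = PheromoneState(tau=np.array(tau[:n]), eta=np.array(eta[:n]))
        p = selection_probabilities(state, AcoParams())
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p >= 0)

    def test_zero_heuristics_fall_back_to_uniform(self):
        state = PheromoneState(tau=np.ones(3), eta=np.zeros(3))
        with pytest.warns(UserWarning, match="uniform"):
            p = selection_probabilities(state, AcoParams())
        np.testing.assert_allclose(p, [1 / 3] * 3)


class TestConstructSubset:
    def test_single_feature_forced(self):
        rng = np.random.default_rng(0)
        mask = construct_subset(np.array([1.0]), rng)
        assert mask.tolist() == [True]

    def test_high_probability_feature_dominates(self):
        rng = np.random.default_rng(1)
        p = np.array([0.999] + [0.001 / 9] * 9)
        counts = np.zeros(10)
        for _ in range(10_000):
            counts += construct_subset(p, rng)
        assert counts[0] == counts.max()

    def test_subsets_are_nonempty_and_within_range(self):
        rng = np.random.default_rng(2)
        p = np.full(8, 1 / 8)
        for _ in range(200):
            mask = construct_subset(p, rng)
            assert 1 <= mask.sum() <= 8


class TestUpdatePheromone:
    def test_pure_evaporation(self):
        state = PheromoneState(tau=np.array([1.0]), eta=np.array([1.0]))
        new = update_pheromone(state, [np.array([False])], [0.5],
                               AcoParams(rho=0.1))
        assert new.tau[0] == pytest.approx(0.9)

    def test_evaporation_plus_deposit(self):
        state = PheromoneState(tau=np.array([1.0]), eta=np.array([1.0]))
        new = update_pheromone(state, [np.array([True])], [0.5],
                               AcoParams(rho=0.1, q=1.0))
        assert new.tau[0] == pytest.approx(1.4)

    def test_floor_clamp_under_full_evaporation(self):
        state = PheromoneState(tau=np.array([1.0]), eta=np.array([1.0]))
        new = update_pheromone(state, [np.array([False])], [0.0],
                               AcoParams(rho=0.999999))
        assert new.tau[0] >= TAU_MIN


class TestSelectElite:
    def test_ranking(self):
        subsets = [np.array([1, 0, 0], bool), np.array([0, 1, 0], bool),
                   np.array([0, 0, 1], bool), np.array([1, 1, 1], bool)]
        fits = [0.9, 0.8, 0.7, 0.1]
        a, b, d, pool = select_elite(subsets, fits, 0.5)
        np.testing.assert_array_equal(a, subsets[0])
        np.testing.assert_array_equal(b, subsets[1])
        np.testing.assert_array_equal(d, subsets[2])

    def test_equal_fitness_breaks_by_size_then_lexicographic(self):
        subsets = [np.array([1, 1, 0], bool), np.array([0, 0, 1], bool),
                   np.array([0, 1, 0], bool)]
        fits = [0.5, 0.5, 0.5]
        a, b, d, _ = select_elite(subsets, fits, 1.0)
        np.testing.assert_array_equal(a, [0, 0, 1])  # size 1, lexicographically first
        np.testing.assert_array_equal(b, [0, 1, 0])
        np.testing.assert_array_equal(d, [1, 1, 0])

    def test_alpha_matches_full_sort_oracle(self):
        rng = np.random.default_rng(4)
        subsets = [rng.random(6) < 0.5 for _ in range(30)]
        for s in subsets:
            if not s.any():
                s[0] = True
        fits = rng.random(30).tolist()
        a, _, _, pool = select_elite(subsets, fits, 0.1)
        assert fits[int(np.argmax(fits))] == pytest.approx(
            max(f for s, f in zip(subsets, fits)
                if any(np.array_equal(s, p) for p in pool)))
        np.testing.assert_array_equal(a, subsets[int(np.argmax(fits))])

    def test_too_few_subsets_rejected(self):
        with pytest.raises(ValueError):
            select_elite([np.array([True])] * 2, [0.1, 0.2], 0.5)


class TestAdaptiveA:
    def test_final_iteration_is_zero(self):
        assert adaptive_A(100, 100, 0.3, 0.9) == 0.0

    def test_start_without_improvement_is_two(self):
        assert adaptive_A(0, 100, 0.0, 0.9) == 2.0

    def test_midpoint_with_half_ratio(self):
        assert adaptive_A(50, 100, 0.45, 0.9) == pytest.approx(1.5)

    def test_floor_guard(self):
        with pytest.warns(UserWarning, match="floor"):
            assert adaptive_A(50, 100, 0.5, 0.0) == pytest.approx(1.0)


class _HalfRng:
    """Stub generator returning 0.5 everywhere (forces c = 1)."""

    def random(self, n=None):
        return np.full(n, 0.5) if n is not None else 0.5


class TestWolfStep:
    def test_fixed_point_at_consensus(self):
        x = np.array([1, 0, 1, 0], float)
        wolves = WolfState(x_alpha=x, x_beta=x, x_delta=x, pack=[], a=0.0)
        # A=0 and a=0 force every step term a_k to 0, so the continuous
        # consensus equals the shared leader position exactly
        rng = np.random.default_rng(0)
        n = x.size
        steps = []
        for leader in (wolves.x_alpha, wolves.x_beta, wolves.x_delta):
            c = 2.0 * rng.random(n)
            D = np.abs(c * leader - x)
            a_k = 2.0 * 0.0 * rng.random(n) - wolves.a
            steps.append(leader - a_k * D)
        consensus = sum(steps) / 3.0
        np.testing.assert_allclose(consensus, x)

    def test_forced_half_random_gives_plain_distance(self):
        x = np.array([1, 0, 0], float)
        leader = np.array([0, 1, 0], float)
        rng = _HalfRng()
        c = 2.0 * rng.random(3)
        D = np.abs(c * leader - x)
        np.testing.assert_allclose(D, np.abs(leader - x))

    def test_sigmoid_of_zero_consensus_is_half(self):
        # zero consensus coordinates binarize to 1 with frequency sigmoid(0)=0.5
        n = 20
        zero = np.zeros(n, float)
        wolves = WolfState(x_alpha=zero, x_beta=zero, x_delta=zero, pack=[], a=0.0)
        rng = np.random.default_rng(5)
        ones, total = 0, 0
        for _ in range(1_000):
            ones += int(wolf_step(zero, wolves, 0.0, rng).sum())
            total += n
        assert abs(ones / total - 0.5) <= 0.02


class TestHybridScore:
    def _wolves(self, leader):
        return WolfState(x_alpha=leader, x_beta=leader, x_delta=leader, pack=[])

    def test_gamma_zero_reduces_to_fitness(self):
        leader = np.array([1, 0, 1], bool)
        score = hybrid_score(np.array([0, 1, 0], bool), 0.42,
                             self._wolves(leader), 0.7, gamma=0.0)
        assert score == pytest.approx(0.42)

    def test_full_agreement_earns_gamma_bonus(self):
        leader = np.array([1, 0, 1], bool)
        score = hybrid_score(leader, 0.5, self._wolves(leader),
                             np.zeros(3), gamma=0.1)
        assert score == pytest.approx(0.5 + 0.1)

    def test_closer_subset_wins_at_equal_fitness(self):
        leader = np.array([1, 1, 0, 0], bool)
        near = np.array([1, 1, 1, 0], bool)
        far = np.array([0, 0, 1, 1], bool)
        wolves = self._wolves(leader)
        assert (hybrid_score(near, 0.5, wolves, 0.2, 0.1)
                > hybrid_score(far, 0.5, wolves, 0.2, 0.1))


def _planted_problem(seed, n=10, k=3):
    rng = np.random.default_rng(1000 + seed)
    target = np.zeros(n, bool)
    target[rng.choice(n, k, replace=False)] = True
    oracle = PlantedOracle(n, target)
    return oracle, (lambda mask: planted_fitness(oracle, mask))


class TestRun:
    def test_single_feature_problem_is_forced(self):
        oracle = PlantedOracle(1, np.array([True]))
        res = optimize(lambda m: planted_fitness(oracle, m), 1,
                       HagwoConfig(mode="hybrid", max_iters=5, seed=0))
        assert res.best_subset.tolist() == [True]
        assert res.best_fitness == 1.0

    @pytest.mark.parametrize("mode", ["aco", "mgwo", "hybrid"])
    def test_trace_best_is_nondecreasing(self, mode):
        _, fn = _planted_problem(0)
        res = optimize(fn, 10, HagwoConfig(mode=mode, max_iters=30, seed=1))
        best = [s["best"] for s in res.trace]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))
        assert res.mode == mode

    def test_reproducible_from_seed(self):
        table, _ = make_feature_table(TableSpec(120, 10, 2, effect_size=1.5, seed=3))
        cfg = HagwoConfig(mode="hybrid", max_iters=15, seed=7)
        r1, r2 = run(table, cfg), run(table, cfg)
        np.testing.assert_array_equal(r1.best_subset, r2.best_subset)
        assert r1.best_fitness == r2.best_fitness
        assert [s["best"] for s in r1.trace] == [s["best"] for s in r2.trace]

    def test_best_fitness_reevaluates_exactly(self):
        oracle, fn = _planted_problem(2)
        res = optimize(fn, 10, HagwoConfig(mode="hybrid", max_iters=30, seed=2))
        assert res.best_fitness == pytest.approx(fn(res.best_subset))

    def test_hybrid_attains_exhaustive_optimum_at_full_budget(self):
        """On a small planted problem the hybrid matches brute force over
        all 2^10 subsets in most seeded runs."""
        hits = 0
        for seed in range(1, 11):
            oracle, fn = _planted_problem(seed)
            brute_best = max(
                planted_fitness(oracle, np.array(bits, bool))
                for bits in itertools.product([0, 1], repeat=10)
                if any(bits))
            cfg = HagwoConfig(mode="hybrid", max_iters=100, seed=seed,
                              stall_patience=100)
            res = optimize(fn, 10, cfg)
            hits += res.best_fitness == pytest.approx(brute_best)
        assert hits >= 9

    def test_single_class_table_rejected(self):
        table, _ = make_feature_table(TableSpec(50, 5, 1, seed=0,
                                                class_balance=0.0))
        with pytest.raises(ValueError, match="single class"):
            run(table, HagwoConfig(max_iters=2))
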