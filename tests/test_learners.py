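"""Base learners: search behavior, independence testing, skeleton discovery,
and agreement with the exhaustive oracle."""

import math

import numpy as np
import pytest

from penbayes import (
    CategoricalDataset,
    DirectedGraph,
    SearchConfig,
    bdeu_log_score,
    cancer_fixture,
    exhaustive_search,
    forward_sample,
    g2_test,
    hill_climb,
    is_acyclic,
    markov_equivalent,
    mmhc,
    mmpc,
    or_gate_cpts,
    random_cpts,
    random_dag,
    shd,
    skeleton_and_vstructures,
    tabu_search,
)
from penbayes.learners import enumerate_dags


def independent_coins(p: int, n: int, seed: int) -> CategoricalDataset:
    rng = np.random.default_rng(seed)
    return CategoricalDataset(
        tuple(f"x{i}" for i in range(p)), (2,) * p, rng.integers(0, 2, size=(n, p))
    )


def strong_problem(seed: int, p: int = 3, n: int = 1000):
    """A benchmark-style trial: 1-3 edges, strong (Dirichlet 0.25) CPTs."""
    rng = np.random.default_rng(seed)
    truth = random_dag(p, int(rng.integers(1, 4)), seed)
    bn = random_cpts(truth, [2] * p, concentration=0.25, seed=seed + 100)
    return truth, forward_sample(bn, n, seed + 200)


def identifiable_problem(seed: int, p: int = 3, n: int = 1000):
    """A trial whose structure is recoverable in principle: 1-3 edges and
    OR-gate CPTs at strength 0.9, so no variable is near-constant and every
    dependence is detectable."""
    rng = np.random.default_rng(seed)
    truth = random_dag(p, int(rng.integers(1, 4)), seed)
    bn = or_gate_cpts(truth, strength=0.9)
    return truth, forward_sample(bn, n, seed + 200)


class TestHillClimb:
    def test_independent_variables_yield_empty_graph(self):
        d = independent_coins(2, 10_000, seed=1)
        assert hill_climb(d).m == 0

    def test_recovers_identifiable_collider(self):
        truth = DirectedGraph.from_edges(3, [(0, 2), (1, 2)])
        d = forward_sample(or_gate_cpts(truth, 0.9), 10_000, seed=6)
        learned = hill_climb(d)
        skel, vs = skeleton_and_vstructures(learned)
        assert skel == {frozenset((0, 2)), frozenset((1, 2))}
        assert vs == {(0, 2, 1)}

    def test_matches_exhaustive_optimum_on_most_seeds(self):
        hits = 0
        for seed in range(20):
            _, d = strong_problem(seed, n=500)
            best = bdeu_log_score(exhaustive_search(d), d)
            hits += abs(bdeu_log_score(hill_climb(d), d) - best) < 1e-6
        assert hits >= 19

    def test_score_trace_strictly_increases(self, cancer_data_20k):
        trace: list[float] = []
        hill_climb(cancer_data_20k, score_trace=trace)
        assert len(trace) >= 2
        assert all(b > a for a, b in zip(trace, trace[1:]))

    def test_output_is_acyclic_on_random_inputs(self):
        for seed in range(5):
            _, d = strong_problem(seed, p=4, n=400)
            assert is_acyclic(hill_climb(d))


class TestTabuSearch:
    def test_matches_hill_climb_when_no_escape_needed(self, cancer_data_20k):
        hc = hill_climb(cancer_data_20k)
        tb = tabu_search(cancer_data_20k)
        assert bdeu_log_score(tb, cancer_data_20k) == pytest.approx(
            bdeu_log_score(hc, cancer_data_20k)
        )

    @pytest.mark.parametrize("seed", range(50))
    def test_never_scores_below_hill_climb(self, seed):
        _, d = strong_problem(seed, n=300)
        s_hc = bdeu_log_score(hill_climb(d), d)
        s_tb = bdeu_log_score(tabu_search(d), d)
        assert s_tb >= s_hc - 1e-9

    def test_degenerate_config_equals_one_hill_climb_step(self):
        _, d = strong_problem(3, n=500)
        cfg = SearchConfig(tabu_length=1, max_iterations=1)
        assert tabu_search(d, cfg) == hill_climb(d, cfg)


class TestG2Test:
    def test_perfect_dependence(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, size=1000)
        d = CategoricalDataset(("x", "y"), (2, 2), np.column_stack([x, x]))
        stat, p = g2_test(d, 0, 1)
        assert p < 1e-10

    def test_hand_built_table(self):
        # counts (30, 10, 10, 30): all margins 40, expected 20 everywhere
        rows = (
            [[0, 0]] * 30 + [[0, 1]] * 10 + [[1, 0]] * 10 + [[1, 1]] * 30
        )
        d = CategoricalDataset(("x", "y"), (2, 2), np.array(rows))
        stat, _ = g2_test(d, 0, 1)
        expected = 2 * (60 * math.log(30 / 20) + 20 * math.log(10 / 20))
        assert stat == pytest.approx(expected, abs=1e-9)

    def test_type_one_error_rate_near_alpha(self):
        # x, y independent fair coins: p-values uniform, rejections ~ alpha
        rng = np.random.default_rng(2024)
        rejections = 0
        trials = 1000
        for _ in range(trials):
            arr = rng.integers(0, 2, size=(10_000, 2))
            d = CategoricalDataset(("x", "y"), (2, 2), arr)
            _, p = g2_test(d, 0, 1)
            rejections += p < 0.05
        assert 0.03 <= rejections / trials <= 0.07

    def test_zero_margin_strata_reduce_dof(self):
        # conditioning stratum z=1 never occurs for x=1: dof shrinks, p stays valid
        rows = [[0, 0, 0]] * 20 + [[0, 1, 0]] * 20 + [[1, 0, 1]] * 20
        d = CategoricalDataset(("x", "y", "z"), (2, 2, 2), np.array(rows))
        stat, p = g2_test(d, 0, 1, (2,))
        assert stat >= 0 and 0 <= p <= 1

    def test_empty_dataset_rejected(self):
        d = CategoricalDataset(("x", "y"), (2, 2), np.empty((0, 2), dtype=int))
        with pytest.raises(ValueError):
            g2_test(d, 0, 1)


class TestMMPC:
    def test_independent_variables_give_no_edges(self):
        d = independent_coins(4, 5000, seed=9)
        assert len(mmpc(d)) <= 1  # at most a false positive at alpha=0.05

    def test_chain_excludes_shielded_pair(self):
        truth = DirectedGraph.from_edges(3, [(0, 1), (1, 2)])
        bn = random_cpts(truth, [2, 2, 2], concentration=0.25, seed=21)
        d = forward_sample(bn, 10_000, seed=22)
        skel = mmpc(d)
        assert skel == {frozenset((0, 1)), frozenset((1, 2))}

    def test_recovers_cancer_skeleton(self, cancer_truth):
        strong = cancer_fixture(cpt_strength=0.99)
        d = forward_sample(strong.network, 20_000, seed=33)
        skel = mmpc(d)
        expected, _ = skeleton_and_vstructures(strong.network.graph)
        assert skel == expected


class TestMMHC:
    def test_empty_skeleton_forces_empty_graph(self, cancer_data_20k):
        empty_whitelist = np.zeros((5, 5), dtype=bool)
        g = hill_climb(cancer_data_20k, whitelist=empty_whitelist)
        assert g.m == 0

    def test_skeleton_constrains_output(self, cancer_data_20k, cancer_truth):
        learned = mmhc(cancer_data_20k)
        skel_learned, _ = skeleton_and_vstructures(learned)
        skel_mmpc = mmpc(cancer_data_20k)
        assert skel_learned <= skel_mmpc

    def test_cancer_recovery(self, cancer_data_20k, cancer_truth):
        learned = mmhc(cancer_data_20k)
        truth = cancer_truth.network.graph
        assert shd(learned, truth) <= 2
        skel, _ = skeleton_and_vstructures(learned)
        assert skel == skeleton_and_vstructures(truth)[0]

    def test_deterministic_across_runs(self, cancer_data_20k):
        assert mmhc(cancer_data_20k) == mmhc(cancer_data_20k)


class TestExhaustiveSearch:
    def test_single_node(self):
        d = CategoricalDataset(("x",), (2,), np.array([[0], [1], [0]]))
        assert exhaustive_search(d) == DirectedGraph.empty(1)

    def test_three_node_dag_count(self):
        assert sum(1 for _ in enumerate_dags(3)) == 25

    def test_four_node_dag_count(self):
        assert sum(1 for _ in enumerate_dags(4)) == 543

    def test_refuses_large_problems(self):
        d = independent_coins(6, 10, seed=0)
        with pytest.raises(ValueError):
            exhaustive_search(d)

    def test_collider_cross_check(self):
        truth = DirectedGraph.from_edges(3, [(0, 2), (1, 2)])
        d = forward_sample(or_gate_cpts(truth, 0.9), 10_000, seed=6)
        assert markov_equivalent(exhaustive_search(d), hill_climb(d))


class TestOracleAgreementAcrossLearners:
    def test_learners_recover_equivalent_structures(self):
        agree = 0
        for seed in range(40):
            _, d = identifiable_problem(seed, n=1000)
            ex = exhaustive_search(d)
            if all(
                markov_equivalent(learner(d), ex)
                for learner in (hill_climb, tabu_search, mmhc)
            ):
                agree += 1
        assert agree >= 0.95 * 40 - 1e-9  # allow exactly the 5% miss budget
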