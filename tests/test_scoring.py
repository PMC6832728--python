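"""BDeu scoring against a literal arbitrary-precision oracle, plus Edge
Strength and weight behavior."""

import itertools
import math

import mpmath
import numpy as np
import pytest

from penbayes import (
    CategoricalDataset,
    DirectedGraph,
    bdeu_log_score,
    edge_strength,
    forward_sample,
    random_cpts,
    random_dag,
    structure_weights,
    weighted_adjacency,
)
from penbayes.learners import enumerate_dags

from test_graphs import dag_from_masks


def bdeu_oracle(g: DirectedGraph, d: CategoricalDataset, ess: float) -> float:
    """Literal transcription of the BDeu marginal likelihood.

    Product over nodes i and parent configurations j of
    Gamma(N'_ij) / Gamma(N'_ij + N_ij) * prod_k Gamma(N'_ijk + N_ijk) / Gamma(N'_ijk)
    with N'_ijk = ess / (r_i * q_i), evaluated in 60-digit arithmetic and
    independent of the package's vectorised counting path.
    """
    with mpmath.workdps(60):
        log_total = mpmath.mpf(0)
        for i in range(d.p):
            parents = g.parents(i)
            r_i = d.arities[i]
            q_i = 1
            for j in parents:
                q_i *= d.arities[j]
            a_ijk = mpmath.mpf(ess) / (r_i * q_i)
            a_ij = mpmath.mpf(ess) / q_i
            parent_space = list(
                itertools.product(*[range(d.arities[j]) for j in parents])
            ) or [()]
            for config in parent_space:
                rows = np.ones(d.n, dtype=bool)
                for j, v in zip(parents, config):
                    rows &= d.records[:, j] == v
                n_ij = int(rows.sum())
                log_total += mpmath.loggamma(a_ij) - mpmath.loggamma(a_ij + n_ij)
                for k in range(r_i):
                    n_ijk = int((d.records[rows, i] == k).sum())
                    log_total += mpmath.loggamma(a_ijk + n_ijk) - mpmath.loggamma(a_ijk)
        return float(log_total)


def random_problem(seed: int) -> tuple[DirectedGraph, CategoricalDataset]:
    rng = np.random.default_rng(seed)
    p = int(rng.integers(2, 5))
    arities = [int(a) for a in rng.integers(2, 4, size=p)]
    truth = random_dag(p, int(rng.integers(0, p * (p - 1) // 2 + 1)), seed)
    bn = random_cpts(truth, arities, concentration=1.0, seed=seed + 1)
    data = forward_sample(bn, int(rng.integers(1, 201)), seed + 2)
    scored = random_dag(p, int(rng.integers(0, p * (p - 1) // 2 + 1)), seed + 3)
    return scored, data


class TestBDeuScore:
    def test_empty_dataset_scores_zero(self):
        d = CategoricalDataset(("a", "b"), (2, 2), np.empty((0, 2), dtype=int))
        assert bdeu_log_score(DirectedGraph.empty(2), d) == 0.0

    def test_single_binary_variable_closed_form(self):
        # ln[ Gamma(1)/Gamma(3) * (Gamma(1.5)/Gamma(0.5))^2 ] = ln(1/8)
        d = CategoricalDataset(("x",), (2,), np.array([[0], [1]]))
        assert bdeu_log_score(DirectedGraph.empty(1), d, ess=1.0) == pytest.approx(
            math.log(1 / 8), abs=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 7, 19])
    @pytest.mark.parametrize("ess", [1.0, 5.0])
    def test_matches_literal_oracle(self, seed, ess):
        g, d = random_problem(seed)
        assert bdeu_log_score(g, d, ess) == pytest.approx(
            bdeu_oracle(g, d, ess), abs=1e-8
        )

    def test_nonpositive_for_nonempty_data(self):
        g, d = random_problem(5)
        assert bdeu_log_score(g, d) <= 0.0

    def test_rejects_cyclic_graph(self):
        d = CategoricalDataset(("a", "b"), (2, 2), np.array([[0, 1]]))
        cyc = DirectedGraph(np.array([[0, 1], [1, 0]]))
        with pytest.raises(ValueError):
            bdeu_log_score(cyc, d)

    def test_score_equivalence_over_3_node_classes(self):
        from penbayes import skeleton_and_vstructures

        bn = random_cpts(random_dag(3, 2, 0), [2, 3, 2], 1.0, seed=1)
        d = forward_sample(bn, 300, seed=2)
        classes: dict = {}
        for masks in enumerate_dags(3):
            g = dag_from_masks(3, masks)
            skel, vs = skeleton_and_vstructures(g)
            classes.setdefault((frozenset(skel), frozenset(vs)), []).append(
                bdeu_log_score(g, d)
            )
        for scores in classes.values():
            assert max(scores) - min(scores) < 1e-6

    def test_decomposability(self):
        # changing one node's parent set changes only that family's term
        _, d = random_problem(11)
        p = d.p
        g1 = DirectedGraph.empty(p)
        g2 = DirectedGraph.from_edges(p, [(0, 1)])
        from penbayes.scoring import FamilyScoreCache

        cache = FamilyScoreCache(d)
        diff = bdeu_log_score(g2, d) - bdeu_log_score(g1, d)
        family_diff = cache.family_score(1, (0,)) - cache.family_score(1, ())
        assert diff == pytest.approx(family_diff, abs=1e-10)


class TestEdgeStrength:
    def test_edgeless_graph_gets_inf_sentinel(self):
        d = CategoricalDataset(("a", "b"), (2, 2), np.array([[0, 1], [1, 0]]))
        assert edge_strength(DirectedGraph.empty(2), d) == math.inf

    def test_empty_dataset_is_an_error(self):
        d = CategoricalDataset(("a", "b"), (2, 2), np.empty((0, 2), dtype=int))
        with pytest.raises(ValueError):
            edge_strength(DirectedGraph.from_edges(2, [(0, 1)]), d)

    def test_scales_inversely_with_edge_count(self):
        g, d = random_problem(3)
        if g.m == 0 or d.n == 0:
            pytest.skip("degenerate draw")
        es = edge_strength(g, d)
        assert es == pytest.approx(abs(bdeu_log_score(g, d)) / (d.n * g.m))

    def test_positive_and_lower_for_better_fit(self, cancer_truth, cancer_data_20k):
        truth = cancer_truth.network.graph
        wrong = DirectedGraph.from_edges(5, [(4, 0), (3, 0)])
        es_truth = edge_strength(truth, cancer_data_20k)
        assert 0 < es_truth < edge_strength(wrong, cancer_data_20k)


class TestStructureWeights:
    def test_single_structure_gets_weight_one(self, cancer_graph, cancer_data_20k):
        w = structure_weights([cancer_graph], cancer_data_20k)
        assert w == pytest.approx([1.0])

    def test_score_equivalent_structures_share_weight(self, cancer_data_20k):
        a = DirectedGraph.from_edges(5, [(0, 1)])
        b = DirectedGraph.from_edges(5, [(1, 0)])
        c = DirectedGraph.from_edges(5, [(0, 1)])
        w = structure_weights([a, b, c], cancer_data_20k)
        assert w == pytest.approx([1 / 3, 1 / 3, 1 / 3])
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_edgeless_structures_excluded_with_warning(self, cancer_graph, cancer_data_20k):
        with pytest.warns(UserWarning):
            w = structure_weights(
                [cancer_graph, DirectedGraph.empty(5)], cancer_data_20k
            )
        assert w == pytest.approx([1.0, 0.0])

    def test_all_edgeless_is_an_error(self, cancer_data_20k):
        with pytest.raises(ValueError):
            structure_weights([DirectedGraph.empty(5)], cancer_data_20k)


class TestWeightedAdjacency:
    def test_zero_weight_zeroes_matrix(self, cancer_graph):
        assert not weighted_adjacency(cancer_graph, 0.0).matrix.any()

    def test_unit_weight_preserves_matrix(self, cancer_graph):
        out = weighted_adjacency(cancer_graph, 1.0).matrix
        assert np.array_equal(out, cancer_graph.adjacency.astype(float))

    def test_worked_example_first_summand(self, worked_example):
        graphs, weights = worked_example
        out = weighted_adjacency(graphs[0], weights[0]).matrix
        expected = np.zeros((5, 5))
        for child, parent in [(1, 0), (2, 0), (3, 1), (4, 2)]:
            expected[child, parent] = 0.31
        assert np.allclose(out, expected)

    def test_out_of_range_weight_rejected(self, cancer_graph):
        with pytest.raises(ValueError):
            weighted_adjacency(cancer_graph, 1.5)
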