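"""Shared fixtures: the Cancer ground truth, sampled data, and the canonical
three-structure merge example."""

from __future__ import annotations

import numpy as np
import pytest

from penbayes import DirectedGraph, cancer_fixture, forward_sample


def graph_from_rows(rows: list[str]) -> DirectedGraph:
    """Build a graph from adjacency rows written as 0/1 strings (row = child)."""
    return DirectedGraph(np.array([[int(c) for c in row] for row in rows]))


@pytest.fixture(scope="session")
def cancer_truth():
    return cancer_fixture(cpt_strength=0.9)


@pytest.fixture(scope="session")
def cancer_graph(cancer_truth):
    return cancer_truth.network.graph


@pytest.fixture(scope="session")
def cancer_data_20k(cancer_truth):
    """20,000 records from the Cancer network at strength 0.9."""
    return forward_sample(cancer_truth.network, 20_000, seed=42)


@pytest.fixture(scope="session")
def worked_example():
    """The three partially wrong Cancer structures and their fixed weights.

    Each structure misses exactly one of the five true edges; the weights are
    treated as given inputs (their generating dataset is not available).
    """
    b1 = graph_from_rows(["00000", "10000", "10000", "01000", "00100"])  # no L->D
    b2 = graph_from_rows(["00000", "10000", "10000", "00100", "00100"])  # no B->D
    b3 = graph_from_rows(["00000", "10000", "10000", "01100", "00000"])  # no L->X
    return [b1, b2, b3], [0.31, 0.34, 0.35]
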