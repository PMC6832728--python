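"""Directed graphs over a fixed variable order, plus structural statistics.

Adjacency convention used throughout the package: ``adjacency[i, j] == 1``
means there is a directed edge j -> i, i.e. row = child, column = parent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DirectedGraph:
    """A directed graph as a P x P binary adjacency matrix (row = child)."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        adj = np.ascontiguousarray(self.adjacency, dtype=np.int8)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.diagonal(adj).any():
            raise ValueError("self-loops are not allowed")
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)

    @classmethod
    def empty(cls, p: int) -> "DirectedGraph":
        return cls(np.zeros((p, p), dtype=np.int8))

    @classmethod
    def from_edges(cls, p: int, edges: list[tuple[int, int]]) -> "DirectedGraph":
        """Build from (parent, child) pairs."""
        adj = np.zeros((p, p), dtype=np.int8)
        for parent, child in edges:
            adj[child, parent] = 1
        return cls(adj)

    @property
    def p(self) -> int:
        return int(self.adjacency.shape[0])

    @property
    def m(self) -> int:
        """Edge count."""
        return int(self.adjacency.sum())

    def parents(self, node: int) -> list[int]:
        return [int(j) for j in np.flatnonzero(self.adjacency[node])]

    def children(self, node: int) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.adjacency[:, node])]

    def edges(self) -> list[tuple[int, int]]:
        """All (parent, child) pairs."""
        child, parent = np.nonzero(self.adjacency)
        return [(int(j), int(i)) for i, j in zip(child, parent)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedGraph):
            return NotImplemented
        return bool(np.array_equal(self.adjacency, other.adjacency))

    def __hash__(self) -> int:
        return hash(self.adjacency.tobytes())


def is_acyclic(g: DirectedGraph) -> bool:
    """True iff the graph contains no directed cycle (Kahn's peeling)."""
    adj = g.adjacency
    # in-degree of node i (as child) = number of its parents = row sum
    remaining = np.ones(g.p, dtype=bool)
    n_parents = adj.sum(axis=1).astype(np.int64)
    while remaining.any():
        sources = remaining & (n_parents == 0)
        if not sources.any():
            return False
        for s in np.flatnonzero(sources):
            n_parents -= adj[:, s].astype(np.int64)
        remaining &= ~sources
    return True


def topological_order(g: DirectedGraph) -> list[int]:
    """A topological order (parents before children); raises on cycles."""
    adj = g.adjacency
    n_parents = adj.sum(axis=1).astype(np.int64)
    order: list[int] = []
    ready = sorted(int(i) for i in np.flatnonzero(n_parents == 0))
    seen = np.zeros(g.p, dtype=bool)
    while ready:
        node = ready.pop(0)
        order.append(node)
        seen[node] = True
        for child in g.children(node):
            n_parents[child] -= 1
            if n_parents[child] == 0:
                ready.append(child)
        ready.sort()
    if len(order) != g.p:
        raise ValueError("graph has a directed cycle; no topological order")
    return order


def markov_blanket(g: DirectedGraph, node: int) -> set[int]:
    """Parents, children, and children's other parents of ``node``."""
    if not (0 <= node < g.p):
        raise IndexError(f"node {node} out of range for P={g.p}")
    blanket: set[int] = set(g.parents(node))
    for child in g.children(node):
        blanket.add(child)
        blanket.update(g.parents(child))
    blanket.discard(node)
    return blanket


def ambs(g: DirectedGraph) -> float:
    """Average Markov blanket size: sum of per-node blanket sizes over P.

    A complexity statistic of the structure; invariant across the Markov
    equivalence class of a DAG.
    """
    return sum(len(markov_blanket(g, i)) for i in range(g.p)) / g.p


def shd(g1: DirectedGraph, g2: DirectedGraph) -> int:
    """Structural Hamming distance with add/delete/reverse operations.

    A wrongly-oriented edge counts as one reversal, not a delete plus an add.
    Symmetric in its arguments.
    """
    if g1.p != g2.p:
        raise ValueError("graphs must share the same node set")
    a, b = g1.adjacency, g2.adjacency
    # same undirected edge, opposite orientation: counts 1 per edge
    reversal = (a == 1) & (b == 0) & (b.T == 1)
    n_reversals = int(reversal.sum())
    undirected_a = (a + a.T) > 0
    undirected_b = (b + b.T) > 0
    n_add_delete = int((undirected_a != undirected_b).sum()) // 2
    return n_add_delete + n_reversals


def skeleton_and_vstructures(
    g: DirectedGraph,
) -> tuple[set[frozenset[int]], set[tuple[int, int, int]]]:
    """Undirected skeleton and collider triples of a DAG.

    Returns the edge set as frozensets {i, j} and every triple (x, z, y) with
    x -> z <- y where x and y are non-adjacent, normalised so x < y. Together
    these determine the Markov-equivalence class.
    """
    skeleton = {frozenset((parent, child)) for parent, child in g.edges()}
    vstructs: set[tuple[int, int, int]] = set()
    for z in range(g.p):
        pa = g.parents(z)
        for ai in range(len(pa)):
            for bi in range(ai + 1, len(pa)):
                x, y = sorted((pa[ai], pa[bi]))
                if frozenset((x, y)) not in skeleton:
                    vstructs.add((x, z, y))
    return skeleton, vstructs


def markov_equivalent(g1: DirectedGraph, g2: DirectedGraph) -> bool:
    """True iff two DAGs share skeleton and v-structures."""
    return skeleton_and_vstructures(g1) == skeleton_and_vstructures(g2)
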