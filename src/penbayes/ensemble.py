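"""Weighted-adjacency-matrix structure voting.

The merge used at every layer of the pipeline: each candidate structure's
adjacency is scaled by its normalised Edge-Strength weight; the scaled matrices
are summed into the final weighted adjacency matrix (FWAM); entries above the
voting threshold gamma = T * min(weights) become edges of the merged network,
added in descending vote order under a cycle guard, so stronger consensus
edges win cycle conflicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import CategoricalDataset
from .graphs import DirectedGraph
from .scoring import structure_weights, weighted_adjacency


@dataclass(frozen=True)
class FWAMatrix:
    """Final weighted adjacency matrix with its voting threshold.

    With weights summing to one, every entry lies in [0, 1]; an entry is the
    total weight of the structures voting for that directed edge. ``gamma`` is
    ``t_factor * min(weight)`` over the participating structures, or None when
    the matrix was built without a threshold.
    """

    matrix: np.ndarray
    gamma: float | None = None
    t_factor: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))


def final_weighted_adjacency(
    graphs: list[DirectedGraph], weights: list[float] | np.ndarray
) -> FWAMatrix:
    """Sum of weight-scaled adjacency matrices (threshold left unset)."""
    if len(graphs) != len(weights):
        raise ValueError("graphs and weights must have equal length")
    if not graphs:
        raise ValueError("at least one graph is required")
    total = np.zeros((graphs[0].p, graphs[0].p), dtype=float)
    for g, w in zip(graphs, weights):
        total += weighted_adjacency(g, float(w)).matrix
    return FWAMatrix(total)


def threshold_vote(fwam: np.ndarray, gamma: float) -> DirectedGraph:
    """Turn a vote matrix into a DAG: entries strictly above gamma become
    edges, visited in descending vote value (ties: ascending (child, parent)),
    skipping any edge that would close a directed cycle."""
    p = fwam.shape[0]
    candidates = [
        (float(fwam[i, j]), i, j)
        for i in range(p)
        for j in range(p)
        if i != j and fwam[i, j] > gamma
    ]
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    adj = np.zeros((p, p), dtype=np.int8)

    def reaches(src: int, dst: int) -> bool:
        stack, seen = [src], set()
        while stack:
            node = stack.pop()
            if node == dst:
                return True
            if node in seen:
                continue
            seen.add(node)
            stack.extend(int(c) for c in np.flatnonzero(adj[:, node]))
        return False

    for _, child, parent in candidates:
        # adding parent->child cycles iff parent is reachable from child
        if not reaches(child, parent):
            adj[child, parent] = 1
    return DirectedGraph(adj)


def structure_ensemble(
    graphs: list[DirectedGraph],
    d: CategoricalDataset,
    t_factor: float,
    ess: float = 1.0,
) -> DirectedGraph:
    """Merge candidate structures by weighted majority voting on a dataset.

    Weights come from :func:`penbayes.scoring.structure_weights` evaluated on
    ``d``; edgeless candidates are excluded there and cast no votes. The
    voting threshold is gamma = t_factor * min(weight) over participating
    structures; an entry of the FWAM must strictly exceed gamma, so with
    near-equal weights an edge needs more than t_factor supporters. The result
    is always a DAG, and its edges are a subset of the union of input edges.
    """
    if not graphs:
        raise ValueError("cannot merge an empty list of structures")
    if t_factor <= 0:
        raise ValueError("t_factor must be positive")
    weights = structure_weights(graphs, d, ess)
    participating = weights > 0
    gamma = float(t_factor * weights[participating].min())
    fwam = final_weighted_adjacency(
        [g for g, keep in zip(graphs, participating) if keep],
        weights[participating],
    )
    merged = threshold_vote(fwam.matrix, gamma)
    return merged


def ensemble_details(
    graphs: list[DirectedGraph],
    d: CategoricalDataset,
    t_factor: float,
    ess: float = 1.0,
) -> tuple[DirectedGraph, FWAMatrix, np.ndarray]:
    """As :func:`structure_ensemble` but also exposing the FWAM and weights."""
    weights = structure_weights(graphs, d, ess)
    participating = weights > 0
    gamma = float(t_factor * weights[participating].min())
    fwam = final_weighted_adjacency(
        [g for g, keep in zip(graphs, participating) if keep],
        weights[participating],
    )
    fwam = FWAMatrix(fwam.matrix, gamma=gamma, t_factor=float(t_factor))
    return threshold_vote(fwam.matrix, gamma), fwam, weights
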