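"""Discrete Bayesian networks: a DAG plus per-node conditional probability tables.

Used for forward simulation and as ground truth in evaluation; the structure
learners themselves never see CPTs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import DirectedGraph, is_acyclic

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class BayesianNetwork:
    """A DAG with one CPT per node.

    ``cpts[i]`` has shape (q_i, r_i): one row per joint configuration of node
    i's parents (parents in ascending node order, last parent varying fastest),
    one column per state of node i. Rows sum to 1. For a parentless node the
    table is 1 x r_i and holds the marginal.
    """

    graph: DirectedGraph
    arities: tuple[int, ...]
    cpts: tuple[np.ndarray, ...]
    variable_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "arities", tuple(int(r) for r in self.arities))
        object.__setattr__(self, "variable_names", tuple(self.variable_names))
        object.__setattr__(
            self, "cpts", tuple(np.asarray(t, dtype=float) for t in self.cpts)
        )
        if not is_acyclic(self.graph):
            raise ValueError("BayesianNetwork requires a DAG")
        p = self.graph.p
        if len(self.arities) != p or len(self.cpts) != p or len(self.variable_names) != p:
            raise ValueError("arities, cpts and variable_names must all have length P")
        for i, table in enumerate(self.cpts):
            q_i = int(np.prod([self.arities[j] for j in self.graph.parents(i)], dtype=int))
            r_i = self.arities[i]
            if table.shape != (q_i, r_i):
                raise ValueError(
                    f"CPT of node {self.variable_names[i]!r} must be {q_i} x {r_i}, "
                    f"got {table.shape}"
                )
            if not np.allclose(table.sum(axis=1), 1.0, atol=_ROW_SUM_TOL):
                raise ValueError(f"CPT rows of node {self.variable_names[i]!r} must sum to 1")

    @property
    def p(self) -> int:
        return self.graph.p

    def parent_config_index(self, node: int, record: np.ndarray) -> int:
        """Row index into node's CPT for a full record (last parent fastest)."""
        idx = 0
        for parent in self.graph.parents(node):
            idx = idx * self.arities[parent] + int(record[parent])
        return idx
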