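"""BDeu scoring, Edge Strength, and structure weights.

The BDeu (Bayesian Dirichlet equivalent uniform) score is the log marginal
likelihood of the data given a structure under symmetric Dirichlet priors with
equivalent sample size ``ess``: for node i with arity r_i and q_i joint parent
configurations, the Dirichlet hyperparameters are N'_ijk = ess / (r_i * q_i).
The uniform structure prior is a constant under comparison and is dropped; all
logs are natural.

Edge Strength (ES) normalises the magnitude of the log-score by record count N
and edge count M: ES = |log BDeu| / (N * M). It measures the average score
burden per edge; a lower ES means higher per-edge structural quality. Structure
weights divide each candidate's ES by the sum of ES over candidates, so the
weights sum to one. Note the deliberate literalism: because weights are
proportional to ES while lower ES means better quality, slightly worse networks
receive slightly larger weights; the voting threshold gamma = T * min(W)
downstream is defined against exactly this convention (see docs/methods.md).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .dataset import CategoricalDataset
from .graphs import DirectedGraph, is_acyclic


class FamilyScoreCache:
    """Memoised per-family BDeu terms for one (dataset, ess) pair.

    The BDeu score decomposes over families (node, parent set); local search
    re-evaluates the same families constantly, so each is computed once. Parent
    sets are keyed by bitmask.
    """

    def __init__(self, data: CategoricalDataset, ess: float = 1.0) -> None:
        if ess <= 0:
            raise ValueError("ess must be positive")
        self.data = data
        self.ess = float(ess)
        self._cache: dict[tuple[int, int], float] = {}
        self._arr = data.records
        self._arities = np.asarray(data.arities, dtype=np.int64)

    def family_score(self, node: int, parents: tuple[int, ...] | frozenset[int]) -> float:
        parents = tuple(sorted(parents))
        mask = 0
        for j in parents:
            mask |= 1 << j
        key = (node, mask)
        if key not in self._cache:
            self._cache[key] = self._compute(node, parents)
        return self._cache[key]

    def _compute(self, node: int, parents: tuple[int, ...]) -> float:
        n = self.data.n
        if n == 0:
            return 0.0
        r_i = int(self._arities[node])
        q_i = int(np.prod(self._arities[list(parents)], dtype=np.int64)) if parents else 1
        # joint index over (parent config, child state); child varies fastest
        idx = np.zeros(n, dtype=np.int64)
        for j in parents:
            idx = idx * self._arities[j] + self._arr[:, j]
        idx = idx * r_i + self._arr[:, node]
        counts = np.bincount(idx, minlength=q_i * r_i).reshape(q_i, r_i)
        n_ij = counts.sum(axis=1)
        a_ijk = self.ess / (r_i * q_i)
        a_ij = self.ess / q_i
        occupied = n_ij > 0  # empty parent configurations contribute 0
        nz = counts[occupied]
        score = float(
            np.sum(gammaln(a_ij) - gammaln(a_ij + n_ij[occupied]))
            + np.sum(gammaln(a_ijk + nz) - gammaln(a_ijk))
        )
        return score

    def graph_score(self, g: DirectedGraph) -> float:
        return sum(self.family_score(i, tuple(g.parents(i))) for i in range(g.p))


def bdeu_log_score(g: DirectedGraph, d: CategoricalDataset, ess: float = 1.0) -> float:
    """Natural-log BDeu score of a DAG against data.

    Decomposes as a sum of per-family terms; <= 0 for any dataset with N >= 1,
    and exactly 0 for an empty dataset. Markov-equivalent DAGs receive equal
    scores (score equivalence of BDeu).
    """
    if g.p != d.p:
        raise ValueError("graph and dataset must share the variable set")
    if not is_acyclic(g):
        raise ValueError("bdeu_log_score requires a DAG")
    return FamilyScoreCache(d, ess).graph_score(g)


def edge_strength(g: DirectedGraph, d: CategoricalDataset, ess: float = 1.0) -> float:
    """Edge Strength: |log BDeu| / (N * M); lower means higher quality.

    An edgeless structure carries no votes and gets the +inf sentinel.
    """
    if d.n == 0:
        raise ValueError("edge strength is undefined on an empty dataset")
    if g.m == 0:
        return math.inf
    return abs(bdeu_log_score(g, d, ess)) / (d.n * g.m)


def structure_weights(
    structures: list[DirectedGraph], d: CategoricalDataset, ess: float = 1.0
) -> np.ndarray:
    """Normalised ensemble weights, one per structure, proportional to ES.

    Edgeless structures (M = 0, ES = +inf) are excluded with a warning and
    receive weight 0; the rest are renormalised. Raises if no structure has an
    edge. Scale-free: multiplying every ES by a constant leaves the weights
    unchanged.
    """
    if not structures:
        raise ValueError("at least one structure is required")
    es = np.array([edge_strength(g, d, ess) for g in structures], dtype=float)
    finite = np.isfinite(es)
    if not finite.any():
        raise ValueError("all structures are edgeless; weights are undefined")
    if not finite.all():
        warnings.warn(
            f"excluding {int((~finite).sum())} edgeless structure(s) from the ensemble",
            stacklevel=2,
        )
    weights = np.zeros_like(es)
    weights[finite] = es[finite] / es[finite].sum()
    return weights


@dataclass(frozen=True)
class ScoredStructure:
    """A structure bundled with its score, Edge Strength, and ensemble weight."""

    graph: DirectedGraph
    bdeu_log: float
    edge_strength: float
    weight: float


@dataclass(frozen=True)
class WeightedAdjacency:
    """A structure's adjacency scaled by its single ensemble weight."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))


def weighted_adjacency(g: DirectedGraph, w: float) -> WeightedAdjacency:
    """Elementwise product of a structure's adjacency and its weight."""
    if not (0.0 <= w <= 1.0):
        raise ValueError("weight must lie in [0, 1]")
    return WeightedAdjacency(g.adjacency.astype(float) * w)


def score_structures(
    structures: list[DirectedGraph], d: CategoricalDataset, ess: float = 1.0
) -> list[ScoredStructure]:
    """Convenience wrapper bundling score, ES and weight for each structure."""
    weights = structure_weights(structures, d, ess)
    out = []
    for g, w in zip(structures, weights):
        out.append(
            ScoredStructure(
                graph=g,
                bdeu_log=bdeu_log_score(g, d, ess),
                edge_strength=edge_strength(g, d, ess),
                weight=float(w),
            )
        )
    return out
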