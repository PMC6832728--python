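"""Ground-truth networks and forward sampling.

Provides the five-node Cancer diagnosis network as a fully specified fixture,
random network generators, ancestral (forward) sampling, and a structure
degrader used to probe ensemble robustness. Sampling emulates the kind of
synthetic benchmark data produced by forward-simulation tools for reference
networks: iid records drawn from the network's joint distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayesnet import BayesianNetwork
from .dataset import CategoricalDataset
from .graphs import DirectedGraph, ambs, is_acyclic, topological_order

CANCER_NODES = ("Smoking", "Bronchitis", "LungCancer", "Dyspnea", "Xray")
# (parent, child) pairs, indices into CANCER_NODES
CANCER_EDGES = ((0, 1), (0, 2), (1, 3), (2, 3), (2, 4))


@dataclass(frozen=True)
class GroundTruth:
    """A reference network with its structural statistics."""

    network: BayesianNetwork
    name: str
    true_ambs: float
    true_edge_count: int


def or_gate_cpts(
    g: DirectedGraph,
    strength: float,
    names: tuple[str, ...] | None = None,
) -> BayesianNetwork:
    """Fill a binary DAG with deterministic-rule CPTs of a given strength.

    Roots are fair coins; every child's most likely state given its parents is
    the logical OR of the parent values, and that state receives probability
    ``strength``. All distributions stay bounded away from determinism for
    strength < 1, so the structure is identifiable from enough data.
    """
    if not (0.5 < strength < 1.0):
        raise ValueError("strength must lie in (0.5, 1)")
    names = names or tuple(f"X{i}" for i in range(g.p))
    cpts: list[np.ndarray] = []
    for node in range(g.p):
        parents = g.parents(node)
        if not parents:
            cpts.append(np.array([[0.5, 0.5]]))
            continue
        q = 2 ** len(parents)
        table = np.empty((q, 2))
        for row in range(q):
            # row encodes parent values, first parent most significant
            values = [(row >> (len(parents) - 1 - k)) & 1 for k in range(len(parents))]
            likely = 1 if any(values) else 0
            table[row, likely] = strength
            table[row, 1 - likely] = 1.0 - strength
        cpts.append(table)
    return BayesianNetwork(g, (2,) * g.p, tuple(cpts), names)


def cancer_fixture(cpt_strength: float = 0.9) -> GroundTruth:
    """The five-node Cancer network with parametric noisy-OR-style CPTs.

    Structure: Smoking -> {Bronchitis, LungCancer}; {Bronchitis, LungCancer}
    -> Dyspnea (a collider); LungCancer -> Xray. All nodes binary.

    CPT construction rule (fixed so derived numbers are reproducible): the
    root Smoking is a fair coin; every child's most likely state given its
    parents is the logical OR of the parent values, and that state gets
    probability ``cpt_strength``. Strength near 1 gives near-deterministic
    data from which every learner recovers the skeleton; strength near 0.5
    gives uninformative data.
    """
    graph = DirectedGraph.from_edges(5, list(CANCER_EDGES))
    network = or_gate_cpts(graph, cpt_strength, CANCER_NODES)
    return GroundTruth(network, "cancer", true_ambs=ambs(graph), true_edge_count=graph.m)


def random_dag(p: int, m: int, seed: int) -> DirectedGraph:
    """A random DAG: random topological order plus m random forward edges."""
    if m > p * (p - 1) // 2:
        raise ValueError(f"a DAG on {p} nodes holds at most {p * (p - 1) // 2} edges")
    rng = np.random.default_rng(seed)
    order = rng.permutation(p)
    pairs = [
        (int(order[a]), int(order[b])) for a in range(p) for b in range(a + 1, p)
    ]  # (parent earlier in order, child later)
    chosen = rng.choice(len(pairs), size=m, replace=False)
    return DirectedGraph.from_edges(p, [pairs[int(c)] for c in chosen])


def random_cpts(
    g: DirectedGraph,
    arities: list[int] | tuple[int, ...],
    concentration: float,
    seed: int,
    names: tuple[str, ...] | None = None,
) -> BayesianNetwork:
    """Fill a DAG with CPT rows drawn from a symmetric Dirichlet.

    Small concentration (e.g. 0.01) gives near-deterministic rows; large
    concentration gives near-uniform ones.
    """
    rng = np.random.default_rng(seed)
    arities = tuple(int(r) for r in arities)
    names = names or tuple(f"X{i}" for i in range(g.p))
    cpts = []
    for node in range(g.p):
        q = int(np.prod([arities[j] for j in g.parents(node)], dtype=int))
        cpts.append(rng.dirichlet([concentration] * arities[node], size=q))
    return BayesianNetwork(g, arities, tuple(cpts), names)


def forward_sample(bn: BayesianNetwork, n: int, seed: int) -> CategoricalDataset:
    """Ancestral sampling: n iid records from the network's joint distribution."""
    rng = np.random.default_rng(seed)
    records = np.zeros((n, bn.p), dtype=np.int64)
    if n:
        for node in topological_order(bn.graph):
            parents = bn.graph.parents(node)
            table = bn.cpts[node]
            if parents:
                rows = np.zeros(n, dtype=np.int64)
                for parent in parents:
                    rows = rows * bn.arities[parent] + records[:, parent]
            else:
                rows = np.zeros(n, dtype=np.int64)
            u = rng.random(n)
            cdf = np.cumsum(table, axis=1)
            records[:, node] = (u[:, None] > cdf[rows]).sum(axis=1)
    return CategoricalDataset(bn.variable_names, bn.arities, records)


def degrade_structure(g: DirectedGraph, fraction: float, seed: int) -> DirectedGraph:
    """Corrupt a DAG: drop ceil(fraction * M) random edges, rewire half of them.

    Rewired edges go to random positions that keep the result acyclic. Models
    a base learner performing badly so the ensemble's tolerance can be tested.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    edges = g.edges()
    n_remove = int(np.ceil(fraction * len(edges)))
    if n_remove == 0:
        return g
    removed_idx = rng.choice(len(edges), size=n_remove, replace=False)
    removed = {edges[int(i)] for i in removed_idx}
    kept = [e for e in edges if e not in removed]
    adj = np.zeros((g.p, g.p), dtype=np.int8)
    for parent, child in kept:
        adj[child, parent] = 1
    n_rewire = n_remove // 2
    attempts = 0
    placed = 0
    while placed < n_rewire and attempts < 100 * (n_rewire + 1):
        attempts += 1
        parent, child = (int(v) for v in rng.integers(0, g.p, size=2))
        if parent == child or adj[child, parent] or adj[parent, child]:
            continue
        adj[child, parent] = 1
        if is_acyclic(DirectedGraph(adj.copy())):
            placed += 1
        else:
            adj[child, parent] = 0
    return DirectedGraph(adj)
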