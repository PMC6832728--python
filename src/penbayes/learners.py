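"""Constituent structure learners: hill climbing, tabu search, and MMHC.

All three are score-based or hybrid searches over DAGs using the BDeu score.
They are deterministic: search starts from the empty graph, and equal-score
moves are broken by a fixed operator order (add < delete < reverse, then
lexicographic (parent, child)). A brute-force exhaustive learner over all DAGs
(P <= 5) serves as an optimality oracle in tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .dataset import CategoricalDataset
from .graphs import DirectedGraph
from .scoring import FamilyScoreCache

_ADD, _DELETE, _REVERSE = 0, 1, 2  # tie-break order of operators


@dataclass(frozen=True)
class SearchConfig:
    """Knobs shared by the search-based learners.

    ess
        BDeu equivalent sample size (Dirichlet prior mass).
    max_iterations
        Cap on accepted moves per search.
    tabu_length
        Number of recently reversed decisions kept forbidden in tabu search.
    alpha
        Significance level of the G-squared independence tests in MMPC.
    max_parents
        Optional cap on any node's parent-set size.
    max_cond_set
        Largest conditioning-set size materialised by MMPC's tests.
    """

    ess: float = 1.0
    max_iterations: int = 200
    tabu_length: int = 10
    alpha: float = 0.05
    max_parents: int | None = None
    max_cond_set: int = 3

    def __post_init__(self) -> None:
        if self.ess <= 0:
            raise ValueError("ess must be positive")
        if self.max_iterations < 1 or self.tabu_length < 1:
            raise ValueError("max_iterations and tabu_length must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


# ---------------------------------------------------------------------------
# greedy search machinery


class _SearchState:
    """Mutable adjacency + incremental BDeu bookkeeping during local search."""

    def __init__(self, data: CategoricalDataset, cfg: SearchConfig) -> None:
        self.p = data.p
        self.cfg = cfg
        self.cache = FamilyScoreCache(data, cfg.ess)
        self.adj = np.zeros((self.p, self.p), dtype=np.int8)
        self.family = [self.cache.family_score(i, ()) for i in range(self.p)]
        self.score = float(sum(self.family))

    def parents_of(self, node: int) -> tuple[int, ...]:
        return tuple(int(j) for j in np.flatnonzero(self.adj[node]))

    def _would_cycle(self, parent: int, child: int) -> bool:
        """True if adding parent->child creates a cycle (path child ~> parent)."""
        if parent == child:
            return True
        stack = [child]
        seen = np.zeros(self.p, dtype=bool)
        while stack:
            node = stack.pop()
            if node == parent:
                return True
            if seen[node]:
                continue
            seen[node] = True
            stack.extend(int(i) for i in np.flatnonzero(self.adj[:, node]))
        return False

    def candidate_moves(self, whitelist: np.ndarray | None):
        """Yield (delta, op, child, parent) for every legal single-edge move.

        ``whitelist`` (symmetric boolean matrix), when given, restricts which
        pairs may gain an edge via add or reverse; deletions are unrestricted.
        """
        max_pa = self.cfg.max_parents
        for child in range(self.p):
            base = self.family[child]
            n_parents = int(self.adj[child].sum())
            for parent in range(self.p):
                if parent == child:
                    continue
                if self.adj[child, parent]:
                    pa = self.parents_of(child)
                    pa_without = tuple(x for x in pa if x != parent)
                    delta_del = self.cache.family_score(child, pa_without) - base
                    yield (delta_del, _DELETE, child, parent)
                    # reverse: delete parent->child, add child->parent
                    if whitelist is None or whitelist[parent, child]:
                        if max_pa is not None and int(self.adj[parent].sum()) >= max_pa:
                            continue
                        self.adj[child, parent] = 0
                        cycles = self._would_cycle(child, parent)
                        self.adj[child, parent] = 1
                        if not cycles:
                            pa_new = tuple(sorted(self.parents_of(parent) + (child,)))
                            delta_rev = (
                                delta_del
                                + self.cache.family_score(parent, pa_new)
                                - self.family[parent]
                            )
                            yield (delta_rev, _REVERSE, child, parent)
                elif not self.adj[parent, child]:
                    if whitelist is not None and not whitelist[child, parent]:
                        continue
                    if max_pa is not None and n_parents >= max_pa:
                        continue
                    if self._would_cycle(parent, child):
                        continue
                    pa_new = tuple(sorted(self.parents_of(child) + (parent,)))
                    delta_add = self.cache.family_score(child, pa_new) - base
                    yield (delta_add, _ADD, child, parent)

    def apply(self, op: int, child: int, parent: int) -> None:
        if op == _ADD:
            self.adj[child, parent] = 1
            self._refresh(child)
        elif op == _DELETE:
            self.adj[child, parent] = 0
            self._refresh(child)
        else:
            self.adj[child, parent] = 0
            self.adj[parent, child] = 1
            self._refresh(child)
            self._refresh(parent)

    def _refresh(self, node: int) -> None:
        old = self.family[node]
        self.family[node] = self.cache.family_score(node, self.parents_of(node))
        self.score += self.family[node] - old

    def graph(self) -> DirectedGraph:
        return DirectedGraph(self.adj.copy())


def _best_move(moves, forbidden: set | None = None, best_needed: float | None = None):
    """Pick the move maximising delta; ties by (op, parent, child) ascending.

    Ordering ties by parent first matters: breaking by child first would hand
    node 0 the hub as a parent whenever the two orientations of a fresh edge
    score equally, which locks greedy search into fork-shaped local optima and
    prevents collider recovery.

    ``forbidden`` holds tabu (op, child, parent) triples; a tabu move is still
    admissible if it lifts the score above ``best_needed`` (aspiration).
    """
    best = None
    for delta, op, child, parent in moves:
        if forbidden and (op, child, parent) in forbidden:
            if best_needed is None or delta <= best_needed:
                continue
        key = (-delta, op, parent, child)
        if best is None or key < best[0]:
            best = (key, delta, op, child, parent)
    return None if best is None else best[1:]


def hill_climb(
    d: CategoricalDataset,
    cfg: SearchConfig | None = None,
    whitelist: np.ndarray | None = None,
    score_trace: list[float] | None = None,
) -> DirectedGraph:
    """Greedy BDeu hill climbing from the empty graph.

    Accepts the single best strictly improving add/delete/reverse move per
    step; stops at a local optimum or after ``max_iterations`` moves. With a
    ``whitelist`` the search is skeleton-constrained (used by MMHC). Passing a
    list as ``score_trace`` records the score of every accepted state,
    starting with the empty graph.
    """
    cfg = cfg or SearchConfig()
    state = _SearchState(d, cfg)
    if score_trace is not None:
        score_trace.append(state.score)
    for _ in range(cfg.max_iterations):
        picked = _best_move(state.candidate_moves(whitelist))
        if picked is None or picked[0] <= 1e-12:
            break
        _, op, child, parent = picked
        state.apply(op, child, parent)
        if score_trace is not None:
            score_trace.append(state.score)
    return state.graph()


def tabu_search(d: CategoricalDataset, cfg: SearchConfig | None = None) -> DirectedGraph:
    """Tabu-list local search; returns the best-scoring DAG visited.

    Identical to hill climbing while moves improve; at a local optimum it
    accepts the best non-improving admissible move, keeping the inverse of the
    last ``tabu_length`` decisions forbidden (aspiration lifts the taboo for a
    move that beats the incumbent). Gives up after ``2 * tabu_length``
    consecutive moves without a new incumbent, so its score never falls below
    hill climbing's on the same input.
    """
    cfg = cfg or SearchConfig()
    state = _SearchState(d, cfg)
    best_adj = state.adj.copy()
    best_score = state.score
    tabu: list[tuple[int, int, int]] = []
    stale = 0
    for _ in range(cfg.max_iterations):
        picked = _best_move(
            state.candidate_moves(None),
            forbidden=set(tabu),
            best_needed=best_score - state.score,
        )
        if picked is None:
            break
        delta, op, child, parent = picked
        state.apply(op, child, parent)
        # forbid undoing this decision
        if op == _ADD:
            inverse = (_DELETE, child, parent)
        elif op == _DELETE:
            inverse = (_ADD, child, parent)
        else:
            inverse = (_REVERSE, parent, child)
        tabu.append(inverse)
        if len(tabu) > cfg.tabu_length:
            tabu.pop(0)
        if state.score > best_score + 1e-12:
            best_score = state.score
            best_adj = state.adj.copy()
            stale = 0
        else:
            stale += 1
            if stale >= 2 * cfg.tabu_length:
                break
    return DirectedGraph(best_adj)


# ---------------------------------------------------------------------------
# constraint-based phase (MMPC) and the hybrid MMHC


def g2_test(
    d: CategoricalDataset, x: int, y: int, z: tuple[int, ...] = ()
) -> tuple[float, float]:
    """Conditional G-squared independence test of x and y given z.

    G^2 = 2 * sum o * ln(o / e) over the x-by-y table within each stratum of
    z. Degrees of freedom are (nonzero x-levels - 1)(nonzero y-levels - 1)
    summed over non-empty strata, so strata with structural zeros contribute
    nothing. Returns (statistic, p-value).
    """
    if d.n == 0:
        raise ValueError("g2_test requires a non-empty dataset")
    arr = d.records
    arities = d.arities
    rx, ry = arities[x], arities[y]
    qz = 1
    idx = np.zeros(d.n, dtype=np.int64)
    for j in z:
        idx = idx * arities[j] + arr[:, j]
        qz *= arities[j]
    idx = (idx * rx + arr[:, x]) * ry + arr[:, y]
    counts = np.bincount(idx, minlength=qz * rx * ry).reshape(qz, rx, ry).astype(float)
    row = counts.sum(axis=2, keepdims=True)
    col = counts.sum(axis=1, keepdims=True)
    tot = counts.sum(axis=(1, 2), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row * col / tot
        ratio = np.where(counts > 0, counts / expected, 1.0)
        stat = float(2.0 * np.sum(counts * np.log(ratio)))
    nz_rows = (row[:, :, 0] > 0).sum(axis=1)
    nz_cols = (col[:, 0, :] > 0).sum(axis=1)
    dof = int(np.sum(np.maximum(nz_rows - 1, 0) * np.maximum(nz_cols - 1, 0)))
    p_value = float(chi2.sf(stat, dof)) if dof > 0 else 1.0
    return stat, p_value


def _min_assoc(
    d: CategoricalDataset, x: int, t: int, cpc: list[int], cap: int
) -> tuple[float, float]:
    """(min G2 statistic, max p-value) of x vs t over subsets of cpc (<= cap)."""
    min_stat = math.inf
    max_p = 0.0
    for size in range(0, min(cap, len(cpc)) + 1):
        for subset in itertools.combinations(sorted(cpc), size):
            stat, p = g2_test(d, x, t, subset)
            min_stat = min(min_stat, stat)
            max_p = max(max_p, p)
            if max_p >= 1.0:
                return min_stat, max_p
    return min_stat, max_p


def mmpc(d: CategoricalDataset, cfg: SearchConfig | None = None) -> set[frozenset[int]]:
    """Max-min parents-and-children skeleton discovery.

    For each target, grows a candidate set by repeatedly admitting the variable
    with the largest minimum association (G^2) over subsets of the current set,
    excluding any variable some subset renders independent at level alpha;
    then shrinks by re-testing each member against subsets of the others. An
    undirected edge is kept only when found from both endpoints (AND rule).
    """
    cfg = cfg or SearchConfig()
    if d.n == 0:
        raise ValueError("mmpc requires a non-empty dataset")
    cap = cfg.max_cond_set
    neighbours: list[set[int]] = []
    for t in range(d.p):
        cpc: list[int] = []
        candidates = [v for v in range(d.p) if v != t]
        while candidates:
            scored = []
            still = []
            for x in candidates:
                stat, p = _min_assoc(d, x, t, cpc, cap)
                if p >= cfg.alpha:
                    continue  # some subset separates x from t; drop for good
                scored.append((stat, x))
                still.append(x)
            if not scored:
                break
            # max-min heuristic: admit the candidate with maximal min-association
            scored.sort(key=lambda sx: (-sx[0], sx[1]))
            chosen = scored[0][1]
            cpc.append(chosen)
            candidates = [x for x in still if x != chosen]
        # backward shrink: re-test each member given subsets of the rest
        for x in list(cpc):
            rest = [v for v in cpc if v != x]
            _, p = _min_assoc(d, x, t, rest, cap)
            if p >= cfg.alpha:
                cpc.remove(x)
        neighbours.append(set(cpc))
    edges = set()
    for t in range(d.p):
        for x in neighbours[t]:
            if t in neighbours[x]:
                edges.add(frozenset((t, x)))
    return edges


def mmhc(d: CategoricalDataset, cfg: SearchConfig | None = None) -> DirectedGraph:
    """Max-min hill climbing: BDeu search constrained to the MMPC skeleton.

    Edge additions (and the adding half of reversals) are only allowed within
    the undirected skeleton found by :func:`mmpc`; deletions are unrestricted.
    The result's skeleton is a subset of the MMPC skeleton.
    """
    cfg = cfg or SearchConfig()
    skeleton = mmpc(d, cfg)
    whitelist = np.zeros((d.p, d.p), dtype=bool)
    for edge in skeleton:
        i, j = tuple(edge)
        whitelist[i, j] = whitelist[j, i] = True
    return hill_climb(d, cfg, whitelist=whitelist)


# ---------------------------------------------------------------------------
# exhaustive oracle


def enumerate_dags(p: int):
    """Yield every DAG over p nodes as a parent-bitmask tuple (p <= 5)."""
    if p > 5:
        raise ValueError("exhaustive enumeration is limited to P <= 5 nodes")
    others = [
        [mask for mask in range(1 << p) if not (mask >> node) & 1] for node in range(p)
    ]

    def acyclic(parent_masks: tuple[int, ...]) -> bool:
        remaining = (1 << p) - 1
        masks = list(parent_masks)
        while remaining:
            progressed = False
            for node in range(p):
                if (remaining >> node) & 1 and not (masks[node] & remaining):
                    remaining &= ~(1 << node)
                    progressed = True
            if not progressed:
                return False
        return True

    for combo in itertools.product(*others):
        if acyclic(combo):
            yield combo


def exhaustive_search(d: CategoricalDataset, cfg: SearchConfig | None = None) -> DirectedGraph:
    """Brute-force BDeu-optimal DAG over all DAGs (refuses P > 5).

    Ties are broken by fewest edges, then lexicographically smallest flattened
    adjacency. Intended as a test oracle for the heuristic searches.
    """
    cfg = cfg or SearchConfig()
    p = d.p
    if p > 5:
        raise ValueError("exhaustive_search refuses problems with more than 5 nodes")
    cache = FamilyScoreCache(d, cfg.ess)
    family: dict[tuple[int, int], float] = {}
    for node in range(p):
        for mask in range(1 << p):
            if (mask >> node) & 1:
                continue
            parents = tuple(j for j in range(p) if (mask >> j) & 1)
            family[(node, mask)] = cache.family_score(node, parents)
    best = None
    for combo in enumerate_dags(p):
        score = sum(family[(node, combo[node])] for node in range(p))
        n_edges = sum(mask.bit_count() for mask in combo)
        key = (-score, n_edges, combo)
        if best is None or key < best[0]:
            best = (key, combo)
    assert best is not None
    adj = np.zeros((p, p), dtype=np.int8)
    for node, mask in enumerate(best[1]):
        for j in range(p):
            if (mask >> j) & 1:
                adj[node, j] = 1
    return DirectedGraph(adj)
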