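"""Three-layer ensemble orchestration.

Layer 1 (data-slice learner): three algorithms — MMHC, hill climbing, tabu
search — each learn a structure from one ALS-sized data slice; the three are
merged by weighted voting with threshold factor T = 2 (simple majority of
three).

Layer 2 (local learner): one learner per contiguous global partition merges
its per-slice structures with T = Nd / 2 (an edge must appear in more than
half of the slice structures), weighting on the slice whose merged structure
had the best (lowest) Edge Strength.

Layer 3 (global ensemble): the K local structures are merged with
T = 2K / 3 on the globally best slice.

The layers are pure functions of (data, config): running local learners in
parallel worker processes gives bit-identical results to a serial run.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Callable

from joblib import Parallel, delayed

from .als import ALSConfig, ALSResult, calculate_als
from .dataset import CategoricalDataset
from .ensemble import structure_ensemble
from .graphs import DirectedGraph
from .learners import SearchConfig, hill_climb, mmhc, tabu_search
from .scoring import edge_strength

BaseLearner = Callable[[CategoricalDataset, SearchConfig], DirectedGraph]

DEFAULT_BASE_LEARNERS: tuple[BaseLearner, ...] = (mmhc, hill_climb, tabu_search)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of the full pipeline.

    k_learners
        Number K of local learners (global partitions).
    ess
        BDeu equivalent sample size, used by every scorer and search.
    als_config / search_config
        Sub-configurations for ALS estimation and the base searches.
    workers
        Worker processes for the local-learning phase; results are identical
        for any worker count.
    seed
        Echoed into reports; the pipeline itself is deterministic.
    base_learners
        The constituent algorithms merged at the slice layer; replaceable for
        robustness experiments.
    """

    k_learners: int = 4
    ess: float = 1.0
    als_config: ALSConfig | None = None
    search_config: SearchConfig | None = None
    workers: int = 1
    seed: int = 0
    base_learners: tuple[BaseLearner, ...] = DEFAULT_BASE_LEARNERS

    def __post_init__(self) -> None:
        if self.k_learners < 1 or self.workers < 1:
            raise ValueError("k_learners and workers must be >= 1")
        if self.als_config is None:
            object.__setattr__(self, "als_config", ALSConfig(ess=self.ess))
        if self.search_config is None:
            object.__setattr__(self, "search_config", SearchConfig(ess=self.ess))


@dataclass(frozen=True)
class LocalResult:
    """One local learner's merged structure and its best slice."""

    local_graph: DirectedGraph
    best_slice_id: int
    best_slice_es: float
    slice_graphs: int
    best_slice: CategoricalDataset = field(repr=False, compare=False, default=None)


def partition_global(d: CategoricalDataset, k: int) -> list[CategoricalDataset]:
    """Split into K contiguous blocks of floor(N/K) rows, remainder to the last."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > d.n:
        raise ValueError(f"cannot split {d.n} records into {k} non-empty partitions")
    base = d.n // k
    blocks = []
    start = 0
    for i in range(k):
        stop = start + base if i < k - 1 else d.n
        blocks.append(d.rows(start, stop))
        start = stop
    return blocks


def num_data_slices(n: int, k: int, als: int) -> int:
    """Number of ALS-sized slices per local learner: floor(N / (K * ALS)), >= 1."""
    if n < 1 or k < 1 or als < 1:
        raise ValueError("n, k and als must all be positive")
    nd = n // (k * als)
    if nd < 1:
        warnings.warn(
            f"N={n} is smaller than K*ALS={k * als}; using one undersized slice",
            stacklevel=2,
        )
        return 1
    return nd


def data_slice_learner(
    d: CategoricalDataset, cfg: PipelineConfig | None = None
) -> DirectedGraph:
    """Layer 1: learn with each base algorithm, merge by majority (T = 2).

    A base learner that raises is dropped with a warning; if fewer than two
    structures remain, the best-ES survivor is returned as-is. If every
    learner returns an edgeless graph the merge degenerates to the empty
    graph.
    """
    cfg = cfg or PipelineConfig()
    if d.n == 0:
        raise ValueError("cannot learn from an empty data slice")
    graphs: list[DirectedGraph] = []
    for learner in cfg.base_learners:
        try:
            graphs.append(learner(d, cfg.search_config))
        except Exception as exc:  # noqa: BLE001 - a failing learner is dropped
            warnings.warn(f"base learner {learner!r} failed: {exc}", stacklevel=2)
    if not graphs:
        raise RuntimeError("every base learner failed on this slice")
    if all(g.m == 0 for g in graphs):
        return DirectedGraph.empty(d.p)
    if len(graphs) < 2:
        return graphs[0]
    return structure_ensemble(graphs, d, t_factor=2.0, ess=cfg.ess)


def local_learner(
    slices: list[CategoricalDataset], cfg: PipelineConfig | None = None
) -> LocalResult:
    """Layer 2: per-slice learning then majority merge with T = Nd / 2.

    Tracks the slice whose merged structure has the best (lowest) Edge
    Strength; the final merge weights every slice structure on that best
    slice.
    """
    cfg = cfg or PipelineConfig()
    if not slices:
        raise ValueError("local_learner needs at least one data slice")
    nd = len(slices)
    graphs = []
    best_id, best_es = 0, float("inf")
    for k, data_slice in enumerate(slices):
        g = data_slice_learner(data_slice, cfg)
        graphs.append(g)
        es = edge_strength(g, data_slice, cfg.ess)
        if es < best_es:
            best_id, best_es = k, es
    if all(g.m == 0 for g in graphs):
        merged = DirectedGraph.empty(slices[0].p)
    else:
        merged = structure_ensemble(graphs, slices[best_id], t_factor=nd / 2, ess=cfg.ess)
    return LocalResult(
        local_graph=merged,
        best_slice_id=best_id,
        best_slice_es=best_es,
        slice_graphs=nd,
        best_slice=slices[best_id],
    )


def global_ensemble(
    local_results: list[LocalResult], cfg: PipelineConfig | None = None
) -> DirectedGraph:
    """Layer 3: merge local structures with T = 2K / 3 on the globally best slice."""
    cfg = cfg or PipelineConfig()
    if not local_results:
        raise ValueError("global_ensemble needs at least one local result")
    k = len(local_results)
    best = min(local_results, key=lambda r: r.best_slice_es)
    graphs = [r.local_graph for r in local_results]
    if all(g.m == 0 for g in graphs):
        return DirectedGraph.empty(graphs[0].p)
    return structure_ensemble(graphs, best.best_slice, t_factor=2 * k / 3, ess=cfg.ess)


def _run_local(slices: list[CategoricalDataset], cfg: PipelineConfig) -> LocalResult:
    return local_learner(slices, cfg)


def run_penbayes(
    d: CategoricalDataset, cfg: PipelineConfig | None = None
) -> tuple[DirectedGraph, dict]:
    """End-to-end pipeline: ALS, partitioning, local learning, global merge.

    Returns the final DAG and a run report (ALS, Nd, per-layer Edge Strengths,
    work counts and timings). The final graph is a pure function of the data
    and configuration, independent of ``workers``.
    """
    cfg = cfg or PipelineConfig()
    t0 = time.perf_counter()
    partitions = partition_global(d, cfg.k_learners)
    als_result: ALSResult = calculate_als(partitions[0], cfg.als_config)
    als = als_result.als
    t_als = time.perf_counter()
    nd = num_data_slices(d.n, cfg.k_learners, als)
    # each partition yields Nd leading slices of size ALS; leftover rows join
    # the last slice
    jobs: list[list[CategoricalDataset]] = []
    for part in partitions:
        bounds = [min(i * als, part.n) for i in range(nd)] + [part.n]
        jobs.append([part.rows(bounds[i], bounds[i + 1]) for i in range(nd)])
    if cfg.workers == 1:
        local_results = [_run_local(job, cfg) for job in jobs]
    else:
        local_results = Parallel(n_jobs=cfg.workers)(
            delayed(_run_local)(job, cfg) for job in jobs
        )
    t_local = time.perf_counter()
    final = global_ensemble(local_results, cfg)
    t_final = time.perf_counter()
    report = {
        "n_records": d.n,
        "p_variables": d.p,
        "k_learners": cfg.k_learners,
        "seed": cfg.seed,
        "ess": cfg.ess,
        "als": als,
        "als_truncated": als_result.truncated,
        "als_ambs_trace": list(als_result.ambs_trace),
        "als_es_trace": list(als_result.es_trace),
        "nd": nd,
        # counted from the work actually performed, not recomputed from K*Nd
        "slice_learner_calls": sum(r.slice_graphs for r in local_results),
        "merge_calls": len(local_results) + 1,
        "local_best_es": [r.best_slice_es for r in local_results],
        "local_best_slice_id": [r.best_slice_id for r in local_results],
        "local_edge_counts": [r.local_graph.m for r in local_results],
        "final_edges": [
            [int(parent), int(child)] for parent, child in final.edges()
        ],
        "timings_s": {
            "als": t_als - t0,
            "local_learning": t_local - t_als,
            "global_ensemble": t_final - t_local,
        },
    }
    return final, report
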