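"""Appropriate Learning Size estimation by greedy doubling.

The Appropriate Learning Size (ALS) of a large iid categorical dataset is the
smallest data-slice size at which the structure learned from a leading prefix
stabilises: both the average Markov blanket size (AMBS) of the learned network
and its Edge Strength (ES) stop changing, in relative terms, under a doubling
of the slice. The estimator reads geometrically growing prefixes, learns a
structure on each, and stops once consecutive AMBS values agree within
``eps1`` (relative) and consecutive ES values within ``eps2``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .dataset import CategoricalDataset
from .graphs import DirectedGraph, ambs
from .scoring import edge_strength

Learner = Callable[[CategoricalDataset], DirectedGraph]


@dataclass(frozen=True)
class ALSConfig:
    """Tolerances and limits for the doubling estimator.

    eps1, eps2
        Relative convergence tolerances on AMBS and Edge Strength (default
        0.05 each).
    mstep
        Maximum number of doublings.
    initial_multiplier
        Records per attribute in the first slice: the initial slice holds
        ``initial_multiplier * P`` leading records.
    ess
        BDeu equivalent sample size used when scoring each slice's structure.
    """

    eps1: float = 0.05
    eps2: float = 0.05
    mstep: int = 20
    initial_multiplier: int = 50
    ess: float = 1.0

    def __post_init__(self) -> None:
        if self.eps1 <= 0 or self.eps2 <= 0:
            raise ValueError("eps1 and eps2 must be positive")
        if self.mstep < 0:
            raise ValueError("mstep must be >= 0")
        if self.initial_multiplier < 1:
            raise ValueError("initial_multiplier must be >= 1")


@dataclass(frozen=True)
class ALSResult:
    """Outcome of the doubling run.

    ``als`` is the final slice's record count (initial size * 2**steps);
    the traces hold the AMBS and ES observed at each slice, initial slice
    included. ``truncated`` flags a dataset exhausted before convergence.
    """

    als: int
    ambs_trace: tuple[float, ...]
    es_trace: tuple[float, ...]
    steps: int
    final_ambs: float
    truncated: bool = False

    def to_dict(self) -> dict:
        return {
            "als": self.als,
            "ambs_trace": list(self.ambs_trace),
            "es_trace": list(self.es_trace),
            "steps": self.steps,
            "final_ambs": self.final_ambs,
            "truncated": self.truncated,
        }


def _default_learner(cfg: ALSConfig) -> Learner:
    # the triple-ensemble slice learner; imported lazily to avoid a cycle
    from .pipeline import PipelineConfig, data_slice_learner

    pipeline_cfg = PipelineConfig(ess=cfg.ess)

    def learn(d: CategoricalDataset) -> DirectedGraph:
        return data_slice_learner(d, pipeline_cfg)

    return learn


def calculate_als(
    d: CategoricalDataset,
    cfg: ALSConfig | None = None,
    learner: Learner | None = None,
) -> ALSResult:
    """Estimate the Appropriate Learning Size of a dataset by greedy doubling.

    Reads ``initial_multiplier * P`` leading records, learns a structure with
    ``learner`` (default: the three-algorithm slice ensemble), then keeps
    doubling the prefix while either the relative AMBS change exceeds ``eps1``
    or the relative ES change exceeds ``eps2``, up to ``mstep`` doublings.
    Candidate sizes are exactly ``initial * 2**k``. If a doubling would
    overrun the dataset, the best size so far is returned with
    ``truncated=True``.
    """
    cfg = cfg or ALSConfig()
    learner = learner or _default_learner(cfg)
    slice_size = cfg.initial_multiplier * d.p
    if d.n < slice_size:
        raise ValueError(
            f"dataset has {d.n} records; the initial slice needs {slice_size}"
        )
    # sentinels chosen so the first comparison always continues the loop
    best_ambs = 1.0
    best_es = -1.0
    step = 0
    sliced = d.head(slice_size)
    graph = learner(sliced)
    current_ambs = ambs(graph)
    current_es = edge_strength(graph, sliced, cfg.ess)
    ambs_trace = [current_ambs]
    es_trace = [current_es]
    truncated = False

    def unconverged() -> bool:
        return (
            abs(current_ambs - best_ambs) > best_ambs * cfg.eps1
            or abs(current_es - best_es) > abs(best_es) * cfg.eps2
        )

    while step < cfg.mstep and unconverged():
        if slice_size * 2 > d.n:
            truncated = True
            break
        slice_size *= 2
        best_ambs, best_es = current_ambs, current_es
        sliced = d.head(slice_size)
        graph = learner(sliced)
        current_ambs = ambs(graph)
        current_es = edge_strength(graph, sliced, cfg.ess)
        ambs_trace.append(current_ambs)
        es_trace.append(current_es)
        step += 1
    return ALSResult(
        als=sliced.n,
        ambs_trace=tuple(ambs_trace),
        es_trace=tuple(es_trace),
        steps=step,
        final_ambs=current_ambs,
        truncated=truncated,
    )
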