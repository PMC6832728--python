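# Methods

## The problem

Given a large dataset of N complete records over P categorical variables,
assumed iid draws from a distribution that is faithful to some directed
acyclic graph (DAG), the package estimates that DAG. Whole-dataset structure
learning is expensive and a single algorithm's accuracy varies by dataset, so
the package (a) estimates how much data a single learning call actually
needs, (b) runs three different learners on many data slices of that size,
and (c) merges everything by weighted voting into one structure.

## Scoring

Structures are scored with the BDeu (Bayesian Dirichlet equivalent uniform)
log marginal likelihood. For node $X_i$ with arity $r_i$, parent set
$\pi_i$ with $q_i$ joint configurations, counts $N_{ijk}$ (times $X_i=k$
while $\pi_i$ is in configuration $j$), and Dirichlet hyperparameters
$N'_{ijk} = \mathrm{ess}/(r_i q_i)$:

$$\log P(D \mid B) = \sum_i \sum_j \left[ \log\frac{\Gamma(N'_{ij})}{\Gamma(N'_{ij}+N_{ij})} + \sum_k \log\frac{\Gamma(N'_{ijk}+N_{ijk})}{\Gamma(N'_{ijk})} \right]$$

The uniform structure prior is constant under comparison and dropped. The
equivalent sample size defaults to `ess = 1` (the customary default of the R
implementations these algorithms come from); it is configurable everywhere.
Empty parent configurations contribute zero. The score is score-equivalent:
all DAGs in one Markov-equivalence class score identically, which the test
suite verifies by exhaustive enumeration of 3-node classes.

**Edge Strength.** $ES(B, D) = |\log P(D\mid B)| / (N \cdot M)$ for a
structure with $M \ge 1$ edges: the average score burden per edge per record.
Lower is better. An edgeless structure has no per-edge quantity; it receives
the sentinel $ES = +\infty$, weight 0, and is excluded from ensembles (a
no-edge network carries no votes).

**Structure weights.** Within an ensemble of structures $B_1..B_k$, weight
$W(B_i) = ES_i / \sum_j ES_j$. This is deliberately literal: the weight is
*proportional* to ES although lower ES means higher quality, so a slightly
worse structure gets a slightly larger weight. The worked merge example and
the voting threshold $\gamma = T\cdot\min_i W(B_i)$ are built on exactly this
convention, and with near-equal weights ($\approx 1/k$ each) the threshold
semantics reduce to "an edge needs strictly more than $T$ supporters", which
is what the layer-specific factors below rely on. The contradiction between
the weight direction and the quality direction is documented rather than
resolved; resolving it would change the worked example's arithmetic.

## The structure ensemble (one merge layer)

Given structures and a dataset: compute weights on that dataset, form the
final weighted adjacency matrix $FWAM = \sum_i W(B_i)\,AM_{B_i}$
(row = child, column = parent, everywhere in the package), set
$\gamma = T \cdot \min_i W(B_i)$, and add every entry with
$FWAM[c,p] > \gamma$ (strictly) as an edge $p \to c$ unless it would close a
directed cycle. Candidate entries are visited in descending vote value, ties
by ascending (child, parent), so stronger consensus edges win cycle
conflicts; this iteration order is a deterministic choice the algorithm's
statement leaves open. Consequences worth knowing:

- the merged edge set is a subset of the union of input edge sets;
- the output is always a DAG;
- with exactly two identical inputs and $T = 2$ the strict threshold cannot
  be cleared (each entry equals $2\cdot\min W$ exactly); two *distinct*
  inputs merge normally because their weights differ.

## Appropriate Learning Size

`calculate_als` reads a leading prefix of `initial_multiplier * P` records
(default 50 records per attribute — small enough to start below the
converged size for networks of this complexity, large enough for
non-degenerate learning), learns a structure, and repeatedly doubles the
prefix while either the average Markov blanket size (AMBS) of the learned
structure changes by more than `eps1` (relative) or its Edge Strength
changes by more than `eps2`, up to `mstep` doublings (default 20). Defaults
`eps1 = eps2 = 0.05`. `mstep` counts the maximum number of doublings, so
`mstep = 0` returns the initial slice untouched. The sentinels
(best AMBS 1, best ES −1) make the first comparison always continue, so at
least one doubling happens whenever `mstep ≥ 1`. Slices are leading
prefixes — the data is assumed iid, so no shuffling is performed. If a
doubling would overrun the dataset the run stops with `truncated=True` and
returns the last size actually learned.

The default learning call per slice is the three-algorithm slice ensemble
below; any learner with the same signature can be substituted (the
statement of the procedure leaves the learner abstract, and a single-learner
mode is useful for speed).

## Base learners

All searches are deterministic and start from the empty graph; no restarts.
Equal-score moves are ordered add < delete < reverse, then by ascending
(parent, child). Breaking ties by parent first is load-bearing: the two
orientations of a fresh edge score identically (score equivalence), and a
child-first order would always hand the lower-indexed node the other as a
parent, which systematically builds fork-shaped structures around hub nodes
and makes identifiable colliders unreachable by single moves.

- **Hill climbing**: accept the best strictly improving
  add/delete/reverse move; stop at a local optimum or `max_iterations`.
- **Tabu search**: identical while moves improve; at a local optimum it
  takes the best non-improving admissible move, keeps the inverses of the
  last `tabu_length` (default 10) decisions forbidden, lifts a taboo only
  for a move beating the incumbent, gives up after `2 * tabu_length`
  consecutive moves without a new incumbent, and returns the best DAG
  visited — hence never worse than hill climbing on the same input.
- **MMHC**: a hybrid. The max-min parents-and-children phase (MMPC) grows a
  candidate neighbour set per node using conditional G² independence tests
  (significance `alpha = 0.05`, conditioning sets capped at 3 variables),
  admitting the candidate with the largest minimum association over subsets
  of the current set and discarding any candidate some subset renders
  independent; a backward pass re-tests each member; edges must be found
  from both endpoints (AND rule). Hill climbing then runs with additions
  restricted to that skeleton.
- **Exhaustive search** (oracle only): enumerates every DAG on P ≤ 5 nodes
  (25 for P=3, 543 for P=4) and returns the BDeu-maximal one, ties broken by
  fewest edges then lexicographic adjacency.

The G² statistic is $2\sum o \ln(o/e)$ over the x×y table within each
stratum of the conditioning set; degrees of freedom are
(nonzero x-levels − 1)(nonzero y-levels − 1) summed over non-empty strata,
so structural zeros reduce the reference distribution rather than inflate
the statistic.

## The three layers

1. **Data-slice learner** (threshold factor T = 2): MMHC, hill climbing and
   tabu search each learn one structure from an ALS-sized slice; the three
   are merged. A learner that raises is dropped with a warning; with fewer
   than two survivors the best-ES survivor is returned as-is; if all three
   structures are edgeless the slice yields the empty graph.
2. **Local learner** (T = Nd/2): each of the K contiguous global partitions
   holds Nd = ⌊N/(K·ALS)⌋ slices (minimum 1; leftover rows join the last
   slice); the per-slice structures are merged, weighted on the slice whose
   merged structure had the lowest ES. An edge must appear in more than half
   of the slice structures.
3. **Global ensemble** (T = 2K/3): the K local structures are merged on the
   globally best slice; an edge needs more than two-thirds of the locals.

T values are used as exact reals. ALS is estimated once, on the first
partition, and shared. Local learners are pure functions of their partition
and configuration, so running them in parallel worker processes (joblib)
returns bit-identical results to a serial run; results are ordered by
partition index before the global merge. The counted work is
K·Nd slice-learning calls plus K + 1 merges — linear in Nd — and the run
report exposes those counts from actual instrumentation.

## Synthetic data

The generator produces the study conditions for every test:

- **Cancer fixture**: the five-node diagnosis network
  (Smoking → Bronchitis, Smoking → LungCancer, Bronchitis → Dyspnea,
  LungCancer → Dyspnea, LungCancer → Xray), 5 edges, true AMBS 12/5 = 2.4.
  The published form of this network specifies structure only, so the CPTs
  here are constructed by a fixed rule: roots are fair coins; each child's
  most likely state is the logical OR of its parent values and receives
  probability `cpt_strength` (default 0.9). The rule keeps every
  conditional bounded away from determinism, makes the single v-structure
  (at Dyspnea) identifiable, and makes all derived numbers reproducible.
- **Random networks**: uniform-ish DAGs via a random topological order plus
  random forward edges; CPT rows from a symmetric Dirichlet, or the same
  OR-gate rule applied to arbitrary binary DAGs (`or_gate_cpts`).
- **Forward sampling**: ancestral sampling in topological order;
  deterministic per seed (NumPy `default_rng`).
- **Degradation**: removes ⌈fraction·M⌉ random edges and rewires half of
  them to random acyclic positions — a model of one constituent algorithm
  failing badly.

What this emulates — and what it does not: the data is exactly iid and
exactly faithful to a known small network with clean, homogeneous CPTs.
Real sensor-style data has missingness, drift, hidden variables and far
larger networks; passing these tests demonstrates the correctness of the
machinery and its behavior in the regime the method was designed for, not
performance on any particular real domain.

### Trial conditions for oracle-agreement tests

The 3-variable agreement trials use random DAGs with 1–3 edges. Score-only
comparisons use Dirichlet(0.25) CPTs; the Markov-equivalence agreement
trials (which also exercise the independence tests inside MMPC) use the
OR-gate rule at strength 0.9, because symmetric-Dirichlet draws occasionally
produce a near-constant variable — a trial whose structure is unidentifiable
in principle and that no learner could pass.

## Problem sizes used by the tests and the acceptance script

Chosen once as the package's study conditions: end-to-end recovery uses
N = 400,000 records, K = 4 learners, 5 seeds; the learning-size study uses a
200,000-record stream with 10 seeds per slice size; the robustness study
uses the same conditions as the recovery study (N = 400,000, K = 4), 10
seeds, comparing the median SHD change across
seeds against the (zero) change of the untouched learners. Median is the
aggregator used throughout the slice-size study as well; per-seed SHD is an
integer-valued statistic that occasionally flips by one edge, and the
robustness claim concerns the aggregate behavior.

## Numerical choices and degenerate inputs

- All logs natural; gamma functions via `scipy.special.gammaln`; the test
  oracle recomputes scores with 60-digit `mpmath` arithmetic.
- Strict inequalities are kept strict (the voting threshold, score
  improvement > 1e-12); weights renormalise over participating structures.
- Empty dataset: BDeu score 0; Edge Strength undefined (error).
- Zero-margin strata in G² contribute nothing and shed degrees of freedom;
  dof 0 yields p = 1.
- A dataset column with a single observed level is padded to arity 2 on CSV
  read (a categorical variable needs at least two states).

## Known limitations

- The exhaustive oracle stops at 5 nodes by design.
- MMPC materialises full contingency tables; conditioning sets are capped at
  3 variables, which is fine for small-to-moderate arities.
- The weight-direction literalism means a very bad structure in a small
  ensemble can carry disproportionate weight; the layered majority voting is
  what keeps this from propagating (verified by the robustness study), but a
  two-member ensemble with one bad member has weak protection.
- ALS is estimated on the first partition only; heterogeneous (non-iid) data
  violates the assumptions of both the estimator and the slicing.
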