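"""Show that the layered ensemble tolerates one badly failing base learner.

One of the three slice-level algorithms is wrapped so its output loses half
its edges (some rewired at random); majority voting across algorithms and
slices filters the damage out of the final structure.
"""

import itertools
import warnings

import penbayes as pb
from penbayes.learners import hill_climb, mmhc, tabu_search
from penbayes.simulate import degrade_structure

truth = pb.cancer_fixture(cpt_strength=0.9)
data = pb.forward_sample(truth.network, 100_000, seed=5)
counter = itertools.count(0)


def broken_mmhc(d, cfg):
    return degrade_structure(mmhc(d, cfg), fraction=0.5, seed=next(counter))


with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    normal, _ = pb.run_penbayes(data, pb.PipelineConfig(k_learners=2, seed=5))
    damaged, _ = pb.run_penbayes(
        data,
        pb.PipelineConfig(
            k_learners=2, seed=5, base_learners=(broken_mmhc, hill_climb, tabu_search)
        ),
    )

tg = truth.network.graph
print("SHD with three healthy learners:", pb.shd(normal, tg))
print("SHD with one half-destroyed learner:", pb.shd(damaged, tg))

# The two healthy algorithms outvote the damaged one on every slice, and the
# damaged learner's random rewired edges differ across slices, so they never
# reach a majority: the final structure is unchanged.
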