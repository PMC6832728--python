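"""Forward-sample the Cancer network and score structures against the data.

Shows how the BDeu log score separates the true structure from a wrong one,
and how Edge Strength normalises the score per edge and record.
"""

import penbayes as pb

truth = pb.cancer_fixture(cpt_strength=0.9)
data = pb.forward_sample(truth.network, 20_000, seed=1)

true_graph = truth.network.graph
wrong = pb.DirectedGraph.from_edges(5, [(4, 0), (3, 1)])  # Xray->Smoking etc.

for name, g in [("true structure", true_graph), ("wrong structure", wrong)]:
    score = pb.bdeu_log_score(g, data)
    es = pb.edge_strength(g, data)
    print(f"{name}: log BDeu = {score:.1f}, Edge Strength = {es:.3f}")

# The true structure has the higher (less negative) score. Edge Strength is
# |score| / (N * edges): lower means each edge carries less score burden,
# i.e. a structurally better network.
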