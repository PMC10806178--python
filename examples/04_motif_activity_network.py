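"""Infer motif activities from promoter motif counts, build the TF->target
network from signal-to-noise scores above 2, and test directed enrichment
between gene groups (NEAT).

Prints edge recovery against the planted network, the NEAT test for a
TF's own target block, and the TF-target coexpression ranking head.
"""

import octempo as oc

net_truth, motif, cluster_expr = oc.generate_regulatory_truth(
    n_tfs=25, n_genes=1200, targets_per_tf=30, n_clusters=25, coupling=0.8, seed=2
)

E = cluster_expr.T.loc[motif.index]
E = E - E.to_numpy().mean(axis=1, keepdims=True)
act = oc.fit_motif_activity(E, motif, ridge_lambda="auto", seed=0)
print(f"ridge penalty chosen by 5-fold CV: {act.ridge_lambda:g}")

sig = oc.activity_significance(act, p_threshold=1e-3)
print(f"motifs with differential activity (p < 1e-3): {int(sig['differential'].sum())} of {len(sig)}")

scores = oc.score_targets(motif, act, threshold=2.0)
net = oc.build_network(scores, threshold=2.0)
true = set(map(tuple, net_truth.edges[["source", "target"]].to_numpy()))
pred = set(map(tuple, net.edges[["source", "target"]].to_numpy()))
tp = len(true & pred)
print(f"network: {net.W} edges; precision {tp/len(pred):.2f}, recall {tp/len(true):.2f}")

tf = net.out_degree.index[0]
res = oc.neat_test(net, {tf}, net.targets_of(tf))
print(f"NEAT {tf} -> its targets: observed {res['n_AB']}, expected {res['expected']:.1f}, "
      f"p = {res['pvalue']:.2e}")

ranking = oc.tf_target_coexpression(cluster_expr, net)
print("top TFs by Spearman rho(TF expression, summed target expression):")
print(ranking.head(3).to_string(index=False))
print("-> rho approaches the generator's coupling (0.8); the NEAT p is the"
      " exact degree-conditioned hypergeometric tail")
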