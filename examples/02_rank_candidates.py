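"""Rank novel interaction-partner candidates for a predictive seed set.

Builds the textbook configuration: a five-gene functional module in which
four members are known interaction partners of a query gene X. The fifth
module member should emerge as the top-ranked novel candidate. Also shows
the display cluster (edges above LLS 3.0, neighbors with >= 2 partner
links) used to visualize such predictions.
"""

from netgi import (
    FunctionalNetwork,
    SeedSet,
    evaluate_seed_set,
    extract_display_cluster,
    rank_candidates,
)

module = ["A", "B", "C", "D", "E"]
net = FunctionalNetwork()
for i in range(5):
    for j in range(i + 1, 5):
        net.add_edge(module[i], module[j], 3.5)
net.add_edge("F", "G", 1.5)  # unrelated genes
net.add_edge("B", "F", 0.5)
for i in range(20):
    net.add_gene(f"bg{i:02d}")  # background genes with no evidence

seed_set = SeedSet("X", frozenset(["A", "C", "D", "E"]), "Phenotypic Enhancement")
result = evaluate_seed_set(net, seed_set)
print(f"seed X, partners {sorted(seed_set.partners)}: AUC = {result.auc:.3f}")

candidates = rank_candidates(result, min_auc=0.9, top_k=5)
for c in candidates.entries:
    print(f"  rank {c.rank}: {c.gene}  score={c.score:.1f}  percentile={c.percentile:.1f}")
print("B tops the list: it is the one module member not yet known to "
      "interact with X, i.e. the predicted novel partner.")

cluster = extract_display_cluster(net, seed_set.partners, lls_cutoff=3.0, min_links=2)
print(f"\ndisplay cluster: {sorted(cluster.nodes)} "
      f"({cluster.n_edges} edges above LLS 3.0)")
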