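"""Clustering and tree-accuracy metrics between a predicted and a true
clonal tree."""

import jointphy as jp

cfg = jp.SimulationConfig(s=6, n=20, m=25, seed=3)
truth, D, counts = jp.simulate_dataset(cfg)
best = jp.run_search(D, counts,
                     jp.SearchConfig(chain_length=3000, restarts=2, seed=7,
                                     doublets=True))
pred = jp.compress_tree(best.tree, best.assignment, counts)

v = jp.v_measure(truth.partition, pred.partition())
ari = jp.adjusted_rand(truth.partition, pred.partition())
anc, sep, co = jp.pairwise_tree_accuracies(truth.tree, pred)
print(f"V-measure            = {v:.3f}   (partition agreement, entropy based)")
print(f"adjusted Rand index  = {ari:.3f}   (pair-counting, chance corrected)")
print(f"ancestry accuracy    = {anc:.3f}   (ancestor-descendant pairs kept, "
      "same direction)")
print(f"separate lineages    = {sep:.3f}   (branch separations kept)")
print(f"co-clustering        = {co:.3f}   (same-clone status agreement, "
      "all pairs)")
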