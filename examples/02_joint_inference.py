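"""Joint MCMC inference of the mutation tree from single-cell + bulk
data, compared against the generating truth."""

import jointphy as jp

cfg = jp.SimulationConfig(s=6, n=20, m=25, seed=3)
truth, D, counts = jp.simulate_dataset(cfg)

best = jp.run_search(D, counts,
                     jp.SearchConfig(chain_length=3000, restarts=2, seed=7,
                                     doublets=True))
print(f"S_joint = {best.s_joint:.2f}  (S_bulk = {best.s_bulk:.2f}, "
      f"S_sc = {best.s_sc:.2f})")
print(f"estimated dropout beta = {best.theta.beta:.3f} "
      f"(simulated with 0.2); doublet delta = {best.delta_hat:.3f}")
# S_bulk near 0 means the tree's subclone frequencies can reproduce the
# observed VAFs almost exactly; S_sc is the log-likelihood of the 25
# noisy cell profiles under the tree.
print("inferred parent vector:", best.tree.to_parent_string())
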