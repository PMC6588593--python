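"""Generate a benchmark dataset: clonal ground truth, noisy single-cell
mutation matrix and binomial bulk read counts."""

import numpy as np

import jointphy as jp

cfg = jp.SimulationConfig(s=6, n=20, m=25, h=1, lambda_=100, coverage=10_000,
                          alpha=1e-5, beta=0.2, na_rate=0.05,
                          doublet_rate=0.1, seed=3)
truth, D, counts = jp.simulate_dataset(cfg)

sizes = sorted(len(lab) for lab in truth.tree.labels)
print(f"true tree: {truth.tree.s} clones, label sizes {sizes}")
print(f"single-cell matrix: {D.n} mutations x {D.m} cells, "
      f"{(D.data == -1).mean():.1%} missing")
print(f"bulk: coverage {counts.t[0, 0]}, observed fractions z in "
      f"[{counts.z.min():.3f}, {counts.z.max():.3f}]")
# z approximates the true cell fraction of each mutation (2r/t ~ y):
err = np.abs(counts.z[:, 0] - truth.y[:, 0]).max()
print(f"max |z - true y| = {err:.4f}  (binomial noise at this coverage)")
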