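# jointphy

Joint inference of tumour mutation histories from **single-cell** and
**bulk** DNA sequencing data.

Single-cell sequencing resolves which mutations co-occur in the same
cell but is noisy (allelic dropout, false positives, missing entries,
doublets) and samples few cells; bulk sequencing measures variant allele
frequencies (VAFs) precisely but superimposes all subclones. `jointphy`
combines both: a Metropolis–Hastings search over **mutation trees**
scores every candidate tree *T* by

```
S_joint(T, θ) = S_bulk(T) + S_sc(T, θ)
```

* `S_sc(T, θ)` — log marginal likelihood of the observed mutation matrix
  `D` (rows mutations, columns cells, entries 0/1/NA) under the standard
  single-cell error model with false-positive rate α, false-negative
  rate β and doublet fraction δ. Cell attachments are marginalised over
  all n+1 tree nodes; each cell is a (1−δ, δ) mixture of a singlet and a
  doublet whose genotype is the union of two attachment lineages
  (computed in O(n²) per cell via lowest common ancestors); δ is
  maximised by golden-section search, and β (optionally α) is sampled by
  the chain.
* `S_bulk(T)` — the maximum over tree-constrained subclone frequencies
  φ (per sample: φ ≥ 0, Σφ = 1; mutation fraction `y = A_T φ` with A_T
  the ancestor matrix) of the Gaussian-approximated binomial
  log-likelihood of the variant/total read counts (r, t); with the
  variances evaluated at the observed fractions `z = 2r/t` this is a
  convex quadratic program, solved exactly per sample by non-negative
  least squares.

The best tree is **compressed into a clonal tree** by clustering each
branching-free chain on its inferred cell fractions with a 1-D Gaussian
mixture whose component variances are tied to their means through the
binomial read-count approximation (EM, AIC model selection, contiguity
enforced by dynamic programming). A **weight report** estimates the
relative information content of the two data types,
ρ = ΔS_bulk / ΔS_sc between the best tree and a one-clone baseline,
ω = ρ/(1+ρ).

The package also ships the **benchmark simulator** (random clonal trees,
λ-biased single-cell sampling, FP/FN/NA/doublet corruption, binomial
bulk counts, optional CNA perturbation) and the **evaluation metrics**
(V-measure, adjusted Rand index, pairwise ancestry / separate-lineage /
co-clustering tree accuracies).

## Worked example

```python
import jointphy as jp

# simulate a tumour with 6 subclones, 20 mutations, 25 cells, 1 bulk sample
cfg = jp.SimulationConfig(s=6, n=20, m=25, h=1, lambda_=100, coverage=10_000,
                          alpha=1e-5, beta=0.2, na_rate=0.05,
                          doublet_rate=0.1, seed=3)
truth, D, counts = jp.simulate_dataset(cfg)

best = jp.run_search(D, counts, jp.SearchConfig(chain_length=3000,
                                                restarts=2, seed=7,
                                                doublets=True))
clonal = jp.compress_tree(best.tree, best.assignment, counts)
print(f"S_joint={best.s_joint:.2f} (S_bulk={best.s_bulk:.2f}, "
      f"S_sc={best.s_sc:.2f}), beta_hat={best.theta.beta:.3f}, "
      f"delta_hat={best.delta_hat:.3f}")
print(f"{clonal.s} clones, V-measure = "
      f"{jp.v_measure(truth.partition, clonal.partition()):.3f}")
```

prints

```
S_joint=-143.81 (S_bulk=-1.47, S_sc=-142.34), beta_hat=0.143, delta_hat=0.285
6 clones, V-measure = 1.000
```

`S_bulk` near zero says the inferred tree explains the bulk VAFs almost
perfectly; `S_sc` is the log-likelihood of the 25 noisy cell profiles;
the estimated dropout rate β̂ and doublet fraction δ̂ are in the range
injected by the simulator; and the compressed clonal tree recovers the
true 6-clone mutation partition exactly (V-measure 1.0).

The same pipeline is available from the shell:

```bash
jointphy simulate -s 6 -n 20 -m 25 --seed 3 -o sim
jointphy infer -i sim.sc.txt -b sim.bulk.tsv -l 3000 -r 2 --doublet --seed 7 -o run
jointphy evaluate sim.truth.json run.json
```

See `examples/` for narrative scripts covering each capability.

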