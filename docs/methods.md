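# Methods

## Model

A tumour's mutation history is represented as a rooted **clonal tree**:
the root is the healthy population, every other node a subclone labelled
with the set of mutations it newly acquired, plus a per-sample
population frequency. Under the infinite-sites assumption each mutation
arises once and is never lost, so the mutations present in a subclone
are those on its root path. The **mutation tree** (one mutation per
node, s = n) is the search space; clonal trees arise by compression.
Topology is encoded by the ancestor matrix `A[i,j] = 1` iff node i is an
ancestor of j or i = j. Node indices are 1-based with the root at n+1,
also in serialised parent vectors.

### Bulk likelihood

For mutation i in sample j with variant/total read counts (r, t), the
variant read count is modelled Binomial(t, y/2), y the fraction of cells
carrying the mutation (heterozygous, diploid region). At high coverage
the binomial is approximated by a Gaussian; writing z = 2r/t, the
log-density is

    log 1/√(2π) − ½ log(t·(y/2)(1−y/2)) − t/(8(y/2)(1−y/2))·(z−y)².

Evaluating the variance at z instead of y makes the weights constant, so
maximising over tree-feasible y (y = A φ, φ on the per-sample
probability simplex including the healthy root) is a convex QP:

    S_bulk(T) = max_φ Σ_ij −w_ij (z_ij − y_ij)², w_ij = t/(8(z̃/2)(1−z̃/2)).

Numerical choices: z̃ clamps z to [10⁻³, 2−10⁻³] when forming weights
(they diverge at z ∈ {0, 2}); the raw z stays in the residual, and
mutations with z > 1 (CNA-suspect) are logged. The constant log-terms
are dropped from the optimisation but retained in
`gaussian_binomial_logdensity` for diagnostics. Samples separate, so the
QP is solved per sample. The solver is pluggable ("minimise convex
quadratic under linear constraints"); the default backend adds the
simplex slack as an extra variable with a quadratic penalty row, solves
the non-negative problem exactly with Lawson–Hanson NNLS, and removes
the penalty bias by iterated target correction (2–3 passes reach
equality residuals < 10⁻¹⁴). Verified in the tests against a
hierarchical simplex grid search and KKT conditions; relative KKT gaps
are below 10⁻⁶ across random instances up to n = 30 and coverage 10⁵.

### Single-cell likelihood

Observation model per entry: P(1|0) = α, P(0|1) = β, NA entries are
neutral (probability 1). Attachments are marginalised with a uniform
prior 1/(n+1); the attachment-pair prior for doublets is uniform over
the (n+1)² ordered pairs. These uniform priors are the only choice the
model's symbols admit without extra parameters and match the cited
single-cell samplers. Per cell, attachment log-likelihoods are computed
incrementally down the tree (O(nm) total); the doublet sum uses
path(u) ∪ path(v) = path(u) + path(v) − path(lca(u,v)), giving O(n²)
per cell with a cached per-topology LCA table. δ is maximised by
golden-section search on [0, 1) with tolerance 10⁻⁴ (the per-δ objective
is a sum of logs of linear functions, hence concave), warm-started from
the previous accepted state and compared against the δ = 0 endpoint.
All marginalisations run in log space.

### Search

Metropolis–Hastings over (T, θ) maximising S_joint = S_bulk + S_sc.
Moves and default mix: prune & reattach 0.55 (symmetric by counting:
same node, same excluded subtree ⇒ log q-ratio 0), subtree swap 0.20
(q-ratio = ratio of the counts of non-nested node pairs in the two
states), node-label exchange 0.15 (symmetric), θ-move 0.10
(multiplicative log-normal on β, scale 0.1, with q-ratio log β′ − log β;
α is fixed by default — it is poorly identified from few cells and a
platform prior is typically reliable — and learned only with an opt-in
flag; the θ prior is uniform on (0,1), proposals outside are rejected).
Move probabilities, proposal mechanics, chain length and restarts are
genuinely free design choices; all are exposed in `SearchConfig` with
these defaults. S_bulk depends only on topology and
is cached per parent vector, so θ-moves reuse it exactly; the reported
result is the maximum-score state across restarts (ties: first visited
wins, co-optimal topologies are logged). Initial tree random (seeded),
initial β from config (default 0.2).

### Compression

Maximal branching-free chains are extracted (every non-root node lies in
exactly one chain segment; the end node closest to the root belongs to
the segment above). Within a chain the bulk-inferred fractions y are
clustered with a 1-D Gaussian mixture whose component sd is tied to its
mean: sd² = (4/t̄)(μ/2)(1−μ/2), t̄ the responsibility-weighted mean
coverage of the component (recomputed each EM iteration; which t enters
the tied variance was an open choice). EM fits means and mixing weights;
k-quantile initialisation with 5 jittered restarts; convergence at
|Δloglik| < 10⁻⁸, cap 500 iterations (best-so-far with a warning
beyond). AIC = 2(kh + k − 1) − 2 loglik selects k ≤ min(len, 10); the
parameter count treats the per-sample means as kh parameters plus k−1
mixing weights (logged choice; with multiple samples the assignment is
shared and each component has one mean per sample). Because fractions
decrease down a chain, clusters must be contiguous; EM alone does not
guarantee this, so the fitted assignment is projected onto the best
contiguous segmentation with the same k by dynamic programming over
split points, and block means are refit. Merged clones take the union of
labels and the sum of φ; mutations on different branches can never
merge.

### Data-weight report

ρ = (S_bulk(T*) − S_bulk(T̂)) / (S_sc(T*) − S_sc(T̂)) with T̂ the
one-clone baseline (bulk: one shared y per sample, closed form; sc: two
attachment points). ω = ρ/(1+ρ). ω is reported only and never reweights
S_joint — the joint score is defined as the unweighted sum; a zero sc
range yields NA with a warning, and negative ranges pass through with a
warning (T* maximises the joint score, so either term alone may dip
below its baseline).

## Simulator

Emulates the standard benchmark family for joint single-cell + bulk
inference: uniform random clone topology
(Prüfer), each clone ≥ 1 mutation with the surplus spread multinomially
and mutation ids shuffled; prevalences (incl. healthy root) flat
Dirichlet per sample. Cell sampling: a distribution p over clones is
drawn once per dataset from Dirichlet(λ·s·prevalence) — large λ tracks
the prevalences, small λ distorts them. The Dirichlet mechanism is this
package's concrete choice for the λ bias; it reproduces the qualitative
behaviour the benchmark family describes (sampling probability "usually
close to" prevalence at large λ) with a single concentration knob. Cells are i.i.d. from p (first bulk
sample's prevalences when h > 1); genotype = root-path mutations.
Corruption order: doublets first (OR with a partner genotype resampled
from the drawn cells — physical mixing precedes amplification noise),
then FP/FN flips, then NA masking. Bulk: t = coverage (constant;
Poisson optional), r ~ Binomial(t, y/2). CNA injection multiplies y/2 of
chosen mutations by a factor from {0.5, 1.5} or U(0.5, 1.5) and redraws
r; ISA-violation injection is out of scope. Defaults: FP 10⁻⁵, FN 0.2, NA 0.05,
doublet 0.1, coverage 10⁴ — the regime of targeted single-cell panels
paired with deep bulk sequencing.

What the simulator does **not** emulate: real read-level noise,
copy-number profiles, per-site error-rate variation, spatial sampling,
mutation losses/recurrences. Passing the benchmark therefore shows the
estimator is correct and well-calibrated under its own generative
assumptions, not that those assumptions hold for any given tumour.

## Metrics

V-measure and adjusted Rand index (scikit-learn) compare mutation
partitions. Tree accuracy is pairwise: each unordered mutation pair is
classified per tree as same-clone / ancestor–descendant /
separate-lineage via first-occurrence nodes and the clonal ancestor
matrix; ancestry accuracy = fraction of truth ancestor–descendant pairs
reproduced with the same direction, separate-lineage accuracy =
fraction of truth separate pairs kept separate, co-clustering accuracy
= agreement rate of the same-clone indicator over all pairs. These
pairwise definitions are the standard family such benchmark measures
belong to; they are pluggable so alternative normalisations can be
dropped in.
Mutations absent from the predicted tree are excluded from the pair
universe; an empty truth class yields NaN.

## Problem sizes and defaults in the shipped experiments

The test suite and `scripts/acceptance.py` run the benchmark at a scaled
setting chosen to keep a laptop-class run short while preserving the
regime (clones < mutations, few noisy cells, deep bulk): s = 6 clones,
n = 20 mutations, m = 25 cells, h = 1 sample, chain length 3000 with 2
restarts, 6–10 replicates. Small-instance experiments (n = 3, m = 10)
use exhaustive tree enumeration as the oracle. Search-effort defaults in
the CLI are larger (chain 10⁵, 3 restarts) as appropriate for real data.

## Known limitations

* The bulk model assumes diploid heterozygous SNVs; CNAs only enter as a
  simulator perturbation, not in the likelihood.
* α is poorly identified at small m; learning it is opt-in.
* The MCMC is used as a maximiser; no posterior summaries are reported.
* Compression clusters within chains only; mutations on different
  branches with identical frequencies remain separate clones by design.
* ρ is undefined (NA) when the single-cell score range vanishes
  (e.g. n = 1, where the baseline tree is the only tree).
* δ̂ is an overestimate of the physical doublet rate: the doublet
  component contains the ordered pair (v, v), whose union genotype is
  the singlet genotype of v, so the mixture is only weakly identified in
  δ and surplus mass migrates to the doublet side. Tree recovery is
  insensitive to this.
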