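"""Benchmark simulator: ground-truth clonal trees with matched
single-cell and bulk data.

The generator emulates the benchmark conditions used to evaluate joint
single-cell + bulk inference: a uniformly random clonal tree with s
subclones over n mutations, flat-Dirichlet subclone prevalences, single
cells drawn from a clone-sampling distribution whose fidelity to the
prevalences is controlled by a concentration parameter lambda (large
lambda = faithful sampling), genotype corruption with false positives,
allelic-dropout false negatives, missing entries and doublets, and
binomial bulk read counts at fixed coverage.  An optional CNA injector
perturbs the binomial success probability of selected mutations.

Default rates reflect realistic targeted single-cell + bulk studies:
false-positive rate 1e-5, false-negative rate 0.2, missing rate 0.05,
doublet rate 0.1, coverage 10 000.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bulk import BulkCounts
from .singlecell import NA, SingleCellMatrix
from .trees import ClonalTree, build_ancestor_matrix, random_mutation_tree

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_ground_truth",
    "sample_cells",
    "corrupt_genotypes",
    "simulate_bulk",
    "apply_cna_shift",
    "simulate_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Benchmark scenario parameters (defaults: 10 clones, 50 mutations,
    25 cells at realistic error rates and deep bulk coverage)."""

    s: int = 10
    n: int = 50
    m: int = 25
    h: int = 1
    lambda_: float = 100.0
    coverage: int = 10_000
    alpha: float = 1e-5
    beta: float = 0.2
    na_rate: float = 0.05
    doublet_rate: float = 0.1
    cna_count: int = 0
    cna_mode: str = "discrete"  # factor from {0.5, 1.5}; "uniform": U(0.5, 1.5)
    poisson_coverage: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.s > self.n:
            raise ValueError("need s <= n (every clone acquires a mutation)")
        if self.s < 1 or self.m < 1 or self.h < 1:
            raise ValueError("s, m, h must be positive")
        for name in ("alpha", "beta", "na_rate", "doublet_rate"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be > 0")
        if self.cna_count > self.n:
            raise ValueError("cna_count cannot exceed n")


@dataclass
class GroundTruth:
    """True clonal tree, prevalences and derived quantities."""

    tree: ClonalTree
    clone_of_mutation: np.ndarray   # (n,) subclone index of each mutation, 1-based
    y: np.ndarray                   # (n, h) true cell fractions
    cna_events: List[Tuple[int, float]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.clone_of_mutation)

    @property
    def partition(self) -> Dict[int, int]:
        """True mutation clustering: mutation id -> clone."""
        return {i + 1: int(c) for i, c in enumerate(self.clone_of_mutation)}


def simulate_ground_truth(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> GroundTruth:
    """Uniform random clonal tree with flat-Dirichlet prevalences.

    Each clone acquires at least one mutation; the remaining n - s
    mutations are spread uniformly (multinomial) and mutation ids are
    shuffled across clones.  Prevalences over the s clones plus the
    healthy root are drawn per sample from a flat Dirichlet.
    """
    rng = rng or np.random.default_rng(config.seed)
    s, n, h = config.s, config.n, config.h
    topo = random_mutation_tree(s, rng)  # clone-level topology
    extra = rng.multinomial(n - s, np.full(s, 1.0 / s))
    sizes = 1 + extra
    muts = rng.permutation(np.arange(1, n + 1))
    labels, clone_of = [], np.zeros(n, dtype=np.int64)
    pos = 0
    for c in range(s):
        lab = frozenset(int(x) for x in muts[pos: pos + sizes[c]])
        labels.append(lab)
        for mid in lab:
            clone_of[mid - 1] = c + 1
        pos += sizes[c]
    phi = rng.dirichlet(np.ones(s + 1), size=h).T  # (s + 1, h), root last
    tree = ClonalTree(topo.parent, tuple(labels), phi)
    A = np.asarray(build_ancestor_matrix(topo), dtype=float)
    y_clone = A @ phi[:s, :]                      # fraction of cells at/below clone
    y = y_clone[clone_of - 1, :]
    return GroundTruth(tree, clone_of, y)


def sample_cells(
    truth: GroundTruth,
    m: int,
    lambda_: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw clean single-cell genotypes with lambda-biased clone sampling.

    A clone-sampling distribution p is drawn once per dataset from
    Dirichlet(lambda * s * prevalence) over the s tumour clones (healthy
    root excluded; prevalences of the first bulk sample, renormalised).
    Cells are i.i.d. from p; a cell's genotype carries the mutations on
    its clone's root path.  Large lambda concentrates p on the true
    prevalences; small lambda yields strongly distorted sampling.

    Returns (genotypes (n, m) 0/1, clone assignment (m,) 1-based).
    """
    if lambda_ <= 0:
        raise ValueError("lambda_ must be > 0")
    tree = truth.tree
    s = tree.s
    prev = tree.phi[:s, 0]
    prev = np.clip(prev, 1e-12, None)
    prev = prev / prev.sum()
    p = rng.dirichlet(lambda_ * s * prev)
    origins = rng.choice(s, size=m, p=p) + 1
    A = np.asarray(build_ancestor_matrix(tree.parent))
    n = truth.n
    clone_genotype = np.zeros((s, n), dtype=np.int8)
    for c in range(1, s + 1):
        anc = np.where(A[:, c - 1])[0] + 1  # clones on the root path of c
        for a in anc:
            for mid in tree.labels[a - 1]:
                clone_genotype[c - 1, mid - 1] = 1
    G = clone_genotype[origins - 1].T.copy()  # (n, m)
    return G, origins


def corrupt_genotypes(
    G: np.ndarray,
    alpha: float,
    beta: float,
    na_rate: float,
    doublet_rate: float,
    rng: np.random.Generator,
    partner_pool: Optional[np.ndarray] = None,
) -> SingleCellMatrix:
    """Inject doublets, then FP/FN flips, then missing entries.

    Doublets are formed first (physical cell mixing precedes amplification
    noise): with probability ``doublet_rate`` a cell's genotype is OR-ed
    with a second genotype sampled from ``partner_pool`` (columns; defaults
    to the clean matrix itself, i.e. the empirical clone-sampling
    distribution).  Then true 0s flip to 1 w.p. alpha, true 1s to 0 w.p.
    beta, and entries are masked NA w.p. ``na_rate``, independently.
    """
    G = np.asarray(G, dtype=np.int8)
    n, m = G.shape
    pool = G if partner_pool is None else np.asarray(partner_pool, dtype=np.int8)
    out = G.copy()
    is_doublet = rng.random(m) < doublet_rate
    partners = rng.integers(0, pool.shape[1], size=m)
    for j in np.where(is_doublet)[0]:
        out[:, j] = out[:, j] | pool[:, partners[j]]
    flips = rng.random((n, m))
    fp = (out == 0) & (flips < alpha)
    fn = (out == 1) & (flips < beta)
    out = np.where(fp, 1, np.where(fn, 0, out)).astype(np.int8)
    out[rng.random((n, m)) < na_rate] = NA
    return SingleCellMatrix(out)


def simulate_bulk(
    truth: GroundTruth,
    coverage: int,
    rng: np.random.Generator,
    poisson_coverage: bool = False,
) -> BulkCounts:
    """Binomial bulk read counts: t = coverage, r ~ Binomial(t, y/2)."""
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    n, h = truth.y.shape
    if poisson_coverage:
        t = np.clip(rng.poisson(coverage, size=(n, h)), 1, None)
    else:
        t = np.full((n, h), coverage, dtype=np.int64)
    r = rng.binomial(t, truth.y / 2.0)
    return BulkCounts(r=r, t=t)


def apply_cna_shift(
    counts: BulkCounts,
    truth: GroundTruth,
    cna_count: int,
    rng: np.random.Generator,
    mode: str = "discrete",
) -> BulkCounts:
    """Redraw counts for ``cna_count`` random mutations with a perturbed
    success probability y/2 * f, f from {0.5, 1.5} (``mode='discrete'``)
    or U(0.5, 1.5) (``mode='uniform'``), clipped to [0, 1].  The affected
    mutations and factors are recorded on ``truth.cna_events``."""
    if cna_count > counts.n:
        raise ValueError("cna_count cannot exceed the number of mutations")
    r = counts.r.copy()
    if cna_count:
        chosen = rng.choice(counts.n, size=cna_count, replace=False)
        for i in chosen:
            f = (0.5 if rng.random() < 0.5 else 1.5) if mode == "discrete" \
                else rng.uniform(0.5, 1.5)
            p = np.clip(truth.y[i] / 2.0 * f, 0.0, 1.0)
            r[i] = rng.binomial(counts.t[i], p)
            truth.cna_events.append((int(i) + 1, float(f)))
    return BulkCounts(r=r, t=counts.t, mutation_ids=counts.mutation_ids)


def simulate_dataset(
    config: SimulationConfig,
) -> Tuple[GroundTruth, SingleCellMatrix, BulkCounts]:
    """Full benchmark dataset: ground truth, corrupted SC matrix, bulk counts."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_ground_truth(config, rng)
    G, _ = sample_cells(truth, config.m, config.lambda_, rng)
    D = corrupt_genotypes(G, config.alpha, config.beta, config.na_rate,
                          config.doublet_rate, rng)
    counts = simulate_bulk(truth, config.coverage, rng,
                           config.poisson_coverage)
    if config.cna_count:
        counts = apply_cna_shift(counts, truth, config.cna_count, rng,
                                 config.cna_mode)
    return truth, D, counts
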