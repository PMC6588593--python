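"""Independent brute-force oracles used by the test suite.

These deliberately avoid every fast path in the package: enumeration
over attachments and attachment pairs for the single-cell likelihood,
and hierarchical grid search over the frequency simplex for the bulk
score.
"""

import itertools

import numpy as np

from jointphy.trees import MutationTree, build_ancestor_matrix


def mutation_tree_from_singleton_clonal(ct) -> MutationTree:
    """Invert the s = n special case: clonal tree with singleton labels
    back to the mutation tree over mutation ids."""
    mut_of = {c: next(iter(ct.labels[c - 1])) for c in range(1, ct.s + 1)}
    parent = [0] * ct.s
    for c in range(1, ct.s + 1):
        p = ct.parent[c - 1]
        parent[mut_of[c] - 1] = ct.s + 1 if p == ct.root else mut_of[p]
    return MutationTree(tuple(parent))


def genotype_of(tree: MutationTree, node: int) -> np.ndarray:
    """0/1 genotype of a cell attached at ``node`` (root = all zeros)."""
    A = np.asarray(build_ancestor_matrix(tree))
    if node == tree.n + 1:
        return np.zeros(tree.n, dtype=np.int8)
    return A[:, node - 1].astype(np.int8)


def column_likelihood(column, genotype, alpha, beta) -> float:
    p = 1.0
    for d, g in zip(column, genotype):
        if d == -1:
            continue
        if g == 1:
            p *= (1.0 - beta) if d == 1 else beta
        else:
            p *= alpha if d == 1 else (1.0 - alpha)
    return p


def brute_singlet(column, tree, theta) -> float:
    nodes = list(range(1, tree.n + 2))
    return sum(
        column_likelihood(column, genotype_of(tree, v), theta.alpha, theta.beta)
        for v in nodes
    ) / len(nodes)


def brute_doublet(column, tree, theta) -> float:
    nodes = list(range(1, tree.n + 2))
    total = 0.0
    for u in nodes:
        gu = genotype_of(tree, u)
        for v in nodes:
            g = np.maximum(gu, genotype_of(tree, v))
            total += column_likelihood(column, g, theta.alpha, theta.beta)
    return total / len(nodes) ** 2


def brute_sc_score(D, tree, theta, delta_grid=None) -> float:
    """log marginal likelihood maximised over delta on a fine grid."""
    singlets = [brute_singlet(D.data[:, j], tree, theta) for j in range(D.m)]
    if delta_grid is None:
        return float(np.sum(np.log(singlets)))
    doublets = [brute_doublet(D.data[:, j], tree, theta) for j in range(D.m)]
    best = -np.inf
    for d in delta_grid:
        val = float(np.sum(np.log(
            [(1 - d) * s + d * b for s, b in zip(singlets, doublets)])))
        best = max(best, val)
    return best


def _simplex_grid(dim, step):
    """All points of the probability simplex lattice with spacing ``step``."""
    units = int(round(1.0 / step))
    for comp in itertools.combinations(range(units + dim - 1), dim - 1):
        parts = []
        prev = -1
        for c in comp:
            parts.append(c - prev - 1)
            prev = c
        parts.append(units + dim - 2 - prev)
        yield np.array(parts, dtype=float) * step


def grid_bulk_score(tree, z, w, step=0.01, refine_steps=2) -> float:
    """Hierarchical grid-search maximum of the bulk objective.

    Enumerates phi (including the root component) on a simplex lattice,
    then refines locally around the incumbent with a 10x finer lattice,
    ``refine_steps`` times.  Pure enumeration; independent of the QP.
    """
    A = np.asarray(build_ancestor_matrix(tree), dtype=float)
    n = tree.n

    def value(phi_nonroot):
        y = A @ phi_nonroot
        return float(-np.dot(w, (z - y) ** 2))

    best_phi, best_val = None, -np.inf
    for phi in _simplex_grid(n + 1, step):
        v = value(phi[:n])
        if v > best_val:
            best_val, best_phi = v, phi
    cur_step = step
    for _ in range(refine_steps):
        fine = cur_step / 10.0
        units = int(round(1.0 / fine))
        base = np.round(best_phi / fine).astype(int)
        lo = np.maximum(base - 12, 0)
        hi = np.minimum(base + 12, units)
        ranges = [range(int(l), int(h) + 1) for l, h in zip(lo[:-1], hi[:-1])]
        for comb in itertools.product(*ranges):
            rest = units - sum(comb)
            if rest < lo[-1] or rest > hi[-1]:
                continue
            phi = np.array(list(comb) + [rest], dtype=float) * fine
            v = value(phi[:n])
            if v > best_val:
                best_val, best_phi = v, phi
        cur_step = fine
    return best_val
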