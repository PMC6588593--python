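"""Single-cell tree score S_sc.

The observed mutation matrix D (rows mutations, columns cells, entries
0/1/NA) is scored against a mutation tree under the standard single-cell
error model: a true-0 entry is read as 1 with false-positive rate alpha,
a true-1 entry is read as 0 with false-negative rate beta (allelic
dropout), and missing entries are neutral.  Cell attachments are
marginalised with a uniform prior over the n + 1 nodes; each cell is a
mixture of a singlet and (with probability delta) a doublet whose
genotype is the union of two attachment lineages.  S_sc is the log of
the marginal likelihood, maximised over delta.

The doublet sum over (n+1)^2 ordered attachment pairs is computed in
O(n^2) per cell using the identity that the intersection of two root
paths is the root path of the pair's lowest common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from scipy.special import logsumexp

from .trees import MutationTree, build_ancestor_matrix

__all__ = [
    "SingleCellMatrix",
    "ErrorModel",
    "attachment_loglik",
    "attachment_logliks",
    "marginal_singlet_likelihood",
    "doublet_mixture_likelihood",
    "attachment_posterior",
    "score_sc",
]

#: sentinel for a missing (NA) entry in the integer-coded matrix
NA = -1


@dataclass(frozen=True)
class SingleCellMatrix:
    """Observed mutation states, shape (n mutations, m cells); NA == -1."""

    data: np.ndarray
    mutation_ids: Tuple[str, ...] = ()

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.data, dtype=np.int8))
        if not np.isin(d, (0, 1, NA)).all():
            raise ValueError("matrix entries must be 0, 1 or NA (-1)")
        object.__setattr__(self, "data", d)
        ids = tuple(self.mutation_ids) or tuple(
            f"M{i}" for i in range(1, d.shape[0] + 1)
        )
        if len(ids) != d.shape[0]:
            raise ValueError("one mutation id per row required")
        object.__setattr__(self, "mutation_ids", ids)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ErrorModel:
    """Single-cell noise rates: false positive alpha, false negative beta,
    doublet probability delta."""

    alpha: float = 1e-5
    beta: float = 0.2
    delta: float = 0.0

    def __post_init__(self):
        for name in ("alpha", "beta", "delta"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")

    def with_(self, **kw) -> "ErrorModel":
        return replace(self, **kw)


def _per_entry_logs(D: np.ndarray, theta: ErrorModel):
    """log P(entry | true state 0) and the log-ratio added when the true
    state flips to 1; NA entries contribute 0 to both."""
    with np.errstate(divide="ignore"):
        la, l1a = np.log(theta.alpha), np.log1p(-theta.alpha)
        lb, l1b = np.log(theta.beta), np.log1p(-theta.beta)
    log0 = np.where(D == 1, la, np.where(D == 0, l1a, 0.0))
    log1 = np.where(D == 1, l1b, np.where(D == 0, lb, 0.0))
    return log0, log1 - log0


def _path_sums(tree: MutationTree, delta_logs: np.ndarray) -> np.ndarray:
    """S[c, v] = sum of per-entry log-ratios over the root path of node v
    (columns ordered node 1..n, then root)."""
    m = delta_logs.shape[1]
    n = tree.n
    S = np.zeros((m, n + 1))
    ch = tree.children()
    stack = list(ch[tree.root])
    while stack:
        v = stack.pop()
        p = tree.parent[v - 1]
        p_col = n if p == tree.root else p - 1
        S[:, v - 1] = S[:, p_col] + delta_logs[v - 1]
        stack.extend(ch[v])
    return S


def attachment_logliks(
    D: SingleCellMatrix, tree: MutationTree, theta: ErrorModel
) -> np.ndarray:
    """Log-likelihood of every cell at every attachment.

    Returns shape (m, n + 1); column v - 1 is attachment at node v, the
    last column is attachment at the root (no mutations).
    """
    log0, dlog = _per_entry_logs(D.data, theta)
    base = log0.sum(axis=0)  # per cell, genotype all-zero
    S = _path_sums(tree, dlog)
    return base[:, None] + S


def attachment_loglik(
    column: np.ndarray, tree: MutationTree, theta: ErrorModel, node: int
) -> float:
    """Log-likelihood of one cell column attached at ``node`` (root allowed)."""
    if not 1 <= node <= tree.n + 1:
        raise ValueError("attachment node out of range")
    D = SingleCellMatrix(np.asarray(column).reshape(-1, 1))
    L = attachment_logliks(D, tree, theta)
    col = tree.n if node == tree.n + 1 else node - 1
    return float(L[0, col])


def marginal_singlet_likelihood(
    column: np.ndarray, tree: MutationTree, theta: ErrorModel
) -> float:
    """Attachment-marginalised likelihood of one cell (linear scale),
    uniform prior 1/(n+1) over attachments."""
    D = SingleCellMatrix(np.asarray(column).reshape(-1, 1))
    L = attachment_logliks(D, tree, theta)
    return float(np.exp(logsumexp(L[0]) - np.log(tree.n + 1)))


@lru_cache(maxsize=4096)
def _lca_columns_cached(parent: Tuple[int, ...]) -> np.ndarray:
    n = len(parent)
    A = np.asarray(build_ancestor_matrix(parent), dtype=bool)
    depth = A.sum(axis=0)
    # deepest common ancestor of each ordered node pair, vectorised:
    # weight each ancestor by depth + 1 and take the argmax over rows.
    cols = np.full((n + 1, n + 1), n, dtype=np.int64)  # default: root
    common = A[:, :, None] & A[:, None, :]             # (anc, u, v)
    weighted = np.where(common, depth[:, None, None] + 1, 0)
    any_common = common.any(axis=0)
    lca = weighted.argmax(axis=0)
    cols[:n, :n] = np.where(any_common, lca, n)
    cols.setflags(write=False)
    return cols


def _lca_columns(tree: MutationTree) -> np.ndarray:
    """Column index (into the (n+1)-wide attachment arrays) of the LCA of
    every ordered node pair, root included; cached per topology."""
    return _lca_columns_cached(tree.parent)


def _log_singlet_doublet(
    D: SingleCellMatrix, tree: MutationTree, theta: ErrorModel,
    doublets: bool,
):
    """Per-cell log singlet marginal and (optionally) log doublet marginal."""
    n = tree.n
    log0, dlog = _per_entry_logs(D.data, theta)
    base = log0.sum(axis=0)
    S = _path_sums(tree, dlog)
    log_singlet = logsumexp(S, axis=1) - np.log(n + 1) + base
    if not doublets:
        return log_singlet, None
    lca = _lca_columns(tree)
    # pair sum: S[u] + S[v] - S[lca(u, v)] for all ordered pairs
    pair = S[:, :, None] + S[:, None, :] - S[:, lca]
    log_doublet = (
        logsumexp(pair.reshape(D.m, -1), axis=1) - 2.0 * np.log(n + 1) + base
    )
    return log_singlet, log_doublet


def doublet_mixture_likelihood(
    column: np.ndarray, tree: MutationTree, theta: ErrorModel
) -> float:
    """Likelihood of one cell as a delta-weighted singlet/doublet mixture.

    The doublet component averages, uniformly over the (n+1)^2 ordered
    attachment pairs, the likelihood of the column against the union
    genotype of the two attachment lineages.
    """
    D = SingleCellMatrix(np.asarray(column).reshape(-1, 1))
    ls, ld = _log_singlet_doublet(D, tree, theta, doublets=True)
    d = theta.delta
    return float((1.0 - d) * np.exp(ls[0]) + d * np.exp(ld[0]))


def attachment_posterior(
    D: SingleCellMatrix, tree: MutationTree, theta: ErrorModel
) -> np.ndarray:
    """Posterior over attachments per cell (uniform prior), shape (m, n+1)."""
    L = attachment_logliks(D, tree, theta)
    return np.exp(L - logsumexp(L, axis=1, keepdims=True))


def _golden_section_max(f, lo: float, hi: float, tol: float = 1e-4) -> float:
    """Maximiser of a unimodal f on [lo, hi] by golden-section search."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def score_sc(
    D: SingleCellMatrix,
    tree: MutationTree,
    theta: ErrorModel,
    doublets: bool = True,
    delta_init: Optional[float] = None,
) -> Tuple[float, float]:
    """Log marginal likelihood of the mutation matrix under the tree.

    Returns ``(S_sc, delta_hat)``.  With ``doublets=True`` the per-cell
    mixture weight delta is maximised over [0, 1) by golden-section search
    (the objective is concave in delta); with ``doublets=False`` the
    singlet marginal is returned and ``delta_hat = 0``.
    """
    if D.m == 0:
        raise ValueError("mutation matrix has no cells")
    if D.n != tree.n:
        raise ValueError("matrix and tree cover different mutation sets")
    ls, ld = _log_singlet_doublet(D, tree, theta, doublets)
    if not doublets:
        return float(ls.sum()), 0.0

    def objective(delta: float) -> float:
        if delta <= 0.0:
            return float(ls.sum())
        return float(
            np.logaddexp(np.log1p(-delta) + ls, np.log(delta) + ld).sum()
        )

    hi = 1.0 - 1e-9
    delta_hat = _golden_section_max(objective, 0.0, hi)
    # the golden bracket never lands exactly on the endpoints; compare them
    candidates = [0.0, delta_hat]
    if delta_init is not None and 0.0 <= delta_init < 1.0:
        candidates.append(delta_init)
    best = max(candidates, key=objective)
    return objective(best), best
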