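"""Compression of a mutation tree into a clonal tree.

Mutations on a branching-free chain of the inferred mutation tree whose
bulk-inferred cell fractions are statistically indistinguishable are
merged into a single subclone.  Per chain, the fractions are clustered
with a one-dimensional Gaussian mixture whose component standard
deviation is tied to its mean through the binomial read-count
approximation, sd(mu)^2 = (4 / t)(mu/2)(1 - mu/2); only the component
means (one per bulk sample) and the assignment are free, fitted by EM
with the number of components selected by AIC.  Because the fractions
decrease down a chain, only consecutive mutations may share a cluster;
the EM assignment is projected onto the best contiguous segmentation by
dynamic programming.  Mutations on different branches never merge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bulk import BulkCounts, FrequencyAssignment
from .trees import ClonalTree, MutationTree

__all__ = ["Chain", "extract_chains", "cluster_chain", "compress_tree"]

logger = logging.getLogger(__name__)

_VAR_EPS = 1e-3  # clamp on mu when forming the tied variance
_SD_FLOOR = 1e-6


@dataclass(frozen=True)
class Chain:
    """A maximal branching-free path; ``nodes`` lists the clusterable
    segment top-to-bottom (the end node closest to the root is already
    discarded)."""

    nodes: Tuple[int, ...]


def extract_chains(tree: MutationTree) -> List[Chain]:
    """Split the tree into maximal linear chains.

    A chain starts below the root or below a branching node and runs until
    the next node with zero or several children.  The clusterable segments
    partition the non-root nodes.
    """
    ch = tree.children()
    chains: List[Chain] = []
    starts: List[int] = list(ch[tree.root])
    while starts:
        v = starts.pop()
        seg = [v]
        while len(ch[seg[-1]]) == 1:
            seg.append(ch[seg[-1]][0])
        starts.extend(ch[seg[-1]])
        chains.append(Chain(tuple(seg)))
    return chains


def _tied_sd(mu: np.ndarray, tbar: np.ndarray) -> np.ndarray:
    muc = np.clip(mu, _VAR_EPS, 2.0 - _VAR_EPS)
    tc = np.clip(tbar, 1.0, None)  # empty components have no coverage mass
    return np.sqrt((4.0 / tc) * (muc / 2.0) * (1.0 - muc / 2.0)) + _SD_FLOOR


def _log_normal_pdf(y, mu, sd):
    return -0.5 * np.log(2.0 * np.pi) - np.log(sd) - 0.5 * ((y - mu) / sd) ** 2


def _em_fit(y: np.ndarray, t: np.ndarray, k: int, mu0: np.ndarray,
            max_iter: int = 500, tol: float = 1e-8):
    """EM for the tied-variance mixture; returns (loglik, mu, pi, resp)."""
    L, h = y.shape
    mu = mu0.copy()  # (k, h)
    pi = np.full(k, 1.0 / k)
    tbar = np.tile(t.mean(axis=0), (k, 1))  # (k, h), refined each iteration
    prev = -np.inf
    loglik = -np.inf
    resp = np.full((L, k), 1.0 / k)
    for _ in range(max_iter):
        sd = _tied_sd(mu, tbar)
        logp = np.zeros((L, k))
        for c in range(k):
            logp[:, c] = _log_normal_pdf(y, mu[c], sd[c]).sum(axis=1)
        logw = np.log(pi)[None, :] + logp
        norm = np.logaddexp.reduce(logw, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(logw - norm[:, None])
        if abs(loglik - prev) < tol:
            break
        prev = loglik
        w = resp.sum(axis=0)  # (k,)
        pi = np.clip(w / L, 1e-12, None)
        pi /= pi.sum()
        safe = np.clip(w, 1e-12, None)
        mu = (resp.T @ y) / safe[:, None]
        tbar = (resp.T @ t) / safe[:, None]
    else:
        logger.warning("chain EM hit the iteration cap; using best-so-far fit")
    return loglik, mu, pi, resp


def _contiguous_projection(y: np.ndarray, t: np.ndarray, mu: np.ndarray,
                           k: int) -> np.ndarray:
    """Best contiguous segmentation into k non-empty blocks mapped, in chain
    order, to the components sorted by decreasing mean; DP over split points."""
    L, h = y.shape
    order = np.argsort(-mu.mean(axis=1))
    mu_ord = mu[order]
    tbar = np.tile(t.mean(axis=0), (k, 1))
    sd = _tied_sd(mu_ord, tbar)
    logp = np.zeros((L, k))
    for c in range(k):
        logp[:, c] = _log_normal_pdf(y, mu_ord[c], sd[c]).sum(axis=1)
    NEG = -np.inf
    # dp[i, c]: best score assigning mutations 0..i-1 to components 0..c
    dp = np.full((L + 1, k), NEG)
    back = np.zeros((L + 1, k), dtype=np.int64)
    cum = np.vstack([np.zeros(k), np.cumsum(logp, axis=0)])
    for i in range(1, L + 1):
        dp[i, 0] = cum[i, 0]
    for c in range(1, k):
        for i in range(c + 1, L + 1):
            cand = dp[c:i, c - 1] + (cum[i, c] - cum[c:i, c])
            j = int(np.argmax(cand))
            dp[i, c] = cand[j]
            back[i, c] = j + c
    labels = np.zeros(L, dtype=np.int64)
    i, c = L, k - 1
    while c > 0:
        j = back[i, c]
        labels[j:i] = c
        i, c = j, c - 1
    labels[:i] = 0
    return labels


def cluster_chain(
    y: np.ndarray,
    t: np.ndarray,
    max_k: Optional[int] = None,
    n_restarts: int = 5,
) -> Tuple[int, np.ndarray, np.ndarray]:
    """Cluster one chain segment's fractions.

    Parameters
    ----------
    y
        Inferred cell fractions, shape (segment length, h samples), ordered
        top-to-bottom along the chain (non-increasing within tolerance).
    t
        Matching total read counts, same shape.
    max_k
        Largest number of components tried (default: segment length, capped
        at 10).

    Returns
    -------
    (k, labels, means)
        Selected component count, contiguous cluster label per mutation
        (0-based, in chain order) and per-sample component means, shape
        (k, h).  With multiple samples the assignment is shared and each
        component has one mean per sample.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    t = np.asarray(t, dtype=float)
    if t.ndim == 1:
        t = t[:, None]
    t = np.broadcast_to(t, y.shape).copy()
    L, h = y.shape
    if L == 0:
        return 0, np.zeros(0, dtype=np.int64), np.zeros((0, h))
    cap = min(L, 10) if max_k is None else min(max_k, L)
    best = None
    for k in range(1, cap + 1):
        # k-quantile initialisation plus jittered restarts
        qs = np.quantile(y, np.linspace(0.9, 0.1, k), axis=0)
        fits = []
        for r in range(n_restarts if k > 1 else 1):
            rng = np.random.default_rng(r)
            mu0 = qs if r == 0 else np.clip(
                qs * np.exp(0.05 * rng.standard_normal(qs.shape)), 0.0, 2.0)
            fits.append(_em_fit(y, t, k, mu0))
        loglik, mu, pi, resp = max(fits, key=lambda f: f[0])
        n_params = k * h + (k - 1)  # per-sample means + mixing weights
        aic = 2.0 * n_params - 2.0 * loglik
        if best is None or aic < best[0]:
            best = (aic, k, mu, pi)
    _, k, mu, pi = best
    if k == 1:
        return 1, np.zeros(L, dtype=np.int64), mu
    labels = _contiguous_projection(y, t, mu, k)
    # refit block means from the final contiguous assignment
    means = np.vstack([y[labels == c].mean(axis=0) for c in range(k)])
    return k, labels, means


def compress_tree(
    tree: MutationTree,
    assignment: FrequencyAssignment,
    counts: BulkCounts,
    max_k: Optional[int] = None,
) -> ClonalTree:
    """Merge statistically indistinguishable chain mutations into clones.

    ``assignment`` is the bulk QP solution for ``tree``; merged clone
    labels are the unions of the merged mutations and clone frequencies
    are the sums of the merged nodes' phi.  Ancestry is preserved and
    mutations on different branches never share a clone.
    """
    n = tree.n
    phi = assignment.phi
    y = assignment.y
    group_of: Dict[int, int] = {}
    groups: List[List[int]] = []
    for chain in extract_chains(tree):
        seg = list(chain.nodes)
        idx = [v - 1 for v in seg]
        k, labels, _ = cluster_chain(y[idx, :], counts.t[idx, :], max_k=max_k)
        for c in range(k):
            members = [seg[i] for i in range(len(seg)) if labels[i] == c]
            group_of.update({v: len(groups) for v in members})
            groups.append(members)
    s = len(groups)
    # clone order: by the original index of each group's topmost node
    top = [min(g, key=lambda v: _depth(tree, v)) for g in groups]
    order = sorted(range(s), key=lambda g: (_depth(tree, top[g]), top[g]))
    rank = {g: i + 1 for i, g in enumerate(order)}
    parent = [0] * s
    labels_out: List[frozenset] = [frozenset()] * s
    phi_out = np.zeros((s + 1, phi.shape[1]))
    for g, members in enumerate(groups):
        i = rank[g]
        p = tree.parent[top[g] - 1]
        parent[i - 1] = s + 1 if p == tree.root else rank[group_of[p]]
        labels_out[i - 1] = frozenset(members)
        phi_out[i - 1] = phi[[v - 1 for v in members], :].sum(axis=0)
    phi_out[s] = phi[n]
    # guard against solver round-off before validation
    phi_out = np.clip(phi_out, 0.0, None)
    phi_out /= phi_out.sum(axis=0, keepdims=True)
    return ClonalTree(tuple(parent), tuple(labels_out), phi_out)


def _depth(tree: MutationTree, v: int) -> int:
    d = 0
    while v != tree.root:
        v = tree.parent[v - 1]
        d += 1
    return d
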