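"""Metropolis–Hastings search over (mutation tree, error rates).

The chain maximises the joint score S_joint = S_bulk + S_sc.  Tree
proposals are the classic mutation-tree moves (prune & reattach, subtree
swap, node-label exchange) plus a multiplicative log-normal perturbation
of the error rates; acceptance is min{1, q * exp(ΔS_joint)} with q the
proposal-density ratio.  S_bulk depends only on the tree, so it is cached
per topology and reused across theta moves; the reported result is the
maximum-score state visited across all restarts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .bulk import BulkCounts, FrequencyAssignment, score_bulk
from .singlecell import ErrorModel, SingleCellMatrix, score_sc
from .trees import MutationTree, build_ancestor_matrix, random_mutation_tree

__all__ = [
    "SearchState",
    "SearchConfig",
    "propose",
    "acceptance_probability",
    "run_search",
]

logger = logging.getLogger(__name__)

MOVES = ("prune_reattach", "swap_subtrees", "swap_labels", "theta")


@dataclass(frozen=True)
class SearchState:
    """One point of the search space with cached scores."""

    tree: MutationTree
    theta: ErrorModel
    s_bulk: float
    s_sc: float
    delta_hat: float = 0.0
    assignment: Optional[FrequencyAssignment] = None

    @property
    def s_joint(self) -> float:
        return self.s_bulk + self.s_sc


@dataclass(frozen=True)
class SearchConfig:
    """Chain configuration.

    ``move_probs`` orders (prune & reattach, subtree swap, label exchange,
    theta move) and must sum to one.  With ``learn_alpha=False`` (default)
    the false-positive rate stays fixed at ``alpha``: alpha is poorly
    identified from few cells, and a reliable prior estimate is typically
    available from the sequencing platform.
    """

    chain_length: int = 10_000
    restarts: int = 1
    seed: int = 0
    move_probs: Tuple[float, float, float, float] = (0.55, 0.20, 0.15, 0.10)
    theta_scale: float = 0.1
    doublets: bool = False
    learn_alpha: bool = False
    alpha: float = 1e-5
    beta: float = 0.2
    use_bulk: bool = True
    trace_every: int = 0  # 0 disables trace recording

    def __post_init__(self):
        if self.chain_length < 0:
            raise ValueError("chain_length must be >= 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if abs(sum(self.move_probs) - 1.0) > 1e-9:
            raise ValueError("move probabilities must sum to 1")


def _count_swap_pairs(tree: MutationTree) -> int:
    """Unordered node pairs where neither is an ancestor of the other."""
    A = build_ancestor_matrix(tree)
    n = tree.n
    strict = int(A.sum()) - n  # strict ancestor relations
    return (n * (n - 1) - 2 * strict) // 2


def _swap_label_tree(tree: MutationTree, i: int, j: int) -> MutationTree:
    """Exchange the mutation labels of nodes i and j."""

    def sig(v: int) -> int:
        return j if v == i else i if v == j else v

    parent = [0] * tree.n
    for v in range(1, tree.n + 1):
        parent[sig(v) - 1] = sig(tree.parent[v - 1])
    return MutationTree(tuple(parent))


def propose(
    state: SearchState, rng: np.random.Generator, config: SearchConfig
) -> Tuple[str, Optional[MutationTree], Optional[ErrorModel], float]:
    """Draw one proposal; returns (move, tree', theta', log_q_ratio).

    ``log_q_ratio`` is log q(current | candidate) - log q(candidate |
    current).  Tree moves leave theta unchanged and vice versa; moves with
    an empty neighbourhood (e.g. any tree move at n = 1) fall back to a
    theta move.
    """
    tree, theta = state.tree, state.theta
    n = tree.n
    move = MOVES[rng.choice(4, p=config.move_probs)]
    if n < 2 and move != "theta":
        move = "theta"

    if move == "prune_reattach":
        for _ in range(32):
            v = int(rng.integers(1, n + 1))
            sub = set(tree.subtree(v))
            targets = [u for u in range(1, n + 2)
                       if u not in sub and u != tree.parent[v - 1]]
            if targets:
                new_parent = int(targets[rng.integers(len(targets))])
                return move, tree.with_parent(v, new_parent), None, 0.0
        move = "theta"  # every node saturated (cannot happen for n >= 2)

    if move == "swap_subtrees":
        A = build_ancestor_matrix(tree)
        pairs = [(i, j) for i in range(1, n + 1) for j in range(i + 1, n + 1)
                 if not A[i - 1, j - 1] and not A[j - 1, i - 1]]
        if not pairs:
            move = "swap_labels"  # chain tree: no swappable pair
        else:
            i, j = pairs[rng.integers(len(pairs))]
            p = list(tree.parent)
            p[i - 1], p[j - 1] = p[j - 1], p[i - 1]
            cand = MutationTree(tuple(p))
            log_q = math.log(len(pairs)) - math.log(_count_swap_pairs(cand))
            return "swap_subtrees", cand, None, log_q

    if move == "swap_labels":
        i = int(rng.integers(1, n + 1))
        j = int(rng.integers(1, n))
        if j >= i:
            j += 1
        return "swap_labels", _swap_label_tree(tree, i, j), None, 0.0

    # theta move: log-normal multiplicative perturbation; the proposal
    # density is asymmetric, q(back)/q(fwd) = new / old.
    learn_alpha = config.learn_alpha and rng.random() < 0.5
    if learn_alpha:
        new_alpha = theta.alpha * math.exp(config.theta_scale * rng.standard_normal())
        log_q = math.log(new_alpha) - math.log(theta.alpha)
        return "theta", None, theta.with_(alpha=new_alpha), log_q
    new_beta = theta.beta * math.exp(config.theta_scale * rng.standard_normal())
    log_q = math.log(new_beta) - math.log(theta.beta)
    return "theta", None, theta.with_(beta=new_beta), log_q


def acceptance_probability(
    current: SearchState, candidate: SearchState, log_q_ratio: float
) -> float:
    """min{1, exp(log_q_ratio + S_joint(candidate) - S_joint(current))}."""
    delta = log_q_ratio + candidate.s_joint - current.s_joint
    if math.isnan(delta):
        raise ValueError("NaN joint score: scoring bug upstream")
    return min(1.0, math.exp(min(delta, 0.0)))


class _BulkCache:
    """Per-topology cache of (S_bulk, assignment); S_bulk is theta-free."""

    def __init__(self, counts: Optional[BulkCounts], maxsize: int = 100_000):
        self.counts = counts
        self.maxsize = maxsize
        self.store: Dict[Tuple[int, ...], Tuple[float, FrequencyAssignment]] = {}
        self.last_phi: Optional[np.ndarray] = None

    def get(self, tree: MutationTree) -> Tuple[float, Optional[FrequencyAssignment]]:
        if self.counts is None:
            return 0.0, None
        key = tree.parent
        hit = self.store.get(key)
        if hit is None:
            hit = score_bulk(tree, self.counts, x0=self.last_phi)
            if len(self.store) < self.maxsize:
                self.store[key] = hit
        self.last_phi = hit[1].phi
        return hit


def _score_state(
    tree: MutationTree,
    theta: ErrorModel,
    D: SingleCellMatrix,
    cache: _BulkCache,
    config: SearchConfig,
    delta_init: Optional[float] = None,
) -> SearchState:
    s_bulk, assignment = cache.get(tree)
    s_sc, delta_hat = score_sc(D, tree, theta, doublets=config.doublets,
                               delta_init=delta_init)
    return SearchState(tree, theta, s_bulk, s_sc, delta_hat, assignment)


def run_search(
    D: SingleCellMatrix,
    counts: Optional[BulkCounts],
    config: SearchConfig,
    initial_tree: Optional[MutationTree] = None,
) -> SearchState:
    """Run the Metropolis–Hastings search; returns the best state visited.

    ``counts=None`` disables the bulk term (single-cell-only ablation).
    The run is deterministic under a fixed ``config.seed``.  A move trace
    (step, move, accepted, scores) is logged at DEBUG level and optionally
    recorded every ``config.trace_every`` steps on the returned state's
    ``trace`` attribute via :func:`run_search_with_trace`.
    """
    best, _ = run_search_with_trace(D, counts, config, initial_tree)
    return best


def run_search_with_trace(
    D: SingleCellMatrix,
    counts: Optional[BulkCounts],
    config: SearchConfig,
    initial_tree: Optional[MutationTree] = None,
) -> Tuple[SearchState, List[dict]]:
    if counts is not None and counts.n != D.n:
        raise ValueError("single-cell matrix and bulk counts cover "
                         "different mutation sets")
    rng = np.random.default_rng(config.seed)
    cache = _BulkCache(counts if config.use_bulk else None)
    theta0 = ErrorModel(alpha=config.alpha, beta=config.beta)
    best: Optional[SearchState] = None
    trace: List[dict] = []
    co_optimal: List[Tuple[int, ...]] = []
    for restart in range(config.restarts):
        tree = initial_tree or random_mutation_tree(D.n, rng)
        state = _score_state(tree, theta0, D, cache, config)
        if best is None or state.s_joint > best.s_joint:
            best = state
        for step in range(config.chain_length):
            move, new_tree, new_theta, log_q = propose(state, rng, config)
            if new_theta is not None and not (0.0 < new_theta.beta < 1.0
                                              and 0.0 < new_theta.alpha < 1.0):
                continue  # outside the uniform prior's support
            cand = _score_state(
                new_tree if new_tree is not None else state.tree,
                new_theta if new_theta is not None else state.theta,
                D, cache, config, delta_init=state.delta_hat)
            a = acceptance_probability(state, cand, log_q)
            accepted = rng.random() < a
            if accepted:
                state = cand
            if state.s_joint > best.s_joint + 1e-12:
                best = state
                co_optimal = [state.tree.parent]
            elif abs(state.s_joint - best.s_joint) <= 1e-12 and \
                    state.tree.parent != best.tree.parent and \
                    state.tree.parent not in co_optimal:
                co_optimal.append(state.tree.parent)
                logger.info("co-optimal tree found: %s", state.tree.parent)
            if config.trace_every and step % config.trace_every == 0:
                trace.append({
                    "restart": restart, "step": step, "move": move,
                    "accepted": bool(accepted), "s_bulk": state.s_bulk,
                    "s_sc": state.s_sc, "s_joint": state.s_joint,
                    "beta": state.theta.beta, "delta": state.delta_hat,
                    "best": best.s_joint,
                })
    assert best is not None
    if best.assignment is None and config.use_bulk and counts is not None:
        # chain_length 0 with empty cache cannot happen (initial state scored),
        # but re-derive defensively for externally supplied states.
        s_bulk, assignment = score_bulk(best.tree, counts)
        best = replace(best, s_bulk=s_bulk, assignment=assignment)
    return best, trace
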