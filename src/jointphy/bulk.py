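"""Bulk read-count tree score S_bulk.

For a candidate mutation tree T the bulk score is the maximum, over
tree-constrained subclone frequencies, of the Gaussian-approximated
binomial log-likelihood of the observed variant/total read counts.

For each bulk sample the subclone fractions phi (including the healthy
root) lie on the probability simplex; the fraction of cells carrying
mutation i is y_i = sum over the subtree of node i of phi.  With the
standard deviations evaluated at the observed fractions z = 2r/t, the
log-likelihood reduces (up to constants) to a weighted sum of squares

    S_bulk(T) = max_phi  sum_ij  -w_ij (z_ij - y_ij)^2,
    w_ij = t_ij / (8 (z~_ij/2)(1 - z~_ij/2)),

a convex quadratic program over the simplex, solved here per sample by
non-negative least squares with an exact slack/penalty treatment of the
simplex constraint, behind a pluggable solver interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.optimize import nnls

from .trees import MutationTree, build_ancestor_matrix

__all__ = [
    "BulkCounts",
    "FrequencyAssignment",
    "observed_fraction",
    "gaussian_binomial_logdensity",
    "bulk_weights",
    "score_bulk",
    "solve_simplex_wls",
]

logger = logging.getLogger(__name__)

#: clamp applied to z when forming the quadratic weights, which diverge
#: at z in {0, 2}; the raw z is still used in the residual.
Z_CLAMP_EPS = 1e-3


@dataclass(frozen=True)
class BulkCounts:
    """Per-mutation, per-sample variant (r) and total (t) read counts."""

    r: np.ndarray  # shape (n, h)
    t: np.ndarray  # shape (n, h)
    mutation_ids: Tuple[str, ...] = ()

    def __post_init__(self):
        r = np.atleast_2d(np.asarray(self.r, dtype=np.int64))
        t = np.atleast_2d(np.asarray(self.t, dtype=np.int64))
        if r.shape != t.shape:
            raise ValueError("r and t must have identical shape (n, h)")
        if np.any(t < 1):
            raise ValueError("every scored mutation/sample needs t >= 1")
        if np.any(r < 0) or np.any(r > t):
            raise ValueError("need 0 <= r <= t")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "t", t)
        ids = tuple(self.mutation_ids) or tuple(
            f"M{i}" for i in range(1, r.shape[0] + 1)
        )
        if len(ids) != r.shape[0]:
            raise ValueError("one mutation id per row required")
        object.__setattr__(self, "mutation_ids", ids)

    @property
    def n(self) -> int:
        return self.r.shape[0]

    @property
    def h(self) -> int:
        return self.r.shape[1]

    @property
    def z(self) -> np.ndarray:
        """Observed cell fractions z = 2r/t, range [0, 2]."""
        return 2.0 * self.r / self.t


@dataclass(frozen=True)
class FrequencyAssignment:
    """Optimal subclone fractions phi and implied mutation fractions y.

    ``phi`` has shape (s + 1, h) with the root (healthy) population last;
    ``y[i-1, j]`` is the inferred fraction of cells carrying mutation i in
    sample j, ``y = A phi`` over the non-root rows.
    """

    phi: np.ndarray
    y: np.ndarray


def observed_fraction(r: int, t: int) -> float:
    """Bulk-data-derived cell fraction z = 2r/t (in [0, 2]; values above 1
    arise at CNA-affected loci)."""
    if t < 1:
        raise ValueError("total read count t must be >= 1")
    if not 0 <= r <= t:
        raise ValueError("need 0 <= r <= t")
    return 2.0 * r / t


def gaussian_binomial_logdensity(r, t, y):
    """Gaussian approximation to the Binomial(t, y/2) log-density at r.

    Returns log N(r; t y/2, t (y/2)(1 - y/2)) expressed in the observed
    fraction z = 2r/t.  ``y`` is clamped away from {0, 2} (the density
    degenerates there); a clamped evaluation is logged as a warning.
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(t < 1):
        raise ValueError("t must be >= 1")
    yc = np.clip(y, Z_CLAMP_EPS, 2.0 - Z_CLAMP_EPS)
    if np.any(yc != y):
        logger.warning("gaussian_binomial_logdensity: y clamped to (%g, %g)",
                       Z_CLAMP_EPS, 2.0 - Z_CLAMP_EPS)
    z = 2.0 * r / t
    half = (yc / 2.0) * (1.0 - yc / 2.0)
    return (
        -0.5 * np.log(2.0 * np.pi)
        - 0.5 * np.log(t * half)
        - t / (8.0 * half) * (z - y) ** 2
    )


def bulk_weights(counts: BulkCounts) -> np.ndarray:
    """Quadratic coefficients w = t / (8 (z~/2)(1 - z~/2)), z~ clamped."""
    z = np.clip(counts.z, Z_CLAMP_EPS, 2.0 - Z_CLAMP_EPS)
    return counts.t / (8.0 * (z / 2.0) * (1.0 - z / 2.0))


def solve_simplex_wls(
    A: np.ndarray,
    z: np.ndarray,
    w: np.ndarray,
    x0: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Minimise sum_i w_i (z_i - (A phi)_i)^2 over phi >= 0, sum phi <= 1.

    ``phi`` are the non-root subclone fractions; the healthy root absorbs
    the simplex slack.  Default backend of the pluggable convex-QP
    contract used by :func:`score_bulk`: the simplex constraint is added
    as a slack variable plus a quadratic penalty row, the non-negative
    problem is solved exactly by Lawson–Hanson NNLS, and the penalty bias
    is removed by iterated target correction.  ``x0`` is accepted for
    interface compatibility (active-set NNLS needs no warm start).
    """
    nobs, n = A.shape
    sw = np.sqrt(w)
    rho = 1e4 * max(1.0, float(sw.max()))
    M = np.zeros((nobs + 1, n + 1))
    M[:nobs, :n] = sw[:, None] * A
    M[nobs, :] = rho  # slack column included: sum phi + s = 1
    target = 1.0
    x = np.zeros(n + 1)
    for _ in range(3):
        b = np.concatenate([sw * z, [rho * target]])
        x, _ = nnls(M, b)
        viol = 1.0 - x.sum()
        if abs(viol) < 1e-14:
            break
        target += viol
    phi = np.clip(x[:n], 0.0, None)
    s = phi.sum()
    if s > 1.0:
        phi /= s
    return phi


def score_bulk(
    tree: MutationTree,
    counts: BulkCounts,
    x0: Optional[np.ndarray] = None,
    solver: Optional[Callable] = None,
) -> Tuple[float, FrequencyAssignment]:
    """Maximum tree-constrained bulk log-likelihood (constants dropped).

    Returns ``(S_bulk, assignment)`` with ``S_bulk <= 0`` and equality iff
    the clamped observed fractions are exactly realisable under the tree's
    ancestry constraints.  Samples are solved independently (the simplex
    constraint is per sample).  ``x0`` may carry warm-start phi values of
    shape (n, h) from a neighbouring tree.
    """
    if counts.n != tree.n:
        raise ValueError("counts and tree cover different mutation sets")
    solve = solver or solve_simplex_wls
    A = np.asarray(build_ancestor_matrix(tree), dtype=float)
    z = counts.z
    w = bulk_weights(counts)
    if np.any(z > 1.0):
        logger.info("bulk fractions z > 1 at mutations %s (possible CNA)",
                    [counts.mutation_ids[i] for i in np.where((z > 1).any(axis=1))[0]])
    n, h = counts.n, counts.h
    phi = np.zeros((n + 1, h))
    y = np.zeros((n, h))
    total = 0.0
    for j in range(h):
        start = None if x0 is None else np.asarray(x0)[:n, j]
        pj = solve(A, z[:, j], w[:, j], start)
        yj = A @ pj
        phi[:n, j] = pj
        phi[n, j] = max(0.0, 1.0 - pj.sum())
        y[:, j] = yj
        total += float(-np.dot(w[:, j], (z[:, j] - yj) ** 2))
    total = min(total, 0.0)
    return total, FrequencyAssignment(phi=phi, y=y)
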