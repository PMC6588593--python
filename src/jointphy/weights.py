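"""Relative contribution of bulk vs single-cell data.

The score ranges of the two data types are measured between the best
tree T* and a baseline tree T^ consisting of a single clone that carries
every mutation (hence present in every cell).  Their ratio

    rho = (S_bulk(T*) - S_bulk(T^)) / (S_sc(T*) - S_sc(T^))

estimates the relative weight of the bulk evidence, and
omega = rho / (1 + rho) is its normalisation to [0, 1).  omega is
reported only; the joint score remains the unweighted sum by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.special import logsumexp

from .bulk import BulkCounts, bulk_weights
from .singlecell import ErrorModel, SingleCellMatrix, _golden_section_max, _per_entry_logs
from .mcmc import SearchState

__all__ = ["WeightReport", "baseline_tree_scores", "relative_weight",
           "compute_weight_report"]


@dataclass(frozen=True)
class WeightReport:
    s_bulk_star: float
    s_bulk_hat: float
    s_sc_star: float
    s_sc_hat: float
    rho: float
    omega: float


def baseline_tree_scores(
    D: SingleCellMatrix,
    counts: Optional[BulkCounts],
    theta: ErrorModel,
    doublets: bool = False,
) -> Tuple[float, float]:
    """Scores of the one-clone baseline tree T^.

    Bulk: the QP degenerates to a single shared fraction y per sample,
    maximised in closed form (weighted mean of z, clipped to [0, 1]).
    Single-cell: each cell attaches to the root (no mutations) or to the
    clone (all mutations), uniformly; doublet pairs reduce to the same two
    genotypes, with 3 of the 4 ordered pairs giving the full genotype.
    """
    if counts is not None:
        z, w = counts.z, bulk_weights(counts)
        s_bulk = 0.0
        for j in range(counts.h):
            y = float(np.clip(np.dot(w[:, j], z[:, j]) / w[:, j].sum(), 0.0, 1.0))
            s_bulk += float(-np.dot(w[:, j], (z[:, j] - y) ** 2))
    else:
        s_bulk = 0.0
    log0, dlog = _per_entry_logs(D.data, theta)
    l_root = log0.sum(axis=0)                # genotype all-zero
    l_clone = l_root + dlog.sum(axis=0)      # genotype all-one
    both = np.stack([l_root, l_clone], axis=1)
    ls = logsumexp(both, axis=1) - np.log(2.0)
    if not doublets:
        return s_bulk, float(ls.sum())
    ld = logsumexp(both + np.log(np.array([1.0, 3.0]))[None, :], axis=1) \
        - np.log(4.0)

    def objective(delta: float) -> float:
        if delta <= 0.0:
            return float(ls.sum())
        return float(np.logaddexp(np.log1p(-delta) + ls,
                                  np.log(delta) + ld).sum())

    d = _golden_section_max(objective, 0.0, 1.0 - 1e-9)
    return s_bulk, max(objective(0.0), objective(d))


def relative_weight(
    s_bulk_star: float, s_bulk_hat: float, s_sc_star: float, s_sc_hat: float
) -> Tuple[float, float]:
    """rho and omega from the four scores; NaN when the sc range is zero.

    T* maximises the joint score, so either individual range can in
    principle be slightly negative; such values pass through with a
    warning rather than being clipped.
    """
    bulk_range = s_bulk_star - s_bulk_hat
    sc_range = s_sc_star - s_sc_hat
    if abs(sc_range) <= 1e-12 * max(1.0, abs(s_sc_star)):
        warnings.warn("single-cell score range is zero; rho undefined")
        return float("nan"), float("nan")
    rho = bulk_range / sc_range
    if rho < 0.0:
        warnings.warn(f"negative relative weight rho = {rho:.4g}")
    omega = rho / (1.0 + rho)
    return rho, omega


def compute_weight_report(
    D: SingleCellMatrix,
    counts: Optional[BulkCounts],
    best: SearchState,
    doublets: bool = False,
) -> WeightReport:
    s_bulk_hat, s_sc_hat = baseline_tree_scores(D, counts, best.theta, doublets)
    rho, omega = relative_weight(best.s_bulk, s_bulk_hat, best.s_sc, s_sc_hat)
    return WeightReport(best.s_bulk, s_bulk_hat, best.s_sc, s_sc_hat, rho, omega)
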