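"""Clustering and tree-accuracy measures for benchmarking.

Mutation clusterings are compared with the V-measure (harmonic mean of
entropy-based homogeneity and completeness) and the adjusted Rand index.
Tree accuracy is measured pairwise: every unordered mutation pair is
classified, in each clonal tree, as same-clone, ancestor-descendant (in
one direction) or separate-lineage, and agreement fractions are reported
per relation class.  Mutations absent from the predicted tree (e.g.
clones unobserved at strongly biased cell sampling) are excluded from
the pair universe.
"""

from __future__ import annotations

from typing import Mapping, Tuple

import numpy as np
from sklearn.metrics import adjusted_rand_score, v_measure_score

from .trees import ClonalTree, build_ancestor_matrix, first_occurrence_map

__all__ = ["v_measure", "adjusted_rand", "pairwise_tree_accuracies"]

MutationPartition = Mapping[object, int]


def _aligned_labels(truth: MutationPartition, pred: MutationPartition):
    if set(truth) != set(pred):
        raise ValueError("partitions cover different mutation sets")
    if not truth:
        raise ValueError("empty mutation universe")
    keys = sorted(truth, key=str)
    return [truth[k] for k in keys], [pred[k] for k in keys]


def v_measure(truth: MutationPartition, pred: MutationPartition) -> float:
    """V-measure in [0, 1]; 1 iff the partitions agree up to relabelling."""
    lt, lp = _aligned_labels(truth, pred)
    return float(v_measure_score(lt, lp))


def adjusted_rand(truth: MutationPartition, pred: MutationPartition) -> float:
    """Adjusted Rand index; 1 for identical partitions, ~0 at chance."""
    lt, lp = _aligned_labels(truth, pred)
    return float(adjusted_rand_score(lt, lp))


def _pair_relation(tree: ClonalTree):
    """Per-mutation clone id and the strict-ancestor matrix of the tree."""
    occ = first_occurrence_map(tree)
    A = np.asarray(build_ancestor_matrix(tree.parent), dtype=bool)
    strict = A & ~np.eye(tree.s, dtype=bool)
    return occ, strict


def pairwise_tree_accuracies(
    truth_tree: ClonalTree, pred_tree: ClonalTree
) -> Tuple[float, float, float]:
    """(ancestry, separate-lineage, co-clustering) accuracy.

    * ancestry: fraction of the truth's ancestor-descendant pairs whose
      direction is reproduced in the prediction;
    * separate-lineage: fraction of the truth's separate-lineage pairs
      kept on separate lineages;
    * co-clustering: fraction of all pairs whose same-clone status agrees.

    Pairs are taken over the mutations present in both trees.  A class
    with no truth pairs yields NaN for its accuracy.
    """
    common = sorted(truth_tree.mutations & pred_tree.mutations, key=str)
    if not common:
        raise ValueError("trees share no mutations")
    occ_t, anc_t = _pair_relation(truth_tree)
    occ_p, anc_p = _pair_relation(pred_tree)
    n_anc = n_anc_ok = n_sep = n_sep_ok = n_all = n_co_ok = 0
    for a_idx in range(len(common)):
        for b_idx in range(a_idx + 1, len(common)):
            a, b = common[a_idx], common[b_idx]
            ca, cb = occ_t[a], occ_t[b]
            pa, pb = occ_p[a], occ_p[b]
            n_all += 1
            same_t, same_p = ca == cb, pa == pb
            if same_t == same_p:
                n_co_ok += 1
            if same_t:
                continue
            if anc_t[ca - 1, cb - 1] or anc_t[cb - 1, ca - 1]:
                if anc_t[cb - 1, ca - 1]:
                    a, b, ca, cb, pa, pb = b, a, cb, ca, pb, pa
                n_anc += 1
                if pa != pb and anc_p[pa - 1, pb - 1]:
                    n_anc_ok += 1
            else:
                n_sep += 1
                if pa != pb and not anc_p[pa - 1, pb - 1] \
                        and not anc_p[pb - 1, pa - 1]:
                    n_sep_ok += 1
    ancestry = n_anc_ok / n_anc if n_anc else float("nan")
    separate = n_sep_ok / n_sep if n_sep else float("nan")
    co_clustering = n_co_ok / n_all
    return ancestry, separate, co_clustering
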