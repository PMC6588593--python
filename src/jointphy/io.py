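"""Readers/writers for the on-disk formats and result serialisation.

Formats
-------
* Single-cell mutation matrix: whitespace-separated text, rows are
  mutations, columns are cells.  Two dialects are accepted and
  auto-detected: integer coding with ``3`` for a missing entry, and
  0/1/``NA`` tokens.
* Bulk counts: TSV with header ``mutation_id  r_1  t_1  [r_2  t_2 ...]``;
  row order defines matrix row order.
* Trees: one-line parent vectors (1-based, root = n + 1), result/ground
  truth JSON, and Graphviz DOT for visual inspection.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bulk import BulkCounts
from .simulate import GroundTruth
from .singlecell import NA, SingleCellMatrix
from .trees import ClonalTree, MutationTree

__all__ = [
    "ParseError",
    "read_sc_matrix",
    "write_sc_matrix",
    "read_bulk_counts",
    "write_bulk_counts",
    "RunResult",
    "write_run_result",
    "read_run_result",
    "clonal_tree_to_dict",
    "clonal_tree_from_dict",
    "write_ground_truth",
    "read_ground_truth",
    "mutation_tree_dot",
    "clonal_tree_dot",
]


class ParseError(ValueError):
    pass


_TOKENS = {"0": 0, "1": 1, "2": 1, "3": NA, "NA": NA, "na": NA, "-": NA}


def read_sc_matrix(path) -> SingleCellMatrix:
    """Read a mutation matrix; token ``3`` or ``NA`` marks a missing entry
    (``2``, homozygous in some callers' coding, is treated as present)."""
    rows: List[List[int]] = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        row = []
        for tok in line.split():
            if tok not in _TOKENS:
                raise ParseError(f"{path}:{ln}: illegal token {tok!r}")
            row.append(_TOKENS[tok])
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: empty matrix file")
    width = len(rows[0])
    for ln, row in enumerate(rows, start=1):
        if len(row) != width:
            raise ParseError(f"{path}:{ln}: ragged row "
                             f"({len(row)} != {width} columns)")
    return SingleCellMatrix(np.array(rows, dtype=np.int8))


def write_sc_matrix(D: SingleCellMatrix, path) -> None:
    """Write in the integer dialect (3 = missing)."""
    out = np.where(D.data == NA, 3, D.data)
    Path(path).write_text(
        "\n".join(" ".join(str(v) for v in row) for row in out) + "\n")


def read_bulk_counts(path) -> BulkCounts:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "mutation_id":
        raise ParseError(f"{path}: first column must be mutation_id")
    h = (len(df.columns) - 1) // 2
    if h < 1 or len(df.columns) != 1 + 2 * h:
        raise ParseError(f"{path}: expect r_k/t_k column pairs")
    r = df[[f"r_{k}" for k in range(1, h + 1)]].to_numpy(dtype=np.int64)
    t = df[[f"t_{k}" for k in range(1, h + 1)]].to_numpy(dtype=np.int64)
    try:
        return BulkCounts(r=r, t=t,
                          mutation_ids=tuple(df["mutation_id"].astype(str)))
    except ValueError as e:
        raise ParseError(f"{path}: {e}") from e


def write_bulk_counts(counts: BulkCounts, path) -> None:
    cols: Dict[str, object] = {"mutation_id": list(counts.mutation_ids)}
    for k in range(1, counts.h + 1):
        cols[f"r_{k}"] = counts.r[:, k - 1]
        cols[f"t_{k}"] = counts.t[:, k - 1]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def align_bulk_to_matrix(counts: BulkCounts, ids: Sequence[str]) -> BulkCounts:
    """Reorder bulk rows to match the SC matrix mutation order by id."""
    index = {mid: i for i, mid in enumerate(counts.mutation_ids)}
    missing = [m for m in ids if m not in index]
    if missing:
        raise ParseError(f"bulk counts missing mutations: {missing}")
    order = [index[m] for m in ids]
    return BulkCounts(r=counts.r[order], t=counts.t[order],
                      mutation_ids=tuple(ids))


# ---------------------------------------------------------------- results

@dataclass
class RunResult:
    """Everything a joint inference run produced, JSON-round-trippable."""

    parent_vector: Tuple[int, ...]
    clonal_tree: dict
    alpha: float
    beta: float
    delta_hat: float
    s_bulk: float
    s_sc: float
    s_joint: float
    weights: Optional[dict]
    config: dict
    seed: int
    trace_summary: dict = field(default_factory=dict)


def clonal_tree_to_dict(tree: ClonalTree) -> dict:
    return {
        "parent": list(tree.parent),
        "labels": [sorted(lab, key=str) for lab in tree.labels],
        "phi": np.asarray(tree.phi).tolist(),
    }


def clonal_tree_from_dict(d: dict) -> ClonalTree:
    return ClonalTree(tuple(d["parent"]),
                      tuple(frozenset(l) for l in d["labels"]),
                      np.array(d["phi"], dtype=float))


def write_run_result(result: RunResult, path) -> None:
    Path(path).write_text(json.dumps(asdict(result), indent=2,
                                     sort_keys=True) + "\n")


def read_run_result(path) -> RunResult:
    d = json.loads(Path(path).read_text())
    d["parent_vector"] = tuple(d["parent_vector"])
    return RunResult(**d)


def write_ground_truth(truth: GroundTruth, path) -> None:
    doc = {
        "tree": clonal_tree_to_dict(truth.tree),
        "clone_of_mutation": truth.clone_of_mutation.tolist(),
        "y": truth.y.tolist(),
        "cna_events": [list(e) for e in truth.cna_events],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        tree=clonal_tree_from_dict(d["tree"]),
        clone_of_mutation=np.array(d["clone_of_mutation"], dtype=np.int64),
        y=np.array(d["y"], dtype=float),
        cna_events=[tuple(e) for e in d["cna_events"]],
    )


# ------------------------------------------------------------------- DOT

def mutation_tree_dot(
    tree: MutationTree,
    mutation_ids: Optional[Sequence[str]] = None,
    vafs: Optional[np.ndarray] = None,
) -> str:
    """Graphviz DOT of a mutation tree; nodes annotated with per-sample
    bulk VAF (z / 2) when provided."""
    ids = list(mutation_ids or (f"M{i}" for i in range(1, tree.n + 1)))
    lines = ["digraph mutation_tree {", '  node [shape=box];',
             f'  root [label="root"];']
    for v in range(1, tree.n + 1):
        label = ids[v - 1]
        if vafs is not None:
            vals = np.atleast_1d(np.asarray(vafs)[v - 1])
            label += "\\n" + " ".join(f"{x:.3f}" for x in vals)
        lines.append(f'  n{v} [label="{label}"];')
    for v in range(1, tree.n + 1):
        p = tree.parent[v - 1]
        src = "root" if p == tree.root else f"n{p}"
        lines.append(f"  {src} -> n{v};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def clonal_tree_dot(
    tree: ClonalTree, mutation_ids: Optional[Sequence[str]] = None
) -> str:
    """DOT of a clonal tree; clone nodes list their mutations and the
    per-sample mean VAF of the clone's cell fraction."""
    def name(m):
        if mutation_ids is not None and isinstance(m, int):
            return mutation_ids[m - 1]
        return str(m)

    from .trees import build_ancestor_matrix
    A = np.asarray(build_ancestor_matrix(tree.parent), dtype=float)
    y = A @ tree.phi[:tree.s]  # clone-level cell fractions
    lines = ["digraph clonal_tree {", "  node [shape=box];",
             '  root [label="healthy"];']
    for v in range(1, tree.s + 1):
        muts = ", ".join(sorted((name(m) for m in tree.labels[v - 1])))
        vaf = " ".join(f"{x / 2:.3f}" for x in np.atleast_1d(y[v - 1]))
        lines.append(f'  c{v} [label="{{{muts}}}\\nVAF {vaf}"];')
    for v in range(1, tree.s + 1):
        p = tree.parent[v - 1]
        src = "root" if p == tree.root else f"c{p}"
        lines.append(f"  {src} -> c{v};")
    lines.append("}")
    return "\n".join(lines) + "\n"
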