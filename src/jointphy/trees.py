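"""Tree data model shared by all scoring and search modules.

Two tree kinds are used throughout:

* :class:`MutationTree` — a rooted tree with exactly one mutation per
  non-root node; the object the MCMC search traverses.
* :class:`ClonalTree` — a rooted tree whose nodes (subclones) carry
  disjoint, non-empty mutation-set labels plus per-sample population
  frequencies; the output of mutation-tree compression.

Node indexing is 1-based with the root at ``n + 1`` (resp. ``s + 1``),
the convention used by all serialised parent vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "TreeStructureError",
    "MutationTree",
    "ClonalTree",
    "build_ancestor_matrix",
    "first_occurrence_map",
    "random_mutation_tree",
]


class TreeStructureError(ValueError):
    """Raised when a parent map does not encode a valid rooted tree."""


def _validate_parent_vector(parent: Sequence[int]) -> None:
    """Check that ``parent`` encodes a rooted tree on nodes 1..n with root n+1."""
    n = len(parent)
    if n < 1:
        raise TreeStructureError("tree must contain at least one non-root node")
    root = n + 1
    for i, p in enumerate(parent, start=1):
        if not (1 <= p <= root):
            raise TreeStructureError(f"node {i}: parent {p} outside 1..{root}")
        if p == i:
            raise TreeStructureError(f"node {i} is its own parent")
    # every node must reach the root without revisiting a node
    for i in range(1, n + 1):
        seen = set()
        v = i
        while v != root:
            if v in seen:
                raise TreeStructureError(f"cycle detected at node {v}")
            seen.add(v)
            v = parent[v - 1]


@dataclass(frozen=True)
class MutationTree:
    """Rooted tree with node ``i`` carrying exactly mutation ``i``.

    Parameters
    ----------
    parent
        ``parent[i-1]`` is the parent of node ``i`` (1-based); the root is
        node ``n + 1`` and does not appear as a key.
    """

    parent: Tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent", tuple(int(p) for p in self.parent))
        _validate_parent_vector(self.parent)

    @property
    def n(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n + 1

    def children(self) -> Dict[int, List[int]]:
        """Map node -> sorted list of children (root included)."""
        ch: Dict[int, List[int]] = {v: [] for v in range(1, self.n + 2)}
        for i, p in enumerate(self.parent, start=1):
            ch[p].append(i)
        return ch

    def subtree(self, v: int) -> List[int]:
        """Nodes of the subtree rooted at ``v`` (``v`` included), preorder."""
        ch = self.children()
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(reversed(ch[u]))
        return out

    def depths(self) -> np.ndarray:
        """Depth of each non-root node (root depth 0); index 0 is node 1."""
        d = np.zeros(self.n, dtype=np.int64)
        for i in range(1, self.n + 1):
            v, k = i, 0
            while v != self.root:
                v = self.parent[v - 1]
                k += 1
            d[i - 1] = k
        return d

    def with_parent(self, node: int, new_parent: int) -> "MutationTree":
        p = list(self.parent)
        p[node - 1] = new_parent
        return MutationTree(tuple(p))

    def to_parent_string(self) -> str:
        return " ".join(str(p) for p in self.parent)

    @classmethod
    def from_parent_string(cls, line: str) -> "MutationTree":
        return cls(tuple(int(tok) for tok in line.split()))


@dataclass(frozen=True)
class ClonalTree:
    """Rooted subclone tree with mutation-set labels and frequencies.

    ``parent`` follows the same convention as :class:`MutationTree` over
    ``s`` subclones with root ``s + 1``.  ``labels[i-1]`` is the set of
    mutations newly acquired at subclone ``i`` (pairwise disjoint,
    non-empty, jointly covering the mutation set; the root label is empty
    and not stored).  ``phi`` has shape ``(s + 1, h)``: row ``i - 1`` is
    the population fraction of subclone ``i`` in each bulk sample, row
    ``s`` is the healthy root; each column sums to one.
    """

    parent: Tuple[int, ...]
    labels: Tuple[frozenset, ...]
    phi: np.ndarray = field(compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent", tuple(int(p) for p in self.parent))
        object.__setattr__(self, "labels", tuple(frozenset(l) for l in self.labels))
        _validate_parent_vector(self.parent)
        s = len(self.parent)
        if len(self.labels) != s:
            raise TreeStructureError("one label set per non-root node required")
        seen: set = set()
        for i, lab in enumerate(self.labels, start=1):
            if not lab:
                raise TreeStructureError(f"subclone {i} has an empty label")
            if seen & lab:
                raise TreeStructureError("mutation labels are not disjoint")
            seen |= lab
        phi = np.asarray(self.phi, dtype=float)
        if phi.ndim == 1:
            phi = phi[:, None]
        object.__setattr__(self, "phi", phi)
        if phi.shape[0] != s + 1:
            raise TreeStructureError("phi must have s + 1 rows (root last)")
        if np.any(phi < -1e-9):
            raise TreeStructureError("negative population frequency")
        if not np.allclose(phi.sum(axis=0), 1.0, atol=1e-6):
            raise TreeStructureError("per-sample frequencies must sum to 1")

    @property
    def s(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.s + 1

    @property
    def h(self) -> int:
        return self.phi.shape[1]

    @property
    def mutations(self) -> frozenset:
        out: set = set()
        for lab in self.labels:
            out |= lab
        return frozenset(out)

    def partition(self) -> Dict[object, int]:
        """Map mutation -> subclone index (the mutation clustering)."""
        return {m: i for i, lab in enumerate(self.labels, start=1) for m in lab}

    @classmethod
    def from_mutation_tree(
        cls, tree: MutationTree, phi: np.ndarray
    ) -> "ClonalTree":
        """View a mutation tree as the s = n special case of a clonal tree."""
        labels = tuple(frozenset([i]) for i in range(1, tree.n + 1))
        return cls(tree.parent, labels, phi)


def _ancestor_matrix_from_parent(parent: Tuple[int, ...]) -> np.ndarray:
    n = len(parent)
    root = n + 1
    A = np.zeros((n, n), dtype=np.int8)
    for j in range(1, n + 1):
        v = j
        while v != root:
            A[v - 1, j - 1] = 1
            v = parent[v - 1]
    return A


@lru_cache(maxsize=4096)
def _ancestor_matrix_cached(parent: Tuple[int, ...]) -> np.ndarray:
    _validate_parent_vector(parent)
    A = _ancestor_matrix_from_parent(parent)
    A.setflags(write=False)
    return A


def build_ancestor_matrix(tree) -> np.ndarray:
    """Ancestor matrix A with ``A[i-1, j-1] = 1`` iff node i is an ancestor
    of node j or ``i == j``; root row/column excluded.

    Accepts a :class:`MutationTree`, a :class:`ClonalTree` or a raw parent
    vector. Returned array is read-only (cached).
    """
    if isinstance(tree, (MutationTree, ClonalTree)):
        parent = tree.parent
    else:
        parent = tuple(int(p) for p in tree)
    return _ancestor_matrix_cached(parent)


def first_occurrence_map(tree: ClonalTree) -> Dict[object, int]:
    """Node of first occurrence of each mutation: N(M) = v iff M in L(v)."""
    return tree.partition()


def _prufer_decode(seq: Sequence[int], n_nodes: int) -> List[Tuple[int, int]]:
    """Edges of the labelled tree on 1..n_nodes encoded by a Prüfer sequence."""
    degree = np.ones(n_nodes + 1, dtype=np.int64)
    for x in seq:
        degree[x] += 1
    import heapq

    leaves = [v for v in range(1, n_nodes + 1) if degree[v] == 1]
    heapq.heapify(leaves)
    edges = []
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, x))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u = heapq.heappop(leaves)
    v = heapq.heappop(leaves)
    edges.append((u, v))
    return edges


def random_mutation_tree(n: int, rng: np.random.Generator) -> MutationTree:
    """Uniformly random rooted mutation tree on ``n`` mutations.

    Sampled by drawing a uniform Prüfer sequence over the ``n + 1`` labelled
    nodes (root fixed at ``n + 1``) and orienting the decoded tree away from
    the root, which yields each of the ``(n + 1)^(n - 1)`` rooted trees with
    equal probability.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return MutationTree((2,))
    n_nodes = n + 1
    seq = rng.integers(1, n_nodes + 1, size=n_nodes - 2)
    edges = _prufer_decode(seq.tolist(), n_nodes)
    adj: Dict[int, List[int]] = {v: [] for v in range(1, n_nodes + 1)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    parent = [0] * n
    stack = [n_nodes]
    seen = {n_nodes}
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                parent[v - 1] = u
                stack.append(v)
    return MutationTree(tuple(parent))
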