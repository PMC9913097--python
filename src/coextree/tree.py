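"""Correlation distances and UPGMA coexpression trees.

Genes (or samples) with similar expression profiles get small distances
d = 1 - r, where r is the Pearson correlation coefficient, so d lies in
[0, 2]: 0 for perfectly correlated pairs, 2 for perfectly anti-correlated
ones.  UPGMA (average-linkage agglomerative clustering) turns the distance
matrix into a rooted ultrametric tree whose internal-node heights are half
the average inter-cluster distance at each merge; the tree-implied
(cophenetic) distance between two leaves is twice the height of their
lowest common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .expression import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "DistanceMatrix",
    "Node",
    "Tree",
    "pearson_matrix",
    "corr_to_distance",
    "upgma",
    "cophenetic_matrix",
    "subset_distance_stats",
]

_SYM_TOL = 1e-8


def _check_square_symmetric(a: np.ndarray, n_ids: int, what: str) -> None:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{what} must be square, got shape {a.shape}")
    if a.shape[0] != n_ids:
        raise ValueError(f"{what} shape {a.shape} does not match {n_ids} ids")
    if a.size and not np.allclose(a, a.T, atol=_SYM_TOL, rtol=0):
        raise ValueError(f"{what} is not symmetric")


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        _check_square_symmetric(self.r, len(self.ids), "correlation matrix")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate ids")
        if self.r.size:
            if not np.allclose(np.diag(self.r), 1.0, atol=1e-9):
                raise ValueError("correlation diagonal must be 1")
            if self.r.min() < -1 - 1e-9 or self.r.max() > 1 + 1e-9:
                raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal.

    Correlation-derived distances (d = 1 - r) lie in [0, 2].
    """

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        _check_square_symmetric(self.d, len(self.ids), "distance matrix")
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate ids")
        if self.d.size:
            if np.abs(np.diag(self.d)).max() > 1e-9:
                raise ValueError("distance diagonal must be 0")
            if self.d.min() < -1e-9:
                raise ValueError("distances must be non-negative")

    def index_of(self, name: str) -> int:
        return self.ids.index(name)

    def submatrix(self, names: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index_of(n) for n in names]
        return DistanceMatrix(list(names), self.d[np.ix_(idx, idx)])


def pearson_matrix(m: ExpressionMatrix, axis: str = "genes") -> CorrelationMatrix:
    """All-pairs Pearson correlation of gene rows or sample columns.

    Zero-variance vectors are an error (they should have been removed by
    the zero-SD filter) because their correlation is undefined.
    """
    if axis == "genes":
        X, ids = m.values, m.gene_ids
    elif axis == "samples":
        X, ids = m.values.T, m.sample_ids
    else:
        raise ValueError(f"axis must be 'genes' or 'samples', got {axis!r}")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 observations per vector")
    sd = X.std(axis=1)
    flat = [ids[i] for i in np.flatnonzero(sd == 0)]
    if flat:
        raise ValueError(f"zero-variance vectors (filter these first): {flat[:5]}")
    r = np.corrcoef(X)
    r = (r + r.T) / 2.0  # corrcoef is symmetric only to the last ulp
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(list(ids), r)


def corr_to_distance(c: CorrelationMatrix) -> DistanceMatrix:
    """Transform correlations to distances via d = 1 - r.

    Maps r = 1 to d = 0 (complete correlation) and r = -1 to d = 2
    (complete anti-correlation).  The diagonal is forced to exactly 0 and
    floating-point excursions outside [0, 2] are clamped.
    """
    d = 1.0 - c.r
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(c.ids), d)


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------


class Node:
    """Tree node: a leaf carries a name, an internal node a height.

    ``height`` is the node's distance down to its leaves (0 for leaves);
    ``length`` is the branch length to the parent (None at the root).
    """

    __slots__ = ("name", "children", "parent", "length", "height")

    def __init__(
        self,
        name: str | None = None,
        children: list["Node"] | None = None,
        length: float | None = None,
        height: float = 0.0,
    ):
        self.name = name
        self.children: list[Node] = children or []
        self.parent: Node | None = None
        self.length = length
        self.height = height
        for ch in self.children:
            ch.parent = self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    def iter_postorder(self) -> Iterator["Node"]:
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for ch in reversed(node.children):
                    stack.append((ch, False))

    def leaves(self) -> list["Node"]:
        return [n for n in self.iter_postorder() if n.is_leaf]

    def n_leaves(self) -> int:
        return sum(1 for n in self.iter_postorder() if n.is_leaf)


class Tree:
    """Rooted tree with branch lengths; leaves carry unique labels."""

    def __init__(self, root: Node):
        self.root = root
        names = [lf.name for lf in root.leaves()]
        if any(n is None for n in names):
            raise ValueError("every leaf must be labelled")
        if len(names) != len(set(names)):
            raise ValueError("leaf labels must be unique")

    # -- introspection ------------------------------------------------------

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return self.root.n_leaves()

    def find_leaf(self, name: str) -> Node | None:
        for lf in self.leaves():
            if lf.name == name:
                return lf
        return None

    def is_binary(self) -> bool:
        return all(
            len(n.children) == 2 for n in self.root.iter_postorder() if not n.is_leaf
        )

    def root_to_leaf_lengths(self) -> np.ndarray:
        """Sum of branch lengths from the root to every leaf."""
        out: list[float] = []

        def walk(node: Node, acc: float) -> None:
            if node.is_leaf:
                out.append(acc)
                return
            for ch in node.children:
                walk(ch, acc + (ch.length or 0.0))

        walk(self.root, 0.0)
        return np.asarray(out)

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = self.root_to_leaf_lengths()
        return bool(np.abs(depths - depths.mean()).max() <= tol)

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            c = Node(node.name, [clone(ch) for ch in node.children], node.length, node.height)
            return c

        return Tree(clone(self.root))


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def upgma(dm: DistanceMatrix) -> Tree:
    """Average-linkage (UPGMA) hierarchical clustering of a distance matrix.

    Repeatedly merges the pair of clusters with the minimal average
    inter-cluster distance; the merge height is that distance / 2, and leaf
    branch lengths make the tree ultrametric.  Cluster distances are
    maintained with the exact weighted (Lance-Williams) update
    ``d(i+j, k) = (n_i d(i,k) + n_j d(j,k)) / (n_i + n_j)``, which equals
    the average over all leaf pairs.  When several pairs tie at the minimal
    distance, the pair whose (lexicographically smallest member) labels
    sort first is merged, making the output order-independent.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("need at least 2 ids for UPGMA")
    D = dm.d.astype(float).copy()
    if (D < -1e-9).any():
        raise ValueError("negative distances")
    D = (D + D.T) / 2.0  # exact bitwise symmetry for the min-pair scan
    np.fill_diagonal(D, np.inf)

    nodes: list[Node | None] = [Node(name=i) for i in dm.ids]
    sizes = np.ones(n)
    labels: list[str | None] = list(dm.ids)  # smallest leaf id per cluster
    active = np.ones(n, dtype=bool)

    for _ in range(n - 1):
        dmin = D.min()
        cand = np.argwhere(D == dmin)
        best: tuple[str, str] | None = None
        bi = bj = -1
        for i, j in cand:
            if i >= j:
                continue
            key = tuple(sorted((labels[i], labels[j])))
            if best is None or key < best:
                best, bi, bj = key, int(i), int(j)
        h = dmin / 2.0
        left, right = nodes[bi], nodes[bj]
        left.length = h - left.height
        right.length = h - right.height
        merged = Node(children=[left, right], height=h)
        si, sj = sizes[bi], sizes[bj]
        with np.errstate(invalid="ignore"):
            D[bi, :] = (si * D[bi, :] + sj * D[bj, :]) / (si + sj)
        D[:, bi] = D[bi, :]
        D[bi, bi] = np.inf
        D[bj, :] = np.inf
        D[:, bj] = np.inf
        sizes[bi] = si + sj
        labels[bi] = min(labels[bi], labels[bj])
        nodes[bi], nodes[bj] = merged, None
        active[bj] = False

    root = nodes[int(np.flatnonzero(active)[0])]
    root.length = None
    return Tree(root)


def cophenetic_matrix(t: Tree) -> DistanceMatrix:
    """Tree-implied pairwise leaf distances.

    Entry (i, j) is twice the height of the lowest common ancestor of
    leaves i and j — for a UPGMA tree, the average-linkage merge distance
    of the clusters that joined them.  Comparing this matrix with the
    original distances measures how faithfully the tree represents them.
    """
    leaves = t.leaves()
    ids = [lf.name for lf in leaves]
    index = {id(lf): k for k, lf in enumerate(leaves)}
    n = len(ids)
    d = np.zeros((n, n))
    sets: dict[int, list[int]] = {}
    for node in t.root.iter_postorder():
        if node.is_leaf:
            sets[id(node)] = [index[id(node)]]
            continue
        child_sets = [sets.pop(id(ch)) for ch in node.children]
        coph = 2.0 * node.height
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia = np.asarray(child_sets[a])
                ib = np.asarray(child_sets[b])
                d[np.ix_(ia, ib)] = coph
                d[np.ix_(ib, ia)] = coph
        sets[id(node)] = [k for cs in child_sets for k in cs]
    return DistanceMatrix(ids, d)


def subset_distance_stats(dm: DistanceMatrix, names: Sequence[str]) -> dict[str, float]:
    """Pair count and mean pairwise distance over a subset of ids.

    Useful for comparing a gene family's average pre-clustering distance
    with its average cophenetic distance on the tree.
    """
    present = [n for n in names if n in set(dm.ids)]
    if len(present) < 2:
        raise ValueError("need at least 2 ids present in the matrix")
    sub = dm.submatrix(present).d
    iu = np.triu_indices(len(present), k=1)
    return {
        "n_ids": len(present),
        "n_pairs": int(len(present) * (len(present) - 1) // 2),
        "mean_distance": float(sub[iu].mean()),
    }
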