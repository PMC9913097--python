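"""Driver-gene coexpression clades.

A query gene (the *driver*) anchors a clade: the subtree rooted at its
k-th ancestor (k = the internal-node count, parent = 1).  Increasing k
grows the clade, bounded by a cap of 25% of all genes in the tree.  The
default view is the ancestor clade whose leaf count is closest to 25
genes; for trees too small for the cap to leave room for a 25-gene clade
(fewer than 100 leaves) the cap is waived for the default selection, since
it is a guard against runaway clades on genome-scale trees, not a limit
meant to undercut the default size.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass

from .tree import Node, Tree
from .treeio import newick_string

__all__ = ["Clade", "clade_at", "default_clade", "clade_gene_list", "clade_newick"]

DEFAULT_TARGET_SIZE = 25
CAP_FRACTION = 0.25


@dataclass
class Clade:
    """A driver-anchored subtree with its internal-node count."""

    driver_id: str
    internal_node_count: int
    subtree: Tree
    gene_ids: list[str]
    capped: bool = False

    @property
    def size(self) -> int:
        return len(self.gene_ids)


def size_cap(n_leaves: int) -> int:
    """Maximal clade size: ceil(25% of the genes in the tree), floored at 2.

    The floor keeps the definitional k = 1 clade (driver plus sibling)
    reachable on trees so small that 25% would be a single leaf.
    """
    return max(math.ceil(CAP_FRACTION * n_leaves), 2)


def _find_driver(t: Tree, driver: str) -> Node:
    leaf = t.find_leaf(driver)
    if leaf is None:
        near = difflib.get_close_matches(driver, t.leaf_names(), n=5)
        raise KeyError(f"driver {driver!r} not found in tree; near matches: {near}")
    return leaf


def _ancestors(leaf: Node) -> list[Node]:
    out: list[Node] = []
    node = leaf.parent
    while node is not None:
        out.append(node)
        node = node.parent
    return out


def _subtree(node: Node) -> Tree:
    def clone(n: Node) -> Node:
        return Node(n.name, [clone(ch) for ch in n.children], n.length, n.height)

    root = clone(node)
    root.length = None
    return Tree(root)


def _make_clade(driver: str, k: int, node: Node | None, leaf: Node, capped: bool) -> Clade:
    if node is None:  # even the parent clade exceeds the cap: driver alone
        sub = _subtree(leaf)
        return Clade(driver, 0, sub, [driver], capped=True)
    sub = _subtree(node)
    return Clade(driver, k, sub, sub.leaf_names(), capped=capped)


def clade_at(t: Tree, driver: str, k: int) -> Clade:
    """Clade rooted at the k-th ancestor of the driver leaf (parent = 1).

    If that clade would exceed 25% of all leaves, the largest smaller k
    within the cap is returned instead and the result is flagged
    ``capped``.  k beyond the driver's depth is truncated to the root.
    """
    if k < 1:
        raise ValueError("internal-node count k must be >= 1")
    leaf = _find_driver(t, driver)
    anc = _ancestors(leaf)
    cap = size_cap(t.n_leaves)
    kk = min(k, len(anc))
    chosen: Node | None = None
    chosen_k = 0
    for i in range(kk):
        if anc[i].n_leaves() <= cap:
            chosen, chosen_k = anc[i], i + 1
        else:
            break
    capped = chosen_k < kk
    return _make_clade(driver, chosen_k, chosen, leaf, capped)


def default_clade(t: Tree, driver: str, target: int = DEFAULT_TARGET_SIZE) -> Clade:
    """The ancestor clade whose size is closest to ``target`` (default 25).

    Ties between an undersized and an oversized candidate pick the smaller
    clade (fewer false co-members).  The 25% cap applies whenever it still
    permits a clade of the target size (cap >= target); on smaller trees
    it is waived so the closest achievable clade, possibly the whole tree,
    is returned.
    """
    leaf = _find_driver(t, driver)
    anc = _ancestors(leaf)
    cap = size_cap(t.n_leaves)
    enforce_cap = cap >= target
    best: tuple[int, int, int] | None = None  # (|size-target|, size, k)
    for i, node in enumerate(anc):
        size = node.n_leaves()
        if enforce_cap and size > cap:
            break
        key = (abs(size - target), size, i + 1)
        if best is None or key < best:
            best = key
    if best is None:  # cap enforced and parent already exceeds it
        return _make_clade(driver, 0, None, leaf, capped=True)
    k = best[2]
    return _make_clade(driver, k, anc[k - 1], leaf, capped=False)


def clade_gene_list(
    c: Clade, descriptions: dict[str, str] | None = None
) -> list[tuple[str, str]]:
    """(gene id, description) pairs in subtree traversal order."""
    descriptions = descriptions or {}
    return [(g, descriptions.get(g, "")) for g in c.subtree.leaf_names()]


def clade_newick(c: Clade) -> str:
    """The clade subtree as a Newick string (branch lengths preserved)."""
    return newick_string(c.subtree)
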