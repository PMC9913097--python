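"""Representative-leaf selection by iterative cherry pruning.

A sample tree built from thousands of redundant samples is reduced to the
n most distinct representatives by repeatedly locating the cherry (two
leaves sharing a parent) whose parent has the minimal height — i.e. the
two most similar remaining samples — and deleting one of its members.
Deleting a leaf and contracting its parent never re-estimates heights, so
the cophenetic distance between any two surviving leaves is unchanged.

Which cherry member to drop: the one whose summed cophenetic distance to
all other current leaves is smaller, keeping the more outlying (more
distinct) representative; ties drop the lexicographically larger name.
"""

from __future__ import annotations

from .tree import Node, Tree

__all__ = ["prune_to_n"]


def _leaf_counts(root: Node) -> dict[int, int]:
    counts: dict[int, int] = {}
    for node in root.iter_postorder():
        counts[id(node)] = 1 if node.is_leaf else sum(
            counts[id(ch)] for ch in node.children
        )
    return counts


def _summed_cophenetic(leaf: Node, counts: dict[int, int]) -> float:
    """Sum of cophenetic distances from ``leaf`` to every other leaf.

    At each ancestor a, the leaves whose LCA with ``leaf`` is a number
    count(a) - count(child-on-path), each at distance 2*height(a).
    """
    total = 0.0
    prev = leaf
    anc = leaf.parent
    while anc is not None:
        other = counts[id(anc)] - counts[id(prev)]
        total += 2.0 * anc.height * other
        prev = anc
        anc = anc.parent
    return total


def prune_to_n(t: Tree, n: int) -> tuple[Tree, list[str]]:
    """Prune a binary tree down to exactly ``n`` leaves.

    Returns the pruned tree (the input is not modified) and the ordered
    log of removed leaf names.
    """
    total = t.n_leaves
    if n < 1 or n > total:
        raise ValueError(f"target leaf count {n} outside [1, {total}]")
    work = t.copy()
    if not work.is_binary():
        raise ValueError("pruning requires a strictly binary tree")
    root = work.root
    counts = _leaf_counts(root)
    removed: list[str] = []

    current = total
    while current > n:
        # minimal-height cherry; ties by smallest member name for determinism
        best: Node | None = None
        best_key: tuple[float, str] | None = None
        for node in root.iter_postorder():
            if node.is_leaf or not all(ch.is_leaf for ch in node.children):
                continue
            key = (node.height, min(ch.name for ch in node.children))
            if best_key is None or key < best_key:
                best, best_key = node, key
        assert best is not None, "binary tree with >1 leaf must contain a cherry"

        a, b = best.children
        sa = _summed_cophenetic(a, counts)
        sb = _summed_cophenetic(b, counts)
        if sa < sb:
            victim, keeper = a, b
        elif sb < sa:
            victim, keeper = b, a
        else:
            victim, keeper = (a, b) if a.name > b.name else (b, a)
        removed.append(victim.name)

        parent = best
        grand = parent.parent
        if grand is None:
            keeper.length = None
            keeper.parent = None
            root = keeper
        else:
            keeper.length = (keeper.length or 0.0) + (parent.length or 0.0)
            grand.children[grand.children.index(parent)] = keeper
            keeper.parent = grand
        # leaf counts along the surviving ancestor chain drop by one
        anc = grand
        while anc is not None:
            counts[id(anc)] -= 1
            anc = anc.parent
        current -= 1

    return Tree(root), removed
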