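"""Locating gene-family concentrations on the coexpression tree.

Every internal-node clade of at least ``min_size`` leaves is scored by how
many members of a gene family it contains.  Candidates are ranked by
family count (ties: smaller clade first, so the tightest clade capturing a
given number of family members outranks its ancestors), and a clade
nested inside an already-reported clade with at least the same count is
suppressed, yielding maximal-clade reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .tree import Node, Tree

__all__ = ["FamilyClade", "family_clade_scan"]


@dataclass
class FamilyClade:
    """One reported clade of the family scan."""

    size: int
    family_count: int
    family_fraction: float
    leaf_names: list[str]
    root: Node

    @property
    def label(self) -> str:
        return min(self.leaf_names)


def family_clade_scan(
    t: Tree, family: Iterable[str], min_size: int = 2
) -> list[FamilyClade]:
    """Ranked clades concentrating the given family across the tree."""
    fam = set(family)
    present = fam & set(t.leaf_names())
    if not present:
        raise ValueError("no family member is a leaf of the tree")

    stats: dict[int, tuple[int, int, list[str]]] = {}
    candidates: list[Node] = []
    for node in t.root.iter_postorder():
        if node.is_leaf:
            stats[id(node)] = (1, 1 if node.name in fam else 0, [node.name])
            continue
        size = count = 0
        names: list[str] = []
        for ch in node.children:
            s, c, nm = stats[id(ch)]
            size += s
            count += c
            names += nm
        stats[id(node)] = (size, count, names)
        if size >= min_size and count > 0:
            candidates.append(node)

    def key(node: Node) -> tuple[int, int, str]:
        size, count, names = stats[id(node)]
        return (-count, size, min(names))

    reported: list[FamilyClade] = []
    reported_nodes: list[Node] = []
    for node in sorted(candidates, key=key):
        anc = node.parent
        suppressed = False
        while anc is not None:
            if any(anc is r for r in reported_nodes):
                suppressed = True  # earlier report has >= this count by rank order
                break
            anc = anc.parent
        if suppressed:
            continue
        size, count, names = stats[id(node)]
        reported.append(
            FamilyClade(
                size=size,
                family_count=count,
                family_fraction=count / size,
                leaf_names=sorted(names),
                root=node,
            )
        )
        reported_nodes.append(node)
    return reported
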