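"""Newick and square-PHYLIP serialization.

Newick parsing is delegated to dendropy; writing uses an in-package
serializer so sibling order follows the order of merge operands.  The
PHYLIP distance-matrix dialect is the square one: a count line followed by
one row per taxon (name, then the full row of distances); names are
whitespace-delimited and not length-limited.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import dendropy
import numpy as np

from .tree import DistanceMatrix, Node, Tree

__all__ = ["write_newick", "read_newick", "write_phylip", "read_phylip"]

_NEEDS_QUOTE = re.compile(r"[\s()\[\]:;,']")


def _fmt_label(label: str) -> str:
    if _NEEDS_QUOTE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_length(x: float) -> str:
    return format(float(x), ".10g")


def newick_string(t: Tree) -> str:
    """Serialize a tree to a Newick string with branch lengths."""

    def serialize(node: Node) -> str:
        if node.is_leaf:
            body = _fmt_label(node.name)
        else:
            body = "(" + ",".join(serialize(ch) for ch in node.children) + ")"
        if node.length is not None:
            body += ":" + _fmt_length(node.length)
        return body

    return serialize(t.root) + ";"


def write_newick(t: Tree, path: str | Path | None = None) -> str:
    s = newick_string(t)
    if path is not None:
        Path(path).write_text(s + "\n")
    return s


def read_newick(source: str | Path) -> Tree:
    """Parse a Newick file or string into a :class:`Tree`.

    Node heights are reconstructed as each node's maximal distance down to
    its descendant leaves (exactly the merge height for ultrametric
    trees).  Unlabelled internal nodes are accepted.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "(" not in source and Path(source).exists()
    ):
        data = Path(source).read_text()
    else:
        data = str(source)
    try:
        dtree = dendropy.Tree.get(
            data=data,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed Newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        children = [convert(ch) for ch in dnode.child_nodes()]
        if children:
            node = Node(children=children)
            node.height = max(ch.height + (ch.length or 0.0) for ch in children)
        else:
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is None:
                raise ValueError("unlabelled leaf in Newick input")
            node = Node(name=label)
        node.length = dnode.edge.length
        return node

    root = convert(dtree.seed_node)
    root.length = None
    return Tree(root)


# ---------------------------------------------------------------------------
# PHYLIP square distance matrices
# ---------------------------------------------------------------------------


def _sanitize_names(names: list[str]) -> tuple[list[str], dict[str, str]]:
    mapping: dict[str, str] = {}
    clean: list[str] = []
    seen: set[str] = set()
    for name in names:
        c = re.sub(r"\s+", "_", name)
        base = c
        k = 1
        while c in seen:
            k += 1
            c = f"{base}_{k}"
        seen.add(c)
        if c != name:
            mapping[name] = c
        clean.append(c)
    return clean, mapping


def write_phylip(dm: DistanceMatrix, path: str | Path) -> dict[str, str]:
    """Write a square PHYLIP distance matrix.

    Names containing whitespace are sanitized (warned, and the original to
    sanitized mapping is returned).
    """
    clean, mapping = _sanitize_names(list(dm.ids))
    if mapping:
        warnings.warn(
            f"sanitized {len(mapping)} taxon name(s) containing whitespace",
            stacklevel=2,
        )
    with open(path, "w") as fh:
        fh.write(f"{len(clean)}\n")
        for name, row in zip(clean, dm.d):
            fh.write(name + "  " + "  ".join(format(v, ".10g") for v in row) + "\n")
    return mapping


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix."""
    tokens = Path(path).read_text().split()
    if not tokens:
        raise ValueError("empty PHYLIP file")
    try:
        n = int(tokens[0])
    except ValueError as exc:
        raise ValueError(f"bad taxon count line: {tokens[0]!r}") from exc
    body = tokens[1:]
    if len(body) != n * (n + 1):
        raise ValueError(
            f"expected {n} rows of 1 name + {n} distances "
            f"({n * (n + 1)} tokens), found {len(body)}"
        )
    names: list[str] = []
    d = np.zeros((n, n))
    for i in range(n):
        row = body[i * (n + 1) : (i + 1) * (n + 1)]
        names.append(row[0])
        try:
            d[i] = [float(v) for v in row[1:]]
        except ValueError as exc:
            raise ValueError(f"non-numeric distance in row {row[0]!r}") from exc
    return DistanceMatrix(names, d)
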