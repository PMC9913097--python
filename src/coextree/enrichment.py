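"""Hypergeometric term enrichment of a coexpression clade.

For a clade of n genes drawn from a universe of N, a term annotating K
universe genes and hitting k clade genes gets the upper-tail probability
P(X >= k) under X ~ Hypergeometric(N, K, n).  P-values are adjusted per
category with Benjamini-Hochberg FDR; the report keeps terms with adjusted
p <= 0.05, ranked by raw p ascending, together with the expected hit count
nK/N, the over-representation rate k/expected and the hit percentage
100*k/K (the share of the term's genes captured by the clade).

Only terms with at least one clade hit are tested, and only those count
toward the BH family size m.  The universe defaults to all genes in the
coexpression tree.  Identifiers are matched case-sensitively on stable
IDs; versioned IDs are truncated at the first dot before matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .expression import strip_gene_version

__all__ = [
    "TermLibrary",
    "EnrichmentRow",
    "read_gmt",
    "write_gmt",
    "hypergeom_pvalue",
    "bh_fdr",
    "enrich",
]


@dataclass
class TermLibrary:
    """A category of gene sets: term id -> (description, gene ids)."""

    category: str
    terms: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid!r} has an empty gene set")


@dataclass
class EnrichmentRow:
    term_id: str
    description: str
    p: float
    p_adj: float
    k: int           # clade genes annotated by the term
    n: int           # clade genes in the universe
    K: int           # universe genes annotated by the term
    N: int           # universe size
    expected: float  # n * K / N
    over_representation: float
    hit_percent: float


def read_gmt(path: str | Path, category: str | None = None) -> TermLibrary:
    """Read a GMT file (term, description, then one gene per column)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {ln}: need term, description and >=1 gene")
        tid, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if tid in terms:
            raise ValueError(f"GMT line {ln}: duplicate term {tid!r}")
        terms[tid] = (desc, frozenset(genes))
    return TermLibrary(category or Path(path).stem, terms)


def write_gmt(lib: TermLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid, (desc, genes) in lib.terms.items():
            fh.write("\t".join([tid, desc, *sorted(genes)]) + "\n")


def hypergeom_pvalue(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid sizes: N={N}, K={K}, n={n}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"hits k={k} outside [0, min(n={n}, K={K})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    clade_genes: Iterable[str],
    lib: TermLibrary,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentRow]:
    """Enrichment of a clade against one term library.

    Returns rows for terms with FDR-adjusted p <= ``alpha``, ranked by raw
    p ascending (ties: higher over-representation first, then term id).
    """
    uni = {strip_gene_version(g) for g in universe}
    if not uni:
        raise ValueError("empty universe")
    clade = {strip_gene_version(g) for g in clade_genes} & uni
    missing = {strip_gene_version(g) for g in clade_genes} - uni
    if missing:
        raise ValueError(f"clade genes outside the universe: {sorted(missing)[:5]}")
    N, n = len(uni), len(clade)

    tested: list[tuple[str, str, int, int]] = []
    for tid, (desc, genes) in lib.terms.items():
        tset = {strip_gene_version(g) for g in genes} & uni
        k = len(tset & clade)
        if k >= 1:
            tested.append((tid, desc, k, len(tset)))
    if not tested:
        return []

    pvals = [hypergeom_pvalue(N, K, n, k) for (_, _, k, K) in tested]
    padj = bh_fdr(pvals)

    rows: list[EnrichmentRow] = []
    for (tid, desc, k, K), p, pa in zip(tested, pvals, padj):
        if pa > alpha:
            continue
        expected = n * K / N
        rows.append(
            EnrichmentRow(
                term_id=tid,
                description=desc,
                p=p,
                p_adj=float(pa),
                k=k,
                n=n,
                K=K,
                N=N,
                expected=expected,
                over_representation=k / expected,
                hit_percent=100.0 * k / K,
            )
        )
    rows.sort(key=lambda r: (r.p, -r.over_representation, r.term_id))
    return rows
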