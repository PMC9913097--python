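"""Query documents: clade + enrichment results as a validated JSON shape.

A query is keyed on a driver gene ID, an internal-node count and an
optional two-character enrichment category keyword.  An unknown or absent
keyword simply omits the enrichment block (it is not an error); an
unknown driver yields a structured error document.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

from pydantic import BaseModel

from .clade import clade_at, clade_gene_list, clade_newick
from .enrichment import TermLibrary, enrich
from .expression import strip_gene_version
from .tree import Tree

__all__ = ["CATEGORY_KEYWORDS", "run_query", "validate_document", "QueryDocument"]

log = logging.getLogger("coextree.api")

# two-character category keywords -> human-readable category labels
CATEGORY_KEYWORDS: dict[str, str] = {
    "bp": "GO: Biological Process",
    "mf": "GO: Molecular Function",
    "cc": "GO: Cellular Component",
    "ke": "KEGG Pathways",
    "wi": "WikiPathways",
    "tf": "Transcription Factor Targets",
    "di": "Gene-Disease Associations",
    "pf": "Protein Families",
    "cb": "Cytogenetic Bands",
}


class DriverBlock(BaseModel):
    gene_id: str
    description: str = ""


class CladeBlock(BaseModel):
    newick: str
    internal_node_count: int
    capped: bool
    size: int
    genes: list[list[str]]  # [gene id, description] pairs


class EnrichmentEntry(BaseModel):
    term_id: str
    description: str
    p: float
    p_adj: float
    k: int
    n: int
    K: int
    N: int
    expected: float
    over_representation: float
    hit_percent: float


class EnrichmentBlock(BaseModel):
    category: str
    keyword: str
    family_size: int  # m, the number of terms entering BH adjustment
    rows: list[EnrichmentEntry]


class QueryDocument(BaseModel):
    driver: DriverBlock
    clade: CladeBlock
    enrichment: EnrichmentBlock | None = None


class ErrorDocument(BaseModel):
    error: str
    driver: str


def run_query(
    tree: Tree,
    driver: str,
    k: int,
    keyword: str | None = None,
    libraries: Mapping[str, TermLibrary] | None = None,
    descriptions: dict[str, str] | None = None,
) -> dict:
    """Extract a clade and optionally enrich it; returns a plain dict."""
    libraries = libraries or {}
    try:
        c = clade_at(tree, driver, k)
    except KeyError as exc:
        log.warning("query failed: %s", exc)
        return ErrorDocument(error=str(exc), driver=driver).model_dump()

    doc = QueryDocument(
        driver=DriverBlock(
            gene_id=driver, description=(descriptions or {}).get(driver, "")
        ),
        clade=CladeBlock(
            newick=clade_newick(c),
            internal_node_count=c.internal_node_count,
            capped=c.capped,
            size=c.size,
            genes=[[g, d] for g, d in clade_gene_list(c, descriptions)],
        ),
    )
    if keyword in CATEGORY_KEYWORDS and keyword in libraries:
        lib = libraries[keyword]
        universe = tree.leaf_names()
        rows = enrich(c.gene_ids, lib, universe)
        # m = tested terms: those with >= 1 clade hit in the universe
        clade_set = {strip_gene_version(g) for g in c.gene_ids}
        m = sum(
            1
            for _, (_, genes) in lib.terms.items()
            if {strip_gene_version(g) for g in genes} & clade_set
        )
        doc.enrichment = EnrichmentBlock(
            category=lib.category,
            keyword=keyword,
            family_size=m,
            rows=[EnrichmentEntry(**dataclasses.asdict(r)) for r in rows],
        )
    log.info(
        "query driver=%s k=%d capped=%s m=%s",
        driver,
        k,
        c.capped,
        doc.enrichment.family_size if doc.enrichment else None,
    )
    return doc.model_dump()


def validate_document(doc: dict) -> QueryDocument:
    """Validate a query result against the shipped schema."""
    return QueryDocument.model_validate(doc)
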