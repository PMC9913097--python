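"""Synthetic expression data with planted ground truth.

A latent-factor Gaussian model generates coexpression modules: every gene
of module m is sqrt(rho) * z_m + sqrt(1 - rho) * noise for a shared
latent profile z_m, so the expected pairwise Pearson correlation within
the module is exactly rho and the calibration needs no tuning.
Background genes are independent noise.  A companion generator produces
grouped samples (tissue-like structure) as positive counts for exercising
group-aware normalization and representative pruning, and a third emits
term libraries in which each planted module has a matching term plus
size-matched decoys.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import TermLibrary
from .expression import ExpressionMatrix, SampleMetadata

__all__ = ["make_module_matrix", "make_grouped_samples", "make_term_library"]


def make_module_matrix(
    n_modules: int,
    genes_per_module: int,
    n_background: int,
    n_samples: int,
    within_r: float = 0.9,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, list[str]]]:
    """Expression matrix with planted coexpression modules.

    Returns the matrix (log2 scale, Gaussian values) and a map from module
    name to its gene ids.  ``within_r`` is the expected within-module
    pairwise Pearson correlation and must lie in (0, 1).
    """
    if not 0.0 < within_r < 1.0:
        raise ValueError(f"within_r must lie strictly in (0, 1), got {within_r}")
    if n_modules < 0 or genes_per_module < 1 or n_background < 0 or n_samples < 2:
        raise ValueError("invalid counts")
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    modules: dict[str, list[str]] = {}
    a, b = np.sqrt(within_r), np.sqrt(1.0 - within_r)
    for m in range(n_modules):
        z = rng.standard_normal(n_samples)
        ids = [f"MOD{m}_G{i}" for i in range(genes_per_module)]
        modules[f"MOD{m}"] = ids
        for gid in ids:
            rows.append(a * z + b * rng.standard_normal(n_samples))
            gene_ids.append(gid)
    for i in range(n_background):
        rows.append(rng.standard_normal(n_samples))
        gene_ids.append(f"BG{i}")
    data = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n_samples)),
        index=gene_ids,
        columns=[f"S{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(data, "log2"), modules


def make_grouped_samples(
    groups: int,
    per_group: int,
    shift: float = 2.0,
    seed: int = 0,
    n_genes: int = 200,
    n_cell_line: int = 0,
) -> tuple[ExpressionMatrix, dict[str, SampleMetadata]]:
    """Count matrix whose samples cluster by group, plus matching metadata.

    Each group perturbs a shared log-mean profile by a group-specific
    offset of magnitude ``shift`` on every gene; counts are Poisson around
    the exponentiated means, so shift = 0 makes the groups statistically
    indistinguishable.  Optionally the last ``n_cell_line`` samples of the
    first group are flagged as cell lines.
    """
    if groups < 1 or per_group < 1:
        raise ValueError("need >= 1 group with >= 1 sample")
    rng = np.random.default_rng(seed)
    base = rng.normal(3.0, 1.0, n_genes)  # shared log-scale gene means
    cols: dict[str, np.ndarray] = {}
    meta: dict[str, SampleMetadata] = {}
    flagged = 0
    for g in range(groups):
        offset = shift * rng.standard_normal(n_genes)
        for s in range(per_group):
            sid = f"G{g}_S{s}"
            mu = np.exp(base + offset + 0.1 * rng.standard_normal(n_genes))
            cols[sid] = rng.poisson(mu).astype(float)
            is_cl = g == 0 and flagged < n_cell_line
            if is_cl:
                flagged += 1
            meta[sid] = SampleMetadata(sid, f"group{g}", is_cl)
    data = pd.DataFrame(cols, index=[f"GENE{i}" for i in range(n_genes)])
    return ExpressionMatrix(data, "counts"), meta


def make_term_library(
    modules: dict[str, list[str]],
    universe: list[str],
    n_decoys: int = 5,
    seed: int = 0,
    category: str = "synthetic",
) -> TermLibrary:
    """One term per planted module plus size-matched random decoy terms."""
    rng = np.random.default_rng(seed)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    sizes = [len(g) for g in modules.values()] or [5]
    for name, genes in modules.items():
        terms[f"TERM_{name}"] = (f"planted module {name}", frozenset(genes))
    pool = np.asarray(universe)
    for i in range(n_decoys):
        size = min(int(sizes[i % len(sizes)]), len(pool))
        pick = rng.choice(pool, size=size, replace=False)
        terms[f"DECOY{i}"] = (f"random decoy {i}", frozenset(pick.tolist()))
    return TermLibrary(category, terms)
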