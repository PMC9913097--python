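"""End-to-end drivers tying the preprocessing and tree stages together.

The preprocessing order mirrors the intended workflow: gene filters
(zero-SD, detected on the TPM matrix when one is supplied; ID suffix and
deprecated-ID rules) and the cell-line sample filter run first, then the
surviving count matrix is normalized group-aware (qsmooth) and finally
floored at the lowest non-zero value and log2-transformed.  Whether the
correlation step consumes log2-normalized counts or log2 TPM is a
configuration choice; the default is log2 of qsmooth-normalized counts.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .expression import (
    ExpressionMatrix,
    FilterReport,
    SampleMetadata,
    drop_cell_line_samples,
    filter_gene_ids,
    filter_zero_sd_genes,
    replace_zeros_and_log2,
)
from .qsmooth import qsmooth_normalize
from .tree import Tree, corr_to_distance, pearson_matrix, upgma

__all__ = ["preprocess_pipeline", "build_coexpression_tree"]


def preprocess_pipeline(
    counts: ExpressionMatrix,
    meta: Mapping[str, SampleMetadata],
    tpm: ExpressionMatrix | None = None,
    suffix: str = "_PAR_Y",
    deprecated: Iterable[str] = (),
    log2_output: bool = True,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Filters, group-aware normalization and (optionally) the log2 step."""
    detect = tpm if tpm is not None else counts
    _, rep_sd = filter_zero_sd_genes(detect)
    report = rep_sd
    drop = set(rep_sd.removed_zero_sd)
    kept = counts.data.loc[[g for g in counts.gene_ids if g not in drop]]
    m = ExpressionMatrix(kept, counts.scale)
    m, rep_ids = filter_gene_ids(m, suffix=suffix, deprecated=deprecated)
    report = report.merge(rep_ids)
    m, rep_cl = drop_cell_line_samples(m, meta)
    report = report.merge(rep_cl)
    m = qsmooth_normalize(m, meta)
    if log2_output:
        m = replace_zeros_and_log2(m)
    return m, report


def build_coexpression_tree(m: ExpressionMatrix, axis: str = "genes") -> Tree:
    """Pearson correlation -> d = 1 - r -> UPGMA tree over genes or samples."""
    return upgma(corr_to_distance(pearson_matrix(m, axis=axis)))
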