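"""Expression matrices: loading, filtering and the log2 transform.

The container is a thin wrapper around a genes x samples pandas DataFrame
plus a *scale* tag recording what the numbers mean: raw ``counts``,
``tpm`` (transcripts per million) or ``log2`` values.  Filters return both
the reduced matrix and a :class:`FilterReport` so a pipeline can audit
exactly which genes and samples were dropped and why.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "FilterReport",
    "load_expression",
    "write_expression",
    "load_metadata",
    "replace_zeros_and_log2",
    "filter_zero_sd_genes",
    "filter_gene_ids",
    "drop_cell_line_samples",
    "strip_gene_version",
]

_SCALES = ("counts", "tpm", "log2")


def strip_gene_version(gene_id: str) -> str:
    """Stable ID of a possibly versioned gene ID (truncate at the first dot)."""
    return gene_id.split(".", 1)[0]


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotation: tissue/group label and a cell-line flag."""

    sample_id: str
    group_label: str
    is_cell_line: bool = False

    def __post_init__(self) -> None:
        if not self.group_label:
            raise ValueError(f"sample {self.sample_id!r}: empty group label")


@dataclass
class FilterReport:
    """Audit record of preprocessing filters.

    Each list holds the identifiers removed by one rule; the lists are
    disjoint from the retained gene/sample sets of the filtered matrix.
    """

    removed_zero_sd: list[str] = field(default_factory=list)
    removed_suffix: list[str] = field(default_factory=list)
    removed_deprecated: list[str] = field(default_factory=list)
    removed_cell_line_samples: list[str] = field(default_factory=list)

    def merge(self, other: "FilterReport") -> "FilterReport":
        return FilterReport(
            self.removed_zero_sd + other.removed_zero_sd,
            self.removed_suffix + other.removed_suffix,
            self.removed_deprecated + other.removed_deprecated,
            self.removed_cell_line_samples + other.removed_cell_line_samples,
        )


class ExpressionMatrix:
    """A genes x samples numeric matrix with identifiers and a scale tag.

    Parameters
    ----------
    data
        DataFrame with gene IDs as the index and sample IDs as columns.
    scale
        One of ``counts``, ``tpm``, ``log2``.
    """

    def __init__(self, data: pd.DataFrame, scale: str):
        if scale not in _SCALES:
            raise ValueError(f"unknown scale {scale!r}; expected one of {_SCALES}")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        values = data.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression values must all be finite")
        if scale in ("counts", "tpm") and values.size and values.min() < 0:
            raise ValueError(f"negative values are invalid on the {scale} scale")
        self.data = data
        self.scale = scale

    # -- basic introspection -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float, copy=False)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, "
            f"scale={self.scale!r})"
        )


def load_expression(path: str | Path | io.TextIOBase, scale: str) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    The file has a header row of sample IDs and one row per gene with the
    gene ID in the first column.  An optional two-line GCT preamble
    (``#1.2`` followed by a dimensions line) is tolerated and skipped.
    Row and column order are preserved.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:
        text = path.read()
    lines = text.splitlines()
    skip = 2 if lines and lines[0].startswith("#1.2") else 0
    raw = pd.read_csv(
        io.StringIO("\n".join(lines[skip:])), sep="\t", index_col=0, dtype=str
    )
    raw.index = raw.index.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gi, sj = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric value {raw.iat[gi, sj]!r} at gene "
            f"{raw.index[gi]!r}, sample {raw.columns[sj]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, sj = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing value at gene {raw.index[gi]!r}, sample {raw.columns[sj]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), scale)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV (gene IDs in the first column)."""
    m.data.to_csv(path, sep="\t", index_label="gene_id")


def load_metadata(path: str | Path) -> dict[str, SampleMetadata]:
    """Read sample metadata (TSV: sample_id, group, is_cell_line)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    try:
        sid, grp, flag = cols["sample_id"], cols["group"], cols["is_cell_line"]
    except KeyError as exc:
        raise ValueError(f"metadata missing column {exc}") from exc
    truthy = {"1", "true", "yes"}
    out: dict[str, SampleMetadata] = {}
    for _, row in df.iterrows():
        s = str(row[sid])
        if s in out:
            raise ValueError(f"duplicate sample ID in metadata: {s!r}")
        out[s] = SampleMetadata(s, str(row[grp]), str(row[flag]).lower() in truthy)
    return out


def replace_zeros_and_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace zeros by the matrix-wide minimum non-zero value, then log2.

    The replacement value is global (one number for the whole matrix), so
    every gene's zeros map to the same floor before the transform.  Requires
    at least one strictly positive value.
    """
    values = m.values.copy()
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("all-zero matrix: no non-zero minimum exists")
    floor = positive.min()
    values[values == 0] = floor
    out = pd.DataFrame(np.log2(values), index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(out, "log2")


def filter_zero_sd_genes(m: ExpressionMatrix) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes constant across all samples (zero standard deviation).

    Constancy is tested exactly (row max == row min), not with a floating
    tolerance, so the filter is deterministic.
    """
    if m.n_genes == 0:
        raise ValueError("empty matrix")
    values = m.values
    constant = values.max(axis=1) == values.min(axis=1)
    removed = [g for g, c in zip(m.gene_ids, constant) if c]
    kept = m.data.loc[~constant]
    return (
        ExpressionMatrix(kept, m.scale),
        FilterReport(removed_zero_sd=removed),
    )


def filter_gene_ids(
    m: ExpressionMatrix,
    suffix: str = "_PAR_Y",
    deprecated: Iterable[str] = (),
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes by versioned-ID suffix or deprecated stable ID.

    ``suffix`` targets e.g. Y-chromosome pseudoautosomal copies carrying a
    ``_PAR_Y`` marker in the version code; ``deprecated`` is a set of stable
    IDs (version part ignored when matching).
    """
    dep = {strip_gene_version(d) for d in deprecated}
    removed_suffix: list[str] = []
    removed_deprecated: list[str] = []
    keep: list[bool] = []
    for g in m.gene_ids:
        if suffix and g.endswith(suffix):
            removed_suffix.append(g)
            keep.append(False)
        elif strip_gene_version(g) in dep:
            removed_deprecated.append(g)
            keep.append(False)
        else:
            keep.append(True)
    kept = m.data.loc[np.asarray(keep, dtype=bool)]
    return (
        ExpressionMatrix(kept, m.scale),
        FilterReport(removed_suffix=removed_suffix, removed_deprecated=removed_deprecated),
    )


def drop_cell_line_samples(
    m: ExpressionMatrix, meta: Mapping[str, SampleMetadata]
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop samples flagged as cell lines in the metadata."""
    missing = [s for s in m.sample_ids if s not in meta]
    if missing:
        raise KeyError(f"samples missing from metadata: {missing[:5]}")
    removed = [s for s in m.sample_ids if meta[s].is_cell_line]
    kept = m.data.drop(columns=removed)
    return (
        ExpressionMatrix(kept, m.scale),
        FilterReport(removed_cell_line_samples=removed),
    )
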