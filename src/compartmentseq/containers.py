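"""Core in-memory containers shared across the pipeline.

Everything is a thin, validated wrapper around pandas objects so that
downstream modules can rely on a consistent gene × sample grid and on
sample metadata (isolation method, cell type, sex) always being present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METHODS = ("nuclear", "wholecell", "ribotag")
CELL_TYPES = ("D1", "D2")
SEXES = ("M", "F")

METADATA_COLUMNS = ("method", "cell_type", "sex")


def _check_metadata(metadata: pd.DataFrame, sample_ids) -> pd.DataFrame:
    missing_cols = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing_cols:
        raise ValueError(f"metadata is missing columns: {missing_cols}")
    missing = [s for s in sample_ids if s not in metadata.index]
    if missing:
        raise ValueError(f"metadata does not cover samples: {missing[:5]}")
    bad_method = set(metadata["method"]) - set(METHODS)
    if bad_method:
        raise ValueError(f"unknown method labels: {sorted(bad_method)}")
    bad_ct = set(metadata["cell_type"]) - set(CELL_TYPES)
    if bad_ct:
        raise ValueError(f"unknown cell type labels: {sorted(bad_ct)}")
    return metadata.loc[list(sample_ids)]


@dataclass
class CountMatrix:
    """Integer gene × sample count matrix with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id.
    metadata
        DataFrame indexed by sample id with columns ``method``
        (nuclear / wholecell / ribotag), ``cell_type`` (D1 / D2) and
        ``sex`` (M / F).
    counting_mode
        ``"exon"`` for exon-only counting, ``"all"`` for all-feature
        counting.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    counting_mode: str = "all"

    def __post_init__(self) -> None:
        if self.counting_mode not in ("exon", "all"):
            raise ValueError(f"unknown counting mode {self.counting_mode!r}")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        values = self.counts.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.metadata = _check_metadata(self.metadata, self.counts.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], self.metadata,
                           self.counting_mode)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)],
                           self.metadata.loc[list(sample_ids)],
                           self.counting_mode)

    def subset_method(self, method: str) -> "CountMatrix":
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
        keep = self.metadata.index[self.metadata["method"] == method]
        return self.subset_samples(keep)


@dataclass
class GeneAnnotation:
    """Gene-level annotation: exonic length, biotype and coordinates.

    ``table`` is indexed by gene id with columns ``length_bp`` (union of
    exons, 1-based inclusive), ``biotype``, ``chrom``, ``start``, ``stop``.
    """

    table: pd.DataFrame

    REQUIRED = ("length_bp", "biotype", "chrom", "start", "stop")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if (self.table["length_bp"] <= 0).any():
            bad = self.table.index[self.table["length_bp"] <= 0]
            raise ValueError(f"non-positive length for genes: {list(bad[:5])}")
        if (self.table["start"] >= self.table["stop"]).any():
            bad = self.table.index[self.table["start"] >= self.table["stop"]]
            raise ValueError(f"start >= stop for genes: {list(bad[:5])}")

    def lengths_for(self, gene_ids) -> pd.Series:
        missing = [g for g in gene_ids if g not in self.table.index]
        if missing:
            raise KeyError(
                f"genes without annotated length: {missing[:10]}"
                + (" ..." if len(missing) > 10 else "")
            )
        return self.table.loc[list(gene_ids), "length_bp"]

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index


EXPRESSION_UNITS = ("FPM", "FPKM", "normalized_count", "vst", "log_expression")


@dataclass
class ExpressionMatrix:
    """Real-valued gene × sample expression on the same grid as its source."""

    values: pd.DataFrame
    unit: str
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ValueError(f"unknown expression unit {self.unit!r}")
        if self.unit in ("FPM", "FPKM", "normalized_count"):
            vals = self.values.to_numpy()
            if vals.size and (vals < 0).any():
                raise ValueError(f"{self.unit} values must be non-negative")
        if self.metadata is not None:
            self.metadata = _check_metadata(self.metadata, self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class FilterReport:
    """Bookkeeping for a filtering step: per-rule pass counts and totals."""

    name: str
    genes_in: int
    genes_out: int
    rule_pass_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genes_out > self.genes_in:
            raise ValueError("genes_out exceeds genes_in")

    @property
    def genes_removed(self) -> int:
        return self.genes_in - self.genes_out
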