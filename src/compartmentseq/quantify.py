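"""Expression units, normalization and the detection / final filter cascade.

FPM and FPKM are computed against each sample's *unfiltered* library total,
so filtering never changes the denominator. Size factors use the
median-of-ratios estimator; the variance-stabilizing transform is a
documented stand-in, ``log2(count / size_factor + 1)``, which is monotone in
counts within each sample and adequate for PCA, variance partitioning and
co-expression input.

The filtering cascade mirrors a two-stage design: a permissive detection
filter (fragments-per-million threshold in a minimum number of samples)
followed by method-specific final FPKM filters — a stringent low filter for
the complex nuclear and whole-cell libraries, a relaxed low filter with a
two-sample requirement for the sparser ribosome-bound libraries, and a
common high cap removing over-amplification artifacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    METHODS,
    CountMatrix,
    ExpressionMatrix,
    FilterReport,
    GeneAnnotation,
)

FPKM_CAP = 5e4


def compute_fpm(counts: CountMatrix) -> ExpressionMatrix:
    """Fragments per million: ``count / (library_total / 1e6)``."""
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero)}")
    values = counts.counts / totals * 1e6
    return ExpressionMatrix(values, "FPM", counts.metadata)


def compute_fpkm(counts: CountMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Fragments per kilobase per million:
    ``count / ((length_bp / 1e3) * (library_total / 1e6))``."""
    lengths = annotation.lengths_for(counts.gene_ids)
    fpm = compute_fpm(counts)
    values = fpm.values.div(lengths.to_numpy() / 1e3, axis=0)
    return ExpressionMatrix(values, "FPKM", counts.metadata)


def intron_fraction(all_counts: CountMatrix, exon_counts: CountMatrix) -> pd.DataFrame:
    """Per-gene per-sample intronic fraction ``(all - exon) / all``.

    Undefined (NaN) where the all-feature count is zero.
    """
    if not all_counts.counts.index.equals(exon_counts.counts.index) or not (
        all_counts.counts.columns.equals(exon_counts.counts.columns)
    ):
        raise ValueError("all-feature and exon-only matrices are on different grids")
    a = all_counts.counts.to_numpy(dtype=float)
    e = exon_counts.counts.to_numpy(dtype=float)
    violations = int((a < e).sum())
    if violations:
        raise ValueError(
            f"{violations} cells have exon counts exceeding all-feature counts"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(a > 0, (a - e) / a, np.nan)
    return pd.DataFrame(frac, index=all_counts.counts.index, columns=all_counts.counts.columns)


def detection_filter(
    counts: CountMatrix,
    min_fpm: float = 1.0,
    min_samples: int = 2,
    inclusive: bool = False,
) -> tuple[CountMatrix, FilterReport]:
    """Keep genes exceeding ``min_fpm`` FPM in at least ``min_samples``
    samples.

    The threshold is strict (``>``) by default; ``inclusive=True`` switches
    to ``>=``.
    """
    if min_samples > counts.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {counts.n_samples} available samples"
        )
    fpm = compute_fpm(counts).values
    hits = (fpm >= min_fpm) if inclusive else (fpm > min_fpm)
    keep = hits.sum(axis=1) >= min_samples
    out = counts.subset_genes(counts.gene_ids[keep])
    report = FilterReport(
        name="detection",
        genes_in=counts.n_genes,
        genes_out=int(keep.sum()),
        rule_pass_counts={"min_fpm_in_min_samples": int(keep.sum())},
    )
    return out, report


def final_filter(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    method: str,
    fpkm_cap: float = FPKM_CAP,
) -> tuple[CountMatrix, FilterReport]:
    """Method-specific final FPKM filter.

    nuclear / wholecell: FPKM >= 1 in at least one sample;
    ribotag: FPKM >= 0.1 in at least two samples;
    all methods: FPKM <= ``fpkm_cap`` in every sample.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    fpkm = compute_fpkm(counts, annotation).values
    if method == "ribotag":
        low_pass = (fpkm >= 0.1).sum(axis=1) >= 2
    else:
        low_pass = (fpkm >= 1.0).any(axis=1)
    cap_pass = (fpkm <= fpkm_cap).all(axis=1)
    keep = low_pass & cap_pass
    out = counts.subset_genes(counts.gene_ids[keep])
    report = FilterReport(
        name=f"final_{method}",
        genes_in=counts.n_genes,
        genes_out=int(keep.sum()),
        rule_pass_counts={
            "low_fpkm": int(low_pass.sum()),
            "fpkm_cap": int(cap_pass.sum()),
        },
    )
    return out, report


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Per gene, the geometric mean over samples is taken across genes with no
    zero count; each sample's factor is the median over those genes of
    ``count / geometric_mean``. Factors are reported unscaled.
    """
    mat = counts.counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in every sample")
    logs = np.log(mat[positive])
    log_geomean = logs.mean(axis=1)
    factors = np.exp(np.median(logs - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalized_counts(counts: CountMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Counts divided by their per-sample size factor."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    values = counts.counts / factors
    return ExpressionMatrix(values, "normalized_count", counts.metadata)


def vst_transform(counts: CountMatrix, factors: pd.Series) -> ExpressionMatrix:
    """Variance-stabilizing stand-in: ``log2(count / size_factor + 1)``."""
    if (factors <= 0).any():
        raise ValueError("size factors must be positive")
    values = np.log2(counts.counts / factors + 1.0)
    return ExpressionMatrix(values, "vst", counts.metadata)


def biotype_composition(gene_ids, annotation: GeneAnnotation) -> pd.Series:
    """Share of each biotype among ``gene_ids`` (sums to 1)."""
    gene_ids = list(gene_ids)
    if not gene_ids:
        return pd.Series(dtype=float)
    biotypes = annotation.table.loc[gene_ids, "biotype"]
    return biotypes.value_counts(normalize=True)
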