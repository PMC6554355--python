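"""Fisher's-exact gene-set enrichment and GWAS-catalog preparation.

Enrichment tests a 2x2 contingency table over a declared background
universe (for hub networks, all genes that entered network construction):
rows split the background by gene-set membership, columns by target
(e.g. hub-network) membership. The two-sided p follows the probability-mass
convention (the sum of hypergeometric table probabilities no larger than the
observed one). Catalog preparation filters lead variants at genome-wide
significance (strict p < 5e-8), drops intergenic variants (position must lie
within the named gene's start-stop interval, 1-based inclusive), maps genes
to orthologues and groups raw traits into curated superseding traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneSet:
    """A named gene set with a provenance note."""

    name: str
    genes: set
    provenance: str = ""

    def __post_init__(self) -> None:
        self.genes = set(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    """2x2 Fisher's-exact enrichment of a gene set in a target list."""

    set_name: str
    target_name: str
    table: tuple  # (a, b, c, d): (set&target, set&~target, ~set&target, ~set&~target)
    odds_ratio: float
    odds_ratio_haldane: float
    p: float
    threshold: float
    significant: bool
    notes: list = field(default_factory=list)


def fisher_enrichment(
    target_genes,
    set_genes,
    background_genes,
    n_tests: int = 1,
    set_name: str = "set",
    target_name: str = "target",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Two-sided Fisher's exact test of set-target overlap on a background.

    The set is intersected with the background before testing; the target
    must be a subset of the background. The Bonferroni threshold is
    ``alpha / n_tests``. A Haldane-corrected odds ratio (0.5 added to every
    cell) is reported alongside for tables with zero margins.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background")
    target = set(target_genes)
    stray = target - background
    if stray:
        raise ValueError(f"target genes outside background: {sorted(stray)[:5]}")
    s = set(set_genes) & background
    notes = []
    if not s:
        notes.append("gene set disjoint from background")
    a = len(s & target)
    b = len(s - target)
    c = len(target - s)
    d = len(background) - a - b - c
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
        notes.append("zero-margin cell: odds ratio undefined, see Haldane column")
    else:
        odds = (a * d) / (b * c)
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    threshold = alpha / n_tests
    return EnrichmentResult(
        set_name=set_name,
        target_name=target_name,
        table=(a, b, c, d),
        odds_ratio=float(odds),
        odds_ratio_haldane=float(haldane),
        p=float(p),
        threshold=threshold,
        significant=bool(p < threshold),
        notes=notes,
    )


DEFAULT_GWAS_COLUMNS = {
    "p": "P-VALUE",
    "gene": "MAPPED_GENE",
    "chrom": "CHR_ID",
    "position": "CHR_POS",
    "trait": "DISEASE/TRAIT",
}


def parse_gwas_catalog(
    catalog,
    annotation,
    p_threshold: float = 5e-8,
    columns: dict | None = None,
) -> pd.DataFrame:
    """Filter a GWAS-catalog-style association table to genic, genome-wide
    significant lead variants.

    ``catalog`` is a path or DataFrame. Rows are kept when the lead-variant
    p is strictly below ``p_threshold`` and the variant position lies within
    the named gene's annotated [start, stop] (1-based inclusive, same
    chromosome). Duplicate gene-trait pairs collapse to one. Returns a
    DataFrame with columns ``gene`` and ``trait``.
    """
    cols = dict(DEFAULT_GWAS_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(catalog, sep="\t") if not isinstance(catalog, pd.DataFrame) else catalog.copy()
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"catalog is missing required columns: {missing}")
    df = df[df[cols["p"]].astype(float) < p_threshold]
    ann = annotation.table
    gene_col = df[cols["gene"]].astype(str)
    in_ann = gene_col.isin(ann.index)
    df = df[in_ann]
    if df.empty:
        return pd.DataFrame(columns=["gene", "trait"])
    g = df[cols["gene"]].astype(str)
    pos = df[cols["position"]].astype(float)
    chrom = df[cols["chrom"]].astype(str)
    starts = ann.loc[g, "start"].to_numpy(dtype=float)
    stops = ann.loc[g, "stop"].to_numpy(dtype=float)
    chroms = ann.loc[g, "chrom"].astype(str).to_numpy()
    genic = (
        (chrom.to_numpy() == chroms)
        & (pos.to_numpy() >= starts)
        & (pos.to_numpy() <= stops)
    )
    out = pd.DataFrame(
        {"gene": g.to_numpy()[genic], "trait": df[cols["trait"]].astype(str).to_numpy()[genic]}
    )
    return out.drop_duplicates().reset_index(drop=True)


def map_orthologues(pairs: pd.DataFrame, ortho_map: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Map gene-trait pairs onto target-species ids.

    ``ortho_map`` has columns ``source`` and ``target``. Genes without an
    orthologue are dropped (their count is returned); one-to-many mappings
    expand to every target. Returns ``(mapped pairs, n_dropped_genes)``.
    """
    if ortho_map.empty:
        raise ValueError("empty orthologue map")
    merged = pairs.merge(ortho_map, left_on="gene", right_on="source", how="left")
    dropped = merged["target"].isna()
    n_dropped = int(merged.loc[dropped, "gene"].nunique())
    out = merged.loc[~dropped, ["target", "trait"]].rename(columns={"target": "gene"})
    return out.drop_duplicates().reset_index(drop=True), n_dropped


def curate_traits(pairs: pd.DataFrame, trait_map: dict) -> dict:
    """Group gene-trait pairs into superseding traits.

    ``trait_map`` maps raw trait name -> superseding trait name; unmapped
    traits are dropped. Returns a mapping of superseding trait ->
    :class:`GeneSet`, plus a pooled union set under the key ``"pooled"``.
    """
    import warnings

    mapped = pairs.copy()
    mapped["superseding"] = mapped["trait"].map(trait_map)
    mapped = mapped.dropna(subset=["superseding"])
    if mapped.empty:
        warnings.warn("no traits mapped by the curation table")
        return {}
    sets = {}
    for trait, group in mapped.groupby("superseding"):
        sets[str(trait)] = GeneSet(str(trait), set(group["gene"]), "curated GWAS traits")
    pooled = set(mapped["gene"])
    sets["pooled"] = GeneSet("pooled", pooled, "union of curated superseding traits")
    return sets
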