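"""Synthetic multi-compartment RNA-seq experiments with planted ground truth.

The generator emulates the design of a three-method comparison of cell
type-specific RNA-seq — nuclear-FACS, whole cell-FACS and ribosome-bound
affinity purification — of two closely related cell types (D1 / D2). For
each sample it draws gene-level negative-binomial counts twice, mirroring
all-feature and exon-only counting of the same library:

* per-gene baseline means are log-normal; per-gene NB dispersion ``alpha``
  gives Var = mu + alpha * mu**2;
* library totals are drawn uniformly from a configured range and applied as
  per-sample scalings (exercising size-factor normalization downstream);
* method-dependent capture biases are multiplicative on the mean: the
  ribosome-bound method strongly down-weights non-coding biotypes and short
  genes, while the nuclear method mildly up-weights non-coding genes;
* all-feature counts are split into exonic/intronic origin with a
  method-dependent intron share (nuclear > whole cell > ribosome-bound), so
  exon-only counts are a binomial thinning of all-feature counts and never
  exceed them;
* each method carries its own per-gene, per-sample log-scale technical
  jitter (nuclear noisiest, ribosome-bound tightest), mirroring the
  within-method variance ordering of the real libraries;
* cell-type differential expression (with a method-dependent biotype mix:
  nuclear differences extend across non-coding RNA, ribosome-bound ones
  concentrate in coding RNA), cross-compartment regulation categories,
  method-variable genes, sex effects and co-expression blocks are planted
  per the configuration and reported back as ground truth.

All randomness flows through one ``numpy.random.default_rng`` (PCG64)
instance seeded from ``SimConfig.seed``, so a fixed seed reproduces the
matrices bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CELL_TYPES, METHODS, CountMatrix, ExpressionMatrix, GeneAnnotation
from . import io as cio

REGULATION_CATEGORIES = ("transcriptional", "cytosolic", "translational")

# Compartments reached by a planted cell-type effect of each category:
# transcriptional differences originate in the nucleus and propagate all the
# way to the ribosome; cytosolic differences appear from the cytosol onwards
# (whole cell + ribosome-bound); translational differences only at the
# ribosome. This makes each category the unique signature of one step of the
# nucleus -> cytosol -> ribosome cascade.
CATEGORY_COMPARTMENTS = {
    "transcriptional": ("nuclear", "wholecell", "ribotag"),
    "cytosolic": ("wholecell", "ribotag"),
    "translational": ("ribotag",),
}


@dataclass(frozen=True)
class RegulationPlant:
    """One planted regulation effect: a cell-type shift in the compartments
    downstream of the regulated step."""

    gene: str
    category: str
    direction: str  # cell type that is enriched: "D1" or "D2"
    log2fc: float

    def __post_init__(self) -> None:
        if self.category not in REGULATION_CATEGORIES:
            raise ValueError(f"unknown regulation category {self.category!r}")
        if self.direction not in CELL_TYPES:
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class CoexpressionBlock:
    """A planted co-expression block: ``size`` genes sharing a latent
    per-sample factor ~ N(0, sd**2) added with weight ``loading`` on the log
    scale. ``start`` indexes into the gene list."""

    size: int
    loading: float
    sd: float = 1.0
    start: int | None = None
    loading_jitter: float = 0.0  # per-gene loading ~ U(1-j, 1+j) * loading


@dataclass
class MethodEffects:
    """Multiplicative capture biases per isolation method.

    ``intron_fraction``: expected intronic share of all-feature counts.
    ``noncoding_weight``: mean multiplier for non-protein-coding biotypes.
    ``short_gene_weight``: mean multiplier for genes shorter than
    ``short_gene_bp``. ``expression_shift``: global per-method multiplier.
    """

    intron_fraction: dict = field(
        default_factory=lambda: {"nuclear": 0.45, "wholecell": 0.25, "ribotag": 0.08}
    )
    noncoding_weight: dict = field(
        default_factory=lambda: {"nuclear": 2.0, "wholecell": 1.0, "ribotag": 0.1}
    )
    short_gene_weight: dict = field(
        default_factory=lambda: {"nuclear": 1.0, "wholecell": 1.0, "ribotag": 0.5}
    )
    short_gene_bp: int = 500
    expression_shift: dict = field(
        default_factory=lambda: {"nuclear": 1.0, "wholecell": 1.0, "ribotag": 1.0}
    )
    # per-gene, per-sample log2-scale technical jitter; the nuclear libraries
    # are the noisiest and the ribosome-bound ones the tightest
    sample_noise_log2: dict = field(
        default_factory=lambda: {"nuclear": 0.5, "wholecell": 0.35, "ribotag": 0.05}
    )


def _default_groups() -> dict:
    """The emulated study layout: 16 whole-cell (9 D1 / 7 D2), 11 nuclear
    (6 / 5) and 12 ribosome-bound (6 / 6) male samples."""
    return {
        ("nuclear", "D1", "M"): 6,
        ("nuclear", "D2", "M"): 5,
        ("wholecell", "D1", "M"): 9,
        ("wholecell", "D2", "M"): 7,
        ("ribotag", "D1", "M"): 6,
        ("ribotag", "D2", "M"): 6,
    }


@dataclass
class SimConfig:
    """Configuration of one synthetic experiment.

    Defaults define the desk-scale study conditions: 2 000 genes on the
    emulated study layout (16 whole-cell, 11 nuclear, 12 ribosome-bound
    male samples), a 15% planted differential fraction at |log2FC| = 1 with
    a method-dependent biotype mix, and capture biases and per-method
    technical noise that qualitatively mirror the three methods' library
    composition.
    """

    n_genes: int = 2000
    samples_per_group: dict = field(default_factory=_default_groups)
    baseline_mean_log: tuple = (3.0, 1.3)  # lognormal (mu, sigma), natural log
    dispersion_log: tuple = (np.log(0.05), 0.5)  # per-gene alpha ~ lognormal
    library_size_range: tuple = (8e5, 1.2e6)
    method_effects: MethodEffects = field(default_factory=MethodEffects)
    de_fraction: float = 0.15
    de_log2fc: float = 1.0
    # relative probability of sampling a non-coding gene when planting
    # cell-type DE per method: nuclear cell-type differences extend across
    # non-coding biotypes (nuclear-retained regulatory RNA), while
    # ribosome-bound differences concentrate in translated (coding) RNA
    de_noncoding_bias: dict = field(
        default_factory=lambda: {"nuclear": 2.0, "wholecell": 1.0, "ribotag": 0.25}
    )
    regulation_plan: list = field(default_factory=list)
    module_plan: list = field(default_factory=list)
    sex_effect_genes: list = field(default_factory=list)  # (gene, log2fc) pairs
    n_method_variable: int = 100
    method_variable_log2: tuple = (1.5, 3.0)  # uniform range of planted shift
    noncoding_fraction: float = 0.40
    noncoding_baseline_scale: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.library_size_range[0] <= 0:
            raise ValueError("library sizes must be positive")
        seen: dict = {}
        for method in METHODS:
            for ct in CELL_TYPES:
                n = sum(
                    v for (m, c, _s), v in self.samples_per_group.items()
                    if m == method and c == ct
                )
                if n == 0:
                    raise ValueError(f"no samples configured for ({method}, {ct})")
                if n < 2:
                    raise ValueError(
                        f"need >=2 samples per (method, cell type); got {n} for ({method}, {ct})"
                    )
        for (m, c, s), v in self.samples_per_group.items():
            if v < 0:
                raise ValueError("negative sample count")
            seen[(m, c, s)] = v


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated experiment."""

    deg_labels: dict            # method -> {gene -> "D1"/"D2"}
    regulation_labels: dict     # gene -> list of RegulationPlant
    module_labels: dict         # gene -> block index
    method_variable_genes: set
    mv_preferred_method: dict   # gene -> method with planted peak expression
    sex_effect_genes: set

    def deg_direction(self, gene: str, method: str) -> str:
        return self.deg_labels.get(method, {}).get(gene, "none")


def negative_binomial_counts(mean, alpha, rng: np.random.Generator):
    """Draw NB counts with Var = mu + alpha * mu**2 via gamma-Poisson mixing.

    ``mean`` and ``alpha`` broadcast against each other; ``alpha`` must be
    positive.
    """
    mean = np.asarray(mean, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if (alpha <= 0).any():
        raise ValueError("NB dispersion alpha must be positive")
    shape = 1.0 / alpha
    lam = rng.gamma(np.broadcast_to(shape, mean.shape), mean * alpha)
    return rng.poisson(lam)


def _simulate_annotation(cfg: SimConfig, rng: np.random.Generator) -> GeneAnnotation:
    n = cfg.n_genes
    gene_ids = [f"gene{str(i).zfill(5)}" for i in range(n)]
    nc = cfg.noncoding_fraction
    # biotype mix: protein-coding majority plus a realistic non-coding tail
    biotypes = rng.choice(
        ["protein_coding", "lincRNA", "antisense", "processed_pseudogene", "miRNA"],
        size=n,
        p=[1 - nc, nc * 0.4, nc * 0.25, nc * 0.22, nc * 0.13],
    )
    lengths = np.where(
        biotypes == "miRNA",
        rng.lognormal(np.log(90), 0.3, size=n),
        rng.lognormal(np.log(1200), 1.0, size=n),
    )
    lengths = np.clip(np.round(lengths), 60, 100_000).astype(int)
    chrom = rng.integers(1, 20, size=n).astype(str)
    start = rng.integers(1, 100_000_000, size=n)
    stop = start + (lengths * rng.uniform(1.5, 10.0, size=n)).astype(int) + 1
    table = pd.DataFrame(
        {
            "length_bp": lengths,
            "biotype": biotypes,
            "chrom": chrom,
            "start": start,
            "stop": stop,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return GeneAnnotation(table)


def _sample_table(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for (method, ct, sex), count in sorted(cfg.samples_per_group.items()):
        for i in range(count):
            rows.append(
                {
                    "sample_id": f"{method}_{ct}_{sex}_{i + 1}",
                    "method": method,
                    "cell_type": ct,
                    "sex": sex,
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_experiment(config: SimConfig):
    """Simulate one experiment.

    Returns ``(exon_counts, all_counts, annotation, truth)`` where the two
    :class:`CountMatrix` objects share the same gene/sample grid and the
    all-feature matrix dominates the exon-only matrix elementwise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    annotation = _simulate_annotation(config, rng)
    genes = list(annotation.gene_ids)
    n = config.n_genes
    metadata = _sample_table(config)
    samples = list(metadata.index)

    mu, sigma = config.baseline_mean_log
    baseline = rng.lognormal(mu, sigma, size=n)
    noncoding = (annotation.table["biotype"] != "protein_coding").to_numpy()
    baseline = baseline * np.where(noncoding, config.noncoding_baseline_scale, 1.0)
    alpha = rng.lognormal(*config.dispersion_log, size=n)

    eff = config.method_effects
    short = (annotation.table["length_bp"].to_numpy() < eff.short_gene_bp)
    method_weight = {}
    for m in METHODS:
        w = np.full(n, eff.expression_shift.get(m, 1.0))
        w = w * np.where(noncoding, eff.noncoding_weight.get(m, 1.0), 1.0)
        w = w * np.where(short, eff.short_gene_weight.get(m, 1.0), 1.0)
        method_weight[m] = w

    # planted cell-type differential expression, independently per method
    n_de = int(round(config.de_fraction * n))
    deg_labels: dict = {m: {} for m in METHODS}
    de_shift = {m: np.zeros(n) for m in METHODS}  # log2 shift applied to D1
    for m in METHODS:
        if n_de == 0:
            continue
        bias = config.de_noncoding_bias.get(m, 1.0)
        weights = np.where(noncoding, bias, 1.0)
        weights = weights / weights.sum()
        idx = rng.choice(n, size=n_de, replace=False, p=weights)
        signs = rng.choice([1.0, -1.0], size=n_de)
        for i, s in zip(idx, signs):
            de_shift[m][i] = s * config.de_log2fc
            deg_labels[m][genes[i]] = "D1" if s > 0 else "D2"

    # planted regulation categories: cell-type shifts in the compartments
    # downstream of the regulated step
    regulation_labels: dict = {}
    reg_shift = {m: np.zeros(n) for m in METHODS}  # log2 shift applied to D1
    gene_pos = {g: i for i, g in enumerate(genes)}
    for plant in config.regulation_plan:
        if plant.gene not in gene_pos:
            raise ValueError(f"regulation plan names unknown gene {plant.gene!r}")
        signed = plant.log2fc if plant.direction == "D1" else -plant.log2fc
        for m in CATEGORY_COMPARTMENTS[plant.category]:
            reg_shift[m][gene_pos[plant.gene]] += signed
        regulation_labels.setdefault(plant.gene, []).append(plant)

    # method-variable genes: one strongly up-weighted method each
    mv_genes: set = set()
    mv_preferred: dict = {}
    mv_shift = {m: np.zeros(n) for m in METHODS}
    if config.n_method_variable > 0:
        idx = rng.choice(n, size=min(config.n_method_variable, n), replace=False)
        lo, hi = config.method_variable_log2
        for j, i in enumerate(idx):
            m = METHODS[j % len(METHODS)]
            mv_shift[m][i] = rng.uniform(lo, hi)
            mv_genes.add(genes[i])
            mv_preferred[genes[i]] = m
    sex_shift = np.zeros(n)
    sex_genes: set = set()
    for gene, l2 in config.sex_effect_genes:
        if gene not in gene_pos:
            raise ValueError(f"sex effect names unknown gene {gene!r}")
        sex_shift[gene_pos[gene]] = l2  # applied to F samples
        sex_genes.add(gene)

    intron_mult = rng.uniform(0.4, 1.6, size=n)

    lib_sizes = rng.uniform(*config.library_size_range, size=len(samples))
    all_counts = np.zeros((n, len(samples)), dtype=np.int64)
    exon_counts = np.zeros_like(all_counts)
    for j, sid in enumerate(samples):
        m = metadata.loc[sid, "method"]
        ct = metadata.loc[sid, "cell_type"]
        sex = metadata.loc[sid, "sex"]
        log2_shift = np.zeros(n)
        if ct == "D1":
            log2_shift += de_shift[m] + reg_shift[m]
        if sex == "F":
            log2_shift += sex_shift
        noise_sd = eff.sample_noise_log2.get(m, 0.0)
        jitter = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
        mean = baseline * method_weight[m] * np.exp2(mv_shift[m] + log2_shift + jitter)
        mean = mean / mean.sum() * lib_sizes[j]
        draws = negative_binomial_counts(mean, alpha, rng)
        p_intron = np.clip(eff.intron_fraction[m] * intron_mult, 0.0, 0.9)
        exonic = rng.binomial(draws, 1.0 - p_intron)
        all_counts[:, j] = draws
        exon_counts[:, j] = exonic

    idx = pd.Index(genes, name="gene_id")
    all_cm = CountMatrix(pd.DataFrame(all_counts, index=idx, columns=samples), metadata, "all")
    exon_cm = CountMatrix(pd.DataFrame(exon_counts, index=idx, columns=samples), metadata, "exon")
    truth = GroundTruth(
        deg_labels=deg_labels,
        regulation_labels=regulation_labels,
        module_labels={},
        method_variable_genes=mv_genes,
        mv_preferred_method=mv_preferred,
        sex_effect_genes=sex_genes,
    )
    return exon_cm, all_cm, annotation, truth


def simulate_coexpression_blocks(
    config: SimConfig, base_matrix: ExpressionMatrix, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, dict]:
    """Add planted co-expression blocks to a log-scale expression matrix.

    Genes in each :class:`CoexpressionBlock` receive ``loading_g * f`` where
    ``f`` is a shared per-sample latent factor ~ N(0, sd**2) and the
    per-gene loading is the block loading, optionally jittered. Genes
    outside any block are untouched. Returns the augmented matrix, the
    gene -> block-index labels, and the per-gene true loadings.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    values = base_matrix.values.copy()
    n_genes, n_samples = values.shape
    labels: dict = {}
    loadings: dict = {}
    assigned = np.zeros(n_genes, dtype=bool)
    cursor = 0
    for b, block in enumerate(config.module_plan):
        if block.size > n_genes:
            raise ValueError("block size exceeds number of genes")
        start = block.start if block.start is not None else cursor
        sl = slice(start, start + block.size)
        if assigned[sl].any():
            raise ValueError("overlapping co-expression block assignments")
        assigned[sl] = True
        cursor = max(cursor, start + block.size)
        gene_loadings = np.full(block.size, float(block.loading))
        if block.loading_jitter > 0:
            gene_loadings *= rng.uniform(
                1.0 - block.loading_jitter, 1.0 + block.loading_jitter, size=block.size
            )
        if block.loading != 0 and block.size > 1:
            factor = rng.normal(0.0, block.sd, size=n_samples)
            values.iloc[sl] = values.iloc[sl].to_numpy() + np.outer(gene_loadings, factor)
        for g, lo in zip(values.index[sl], gene_loadings):
            labels[g] = b
            loadings[g] = float(lo) if block.loading != 0 and block.size > 1 else 0.0
    out = ExpressionMatrix(values, base_matrix.unit, base_matrix.metadata)
    return out, labels, loadings


def make_regulation_plan(
    gene_ids,
    n_per_category: int,
    log2fc: float,
    rng: np.random.Generator,
    d1_fraction: dict | None = None,
) -> list:
    """Build a disjoint regulation plan: ``n_per_category`` genes per
    category, directions drawn with per-category D1 probability
    (default 0.5)."""
    d1_fraction = d1_fraction or {}
    gene_ids = list(gene_ids)
    need = n_per_category * len(REGULATION_CATEGORIES)
    if need > len(gene_ids):
        raise ValueError("not enough genes for the requested plan")
    chosen = rng.choice(len(gene_ids), size=need, replace=False)
    plan = []
    for c, cat in enumerate(REGULATION_CATEGORIES):
        p_d1 = d1_fraction.get(cat, 0.5)
        for i in chosen[c * n_per_category:(c + 1) * n_per_category]:
            direction = "D1" if rng.random() < p_d1 else "D2"
            plan.append(RegulationPlant(gene_ids[i], cat, direction, log2fc))
    return plan


def write_fixtures(outputs, directory) -> dict:
    """Write a simulated experiment as plain-text fixtures.

    ``outputs`` is the 4-tuple from :func:`simulate_experiment`. Returns a
    mapping of artefact name to path. Files round-trip losslessly through
    the readers in :mod:`compartmentseq.io`.
    """
    exon_cm, all_cm, annotation, truth = outputs
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts_exon": cio.write_counts_tsv(exon_cm, directory / "counts_exon.tsv"),
        "counts_all": cio.write_counts_tsv(all_cm, directory / "counts_all.tsv"),
        "annotation": cio.write_annotation_tsv(annotation, directory / "annotation.tsv"),
        "metadata": cio.write_metadata_tsv(all_cm.metadata, directory / "metadata.tsv"),
    }
    truth_obj = {
        "deg_labels": truth.deg_labels,
        "regulation_labels": {
            g: [
                {"category": p.category, "direction": p.direction, "log2fc": p.log2fc}
                for p in plants
            ]
            for g, plants in truth.regulation_labels.items()
        },
        "module_labels": truth.module_labels,
        "method_variable_genes": sorted(truth.method_variable_genes),
        "mv_preferred_method": truth.mv_preferred_method,
        "sex_effect_genes": sorted(truth.sex_effect_genes),
    }
    paths["truth"] = cio.write_json(truth_obj, directory / "truth.json")
    return paths
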