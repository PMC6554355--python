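"""Self-contained benchmark experiments on synthetic data.

Each function simulates a planted-truth experiment at a fixed desk scale,
runs the relevant pipeline stage and returns the measured recovery or
calibration quantities. They are used both by the test suite and by the
reproduction script, so the numbers reported in either place are always
recomputed from scratch.

Problem sizes (chosen so each experiment runs in seconds to a couple of
minutes on one CPU):

* regulation recovery: 200 planted genes per category + 400 nulls, n = 6
  samples per (method, cell type), NB dispersion 0.1, effect ln 2;
* differential-expression calibration: 1 000 null genes and 200 genes with
  a planted log2 fold change of 1, n = 6 per group, mu = 100, alpha = 0.1;
* network recovery: two planted blocks of 150 genes (within-block r ~ 0.8)
  in 400 genes x 40 samples;
* qualitative orderings: the default three-method configuration (2 000
  genes on the emulated 16 / 11 / 12-sample study layout).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .containers import METHODS, ExpressionMatrix
from .de import NegativeBinomialDE, estimate_dispersion, nb_wald_test
from .network import CoexpressionNetwork, MutualInformationNetwork, consensus_edges, hub_network
from .pca import ExpressionPCA
from .quantify import detection_filter, final_filter, intron_fraction, size_factors, vst_transform
from .regulation import CompartmentRegulationClassifier
from .simulate import (
    REGULATION_CATEGORIES,
    CoexpressionBlock,
    MethodEffects,
    SimConfig,
    make_regulation_plan,
    negative_binomial_counts,
    simulate_coexpression_blocks,
    simulate_experiment,
)


def _unbiased_method_effects() -> MethodEffects:
    """Method effects with all capture biases switched off (intron shares
    keep their defaults); used when an experiment needs pure NB noise."""
    flat = {m: 1.0 for m in METHODS}
    return MethodEffects(
        noncoding_weight=dict(flat),
        short_gene_weight=dict(flat),
        sample_noise_log2={m: 0.0 for m in METHODS},
    )


def regulation_recovery(
    seed: int,
    n_per_category: int = 200,
    n_null: int = 400,
    effect_ln: float = np.log(2.0),
    alpha: float = 0.1,
) -> dict:
    """Sensitivity and false-flag rate of the regulation classifier.

    Plants ``n_per_category`` genes per regulation category at a natural-log
    effect of ``effect_ln`` (direction random), with ``n_null`` untouched
    genes, NB dispersion fixed at ``alpha`` and n = 6 samples per
    (method, cell type). Sensitivity counts a gene as recovered when its
    category is flagged with the planted direction.
    """
    rng = np.random.default_rng(seed)
    n_genes = 3 * n_per_category + n_null
    genes = [f"gene{str(i).zfill(5)}" for i in range(n_genes)]
    plan = make_regulation_plan(genes, n_per_category, effect_ln / np.log(2.0), rng)
    cfg = SimConfig(
        n_genes=n_genes,
        samples_per_group={
            (m, ct, "M"): 6 for m in METHODS for ct in ("D1", "D2")
        },
        de_fraction=0.0,
        n_method_variable=0,
        baseline_mean_log=(np.log(100.0), 0.8),
        dispersion_log=(np.log(alpha), 1e-9),
        method_effects=_unbiased_method_effects(),
        regulation_plan=plan,
        seed=int(rng.integers(2**31 - 1)),
    )
    _, all_counts, _, _ = simulate_experiment(cfg)
    clf = CompartmentRegulationClassifier().fit(all_counts)
    calls = clf.calls_
    planted = {cat: [] for cat in REGULATION_CATEGORIES}
    for p in plan:
        planted[p.category].append((p.gene, p.direction))
    null_genes = sorted(set(genes) - {p.gene for p in plan})
    out = {}
    for cat in REGULATION_CATEGORIES:
        hits = sum(
            1
            for g, d in planted[cat]
            if calls.loc[g, f"{cat}_flag"] and calls.loc[g, f"{cat}_direction"] == d
        )
        out[f"sensitivity_{cat}"] = hits / len(planted[cat])
        out[f"false_flag_{cat}"] = float(calls.loc[null_genes, f"{cat}_flag"].mean())
    out["n_genes"] = n_genes
    return out


def de_calibration(
    seed: int,
    n_null: int = 1000,
    n_planted: int = 200,
    mu: float = 100.0,
    alpha: float = 0.1,
    n_per_group: int = 6,
) -> dict:
    """Null type-I error and planted-effect bias of the NB Wald engine."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    samples = [f"s{i}" for i in range(n)]
    groups = pd.Series(["D1"] * n_per_group + ["D2"] * n_per_group, index=samples)
    factors = pd.Series(1.0, index=samples)

    null = pd.DataFrame(
        negative_binomial_counts(np.full((n_null, n), mu), alpha, rng),
        index=[f"null{i}" for i in range(n_null)],
        columns=samples,
    )
    disp = estimate_dispersion(null, factors, groups)
    res = nb_wald_test(null, factors, disp, groups)
    type1 = float((res["pvalue"] <= 0.05).mean())

    means = np.full((n_planted, n), mu)
    means[:, :n_per_group] *= 2.0  # log2 fold change of exactly 1, D1-enriched
    planted = pd.DataFrame(
        negative_binomial_counts(means, alpha, rng),
        index=[f"de{i}" for i in range(n_planted)],
        columns=samples,
    )
    disp_p = estimate_dispersion(planted, factors, groups)
    res_p = nb_wald_test(planted, factors, disp_p, groups)
    bias = float(res_p["log2FoldChange"].mean() - 1.0)
    return {"type1_error": type1, "lfc_bias": bias, "n_null": n_null, "n_planted": n_planted}


def network_recovery(
    seed: int,
    block_size: int = 150,
    n_genes: int = 400,
    n_samples: int = 40,
    loading: float = 2.0,
    loading_jitter: float = 0.25,
    power: int = 18,
) -> dict:
    """Planted-block module and hub recovery of the consensus network.

    Two blocks of ``block_size`` genes share latent factors with per-gene
    loadings around ``loading`` (mean within-block correlation ~ 0.8 at unit
    noise). Reports the adjusted Rand index of module labels against the
    planted blocks and, per block, how many of its 20 highest-true-loading
    genes appear in the consensus hub network built from that block's module.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{str(i).zfill(4)}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    base = pd.DataFrame(rng.normal(0.0, 1.0, size=(n_genes, n_samples)), index=genes, columns=samples)
    meta = pd.DataFrame(
        {
            "method": "wholecell",
            "cell_type": ["D1", "D2"] * (n_samples // 2),
            "sex": "M",
        },
        index=samples,
    )
    cfg = SimConfig(
        n_genes=n_genes,
        module_plan=[
            CoexpressionBlock(block_size, loading, 1.0, 0, loading_jitter),
            CoexpressionBlock(block_size, loading, 1.0, block_size, loading_jitter),
        ],
        seed=seed,
    )
    expr, labels, loadings = simulate_coexpression_blocks(
        cfg, ExpressionMatrix(base, "vst", meta), rng=rng
    )
    net = CoexpressionNetwork(power=power).fit(expr)
    truth = np.array([labels.get(g, -1) for g in genes])
    ari = float(adjusted_rand_score(truth, net.modules_.labels.to_numpy()))

    mi_net = MutualInformationNetwork().fit(expr)
    cons = consensus_edges(net.tom_, mi_net.edges_)
    out = {"ari": ari, "n_modules": net.modules_.n_modules, "n_genes": n_genes}
    for b in (0, 1):
        block_genes = [g for g, lab in labels.items() if lab == b]
        top = sorted(block_genes, key=lambda g: -loadings[g])[:20]
        # module containing the majority of this block's genes
        mod_counts = net.modules_.labels.loc[block_genes].value_counts()
        mod = int(mod_counts.idxmax())
        if mod == 0:
            out[f"hub_recovery_block{b}"] = 0
            continue
        module_genes = set(net.modules_.genes_in(mod))
        sub_mask = cons.edges["gene_a"].isin(module_genes) & cons.edges["gene_b"].isin(module_genes)
        sub = type(cons)(sorted(module_genes), cons.edges[sub_mask].reset_index(drop=True))
        hubs = hub_network(sub, k=20)
        out[f"hub_recovery_block{b}"] = sum(1 for g in top if g in hubs.nodes)
    return out


def qualitative_orderings(seed: int, n_genes: int = 2000, varpart_genes: int = 600) -> dict:
    """Method-level signatures on the default synthetic configuration.

    Returns the per-method mean intron fraction, protein-coding share of
    called DEGs, DEG counts, mean within-method PC1/PC2 distance with the
    ribosome-bound t-test p-values, and mean variance fractions on a gene
    subsample.
    """
    cfg = SimConfig(n_genes=n_genes, seed=seed)
    exon, all_counts, annotation, _ = simulate_experiment(cfg)
    out: dict = {"n_genes": n_genes}

    frac = intron_fraction(all_counts, exon)
    per_sample = frac.mean(axis=0)
    for m in METHODS:
        cols = all_counts.metadata.index[all_counts.metadata["method"] == m]
        out[f"intron_fraction_{m}"] = float(per_sample[cols].mean())

    for m in METHODS:
        cm = all_counts.subset_method(m)
        detected, _ = detection_filter(cm)
        final, _ = final_filter(detected, annotation, m)
        called = NegativeBinomialDE().fit(final).call(m)
        degs = called.index[called["enrichment_call"] != "none"]
        out[f"n_degs_{m}"] = int(len(degs))
        bio = annotation.table.loc[degs, "biotype"]
        out[f"protein_coding_deg_share_{m}"] = float((bio == "protein_coding").mean())

    vst = vst_transform(all_counts, size_factors(all_counts))
    est = ExpressionPCA(n_components=4).fit(vst)
    cd = est.centroid_distances_
    for m in METHODS:
        out[f"mean_within_distance_{m}"] = float(cd.mean_within[m])
    for (a, b), (_, p) in cd.t_tests.items():
        out[f"ttest_p_{a}_vs_{b}"] = float(p)

    rng = np.random.default_rng(seed + 1)
    keep = rng.choice(n_genes, size=min(varpart_genes, n_genes), replace=False)
    sub = ExpressionMatrix(vst.values.iloc[sorted(keep)], "vst", vst.metadata)
    from .varpart import partition_variance

    fr = partition_variance(sub)
    out["mean_fraction_method"] = float(fr["fraction_method"].mean())
    out["mean_fraction_celltype"] = float(fr["fraction_celltype"].mean())
    out["mean_fraction_residual"] = float(fr["fraction_residual"].mean())
    return out


def analytic_thresholds() -> dict:
    """Closed-form quantities used throughout the pipeline, computed by the
    package's own functions where they live there."""
    from .enrich import fisher_enrichment
    from .network import eigengene_trait_correlation

    out = {"log2fc_threshold_30pct": float(np.log2(1.3))}

    # Bonferroni threshold for 9 co-expression modules via the trait-
    # correlation routine
    rng = np.random.default_rng(0)
    eg = pd.DataFrame(rng.normal(size=(12, 9)), columns=[f"ME{i+1}" for i in range(9)])
    traits = pd.DataFrame({"is_d1": [0, 1] * 6})
    table = eigengene_trait_correlation(eg, traits)
    out["bonferroni_threshold_9_modules"] = float(table["threshold"].iloc[0])

    # Bonferroni threshold for 3 hub-network enrichment tests via the Fisher
    # routine
    res = fisher_enrichment(["g1"], ["g1", "g2"], [f"g{i}" for i in range(1, 11)], n_tests=3)
    out["bonferroni_threshold_3_gwas_tests"] = float(res.threshold)
    return out
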