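"""Negative-binomial Wald differential expression between cell types.

A deliberately simple, fully specified NB engine: per-gene dispersions come
from a within-group method-of-moments estimate shrunk toward a lowess
mean-dispersion trend (raw and trend averaged on the log scale), and each
gene is fit with a log-link NB GLM (intercept + cell type, log size factor
offset). The reported log2 fold change is the natural-log cell-type
coefficient divided by ln 2, its standard error likewise, and the Wald
statistic is referred to a standard normal. There is no fold-change
shrinkage and no outlier replacement.

DEG calling applies the study's cascade: |log2FC| > 0.38 (a 30% change),
BH-adjusted p <= 0.05, mean normalized counts above the within-method 25th
percentile, and — for the noisy nuclear libraries — removal of called DEGs
in the top quartile of the fold-change standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, GeneAnnotation

LN2 = np.log(2.0)

DE_COLUMNS = ["baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj"]


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: pd.Series,
    floor: float = 1e-8,
    trend_frac: float = 0.5,
    return_raw: bool = False,
):
    """Per-gene NB dispersion ``alpha`` (Var = mu + alpha * mu**2).

    Method of moments on size-factor-normalized counts using the pooled
    within-group variance, floored at ``floor``, then shrunk toward a lowess
    trend of log dispersion on log mean by averaging raw and trend on the
    log scale.
    """
    groups = pd.Series(groups, index=counts.columns)
    sizes = groups.value_counts()
    if (sizes < 2).any():
        bad = sizes.index[sizes < 2]
        raise ValueError(f"groups with fewer than 2 samples: {list(bad)}")
    norm = counts / factors
    mu = norm.mean(axis=1).to_numpy()
    ss = np.zeros(len(counts))
    dof = 0
    for g in sizes.index:
        sub = norm.loc[:, groups == g]
        ss += sub.var(axis=1, ddof=1).to_numpy() * (sub.shape[1] - 1)
        dof += sub.shape[1] - 1
    v = ss / dof
    # log-scale small-sample correction: E[log(chi2_d / d)] = psi(d/2) - log(d/2),
    # so the pooled variance is rescaled to be unbiased on the log scale where
    # the trend shrinkage operates
    from scipy.special import digamma

    v = v * np.exp(-(digamma(dof / 2.0) - np.log(dof / 2.0)))
    # Var(count/s) ≈ mu * E[1/s] + alpha * mu^2; the denominator subtracts
    # Var(mu_hat) ≈ v / n so that E[mu_hat^2] > mu^2 does not bias alpha down
    shot = mu * float((1.0 / factors).mean())
    mu_sq = np.maximum(mu**2 - v / counts.shape[1], (mu**2) * 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, (v - shot) / mu_sq, floor)
    raw = np.clip(raw, floor, None)
    expressed = mu > 0
    alpha = raw.copy()
    if expressed.sum() >= 10:
        log_mu = np.log(mu[expressed])
        log_raw = np.log(raw[expressed])
        trend = lowess(log_raw, log_mu, frac=trend_frac, return_sorted=False)
        alpha[expressed] = np.exp(0.5 * (log_raw + trend))
    alpha = np.clip(alpha, floor, None)
    alpha_s = pd.Series(alpha, index=counts.index, name="alpha")
    if return_raw:
        return alpha_s, pd.Series(raw, index=counts.index, name="alpha_raw")
    return alpha_s


def _fit_nb_gene(y, design, alpha, offset):
    fam = sm.families.NegativeBinomial(alpha=max(float(alpha), 1e-8))
    model = sm.GLM(y, design, family=fam, offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    return res


def nb_wald_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    alpha: pd.Series,
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test of the cell-type effect (D1 vs D2).

    Positive ``log2FoldChange`` means D1-enriched. Genes whose fit fails to
    converge get missing statistics and are flagged in the ``converged``
    column. BH adjustment is over all genes with a defined p-value.
    """
    groups = pd.Series(groups, index=counts.columns)
    levels = set(groups)
    if levels != {"D1", "D2"}:
        raise ValueError(f"expected exactly the groups D1 and D2, got {sorted(levels)}")
    indicator = (groups == "D1").astype(float).to_numpy()
    design = np.column_stack([np.ones_like(indicator), indicator])
    offset = np.log(factors.to_numpy(dtype=float))
    norm = counts / factors
    base_mean = norm.mean(axis=1)

    rows = np.empty((len(counts), 4))
    converged = np.ones(len(counts), dtype=bool)
    y_all = counts.to_numpy()
    for i in range(len(counts)):
        y = y_all[i]
        if y.sum() == 0:
            rows[i] = [np.nan] * 4
            converged[i] = False
            continue
        try:
            res = _fit_nb_gene(y, design, alpha.iloc[i], offset)
            ok = bool(getattr(res, "converged", True)) and np.isfinite(res.bse[1])
        except Exception:
            ok = False
        if not ok:
            rows[i] = [np.nan] * 4
            converged[i] = False
            continue
        b, se = res.params[1], res.bse[1]
        z = b / se if se > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z))
        rows[i] = [b / LN2, se / LN2, z, p]

    out = pd.DataFrame(
        rows, index=counts.index, columns=["log2FoldChange", "lfcSE", "stat", "pvalue"]
    )
    out.insert(0, "baseMean", base_mean)
    out["padj"] = np.nan
    defined = out["pvalue"].notna()
    if defined.any():
        out.loc[defined, "padj"] = multipletests(
            out.loc[defined, "pvalue"], method="fdr_bh"
        )[1]
    out["converged"] = converged
    return out


def call_degs(
    de: pd.DataFrame,
    method: str,
    lfc_threshold: float = 0.38,
    alpha_level: float = 0.05,
    basemean_quantile: float = 0.25,
    se_quantile: float = 0.75,
) -> pd.DataFrame:
    """Apply the DEG-enrichment cascade, returning the table with an
    ``enrichment_call`` column in {D1, D2, none}.

    A gene is called when |log2FC| strictly exceeds ``lfc_threshold``,
    ``padj <= alpha_level`` and its baseMean lies above the within-table
    25th percentile. For the nuclear method, called DEGs in the top quartile
    of ``lfcSE`` among called DEGs are reset to "none".
    """
    if de.empty:
        raise ValueError("empty differential expression table")
    out = de.copy()
    base_cut = out["baseMean"].quantile(basemean_quantile)
    up = (out["log2FoldChange"] > lfc_threshold)
    down = (out["log2FoldChange"] < -lfc_threshold)
    sig = (out["padj"] <= alpha_level) & (out["baseMean"] > base_cut)
    call = np.where(sig & up, "D1", np.where(sig & down, "D2", "none"))
    out["enrichment_call"] = call
    if method == "nuclear":
        called = out["enrichment_call"] != "none"
        if called.any():
            se_cut = out.loc[called, "lfcSE"].quantile(se_quantile)
            noisy = called & (out["lfcSE"] >= se_cut)
            out.loc[noisy, "enrichment_call"] = "none"
    return out


def overlap_degs(calls: dict) -> dict:
    """Cross-method DEG overlaps per direction.

    ``calls`` maps method name to a called DE table. Returns, per direction,
    the per-method sets, the all-method intersection, and per-method unique
    genes.
    """
    if len(calls) < 2:
        raise ValueError("need at least two methods to overlap")
    result: dict = {}
    for direction in ("D1", "D2"):
        sets = {
            m: set(df.index[df["enrichment_call"] == direction])
            for m, df in calls.items()
        }
        inter = set.intersection(*sets.values()) if sets else set()
        unique = {
            m: s - set.union(*(o for k, o in sets.items() if k != m))
            for m, s in sets.items()
        }
        result[direction] = {
            "sets": sets,
            "intersection": inter,
            "unique": unique,
            "counts": {m: len(s) for m, s in sets.items()},
            "intersection_count": len(inter),
        }
    return result


def union_heatmap_matrix(calls: dict, order_by: str) -> pd.DataFrame:
    """log2FC of the union of DEGs across methods, ordered by one method's
    fold change; genes absent from a method's table are NaN ("not
    detected")."""
    if order_by not in calls:
        raise ValueError(f"unknown ordering method {order_by!r}")
    union: set = set()
    for df in calls.values():
        union |= set(df.index[df["enrichment_call"] != "none"])
    union_list = sorted(union)
    mat = pd.DataFrame(index=union_list, columns=list(calls), dtype=float)
    for m, df in calls.items():
        common = [g for g in union_list if g in df.index]
        mat.loc[common, m] = df.loc[common, "log2FoldChange"]
    return mat.sort_values(order_by, ascending=False, na_position="last")


@dataclass
class OverlapRegressionResult:
    """Logistic regression of DEG overlap status on DE features."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    posthoc_feature: str
    posthoc_p: float
    separation_flag: bool


def default_overlap_features(
    de: pd.DataFrame, annotation: GeneAnnotation | None = None
) -> pd.DataFrame:
    feats = pd.DataFrame(index=de.index)
    feats["se_log2fc"] = de["lfcSE"]
    feats["abs_log2fc"] = de["log2FoldChange"].abs()
    feats["log_basemean"] = np.log10(de["baseMean"] + 1.0)
    if annotation is not None:
        tab = annotation.table.reindex(de.index)
        feats["log_length"] = np.log10(tab["length_bp"].astype(float))
        feats["protein_coding"] = (tab["biotype"] == "protein_coding").astype(float)
    return feats


def overlap_logistic_regression(
    de: pd.DataFrame,
    overlap_labels: pd.Series,
    features: pd.DataFrame | None = None,
    annotation: GeneAnnotation | None = None,
    posthoc_feature: str = "se_log2fc",
) -> OverlapRegressionResult:
    """Maximum-likelihood logit of overlap status on DE features.

    ``overlap_labels`` is boolean per gene (True = overlapping DEG). The
    Wald p of ``posthoc_feature`` is reported separately. Quasi-perfect
    separation is flagged rather than raised.
    """
    if features is None:
        features = default_overlap_features(de, annotation)
    labels = overlap_labels.reindex(features.index).astype(float)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if min(n_pos, n_neg) < 10:
        raise ValueError(
            f"need >=10 observations per class, got {n_pos} overlapping / {n_neg} non-overlapping"
        )
    X = sm.add_constant(features.astype(float))
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(labels, X, family=sm.families.Binomial())
        res = model.fit(maxiter=200)
        mu = res.fittedvalues
        if (np.abs(res.params.drop("const")) > 20).any() or np.min(
            np.abs(mu - labels)
        ) < 1e-8 and ((mu > 1 - 1e-6) | (mu < 1e-6)).mean() > 0.95:
            separation = True
    return OverlapRegressionResult(
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        posthoc_feature=posthoc_feature,
        posthoc_p=float(res.pvalues.get(posthoc_feature, np.nan)),
        separation_flag=separation,
    )


class NegativeBinomialDE(BaseEstimator):
    """Within-method D1-vs-D2 differential expression estimator.

    ``fit`` takes a :class:`CountMatrix` (one method's samples) and computes
    size factors, shrunk dispersions and the per-gene NB Wald table;
    ``call`` applies the DEG cascade. Fitted attributes carry a trailing
    underscore per scikit-learn convention.
    """

    def __init__(
        self,
        lfc_threshold: float = 0.38,
        alpha_level: float = 0.05,
        basemean_quantile: float = 0.25,
        se_quantile: float = 0.75,
        dispersion_floor: float = 1e-8,
        trend_frac: float = 0.5,
    ):
        self.lfc_threshold = lfc_threshold
        self.alpha_level = alpha_level
        self.basemean_quantile = basemean_quantile
        self.se_quantile = se_quantile
        self.dispersion_floor = dispersion_floor
        self.trend_frac = trend_frac

    def fit(self, X: CountMatrix, y=None):
        from .quantify import size_factors

        groups = pd.Series(y, index=X.sample_ids) if y is not None else X.metadata["cell_type"]
        self.size_factors_ = size_factors(X)
        self.dispersions_ = estimate_dispersion(
            X.counts,
            self.size_factors_,
            groups,
            floor=self.dispersion_floor,
            trend_frac=self.trend_frac,
        )
        self.results_ = nb_wald_test(X.counts, self.size_factors_, self.dispersions_, groups)
        self.n_features_in_ = X.n_genes
        return self

    def call(self, method: str) -> pd.DataFrame:
        if not hasattr(self, "results_"):
            raise RuntimeError("estimator is not fitted")
        return call_degs(
            self.results_,
            method,
            lfc_threshold=self.lfc_threshold,
            alpha_level=self.alpha_level,
            basemean_quantile=self.basemean_quantile,
            se_quantile=self.se_quantile,
        )
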