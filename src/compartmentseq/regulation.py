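"""Cross-compartment regulation classifier.

A single negative-binomial GLM per gene spans all three isolation methods
and both cell types (log link, log size-factor offset):

    log mu = intercept + compartment + cell_type + compartment:cell_type

with the nuclear compartment and the D2 cell type as references. The
cell-type difference measured in each compartment then decomposes uniquely
along the nucleus -> cytosol -> ribosome cascade:

* transcriptional regulation = the cell-type contrast within the nuclear
  compartment (the ``cell_type`` main effect);
* cytosolic regulation = the change of the cell-type contrast from nucleus
  to whole cell (the ``wholecell:cell_type`` interaction);
* translational regulation = the change from whole cell to ribosome-bound
  (``ribotag:cell_type`` minus ``wholecell:cell_type``).

By construction the transcriptional and cytosolic contrasts sum exactly to
the whole-cell cell-type contrast. Each contrast is tested by a Wald z from
the coefficient covariance; BH adjustment is within each category across
genes (three families), and direction (D1 / D2) comes from the contrast
sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix
from .de import estimate_dispersion
from .simulate import REGULATION_CATEGORIES

# design columns: const, wholecell, ribotag, D1, wholecell:D1, ribotag:D1
DESIGN_NAMES = ("const", "wholecell", "ribotag", "cell_type_D1", "wc_x_D1", "rt_x_D1")

# contrast vectors over the design coefficients (natural-log scale)
CONTRASTS = {
    "transcriptional": np.array([0, 0, 0, 1, 0, 0], dtype=float),
    "cytosolic": np.array([0, 0, 0, 0, 1, 0], dtype=float),
    "translational": np.array([0, 0, 0, 0, -1, 1], dtype=float),
}


@dataclass
class RegulationFit:
    """Coefficients and covariance of one gene's compartment GLM."""

    gene: str
    params: pd.Series
    cov: pd.DataFrame
    converged: bool


def build_design(metadata: pd.DataFrame) -> pd.DataFrame:
    """Compartment + cell type + interaction design (nuclear / D2
    references)."""
    wc = (metadata["method"] == "wholecell").astype(float)
    rt = (metadata["method"] == "ribotag").astype(float)
    d1 = (metadata["cell_type"] == "D1").astype(float)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "wholecell": wc,
            "ribotag": rt,
            "cell_type_D1": d1,
            "wc_x_D1": wc * d1,
            "rt_x_D1": rt * d1,
        },
        index=metadata.index,
    )
    return X


def fit_compartment_glm(
    y: pd.Series,
    metadata: pd.DataFrame,
    factors: pd.Series,
    alpha: float,
    gene: str = "",
) -> RegulationFit:
    """Fit the NB compartment GLM for one gene (IRLS, tol 1e-8, <=100
    iterations)."""
    present = set(metadata["method"])
    missing = {"nuclear", "wholecell", "ribotag"} - present
    if missing:
        raise ValueError(f"missing compartment(s): {sorted(missing)}")
    for (m, ct), group in metadata.groupby(["method", "cell_type"]):
        if len(group) < 2:
            raise ValueError(f"fewer than 2 samples for ({m}, {ct})")
    X = build_design(metadata).loc[y.index]
    offset = np.log(factors.loc[y.index].to_numpy(dtype=float))
    fam = sm.families.NegativeBinomial(alpha=max(float(alpha), 1e-8))
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y.to_numpy(), X.to_numpy(), family=fam, offset=offset).fit(
                maxiter=100, tol=1e-8
            )
        converged = bool(getattr(res, "converged", True)) and np.isfinite(res.bse).all()
        params = pd.Series(res.params, index=DESIGN_NAMES)
        cov = pd.DataFrame(res.cov_params(), index=DESIGN_NAMES, columns=DESIGN_NAMES)
    except Exception:
        converged = False
        params = pd.Series(np.nan, index=DESIGN_NAMES)
        cov = pd.DataFrame(np.nan, index=DESIGN_NAMES, columns=DESIGN_NAMES)
    return RegulationFit(gene=gene, params=params, cov=cov, converged=converged)


def classify_regulation(fit: RegulationFit) -> pd.DataFrame:
    """Per-category contrast estimate, SE and Wald p for one fitted gene.

    Unconverged fits yield NaN statistics (downstream flags stay False).
    """
    rows = []
    for cat in REGULATION_CATEGORIES:
        c = CONTRASTS[cat]
        if not fit.converged:
            rows.append({"category": cat, "estimate": np.nan, "se": np.nan, "p": np.nan})
            continue
        est = float(c @ fit.params.to_numpy())
        var = float(c @ fit.cov.to_numpy() @ c)
        se = np.sqrt(var) if var > 0 else np.nan
        z = est / se if se and np.isfinite(se) else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({"category": cat, "estimate": est, "se": se, "p": p})
    return pd.DataFrame(rows).set_index("category")


def _adjust_and_flag(table: pd.DataFrame, alpha_level: float) -> pd.DataFrame:
    """BH within each category across genes; flag and direction columns."""
    out = table.copy()
    for cat in REGULATION_CATEGORIES:
        p = out[f"{cat}_p"]
        padj = pd.Series(np.nan, index=out.index)
        defined = p.notna()
        if defined.any():
            padj[defined] = multipletests(p[defined], method="fdr_bh")[1]
        out[f"{cat}_padj"] = padj
        flag = padj <= alpha_level
        out[f"{cat}_flag"] = flag.fillna(False)
        direction = np.where(
            out[f"{cat}_flag"], np.where(out[f"{cat}_estimate"] > 0, "D1", "D2"), "none"
        )
        out[f"{cat}_direction"] = direction
    return out


class CompartmentRegulationClassifier(BaseEstimator):
    """Fit the compartment GLM to every gene of a pooled experiment and call
    regulation categories.

    ``fit`` expects a :class:`CountMatrix` containing samples of all three
    methods. Fitted attributes: ``estimates_`` (per-gene contrasts) and
    ``calls_`` (flags, directions, adjusted p-values).
    """

    def __init__(self, alpha_level: float = 0.05, dispersion_floor: float = 1e-8):
        self.alpha_level = alpha_level
        self.dispersion_floor = dispersion_floor

    def fit(self, X: CountMatrix, y=None):
        from .quantify import size_factors

        meta = X.metadata
        self.size_factors_ = size_factors(X)
        groups = meta["method"].astype(str) + "_" + meta["cell_type"].astype(str)
        self.dispersions_ = estimate_dispersion(
            X.counts, self.size_factors_, groups, floor=self.dispersion_floor
        )
        records = {}
        converged = {}
        for gene in X.gene_ids:
            fit = fit_compartment_glm(
                X.counts.loc[gene],
                meta,
                self.size_factors_,
                self.dispersions_.loc[gene],
                gene=gene,
            )
            table = classify_regulation(fit)
            rec = {}
            for cat in REGULATION_CATEGORIES:
                rec[f"{cat}_estimate"] = table.loc[cat, "estimate"]
                rec[f"{cat}_se"] = table.loc[cat, "se"]
                rec[f"{cat}_p"] = table.loc[cat, "p"]
            records[gene] = rec
            converged[gene] = fit.converged
        est = pd.DataFrame.from_dict(records, orient="index")
        est.index.name = "gene_id"
        est["converged"] = pd.Series(converged)
        self.estimates_ = est
        self.calls_ = _adjust_and_flag(est, self.alpha_level)
        self.n_features_in_ = X.n_genes
        return self


def regulation_overlap(calls: pd.DataFrame) -> dict:
    """Contingency of category flag patterns and a direction-dominance
    summary.

    Returns pattern counts keyed by e.g. ``"transcriptional+cytosolic"``
    (or ``"none"``), direction-pattern counts, and per-category counts of D1
    vs D2 direction with the dominant cell type.
    """
    flags = {cat: calls[f"{cat}_flag"].astype(bool) for cat in REGULATION_CATEGORIES}
    patterns: dict = {}
    direction_patterns: dict = {}
    for gene in calls.index:
        active = [cat for cat in REGULATION_CATEGORIES if flags[cat].loc[gene]]
        key = "+".join(active) if active else "none"
        patterns[key] = patterns.get(key, 0) + 1
        if active:
            dkey = "+".join(
                f"{cat}:{calls.loc[gene, f'{cat}_direction']}" for cat in active
            )
            direction_patterns[dkey] = direction_patterns.get(dkey, 0) + 1
    dominance = {}
    for cat in REGULATION_CATEGORIES:
        d = calls.loc[flags[cat], f"{cat}_direction"].value_counts()
        n_d1, n_d2 = int(d.get("D1", 0)), int(d.get("D2", 0))
        if n_d1 == n_d2:
            dom = "tie" if n_d1 else "none"
        else:
            dom = "D1" if n_d1 > n_d2 else "D2"
        dominance[cat] = {"D1": n_d1, "D2": n_d2, "dominant": dom}
    return {
        "patterns": patterns,
        "direction_patterns": direction_patterns,
        "dominance": dominance,
    }
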