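"""Per-gene variance partitioning across isolation method and cell type.

Each gene's transformed expression is modelled with a grand mean and two
crossed random intercepts — one per isolation method, one per cell type —
plus residual noise:

    y = mu + u_method + u_celltype + e,
    u_method ~ N(0, sigma_m^2), u_celltype ~ N(0, sigma_c^2), e ~ N(0, sigma_e^2)

Variance components are estimated by restricted maximum likelihood (REML)
on the profiled covariance V = sigma_m^2 K_m + sigma_c^2 K_c + sigma_e^2 I,
with an ANOVA method-of-moments fallback when the optimizer fails. The
reported fractions are each component over their sum, truncated at zero and
renormalized, so they lie in [0, 1] and sum to one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix

FRACTION_COLUMNS = ("fraction_method", "fraction_celltype", "fraction_residual")

# tie-break priority for categorize_genes: first match wins on exact ties
_TIE_PRIORITY = ("fraction_residual", "fraction_method", "fraction_celltype")


class _CollapsedREML:
    """Exact REML on group-mean sufficient statistics.

    Because the covariance contributed by the two random intercepts is
    constant within each (method, cell type) group, an orthonormal rotation
    splits the data into G scaled group means plus N - G within-group
    contrasts whose covariance is sigma_e^2 I. The restricted likelihood
    then only needs G x G linear algebra per evaluation (G = 6 here),
    instead of N x N.
    """

    def __init__(self, metadata: pd.DataFrame):
        groups = metadata.groupby(["method", "cell_type"], sort=True)
        self.group_index = {key: k for k, (key, _) in enumerate(groups)}
        self.group_of = metadata.set_index(metadata.index).apply(
            lambda r: self.group_index[(r["method"], r["cell_type"])], axis=1
        ).to_numpy()
        self.n_g = np.bincount(self.group_of).astype(float)
        self.G = len(self.n_g)
        self.N = len(metadata)
        keys = list(self.group_index)
        methods = [k[0] for k in keys]
        cts = [k[1] for k in keys]
        self.A = np.equal.outer(methods, methods).astype(float)   # shared method
        self.B = np.equal.outer(cts, cts).astype(float)           # shared cell type
        self.x = np.sqrt(self.n_g)                                # intercept in mean coords
        self.sqrt_ng = np.sqrt(np.outer(self.n_g, self.n_g))

    def stats(self, y: np.ndarray):
        sums = np.bincount(self.group_of, weights=y, minlength=self.G)
        means = sums / self.n_g
        sse = float(((y - means[self.group_of]) ** 2).sum())
        return means * self.x, sse  # scaled means m_g = sqrt(n_g) * ybar_g

    def neg_loglik(self, log_theta, m, sse):
        from scipy.linalg import cho_factor, cho_solve

        sm2, sc2, se2 = np.exp(np.clip(log_theta, -40, 40))
        C = self.sqrt_ng * (sm2 * self.A + sc2 * self.B) + se2 * np.eye(self.G)
        try:
            cf = cho_factor(C, lower=True, check_finite=False)
        except Exception:
            return 1e10
        # residual contrasts: (N - G) iid with variance sigma_e^2
        out = (self.N - self.G) * np.log(se2) + sse / se2
        out += 2.0 * np.log(np.diag(cf[0])).sum()
        sol = cho_solve(cf, np.column_stack([self.x, m]), check_finite=False)
        xcx = self.x @ sol[:, 0]
        if xcx <= 0:
            return 1e10
        beta = (self.x @ sol[:, 1]) / xcx
        r = m - beta * self.x
        out += np.log(xcx) + r @ cho_solve(cf, r, check_finite=False)
        return 0.5 * out


def _moment_start(y, method_labels, ct_labels):
    """ANOVA-flavoured starting values (also the fallback estimate)."""
    df = pd.DataFrame({"y": y, "m": list(method_labels), "c": list(ct_labels)})
    grand = df["y"].mean()
    cell_means = df.groupby(["m", "c"])["y"].mean()
    resid = df["y"] - df.set_index(["m", "c"]).index.map(cell_means).to_numpy()
    se2 = float(np.var(resid, ddof=1)) if len(df) > len(cell_means) else float(np.var(y))
    m_means = df.groupby("m")["y"].mean()
    c_means = df.groupby("c")["y"].mean()
    n_per_m = df.groupby("m").size().mean()
    n_per_c = df.groupby("c").size().mean()
    sm2 = max(float(((m_means - grand) ** 2).mean()) - se2 / n_per_m, 0.0)
    sc2 = max(float(((c_means - grand) ** 2).mean()) - se2 / n_per_c, 0.0)
    return sm2, sc2, max(se2, 1e-12)


def partition_variance(
    expr: ExpressionMatrix, metadata: pd.DataFrame | None = None
) -> pd.DataFrame:
    """REML variance fractions per gene.

    Returns a DataFrame with columns ``fraction_method``,
    ``fraction_celltype``, ``fraction_residual`` (summing to 1) and a
    ``converged`` flag; near-constant genes are flagged with NaN fractions.
    """
    metadata = metadata if metadata is not None else expr.metadata
    if metadata is None:
        raise ValueError("sample metadata required")
    metadata = metadata.loc[expr.sample_ids]
    for col in ("method", "cell_type"):
        counts = metadata[col].value_counts()
        if len(counts) < 2:
            raise ValueError(f"covariate {col!r} needs >=2 levels")
        if (counts < 2).any():
            raise ValueError(f"covariate {col!r} has a level with <2 samples")
    reml = _CollapsedREML(metadata)

    rows = np.empty((expr.values.shape[0], 3))
    converged = np.ones(expr.values.shape[0], dtype=bool)
    mat = expr.values.to_numpy(dtype=float)
    for i in range(mat.shape[0]):
        y = mat[i]
        total = np.var(y)
        if total < 1e-12:
            rows[i] = [np.nan, np.nan, np.nan]
            converged[i] = False
            continue
        m, sse = reml.stats(y)
        start = _moment_start(y, metadata["method"], metadata["cell_type"])
        x0 = np.log(np.maximum(start, 1e-6 * total))
        try:
            res = optimize.minimize(
                reml.neg_loglik,
                x0,
                args=(m, sse),
                method="Nelder-Mead",
                options={"maxiter": 200, "xatol": 1e-3, "fatol": 1e-7},
            )
            theta = np.exp(res.x) if res.success or res.fun < 1e9 else np.array(start)
        except Exception:
            theta = np.array(start)
            converged[i] = False
        theta = np.clip(theta, 0.0, None)
        s = theta.sum()
        if s <= 0:
            rows[i] = [np.nan, np.nan, np.nan]
            converged[i] = False
        else:
            rows[i] = theta / s
    out = pd.DataFrame(
        rows, index=expr.gene_ids,
        columns=["fraction_method", "fraction_celltype", "fraction_residual"],
    )
    out["converged"] = converged
    return out


def categorize_genes(fractions: pd.DataFrame) -> pd.Series:
    """Assign each gene to its argmax fraction: method / celltype /
    residual.

    Exact ties break by the fixed priority residual > method > celltype.
    """
    cats = []
    for _, row in fractions[list(FRACTION_COLUMNS)].iterrows():
        if row.isna().any():
            cats.append("unassigned")
            continue
        best = max(row)
        for col in _TIE_PRIORITY:
            if row[col] == best:
                cats.append(col.replace("fraction_", ""))
                break
    return pd.Series(cats, index=fractions.index, name="category")


def assign_method_by_fpkm(gene_ids, fpkm: ExpressionMatrix) -> pd.Series:
    """Assign each gene to the method with the highest mean FPKM.

    Exact ties between the top methods yield ``"unassigned"``.
    """
    if fpkm.metadata is None:
        raise ValueError("FPKM matrix needs sample metadata")
    missing = [g for g in gene_ids if g not in fpkm.values.index]
    if missing:
        raise KeyError(f"genes absent from FPKM table: {missing[:10]}")
    per_method = fpkm.values.loc[list(gene_ids)].T.groupby(
        fpkm.metadata["method"]
    ).mean().T
    out = {}
    for g, row in per_method.iterrows():
        best = row.max()
        winners = row.index[row == best]
        out[g] = winners[0] if len(winners) == 1 else "unassigned"
    return pd.Series(out, name="assigned_method")


def localization_overlap(assigned: dict, localization_sets: dict) -> pd.DataFrame:
    """Per-method compartment composition of method-variable genes.

    ``assigned`` maps method -> iterable of genes; ``localization_sets``
    maps compartment name -> gene set. Genes absent from the union of the
    sets are dropped; a gene located in several compartments counts toward
    each, so rows can exceed 100% in total. Values are percentages.
    """
    if not localization_sets or all(len(s) == 0 for s in localization_sets.values()):
        raise ValueError("localization sets are empty")
    universe = set().union(*localization_sets.values())
    rows = {}
    for method, genes in assigned.items():
        present = [g for g in genes if g in universe]
        row = {}
        for comp, s in localization_sets.items():
            row[comp] = 100.0 * sum(g in s for g in present) / len(present) if present else np.nan
        rows[method] = row
    return pd.DataFrame.from_dict(rows, orient="index")


class VariancePartitioner(BaseEstimator):
    """Estimator wrapper: ``fit`` computes per-gene variance fractions
    (``fractions_``) and the argmax category per gene (``categories_``)."""

    def __init__(self):
        pass

    def fit(self, X: ExpressionMatrix, y=None):
        self.fractions_ = partition_variance(X)
        self.categories_ = categorize_genes(self.fractions_)
        self.mean_fractions_ = self.fractions_[list(FRACTION_COLUMNS)].mean()
        self.n_features_in_ = X.values.shape[0]
        return self
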