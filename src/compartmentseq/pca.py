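"""PCA of transformed expression and method-centroid distance analysis.

Samples are observations and genes are (centered, unscaled) variables.
Method centroids are means of (PC1, PC2); the headline summaries are the
pairwise centroid distances, the per-sample Euclidean distance to the own
method's centroid, and Welch two-sided t-tests comparing those within-method
distance lists between methods — a compact description of how tightly each
isolation method clusters and how far apart the methods sit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .containers import ExpressionMatrix


def pca(expr: ExpressionMatrix, n_components: int = 6):
    """Sample-space PCA on gene-centered values.

    Returns ``(scores, explained_variance_ratio)``; component signs follow a
    deterministic convention (the largest-magnitude gene loading of each
    component is positive).
    """
    n_samples = expr.values.shape[1]
    max_comp = min(n_samples, expr.values.shape[0])
    if n_components > max_comp:
        raise ValueError(f"n_components={n_components} exceeds min(dim)={max_comp}")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    X = expr.values.T.to_numpy(dtype=float)  # samples x genes
    X = X - X.mean(axis=0)
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    # deterministic sign: flip components whose extreme loading is negative
    for j in range(n_components):
        load = model.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            model.components_[j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(n_components)]
    scores_df = pd.DataFrame(scores, index=expr.sample_ids, columns=cols)
    return scores_df, model.explained_variance_ratio_


@dataclass
class CentroidDistances:
    """Method centroids on PC1/PC2 with within- and between-method
    distances."""

    centroids: pd.DataFrame                  # method x (PC1, PC2)
    pairwise: pd.DataFrame                   # method x method centroid distances
    sample_distances: pd.Series              # per sample, to own centroid
    mean_within: pd.Series                   # per method
    t_tests: dict = field(default_factory=dict)  # (m1, m2) -> (t, p)
    excluded_methods: list = field(default_factory=list)


def centroid_analysis(scores: pd.DataFrame, method_labels: pd.Series) -> CentroidDistances:
    """Centroid geometry and Welch t-tests on PC1/PC2.

    Methods with a single sample are excluded (with a note in
    ``excluded_methods``).
    """
    method_labels = method_labels.loc[scores.index]
    pcs = scores[["PC1", "PC2"]]
    counts = method_labels.value_counts()
    excluded = [m for m in counts.index if counts[m] < 2]
    keep = ~method_labels.isin(excluded)
    pcs = pcs.loc[keep]
    labels = method_labels.loc[keep]

    centroids = pcs.groupby(labels).mean()
    methods = list(centroids.index)
    pairwise = pd.DataFrame(0.0, index=methods, columns=methods)
    for a, b in combinations(methods, 2):
        d = float(np.linalg.norm(centroids.loc[a] - centroids.loc[b]))
        pairwise.loc[a, b] = pairwise.loc[b, a] = d

    own = centroids.loc[labels].to_numpy()
    dist = pd.Series(
        np.linalg.norm(pcs.to_numpy() - own, axis=1), index=pcs.index, name="distance"
    )
    mean_within = dist.groupby(labels).mean()

    t_tests = {}
    for a, b in combinations(methods, 2):
        da, db = dist[labels == a], dist[labels == b]
        if da.var(ddof=1) == 0 and db.var(ddof=1) == 0:
            t, p = (np.nan, 1.0) if np.isclose(da.mean(), db.mean()) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(da, db, equal_var=False)
        t_tests[(a, b)] = (float(t), float(p))
    return CentroidDistances(
        centroids=centroids,
        pairwise=pairwise,
        sample_distances=dist,
        mean_within=mean_within,
        t_tests=t_tests,
        excluded_methods=excluded,
    )


def outlier_flag(
    scores: pd.DataFrame,
    group_labels: pd.Series,
    mapping_rates: pd.Series | None = None,
    unmapped_threshold: float = 0.8,
    robust_z: float = 3.0,
) -> pd.Series:
    """Flag samples with an unmapped-read fraction above the threshold or a
    PC1/PC2 coordinate beyond ``robust_z`` robust z-scores from the group
    centroid.

    Exclusion is the caller's choice; this only reports flags.
    """
    group_labels = group_labels.loc[scores.index]
    flags = pd.Series(False, index=scores.index, name="outlier")
    if mapping_rates is not None:
        flags |= mapping_rates.reindex(scores.index).fillna(0.0) > unmapped_threshold
    for _, idx in scores.groupby(group_labels).groups.items():
        sub = scores.loc[idx, ["PC1", "PC2"]]
        med = sub.median()
        mad = (sub - med).abs().median() * 1.4826
        mad = mad.replace(0.0, np.nan)
        rz = ((sub - med) / mad).abs()
        flags.loc[idx] |= (rz > robust_z).any(axis=1).fillna(False)
    return flags


class ExpressionPCA(BaseEstimator):
    """Estimator wrapper: ``fit`` computes sample scores (``scores_``),
    explained variance ratios and — when metadata is available — the
    centroid-distance analysis (``centroid_distances_``)."""

    def __init__(self, n_components: int = 6):
        self.n_components = n_components

    def fit(self, X: ExpressionMatrix, y=None):
        self.scores_, self.explained_variance_ratio_ = pca(X, self.n_components)
        if X.metadata is not None:
            self.centroid_distances_ = centroid_analysis(
                self.scores_, X.metadata["method"]
            )
        self.n_features_in_ = X.values.shape[0]
        return self

    def transform(self, X: ExpressionMatrix) -> pd.DataFrame:
        if not hasattr(self, "scores_"):
            raise RuntimeError("estimator is not fitted")
        return self.scores_
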