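"""Signed weighted co-expression and mutual-information networks.

The co-expression arm follows the WGCNA recipe: biweight midcorrelation
between genes, a signed adjacency ``((1 + cor) / 2) ** beta`` with the soft
power chosen for approximate scale-free topology (R^2 > 0.8), the signed
topological overlap matrix (TOM), average-linkage clustering on 1 - TOM
with a static cut, module-size filtering, eigengene-based module merging
and kME pruning. Module detection here is deliberately deterministic: a
static tree cut plus size filter and merging stands in for the dynamic
hybrid cut, and no post-assignment of unclustered genes is performed.

The information-theoretic arm builds an ARACNE-style network: equal-
frequency discretization, plug-in empirical mutual information in nats, and
data-processing-inequality pruning that removes the weakest edge of every
triangle. Consensus networks keep only edges detected by both arms, and hub
networks are the top-k nodes by degree together with their first-degree
neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator

from .containers import ExpressionMatrix

# ---------------------------------------------------------------------------
# correlation and adjacency


def bicor_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Biweight midcorrelation between genes (rows), tuning constant 9 MADs.

    Observations more than 9 MADs from the gene median get zero weight;
    weights are ``(1 - u^2)^2``. Genes with zero MAD fall back to Pearson
    (their rows are standardized instead), which is logged via a warning.
    """
    X = expr.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 4:
        raise ValueError("need at least 4 samples for bicor")
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    zero_mad = mad[:, 0] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = (X - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    tilde = (X - med) * w
    # Pearson fallback rows for zero-MAD genes
    if zero_mad.any():
        warnings.warn(f"{int(zero_mad.sum())} zero-MAD gene(s): Pearson fallback")
        centered = X[zero_mad] - X[zero_mad].mean(axis=1, keepdims=True)
        tilde[zero_mad] = centered
    norms = np.linalg.norm(tilde, axis=1, keepdims=True)
    degenerate = norms[:, 0] == 0
    norms[degenerate] = 1.0
    R = tilde / norms
    C = R @ R.T
    C[degenerate, :] = 0.0
    C[:, degenerate] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return pd.DataFrame(C, index=expr.gene_ids, columns=expr.gene_ids)


def signed_adjacency(correlations: pd.DataFrame, power: float) -> pd.DataFrame:
    """Signed adjacency ``((1 + cor) / 2) ** power`` with unit diagonal."""
    A = ((1.0 + correlations.to_numpy()) / 2.0) ** power
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=correlations.index, columns=correlations.columns)


@dataclass
class SoftPowerResult:
    """Scale-free fit per candidate power and the chosen exponent."""

    candidates: list
    r_squared: pd.Series
    power: int
    passed: bool  # False when no candidate reached the R^2 cut


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log regression of the connectivity histogram.

    Follows the standard soft-thresholding convention: the fit index is the
    regression R^2 carrying the sign of minus the slope, so a distribution
    with frequency *increasing* in connectivity (the opposite of scale-free)
    scores negative and can never pass the cut.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        return 0.0
    x = np.log10(centers[keep])
    y = np.log10(counts[keep] / counts.sum())
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return 0.0
    fit = stats.linregress(x, y)
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def select_soft_power(
    correlations: pd.DataFrame,
    candidates=tuple(range(1, 21)),
    r2_cut: float = 0.8,
    n_bins: int = 10,
) -> SoftPowerResult:
    """Choose the smallest power reaching scale-free R^2 > ``r2_cut``; if
    none does, take the R^2-maximizing candidate with a warning."""
    if correlations.shape[0] < 10:
        raise ValueError("need at least 10 genes to assess scale-free topology")
    C = correlations.to_numpy()
    r2 = {}
    for beta in candidates:
        A = ((1.0 + C) / 2.0) ** beta
        np.fill_diagonal(A, 0.0)
        r2[beta] = scale_free_fit(A.sum(axis=0), n_bins=n_bins)
    r2_s = pd.Series(r2)
    passing = [b for b in candidates if r2[b] > r2_cut]
    if passing:
        return SoftPowerResult(list(candidates), r2_s, int(min(passing)), True)
    best = int(r2_s.idxmax())
    warnings.warn(
        f"no candidate power reached scale-free R^2 > {r2_cut}; using {best} "
        f"(R^2 = {r2_s.max():.3f})"
    )
    return SoftPowerResult(list(candidates), r2_s, best, False)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Signed topological overlap:
    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``.
    """
    A = adjacency.to_numpy(dtype=float).copy()
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(A, 0.0)
    if A.size and (A.min() < 0 or A.max() > 1):
        raise ValueError("adjacency values must lie in [0, 1]")
    k = A.sum(axis=0)
    shared = A @ A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = (shared + A) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


# ---------------------------------------------------------------------------
# modules and eigengenes


def module_eigengene(expr_sub: pd.DataFrame):
    """First principal component of a module (gene-standardized rows).

    Returns ``(eigengene, variance_explained)``; the sign is oriented so the
    mean gene-eigengene correlation is positive.
    """
    if expr_sub.shape[0] < 2 or expr_sub.shape[1] < 3:
        raise ValueError("eigengene needs >=2 genes and >=3 samples")
    X = expr_sub.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    if (sd == 0).all():
        raise ValueError("constant module submatrix")
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    v = Vt[0]
    if U[:, 0].mean() < 0:
        v = -v
    var_explained = float(S[0] ** 2 / (S**2).sum())
    return pd.Series(v, index=expr_sub.columns, name="eigengene"), var_explained


@dataclass
class ModuleSet:
    """Module labels (0 = unassigned/"grey"), eigengenes and kME."""

    labels: pd.Series                 # gene -> int module label, 0 unassigned
    eigengenes: pd.DataFrame          # samples x modules ("ME<k>")
    kme: pd.Series                    # gene -> correlation with own eigengene
    variance_explained: dict = field(default_factory=dict)

    @property
    def n_modules(self) -> int:
        return int((self.labels.unique() != 0).sum())

    def genes_in(self, module: int) -> list:
        return list(self.labels.index[self.labels == module])


def _compute_eigengenes(expr: pd.DataFrame, labels: pd.Series):
    eg, ve = {}, {}
    for mod in sorted(set(labels) - {0}):
        sub = expr.loc[labels.index[labels == mod]]
        eg[mod], ve[mod] = module_eigengene(sub)
    return eg, ve


def detect_modules(
    tom: pd.DataFrame,
    expr: ExpressionMatrix,
    min_size: int = 100,
    cut_height: float = 0.99,
    merge_height: float = 0.2,
    min_kme: float = 0.1,
) -> ModuleSet:
    """Average-linkage clustering on 1 - TOM with a static cut.

    Clusters smaller than ``min_size`` become unassigned; modules whose
    eigengenes correlate above ``1 - merge_height`` are merged iteratively;
    genes with |kME| below ``min_kme`` to their module eigengene are
    unassigned. No post-assignment of unclustered genes is performed.
    """
    genes = list(tom.index)
    values = expr.values.loc[genes]
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes, dtype=int)
    sizes = labels.value_counts()
    labels[labels.map(sizes) < min_size] = 0
    if (labels == 0).all():
        warnings.warn("all genes unassigned: no cluster reached min_size")
        return ModuleSet(labels, pd.DataFrame(index=values.columns), pd.Series(dtype=float))

    eigengenes, varexp = _compute_eigengenes(values, labels)
    # iterative merge of the most correlated eigengene pair
    while len(eigengenes) > 1:
        mods = sorted(eigengenes)
        best_pair, best_corr = None, -np.inf
        for a, b in combinations(mods, 2):
            r = float(np.corrcoef(eigengenes[a], eigengenes[b])[0, 1])
            if r > best_corr:
                best_corr, best_pair = r, (a, b)
        if best_corr <= 1.0 - merge_height:
            break
        a, b = best_pair
        labels[labels == b] = a
        sub = values.loc[labels.index[labels == a]]
        eigengenes[a], varexp[a] = module_eigengene(sub)
        del eigengenes[b], varexp[b]

    # kME pruning
    kme = pd.Series(0.0, index=genes)
    for mod, eg in eigengenes.items():
        for g in labels.index[labels == mod]:
            x = values.loc[g].to_numpy(dtype=float)
            if x.std() == 0:
                kme[g] = 0.0
            else:
                kme[g] = float(np.corrcoef(x, eg.to_numpy())[0, 1])
    weak = (labels != 0) & (kme.abs() < min_kme)
    labels[weak] = 0

    # drop modules that fell below min_size after pruning, renumber by size
    sizes = labels[labels != 0].value_counts()
    for mod in list(eigengenes):
        if sizes.get(mod, 0) < min_size:
            labels[labels == mod] = 0
            eigengenes.pop(mod)
            varexp.pop(mod)
    order = sorted(eigengenes, key=lambda m: -int((labels == m).sum()))
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = labels.map(lambda m: remap.get(m, 0))
    eigengenes = {remap[m]: eigengenes[m] for m in order}
    varexp = {remap[m]: varexp[m] for m in order}
    kme[labels == 0] = 0.0
    eg_df = pd.DataFrame({f"ME{m}": eigengenes[m] for m in sorted(eigengenes)})
    return ModuleSet(labels, eg_df, kme, varexp)


def eigengene_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with each trait, with a
    Bonferroni threshold of ``alpha / n_modules``."""
    if eigengenes.shape[1] == 0:
        raise ValueError("no module eigengenes")
    threshold = alpha / eigengenes.shape[1]
    rows = []
    for trait in traits.columns:
        t = traits[trait].to_numpy(dtype=float)
        if np.std(t) == 0:
            raise ValueError(f"constant trait {trait!r}")
        for me in eigengenes.columns:
            r, p = stats.pearsonr(eigengenes[me].to_numpy(), t)
            rows.append(
                {
                    "module": me,
                    "trait": trait,
                    "r": float(r),
                    "p": float(p),
                    "threshold": threshold,
                    "significant": bool(p < threshold),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mutual information and DPI


def equal_frequency_discretize(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency level assignment with stable rank tie-breaking."""
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * bins) // n


def mutual_information_matrix(
    expr: ExpressionMatrix, bins: int | None = None
) -> pd.DataFrame:
    """Empirical plug-in mutual information (nats) on equal-frequency
    discretized expression; the diagonal is excluded (set to 0).

    Constant genes get zero MI with every partner (logged via a warning).
    """
    X = expr.values.to_numpy(dtype=float)
    n_genes, n = X.shape
    if bins is None:
        bins = max(int(np.floor(np.sqrt(n))), 2)
    if bins < 2 or bins > n:
        raise ValueError(f"bins={bins} incompatible with {n} samples")
    D = np.empty((n_genes, n), dtype=np.int64)
    for i in range(n_genes):
        D[i] = equal_frequency_discretize(X[i], bins)
    constant = X.std(axis=1) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant gene(s): MI set to 0")
    M = np.zeros((n_genes, n_genes))
    log_n = np.log(n)
    for i in range(n_genes):
        if constant[i]:
            continue
        Di = D[i] * bins
        for j in range(i + 1, n_genes):
            if constant[j]:
                continue
            joint = np.bincount(Di + D[j], minlength=bins * bins).astype(float)
            joint = joint[joint > 0]
            pi = np.bincount(D[i], minlength=bins).astype(float) / n
            pj = np.bincount(D[j], minlength=bins).astype(float) / n
            h_joint = -np.sum(joint / n * (np.log(joint) - log_n))
            h_i = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
            h_j = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
            M[i, j] = M[j, i] = max(h_i + h_j - h_joint, 0.0)
    return pd.DataFrame(M, index=expr.gene_ids, columns=expr.gene_ids)


def discrete_mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (nats) of two already-discretized integer vectors."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    n = len(x)
    kx, ky = x.max() + 1, y.max() + 1
    joint = np.bincount(x * ky + y, minlength=kx * ky).astype(float).reshape(kx, ky) / n
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    mi = 0.0
    for a in range(kx):
        for b in range(ky):
            if joint[a, b] > 0:
                mi += joint[a, b] * np.log(joint[a, b] / (px[a] * py[b]))
    return max(mi, 0.0)


def aracne_dpi(mi: pd.DataFrame, tolerance: float = 0.0) -> pd.DataFrame:
    """Data-processing-inequality pruning.

    For every triangle, the edge with the smallest MI is removed when it is
    below ``min(other two) * (1 - tolerance)``. Returns the surviving edges
    as a DataFrame (gene_a, gene_b, mi_weight) with gene_a < gene_b.
    """
    W = mi.to_numpy(dtype=float).copy()
    if not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("MI matrix must be symmetric")
    if (W < 0).any():
        raise ValueError("MI must be nonnegative")
    np.fill_diagonal(W, 0.0)
    n = W.shape[0]
    # T[i, j] = max_k min(W[i, k], W[k, j]); absent edges contribute 0
    T = np.zeros_like(W)
    chunk = max(1, int(2e7 / max(n * n, 1)))
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        T[s:e] = np.minimum(W[s:e, :, None], W[None, :, :]).max(axis=1)
    keep = (W > 0) & ~(W < T * (1.0 - tolerance))
    genes = list(mi.index)
    ii, jj = np.where(np.triu(keep, k=1))
    return pd.DataFrame(
        {
            "gene_a": [genes[i] for i in ii],
            "gene_b": [genes[j] for j in jj],
            "mi_weight": W[ii, jj],
        }
    )


# ---------------------------------------------------------------------------
# consensus and hubs


@dataclass
class ConsensusNetwork:
    """Edges detected by both the TOM and the MI/DPI network."""

    genes: list
    edges: pd.DataFrame  # gene_a, gene_b, tom_weight, mi_weight

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, tom=row.tom_weight, mi=row.mi_weight)
        return g


def consensus_edges(
    tom: pd.DataFrame, dpi_edges: pd.DataFrame, tom_edge_threshold: float = 0.02
) -> ConsensusNetwork:
    """Intersect TOM edges (TOM >= threshold) with DPI-surviving MI edges,
    retaining both weights."""
    genes = set(tom.index)
    rows = []
    for row in dpi_edges.itertuples(index=False):
        a, b = row.gene_a, row.gene_b
        if a in genes and b in genes:
            t = float(tom.loc[a, b])
            if t >= tom_edge_threshold:
                rows.append((a, b, t, float(row.mi_weight)))
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "tom_weight", "mi_weight"])
    if edges.empty:
        warnings.warn("consensus network has no edges")
    return ConsensusNetwork(sorted(genes), edges)


@dataclass
class HubNetwork:
    """Top-k hubs by degree with their first-degree neighborhood."""

    hubs: list
    nodes: set
    edges: pd.DataFrame


def hub_network(consensus: ConsensusNetwork, k: int = 20) -> HubNetwork:
    """The k highest-degree nodes (ties by weighted TOM degree, then lexical
    gene id) plus their first-degree neighbors and the induced edges."""
    if consensus.edges.empty:
        raise ValueError("empty consensus network")
    g = consensus.graph()
    connected = [nd for nd in g.nodes if g.degree(nd) >= 1]
    if len(connected) < k:
        warnings.warn(f"only {len(connected)} connected nodes; taking all as hubs")
    wdeg = {nd: sum(d["tom"] for _, _, d in g.edges(nd, data=True)) for nd in connected}
    ranked = sorted(connected, key=lambda nd: (-g.degree(nd), -wdeg[nd], nd))
    hubs = ranked[: min(k, len(ranked))]
    nodes = set(hubs)
    for h in hubs:
        nodes |= set(g.neighbors(h))
    mask = consensus.edges["gene_a"].isin(nodes) & consensus.edges["gene_b"].isin(nodes)
    return HubNetwork(hubs, nodes, consensus.edges[mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# estimator wrappers

# soft powers reused from the published configuration when the sample layout
# matches; anything else re-selects automatically
DEFAULT_POWERS = {
    "pooled": 18,
    "nuclear": 12,
    "wholecell": 18,
    "ribotag": 9,
    "ribotag_female": 6,
}


class CoexpressionNetwork(BaseEstimator):
    """Signed weighted co-expression network estimator.

    ``fit`` computes bicor, selects (or accepts) the soft power, builds the
    signed adjacency and TOM, and detects modules. Fitted attributes:
    ``correlation_``, ``soft_power_``, ``adjacency_``, ``tom_``,
    ``modules_``.
    """

    def __init__(
        self,
        power="auto",
        min_module_size: int = 100,
        cut_height: float = 0.99,
        merge_height: float = 0.2,
        min_kme: float = 0.1,
        r2_cut: float = 0.8,
    ):
        self.power = power
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.merge_height = merge_height
        self.min_kme = min_kme
        self.r2_cut = r2_cut

    def fit(self, X: ExpressionMatrix, y=None):
        self.correlation_ = bicor_matrix(X)
        if self.power == "auto":
            self.soft_power_ = select_soft_power(self.correlation_, r2_cut=self.r2_cut)
            beta = self.soft_power_.power
        else:
            beta = int(self.power)
            self.soft_power_ = None
        self.power_ = beta
        self.adjacency_ = signed_adjacency(self.correlation_, beta)
        self.tom_ = topological_overlap(self.adjacency_)
        self.modules_ = detect_modules(
            self.tom_,
            X,
            min_size=self.min_module_size,
            cut_height=self.cut_height,
            merge_height=self.merge_height,
            min_kme=self.min_kme,
        )
        self.n_features_in_ = X.values.shape[0]
        return self


class MutualInformationNetwork(BaseEstimator):
    """ARACNE-style network estimator: equal-frequency MI plus DPI pruning.

    Fitted attributes: ``mi_`` (gene x gene MI) and ``edges_`` (surviving
    edge list).
    """

    def __init__(self, bins: int | None = None, tolerance: float = 0.0):
        self.bins = bins
        self.tolerance = tolerance

    def fit(self, X: ExpressionMatrix, y=None):
        self.mi_ = mutual_information_matrix(X, bins=self.bins)
        self.edges_ = aracne_dpi(self.mi_, tolerance=self.tolerance)
        self.n_features_in_ = X.values.shape[0]
        return self
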