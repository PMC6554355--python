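"""Co-expression / MI network construction against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from compartmentseq.containers import ExpressionMatrix
from compartmentseq.network import (
    ConsensusNetwork,
    aracne_dpi,
    bicor_matrix,
    consensus_edges,
    detect_modules,
    eigengene_trait_correlation,
    equal_frequency_discretize,
    hub_network,
    module_eigengene,
    mutual_information_matrix,
    scale_free_fit,
    select_soft_power,
    signed_adjacency,
    topological_overlap,
)


def _expr(values, gene_ids=None, sample_ids=None):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(df, "vst")


def bicor_oracle(x, y):
    """Independent biweight midcorrelation (tuning constant 9 MADs)."""
    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        return (v - med) * w

    a, b = weights(np.asarray(x, float)), weights(np.asarray(y, float))
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


class TestBicor:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        em = _expr(rng.normal(size=(5, 10)))
        C = bicor_matrix(em)
        assert np.allclose(np.diag(C), 1.0)

    def test_proportional_genes_give_one(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        em = _expr(np.vstack([x, 3 * x + 2]))
        C = bicor_matrix(em)
        assert C.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=8)
        y = 0.5 * x + rng.normal(size=8)
        em = _expr(np.vstack([x, y]))
        C = bicor_matrix(em)
        assert C.iloc[0, 1] == pytest.approx(bicor_oracle(x, y), abs=1e-10)

    def test_zero_mad_gene_falls_back_to_pearson(self):
        x = np.array([5.0] * 7 + [6.0])  # MAD 0
        y = np.arange(8.0)
        em = _expr(np.vstack([x, y]))
        with pytest.warns(UserWarning, match="zero-MAD"):
            C = bicor_matrix(em)
        expected = np.corrcoef(x - x.mean(), y)[0, 1]
        # fallback row is Pearson-standardized; against a bicor row the value
        # is a hybrid, so only check it is finite and bounded
        assert -1.0 <= C.iloc[0, 1] <= 1.0


class TestSoftPower:
    def test_scale_free_data_passes(self):
        """Connectivity drawn from a bounded power law p(k) ~ k^-2 scores
        R^2 > 0.8."""
        rng = np.random.default_rng(2)
        u = rng.random(3000)
        k = 1.0 / (1.0 - u * (1.0 - 1.0 / 30.0))  # inverse-CDF sample on [1, 30]
        assert scale_free_fit(k) > 0.8

    def test_increasing_frequency_scores_negative(self):
        k = np.concatenate([np.full(10, 1.0), np.full(300, 10.0)]) + np.linspace(0, 1, 310)
        assert scale_free_fit(k) <= 0.0

    def test_selection_returns_smallest_passing(self, monkeypatch):
        import compartmentseq.network as net

        rng = np.random.default_rng(3)
        em = _expr(rng.normal(size=(30, 12)))
        C = bicor_matrix(em)
        fits = {b: (0.9 if b == 9 else 0.5) for b in range(1, 21)}

        def fake_fit(connectivity, n_bins=10, _state={"i": 0}):
            betas = list(range(1, 21))
            val = fits[betas[_state["i"] % 20]]
            _state["i"] += 1
            return val

        monkeypatch.setattr(net, "scale_free_fit", fake_fit)
        res = net.select_soft_power(C)
        assert res.power == 9 and res.passed

    def test_random_data_takes_warning_path(self):
        rng = np.random.default_rng(4)
        em = _expr(rng.normal(size=(60, 20)))
        C = bicor_matrix(em)
        with pytest.warns(UserWarning, match="no candidate"):
            res = select_soft_power(C)
        assert not res.passed

    def test_too_few_genes_rejected(self):
        rng = np.random.default_rng(5)
        em = _expr(rng.normal(size=(5, 12)))
        with pytest.raises(ValueError):
            select_soft_power(bicor_matrix(em))


class TestTOM:
    def test_two_node_forced_value(self):
        A = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]], index=["a", "b"], columns=["a", "b"])
        tom = topological_overlap(A)
        assert tom.loc["a", "b"] == pytest.approx(1.0)

    def test_isolated_pair_is_zero(self):
        A = pd.DataFrame(np.zeros((3, 3)), index=list("abc"), columns=list("abc"))
        np.fill_diagonal(A.values, 1.0)
        tom = topological_overlap(A)
        assert tom.loc["a", "b"] == 0.0

    def test_four_node_hand_oracle(self):
        genes = list("abcd")
        A = np.array(
            [
                [0.0, 0.5, 0.2, 0.0],
                [0.5, 0.0, 0.4, 0.1],
                [0.2, 0.4, 0.0, 0.3],
                [0.0, 0.1, 0.3, 0.0],
            ]
        )
        tom = topological_overlap(pd.DataFrame(A, index=genes, columns=genes))
        k = A.sum(axis=0)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                shared = sum(A[i, u] * A[u, j] for u in range(4))
                expected = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                assert tom.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounds_and_lower_bound_inequality(self):
        rng = np.random.default_rng(6)
        A = rng.random((15, 15)) * 0.5
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        tom = topological_overlap(pd.DataFrame(A)).to_numpy()
        assert tom.min() >= 0 and tom.max() <= 1
        k = A.sum(axis=0)
        lower = A / (np.minimum.outer(k, k) + 1 - A)
        off = ~np.eye(15, dtype=bool)
        assert (tom[off] >= lower[off] - 1e-12).all()

    def test_asymmetric_input_rejected(self):
        A = pd.DataFrame(np.array([[0.0, 0.5], [0.2, 0.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(A)


class TestEigengene:
    def test_identical_genes_explain_everything(self):
        x = np.sin(np.arange(6))
        em = pd.DataFrame(np.vstack([x, x, x]), columns=[f"s{i}" for i in range(6)])
        eg, ve = module_eigengene(em)
        assert ve == pytest.approx(1.0)
        z = (x - x.mean()) / x.std()
        assert np.allclose(np.abs(eg), np.abs(z / np.linalg.norm(z)), atol=1e-10)

    def test_orientation_positive_mean_correlation(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=8)
        mat = np.vstack([base + rng.normal(0, 0.1, 8) for _ in range(5)])
        em = pd.DataFrame(mat, columns=[f"s{i}" for i in range(8)])
        eg, _ = module_eigengene(em)
        corr = [np.corrcoef(mat[i], eg)[0, 1] for i in range(5)]
        assert np.mean(corr) > 0
        # flipping all genes' signs must give the same oriented eigengene
        eg2, _ = module_eigengene(-em)
        assert np.allclose(np.abs(eg), np.abs(eg2), atol=1e-10)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(size=(3, 7))
        em = pd.DataFrame(mat, columns=[f"s{i}" for i in range(7)])
        eg, ve = module_eigengene(em)
        Z = (mat - mat.mean(axis=1, keepdims=True)) / mat.std(axis=1, keepdims=True)
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        assert np.allclose(np.abs(eg), np.abs(Vt[0]), atol=1e-10)
        assert ve == pytest.approx(S[0] ** 2 / (S**2).sum())

    def test_constant_module_rejected(self):
        em = pd.DataFrame(np.ones((3, 5)))
        with pytest.raises(ValueError, match="constant"):
            module_eigengene(em)


class TestModules:
    def _blocks(self, rng, sizes=(150, 150), noise=100, n_samples=40):
        mats, labels = [], []
        for b, size in enumerate(sizes):
            f = rng.normal(size=n_samples)
            mats.append(2.0 * f + rng.normal(0, 1, size=(size, n_samples)))
            labels += [b + 1] * size
        mats.append(rng.normal(size=(noise, n_samples)))
        labels += [0] * noise
        mat = np.vstack(mats)
        em = _expr(mat)
        return em, np.array(labels)

    def test_two_block_recovery(self):
        rng = np.random.default_rng(9)
        em, truth = self._blocks(rng)
        A = signed_adjacency(bicor_matrix(em), 18)
        tom = topological_overlap(A)
        ms = detect_modules(tom, em, min_size=100)
        assert ms.n_modules == 2
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, ms.labels.to_numpy()) >= 0.8

    def test_undersized_cluster_unassigned(self):
        rng = np.random.default_rng(10)
        em, _ = self._blocks(rng, sizes=(50,), noise=60)
        A = signed_adjacency(bicor_matrix(em), 18)
        ms = detect_modules(topological_overlap(A), em, min_size=100)
        assert ms.n_modules == 0

    def test_duplicated_block_merges(self):
        """Two planted blocks driven by the same latent factor merge into a
        single module (eigengene correlation ~ 1)."""
        rng = np.random.default_rng(11)
        f = rng.normal(size=30)
        block = lambda: 2.0 * f + rng.normal(0, 1, size=(120, 30))
        em = _expr(np.vstack([block(), block()]))
        A = signed_adjacency(bicor_matrix(em), 18)
        ms = detect_modules(topological_overlap(A), em, min_size=100)
        assert ms.n_modules == 1


class TestTraitCorrelation:
    def test_trait_equal_to_eigengene(self):
        rng = np.random.default_rng(12)
        eg = pd.DataFrame({"ME1": rng.normal(size=10), "ME2": rng.normal(size=10)})
        traits = pd.DataFrame({"t": eg["ME1"]})
        table = eigengene_trait_correlation(eg, traits)
        r = table.set_index("module").loc["ME1", "r"]
        assert r == pytest.approx(1.0)

    def test_nine_module_threshold(self):
        rng = np.random.default_rng(13)
        eg = pd.DataFrame(rng.normal(size=(12, 9)), columns=[f"ME{i}" for i in range(1, 10)])
        traits = pd.DataFrame({"t": rng.normal(size=12)})
        table = eigengene_trait_correlation(eg, traits)
        assert table["threshold"].iloc[0] == pytest.approx(0.05 / 9)
        assert round(table["threshold"].iloc[0], 3) == 0.006

    def test_constant_trait_rejected(self):
        eg = pd.DataFrame({"ME1": np.arange(5.0)})
        with pytest.raises(ValueError, match="constant trait"):
            eigengene_trait_correlation(eg, pd.DataFrame({"t": np.ones(5)}))


def mi_oracle(x_disc, y_disc):
    """Plug-in MI by direct summation over the joint table (nats)."""
    n = len(x_disc)
    mi = 0.0
    for a in set(x_disc):
        for b in set(y_disc):
            pab = np.mean((x_disc == a) & (y_disc == b))
            if pab > 0:
                pa, pb = np.mean(x_disc == a), np.mean(y_disc == b)
                mi += pab * np.log(pab / (pa * pb))
    return mi


class TestMutualInformation:
    def test_two_bin_hand_pair(self):
        x = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        y = np.array([2.0, 1, 4, 3, 6, 5, 8, 7])  # same halves
        em = _expr(np.vstack([x, y]))
        M = mutual_information_matrix(em, bins=2)
        xd = equal_frequency_discretize(x, 2)
        yd = equal_frequency_discretize(y, 2)
        assert M.iloc[0, 1] == pytest.approx(mi_oracle(xd, yd), abs=1e-12)
        # perfectly aligned halves: MI = log(2)
        assert M.iloc[0, 1] == pytest.approx(np.log(2), abs=1e-12)

    def test_self_information_is_log_bins(self):
        x = np.arange(16.0)
        em = _expr(np.vstack([x, x + 0.0]))
        M = mutual_information_matrix(em, bins=4)
        assert M.iloc[0, 1] == pytest.approx(np.log(4), abs=1e-12)

    def test_independent_genes_below_permutation_null(self):
        rng = np.random.default_rng(14)
        em = _expr(rng.random((20, 40)))
        M = mutual_information_matrix(em)
        observed = M.to_numpy()[np.triu_indices(20, 1)].mean()
        # permutation null: shuffle each gene independently
        null = []
        vals = em.values.to_numpy().copy()
        for _ in range(30):
            perm = np.array([rng.permutation(v) for v in vals])
            Mp = mutual_information_matrix(_expr(perm))
            null.append(Mp.to_numpy()[np.triu_indices(20, 1)].mean())
        assert observed <= np.percentile(null, 95)

    def test_constant_gene_zero_mi(self):
        x = np.arange(9.0)
        em = _expr(np.vstack([x, np.ones(9)]))
        with pytest.warns(UserWarning, match="constant"):
            M = mutual_information_matrix(em, bins=3)
        assert M.iloc[0, 1] == 0.0

    def test_self_information_maximality(self):
        rng = np.random.default_rng(15)
        em = _expr(rng.normal(size=(6, 30)))
        M = mutual_information_matrix(em, bins=5)
        x = em.values.iloc[0].to_numpy()
        xd = equal_frequency_discretize(x, 5)
        self_mi = mi_oracle(xd, xd)
        assert (M.iloc[0, 1:] <= self_mi + 1e-12).all()


def dpi_oracle(W, tol=0.0):
    """Brute-force triangle enumeration."""
    n = W.shape[0]
    keep = W > 0
    removed = np.zeros_like(keep)
    for i in range(n):
        for j in range(n):
            if i == j or W[i, j] <= 0:
                continue
            for k in range(n):
                if k in (i, j):
                    continue
                if W[i, k] > 0 and W[j, k] > 0 and W[i, j] < min(W[i, k], W[j, k]) * (1 - tol):
                    removed[i, j] = True
    return keep & ~removed


class TestDPI:
    def _mi_df(self, W):
        genes = [f"g{i}" for i in range(W.shape[0])]
        return pd.DataFrame(W, index=genes, columns=genes)

    def test_triangle_weakest_edge_removed(self):
        W = np.array([[0, 0.9, 0.1], [0.9, 0, 0.8], [0.1, 0.8, 0]], dtype=float)
        edges = aracne_dpi(self._mi_df(W))
        pairs = set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy()))
        assert pairs == {("g0", "g1"), ("g1", "g2")}

    def test_tolerance_one_removes_nothing(self):
        W = np.array([[0, 0.9, 0.1], [0.9, 0, 0.8], [0.1, 0.8, 0]], dtype=float)
        edges = aracne_dpi(self._mi_df(W), tolerance=1.0)
        assert len(edges) == 3

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(16)
        W = rng.random((6, 6))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        W[W < 0.3] = 0.0  # some absent edges
        edges = aracne_dpi(self._mi_df(W))
        keep = dpi_oracle(W)
        expected = {
            (f"g{i}", f"g{j}") for i in range(6) for j in range(i + 1, 6) if keep[i, j]
        }
        assert set(map(tuple, edges[["gene_a", "gene_b"]].to_numpy())) == expected


class TestConsensusAndHubs:
    def _consensus(self, edges):
        genes = sorted({g for e in edges for g in e[:2]})
        df = pd.DataFrame(edges, columns=["gene_a", "gene_b", "tom_weight", "mi_weight"])
        return ConsensusNetwork(genes, df)

    def test_identical_edge_sets_kept(self):
        genes = list("abcde")
        tom = pd.DataFrame(0.0, index=genes, columns=genes)
        tom.loc["a", "b"] = tom.loc["b", "a"] = 0.5
        tom.loc["c", "d"] = tom.loc["d", "c"] = 0.3
        dpi = pd.DataFrame(
            {"gene_a": ["a", "c"], "gene_b": ["b", "d"], "mi_weight": [0.2, 0.1]}
        )
        cons = consensus_edges(tom, dpi)
        assert len(cons.edges) == 2

    def test_disjoint_sets_empty(self):
        genes = list("abcd")
        tom = pd.DataFrame(0.0, index=genes, columns=genes)
        tom.loc["a", "b"] = tom.loc["b", "a"] = 0.5
        dpi = pd.DataFrame({"gene_a": ["c"], "gene_b": ["d"], "mi_weight": [0.2]})
        with pytest.warns(UserWarning, match="no edges"):
            cons = consensus_edges(tom, dpi)
        assert cons.edges.empty

    def test_hand_made_five_node_two_shared(self):
        genes = list("abcde")
        tom = pd.DataFrame(0.0, index=genes, columns=genes)
        for x, y, w in [("a", "b", 0.5), ("b", "c", 0.4), ("d", "e", 0.01)]:
            tom.loc[x, y] = tom.loc[y, x] = w
        dpi = pd.DataFrame(
            {"gene_a": ["a", "b", "d"], "gene_b": ["b", "c", "e"], "mi_weight": [0.2, 0.3, 0.4]}
        )
        cons = consensus_edges(tom, dpi, tom_edge_threshold=0.02)
        got = set(map(tuple, cons.edges[["gene_a", "gene_b"]].to_numpy()))
        assert got == {("a", "b"), ("b", "c")}  # d-e fails the TOM threshold

    def test_star_graph_single_hub(self):
        edges = [("hub", f"leaf{i}", 0.5, 0.5) for i in range(6)]
        hn = hub_network(self._consensus(edges), k=1)
        assert hn.hubs == ["hub"]
        assert hn.nodes == {"hub"} | {f"leaf{i}" for i in range(6)}
        assert len(hn.edges) == 6

    def test_tie_break_deterministic(self):
        # two nodes with equal degree at the k-th slot: weighted degree then
        # lexical id decides
        edges = [
            ("a", "x", 0.9, 0.5),
            ("b", "y", 0.1, 0.5),
            ("c", "z", 0.1, 0.5),
        ]
        hn = hub_network(self._consensus(edges), k=2)
        # all six nodes have degree 1; 'a' and 'x' share the heaviest edge,
        # and 'a' precedes 'x' lexically
        assert hn.hubs == ["a", "x"]

    def test_matches_brute_force_degree_sort(self):
        rng = np.random.default_rng(17)
        genes = [f"n{i:02d}" for i in range(30)]
        edges = []
        seen = set()
        while len(edges) < 60:
            i, j = rng.integers(0, 30, 2)
            if i == j:
                continue
            a, b = sorted((genes[i], genes[j]))
            if (a, b) in seen:
                continue
            seen.add((a, b))
            edges.append((a, b, float(rng.random()), float(rng.random())))
        cons = self._consensus(edges)
        hn = hub_network(cons, k=5)
        degree = {}
        for a, b, *_ in edges:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        top_by_degree = sorted(degree.values(), reverse=True)[:5]
        assert sorted((degree[h] for h in hn.hubs), reverse=True) == top_by_degree

    def test_empty_network_rejected(self):
        cons = ConsensusNetwork(
            ["a"], pd.DataFrame(columns=["gene_a", "gene_b", "tom_weight", "mi_weight"])
        )
        with pytest.raises(ValueError):
            hub_network(cons)
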