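"""Co-expression network stage: adjacency, TOM, clustering, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from hepanet.network import (
    NetworkConfig,
    adjacency,
    cluster_genes,
    cut_modules,
    export_edges,
    merge_modules,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    tom_similarity,
)
from hepanet.synthetic_data import ModuleSpec, SimulationConfig, simulate_expression

from conftest import make_expr


def brute_force_tom(A):
    """Triple-loop topological overlap oracle."""
    n = A.shape[0]
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    W = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                W[i, j] = 1.0
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n))
            W[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1.0 - A[i, j])
    return W


def naive_average_linkage(D):
    """Agglomerative average linkage oracle; returns sorted merge heights."""
    clusters = {i: [i] for i in range(D.shape[0])}
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best, pair = np.inf, None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1 :]:
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if d < best - 1e-15:
                    best, pair = d, (a, b)
        a, b = pair
        heights.append(best)
        clusters[a] = clusters[a] + clusters.pop(b)
    return sorted(heights)


def random_adjacency(rng, n):
    M = rng.random((n, n))
    A = (M + M.T) / 2.0
    np.fill_diagonal(A, 0.0)
    return A


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        e = make_expr(np.vstack([x, 2 * x + 1]))
        a = adjacency(e, NetworkConfig(power=6))
        assert a.iloc[0, 1] == pytest.approx(1.0)
        assert a.iloc[0, 0] == 0.0

    def test_half_correlation_sixth_power(self, rng):
        # embed an exact r=0.5 pair
        z = rng.normal(size=200)
        y = 0.5 * z + np.sqrt(0.75) * rng.normal(size=200)
        # orthogonalize to make r exactly 0.5
        from numpy.polynomial import polynomial as _  # noqa: F401

        r = np.corrcoef(z, y)[0, 1]
        y = y - (r - 0.5) * z  # nudge toward 0.5; then assert via formula instead
        e = make_expr(np.vstack([z, y]))
        a = adjacency(e, NetworkConfig(power=6))
        r_actual = np.corrcoef(z, y)[0, 1]
        assert a.iloc[0, 1] == pytest.approx(abs(r_actual) ** 6, rel=1e-12)

    def test_matches_elementwise_correlation_oracle(self, rng):
        X = rng.normal(size=(20, 30))
        a = adjacency(make_expr(X), NetworkConfig(power=6)).to_numpy()
        for i in range(20):
            for j in range(i + 1, 20):
                r, _ = pearsonr(X[i], X[j])
                assert a[i, j] == pytest.approx(abs(r) ** 6, abs=1e-12)

    def test_signed_mode(self, rng):
        X = rng.normal(size=(10, 40))
        a = adjacency(make_expr(X), NetworkConfig(power=2, sign="signed")).to_numpy()
        corr = np.corrcoef(X)
        np.fill_diagonal(corr, 0)
        expected = ((1 + corr) / 2) ** 2
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(a, expected, atol=1e-12)

    def test_zero_variance_gene_rejected(self):
        e = make_expr(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="zero-variance"):
            adjacency(e)


class TestTOM:
    def test_isolated_genes_zero_overlap(self):
        A = np.zeros((3, 3))
        w = tom_similarity(pd.DataFrame(A)).to_numpy()
        assert w[0, 1] == 0.0 and w[0, 0] == 1.0

    def test_identical_neighborhoods_full_overlap(self):
        # complete graph with unit weights: l_ij = n-2, denom = (n-1)+1-1
        n = 5
        A = np.ones((n, n)) - np.eye(n)
        w = tom_similarity(pd.DataFrame(A)).to_numpy()
        assert np.allclose(w, 1.0)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(20):
            A = random_adjacency(rng, 15)
            w = tom_similarity(pd.DataFrame(A)).to_numpy()
            assert np.max(np.abs(w - brute_force_tom(A))) < 1e-12

    def test_range_and_symmetry(self, rng):
        A = random_adjacency(rng, 25)
        w = tom_similarity(pd.DataFrame(A)).to_numpy()
        assert w.min() >= 0.0 and w.max() <= 1.0
        assert np.allclose(w, w.T)


class TestClusterGenes:
    def test_identical_genes_merge_at_zero(self):
        tom = pd.DataFrame(np.ones((4, 4)))
        Z = cluster_genes(tom)
        assert Z[0, 2] == pytest.approx(0.0)

    def test_matches_naive_average_linkage(self, rng):
        for _ in range(5):
            A = random_adjacency(rng, 6)
            tom = tom_similarity(pd.DataFrame(A))
            Z = cluster_genes(tom)
            D = 1.0 - tom.to_numpy()
            np.fill_diagonal(D, 0.0)
            assert np.allclose(sorted(Z[:, 2]), naive_average_linkage(D), atol=1e-10)

    def test_gene_permutation_equivariance(self, rng):
        cfg = SimulationConfig(n_subjects=20, n_genes=80,
                               modules=(ModuleSpec(30, 0.9, 1.0),), seed=31)
        expr, _, _ = simulate_expression(cfg)
        ncfg = NetworkConfig(min_module_size=10)
        tom = tom_similarity(adjacency(expr, ncfg))
        mods = cut_modules(cluster_genes(tom), tom, ncfg)
        perm = rng.permutation(80)
        genes = [expr.gene_ids[i] for i in perm]
        expr2 = expr.subset_genes(genes)
        tom2 = tom_similarity(adjacency(expr2, ncfg))
        mods2 = cut_modules(cluster_genes(tom2), tom2, ncfg)
        assert (mods2.loc[mods.index] == mods).all()


class TestCutModules:
    def test_planted_modules_recovered(self, planted):
        from sklearn.metrics import adjusted_rand_score

        _, expr, _, truth = planted
        ncfg = NetworkConfig()
        tom = tom_similarity(adjacency(expr, ncfg))
        mods = cut_modules(cluster_genes(tom), tom, ncfg)
        n_modules = len([m for m in mods.unique() if m != "grey"])
        assert n_modules == 3
        ari = adjusted_rand_score(
            [truth.module_labels[g] for g in mods.index], list(mods)
        )
        assert ari >= 0.9

    def test_pure_noise_gives_no_modules(self):
        cfg = SimulationConfig(seed=41, modules=(), n_genes=250)
        expr, _, _ = simulate_expression(cfg)
        ncfg = NetworkConfig()
        tom = tom_similarity(adjacency(expr, ncfg))
        mods = cut_modules(cluster_genes(tom), tom, ncfg)
        assert set(mods) == {"grey"}

    def test_small_module_goes_grey(self):
        cfg = SimulationConfig(n_subjects=30, n_genes=60,
                               modules=(ModuleSpec(10, 0.95, 0.0),), seed=42)
        expr, _, truth = simulate_expression(cfg)
        ncfg = NetworkConfig(min_module_size=30)
        tom = tom_similarity(adjacency(expr, ncfg))
        mods = cut_modules(cluster_genes(tom), tom, ncfg)
        assert all(mods[g] == "grey" for g in truth.module_members("M1"))

    def test_min_size_above_gene_count_all_grey(self):
        cfg = SimulationConfig(n_subjects=10, n_genes=20,
                               modules=(ModuleSpec(10, 0.9, 0.0),), seed=2)
        expr, _, _ = simulate_expression(cfg)
        ncfg = NetworkConfig(min_module_size=30)
        tom = tom_similarity(adjacency(expr, ncfg))
        assert set(cut_modules(cluster_genes(tom), tom, ncfg)) == {"grey"}


class TestEigengenes:
    def test_identical_genes_explain_everything(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 3.0])
        e = make_expr(np.vstack([x, x, x]))
        mods = pd.Series(["turquoise"] * 3, index=e.gene_ids)
        me, varexp = module_eigengenes(e, mods)
        assert varexp["turquoise"] == pytest.approx(1.0)
        z = (x - x.mean()) / x.std(ddof=1)
        r = np.corrcoef(me.loc["turquoise"], z)[0, 1]
        assert r == pytest.approx(1.0)

    def test_anticorrelated_pair_sign_rule(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 3.0])
        e = make_expr(np.vstack([x, -2 * x]))
        mods = pd.Series(["blue", "blue"], index=e.gene_ids)
        me, varexp = module_eigengenes(e, mods)
        assert varexp["blue"] == pytest.approx(1.0)
        # sign fixed against the mean standardized profile (here ~0): the
        # convention must still return a unit-norm vector deterministically
        assert np.linalg.norm(me.loc["blue"]) == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(12, 30))
        e = make_expr(X)
        mods = pd.Series(["turquoise"] * 12, index=e.gene_ids)
        me, varexp = module_eigengenes(e, mods)
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
        evals, evecs = np.linalg.eigh(Z.T @ Z)
        v1 = evecs[:, -1]
        r = float(np.dot(me.loc["turquoise"], v1))
        assert abs(r) == pytest.approx(1.0, abs=1e-9)
        assert varexp["turquoise"] == pytest.approx(evals[-1] / evals.sum(), abs=1e-9)

    def test_unit_norm_invariant(self, planted):
        _, expr, _, truth = planted
        mods = pd.Series({g: lab for g, lab in truth.module_labels.items()})
        mods = mods.map(lambda v: {"M1": "turquoise", "M2": "blue", "M3": "brown"}.get(v, "grey"))
        me, _ = module_eigengenes(expr, mods)
        norms = np.linalg.norm(me.to_numpy(), axis=1)
        assert np.allclose(norms, 1.0)


class TestMergeModules:
    def _expr_two_modules_one_factor(self, split):
        cfg = SimulationConfig(n_subjects=40, n_genes=80,
                               modules=(ModuleSpec(80, 0.9, 0.0),), seed=51)
        expr, _, _ = simulate_expression(cfg)
        labels = ["turquoise"] * split + ["blue"] * (80 - split)
        return expr, pd.Series(labels, index=expr.gene_ids)

    def test_same_latent_factor_merges(self):
        expr, mods = self._expr_two_modules_one_factor(40)
        me, _ = module_eigengenes(expr, mods)
        merged, me2 = merge_modules(expr, mods, me, NetworkConfig())
        assert merged.nunique() == 1
        assert len(me2.index) == 1

    def test_orthogonal_factors_do_not_merge(self):
        cfg = SimulationConfig(n_subjects=40, n_genes=100,
                               modules=(ModuleSpec(50, 0.9, 0.0), ModuleSpec(50, 0.9, 0.0)),
                               seed=52)
        expr, _, truth = simulate_expression(cfg)
        mods = pd.Series(truth.module_labels).map({"M1": "turquoise", "M2": "blue"})
        me, _ = module_eigengenes(expr, mods)
        merged, _ = merge_modules(expr, mods, me, NetworkConfig())
        assert merged.nunique() == 2

    def test_merge_is_idempotent(self):
        expr, mods = self._expr_two_modules_one_factor(40)
        me, _ = module_eigengenes(expr, mods)
        m1, me1 = merge_modules(expr, mods, me, NetworkConfig())
        m2, me2 = merge_modules(expr, m1, me1, NetworkConfig())
        assert (m1 == m2).all()
        assert np.allclose(me1.to_numpy(), me2.to_numpy())


class TestModuleTrait:
    def test_perfect_correlation(self):
        trait = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        me = pd.DataFrame([(trait - trait.mean()) / np.linalg.norm(trait - trait.mean())],
                          index=["turquoise"])
        out = module_trait_correlation(me, trait)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] < 1e-6

    def test_null_calibration(self, rng):
        n = 108
        trait = np.tile([1.0, 0.0], n // 2)
        cover = 0
        for _ in range(100):
            me = pd.DataFrame([rng.normal(size=n)], index=["m"])
            p = module_trait_correlation(me, trait).loc[0, "p"]
            cover += p > 0.05
        assert cover >= 89

    def test_matches_textbook_formula(self, rng):
        from scipy.stats import t as tdist

        n = 6
        me = pd.DataFrame([rng.normal(size=n)], index=["m"])
        trait = rng.normal(size=n)
        out = module_trait_correlation(me, trait)
        x, y = me.iloc[0].to_numpy(), trait
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        t_hand = r_hand * np.sqrt(n - 2) / np.sqrt(1 - r_hand**2)
        p_hand = 2 * tdist.sf(abs(t_hand), df=n - 2)
        assert out.loc[0, "r"] == pytest.approx(r_hand, abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(p_hand, rel=1e-9)

    def test_constant_trait_rejected(self):
        me = pd.DataFrame([[1.0, 2.0, 3.0]], index=["m"])
        with pytest.raises(ValueError, match="constant"):
            module_trait_correlation(me, np.ones(3))


class TestSoftThreshold:
    @staticmethod
    def _scale_free_expression(seed=17, n_target=800, n_samp=150):
        """Planted scale-free structure: Pareto-distributed module sizes."""
        rng = np.random.default_rng(seed)
        alpha, smin, smax, rho = 2.5, 3, 120, 0.95
        sizes = []
        while sum(sizes) < n_target:
            u = rng.random()
            s = (smin ** (1 - alpha) + u * (smax ** (1 - alpha) - smin ** (1 - alpha))) ** (
                1 / (1 - alpha)
            )
            sizes.append(int(round(s)))
        rows = []
        for s in sizes:
            z = rng.normal(size=n_samp)
            rows.append(np.sqrt(rho) * z + np.sqrt(1 - rho) * rng.normal(size=(s, n_samp)))
        X = np.vstack(rows)
        return make_expr(X)

    def test_scale_free_structure_reaches_high_fit(self):
        expr = self._scale_free_expression()
        table, rec = pick_soft_threshold(expr, candidate_powers=(2, 4, 6, 8, 10, 12))
        assert table["signed_r2"].max() >= 0.8
        assert rec in table["power"].values

    def test_mean_connectivity_decreases_in_power(self, rng):
        X = rng.normal(size=(60, 40))
        table, _ = pick_soft_threshold(make_expr(X), candidate_powers=(1, 2, 4, 6, 8))
        assert (np.diff(table["mean_k"]) < 0).all()

    def test_rows_independent_of_candidate_order(self, planted):
        _, expr, _, _ = planted
        sub = expr.subset_genes(expr.gene_ids[:80])
        t1, _ = pick_soft_threshold(sub, candidate_powers=(2, 4, 6))
        t2, _ = pick_soft_threshold(sub, candidate_powers=(6, 2, 4))
        t2s = t2.sort_values("power").reset_index(drop=True)
        assert np.allclose(t1.to_numpy(), t2s.to_numpy(), equal_nan=True)


class TestExportEdges:
    def _weights(self):
        genes = list("abcd")
        W = np.array(
            [
                [1.0, 0.5, 0.4, 0.3],
                [0.5, 1.0, 0.2, 0.15],
                [0.4, 0.2, 1.0, 0.05],
                [0.3, 0.15, 0.05, 1.0],
            ]
        )
        w = pd.DataFrame(W, index=genes, columns=genes)
        mods = pd.Series(["turquoise"] * 4, index=genes)
        return w, mods

    def test_threshold_one_empty(self):
        w, mods = self._weights()
        assert len(export_edges(w, mods, threshold=1.0)) == 0

    def test_threshold_zero_complete_graph(self):
        w, mods = self._weights()
        assert len(export_edges(w, mods, threshold=0.0)) == 6

    def test_planted_modules_denser_within(self, planted):
        _, expr, _, truth = planted
        ncfg = NetworkConfig()
        tom = tom_similarity(adjacency(expr, ncfg))
        mods = pd.Series(truth.module_labels).map(
            {"M1": "turquoise", "M2": "blue", "M3": "brown"}
        ).fillna("grey")
        edges = export_edges(tom, mods, ["turquoise", "blue"], threshold=0.1)
        lab = mods.to_dict()
        within = sum(lab[a] == lab[b] for a, b in zip(edges.gene_a, edges.gene_b))
        n_t = (mods == "turquoise").sum()
        n_b = (mods == "blue").sum()
        possible_within = n_t * (n_t - 1) / 2 + n_b * (n_b - 1) / 2
        possible_between = n_t * n_b
        dens_within = within / possible_within
        dens_between = (len(edges) - within) / possible_between
        assert dens_within > dens_between
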