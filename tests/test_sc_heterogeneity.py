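"""QC filtering, normalization, SNN clustering and proportion recovery."""

import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest

import stemcnv.sc_heterogeneity as sch
import stemcnv.synthetic_data as sd


def make_adata(counts, genes=None, obs=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[1])]
    adata = ad.AnnData(
        X=counts.astype(np.int32),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    if obs is not None:
        for k, v in obs.items():
            adata.obs[k] = v
    return adata


def ten_cell_fixture():
    """10 cells over 300 genes; 3 planted QC violations.

    cell 0: 150 expressed genes (< 200) -> low_features
    cell 1: pct_mito exactly 7.5 -> removed (strict <)
    cell 2: 250 expressed genes but 20% mito -> high_mito
    cells 3-9: clean (n_features 250, pct_mito ~1%)
    """
    n_genes = 300
    genes = [f"MT-{i}" for i in range(10)] + [f"g{i}" for i in range(n_genes - 10)]
    x = np.zeros((10, n_genes), dtype=np.int32)
    for i in range(10):
        n_feat = 150 if i == 0 else 250
        x[i, 10:10 + n_feat] = 4
    # cell 1: total mito = 7.5% of counts -> mito 81 vs non-mito 1000 -> 7.498
    x[1, :10] = 0
    x[1, 0] = 81
    x[1, 10:260] = 4  # 1000 non-mito
    # adjust to exactly 7.5%: mito m with m/(m+1000)=0.075 -> m=81.081 not integer
    x[1, 0] = 81  # 81/1081 = 7.493% -> tune non-mito to 999
    x[1, 259] = 3  # non-mito 999, 81/1080 = 7.5% exactly
    x[2, 0] = 250  # 20% of 1250
    for i in range(3, 10):
        x[i, 0] = 10  # ~1% mito
    return make_adata(x, genes=genes)


class TestQcFilter:
    def test_hand_built_fixture_exact_tally(self):
        adata = ten_cell_fixture()
        filtered, report = sch.qc_filter(adata)
        assert report["input_cells"] == 10
        assert report["removed_low_features"] == 1
        assert report["removed_high_mito"] == 2  # the 7.5% boundary cell + 20% cell
        assert report["removed_high_features"] == 0
        assert report["removed_total"] == 3
        assert filtered.n_obs == 7

    def test_boundary_semantics(self):
        adata = ten_cell_fixture()
        sch.qc_metrics(adata)
        assert adata.obs["n_features"].iloc[0] == 150
        assert adata.obs["pct_mito"].iloc[1] == pytest.approx(7.5)
        filtered, _ = sch.qc_filter(adata)
        assert adata.obs_names[1] not in filtered.obs_names  # strict < 7.5

    def test_high_feature_rule(self):
        adata = ten_cell_fixture()
        filtered, report = sch.qc_filter(adata, min_features=100, max_features=240)
        assert report["removed_high_features"] == 9
        assert filtered.n_obs == 1  # only the 150-feature cell stays

    def test_tally_consistent_with_io_counts(self):
        adata = ten_cell_fixture()
        _, report = sch.qc_filter(adata)
        assert report["input_cells"] - report["output_cells"] == report["removed_total"]

    def test_all_removed_errors(self):
        adata = ten_cell_fixture()
        with pytest.raises(ValueError, match="survive"):
            sch.qc_filter(adata, min_features=10_000)

    def test_idempotent(self):
        adata = ten_cell_fixture()
        once, _ = sch.qc_filter(adata)
        twice, rep = sch.qc_filter(once)
        assert rep["removed_total"] == 0 and twice.n_obs == once.n_obs


class TestNormalizeLog:
    def test_formula_and_zeros(self):
        x = np.zeros((1, 3), dtype=np.int32)
        x[0] = [100, 9900, 0]
        adata = make_adata(x)
        out = sch.normalize_log(adata, scale=1e4)
        assert out.X[0, 2] == 0.0
        assert out.X[0, 0] == pytest.approx(math.log(101))

    def test_library_size_invariance(self):
        x = np.array([[10, 20, 30], [20, 40, 60]], dtype=np.int32)
        out = sch.normalize_log(make_adata(x))
        assert np.allclose(out.X[0], out.X[1])

    def test_zero_library_errors(self):
        x = np.array([[1, 2], [0, 0]], dtype=np.int32)
        with pytest.raises(ValueError, match="zero library"):
            sch.normalize_log(make_adata(x))


class TestSelectHvg:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(5.0, size=(200, 50))
        x[:, 0] = 7  # constant
        adata = make_adata(x)
        hvg = sch.select_hvg(adata, n=49)
        assert "g0" not in hvg

    def test_planted_program_genes_captured(self, study):
        cfg, gm, net, truth = study
        adatas = sd.simulate_sc_counts(cfg, truth, gm)
        a = sch.normalize_log(sch.qc_filter(adatas["control"])[0])
        hvg = set(sch.select_hvg(a, n=250))
        # program genes drive between-cluster variance -> high residual variance
        counts = a.layers["counts"]
        labels = a.obs["true_cluster"].to_numpy()
        means = np.vstack([counts[labels == k].mean(axis=0)
                           for k in range(cfg.sc_n_clusters)])
        spread = means.max(axis=0) / np.maximum(means.min(axis=0), 1e-9)
        program = set(a.var_names[(spread > 4) & (means.max(axis=0) > 1)])
        assert len(program & hvg) / max(len(program), 1) >= 0.9


class TestSnnGraph:
    def test_jaccard_weights_match_brute_force(self):
        rng = np.random.default_rng(1)
        emb = rng.normal(size=(30, 3))
        k = 4
        g = sch.snn_graph(emb, k_neighbors=k, prune=0.0).toarray()
        # brute-force neighbour sets
        from scipy.spatial.distance import cdist

        d = cdist(emb, emb)
        np.fill_diagonal(d, np.inf)
        nbrs = [set(np.argsort(row, kind="stable")[:k]) for row in d]
        for i in range(30):
            for j in range(30):
                if i == j:
                    continue
                inter = len(nbrs[i] & nbrs[j])
                expect = inter / (2 * k - inter) if inter else 0.0
                assert g[i, j] == pytest.approx(expect)

    def test_example_jaccard_value(self):
        # neighbour sets {b,c} vs {a,c}: |{c}| / |{a,b,c}| = 1/3
        assert 1 / (2 * 2 - 1) == pytest.approx(1 / 3)

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            sch.snn_graph(np.zeros((5, 2)), k_neighbors=5)


class TestClusterSnn:
    def blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 0.3, size=(100, 5))
        b = rng.normal(6, 0.3, size=(80, 5))
        return np.vstack([a, b])

    def test_two_separated_blobs_recovered_exactly(self):
        emb = self.blobs()
        labels = sch.cluster_snn(emb, k_neighbors=15, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:100])) == 1
        assert len(np.unique(labels[100:])) == 1

    def test_seeded_determinism(self):
        emb = self.blobs(3)
        l1 = sch.cluster_snn(emb, seed=7)
        l2 = sch.cluster_snn(emb, seed=7)
        assert (l1 == l2).all()


class TestIntegrate:
    def line(self, seed, shift=0.0, n=150):
        rng = np.random.default_rng(seed)
        n_genes = 40
        labels = rng.integers(0, 2, n)
        mu = np.full((n, n_genes), 3.0)
        mu[labels == 0, :10] *= 8.0  # cluster-specific gene programs
        mu[labels == 1, 10:20] *= 8.0
        x = rng.poisson(mu).astype(np.int32)
        x = x + rng.poisson(shift, size=x.shape)  # per-dataset batch offset
        adata = make_adata(x, obs={"true": labels})
        adata.obs["line"] = f"line{seed}"
        return sch.normalize_log(adata)

    def test_identical_datasets_mix(self):
        from sklearn.metrics import silhouette_score

        a, b = self.line(1), self.line(1)
        b.obs["line"] = "copy"
        joint = sch.integrate([a, b], n_hvg=20, n_pcs=5, seed=0)
        s = silhouette_score(joint.obsm["X_pca"], joint.obs["line"])
        assert abs(s) < 0.05

    def test_batch_shifted_clusters_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        a, b = self.line(1), self.line(2, shift=3.0)
        joint = sch.integrate([a, b], n_hvg=20, n_pcs=5, seed=0)
        labels = sch.cluster_snn(
            joint.obsm["X_pca"], k_neighbors=15, resolution=0.3, seed=0
        )
        assert adjusted_rand_score(joint.obs["true"], labels) >= 0.9

    def test_single_dataset_errors(self):
        with pytest.raises(ValueError, match="2 datasets"):
            sch.integrate([self.line(1)])


class TestClusterProportions:
    def test_single_cluster_is_one(self):
        df = sch.cluster_proportions([0, 0, 0], ["a", "a", "a"])
        assert df["fraction"].tolist() == [1.0]

    def test_simple_fractions(self):
        labels = [0] * 80 + [1] * 20
        df = sch.cluster_proportions(labels, ["s"] * 100)
        assert df.set_index("cluster")["fraction"].tolist() == [0.8, 0.2]

    def test_rows_sum_to_one_and_diff_columns(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, 500)
        origin = np.where(rng.random(500) < 0.5, "case", "control")
        df = sch.cluster_proportions(labels, origin)
        sums = df.groupby("sample")["fraction"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)
        assert {"fraction_diff", "z", "p"} <= set(df.columns)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="cells"):
            sch.cluster_proportions([], [])


class TestClusterMarkers:
    def test_planted_program_gene_is_marker(self, study):
        cfg, gm, net, truth = study
        adatas = sd.simulate_sc_counts(cfg, truth, gm)
        a = sch.normalize_log(sch.qc_filter(adatas["control"])[0])
        labels = a.obs["true_cluster"].to_numpy()
        markers = sch.cluster_markers(a, labels)
        counts = a.layers["counts"]
        for k in range(cfg.sc_n_clusters):
            means_in = counts[labels == k].mean(axis=0)
            means_out = counts[labels != k].mean(axis=0)
            top = a.var_names[np.argmax(means_in / np.maximum(means_out, 1e-9))]
            hits = set(markers[markers["cluster"] == k]["gene"])
            assert top in hits

    def test_label_permutation_yields_few_markers(self, study):
        cfg, gm, net, truth = study
        adatas = sd.simulate_sc_counts(cfg, truth, gm)
        a = sch.normalize_log(sch.qc_filter(adatas["control"])[0])
        rng = np.random.default_rng(0)
        labels = rng.permutation(a.obs["true_cluster"].to_numpy())
        markers = sch.cluster_markers(a, labels)
        assert len(markers) <= 0.01 * a.n_vars * cfg.sc_n_clusters

    def test_tiny_cluster_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        a = sch.normalize_log(make_adata(rng.poisson(5, size=(20, 30)) + 1))
        labels = np.zeros(20, dtype=int)
        labels[:2] = 1
        with pytest.warns(UserWarning, match="markers skipped"):
            sch.cluster_markers(a, labels)
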