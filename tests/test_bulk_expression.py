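"""RLE normalization, the NB Wald test, VST closed form, sample distances."""

import math

import numpy as np
import pandas as pd
import pytest

import stemcnv.bulk_expression as be
import stemcnv.synthetic_data as sd


def frame(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


class TestPrefilter:
    def test_strict_greater_than_boundary(self):
        counts = frame([[5, 5], [6, 0], [2, 3]])
        kept = be.prefilter_genes(counts, min_reads=5, min_samples=1)
        assert list(kept.index) == ["g1"]  # a single 6 passes, max-5 gene fails

    def test_all_removed_errors(self):
        with pytest.raises(ValueError, match="review"):
            be.prefilter_genes(frame([[1, 1]]), min_reads=5)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            be.prefilter_genes(pd.DataFrame())


class TestRleSizeFactors:
    def test_identical_columns_unit_factors(self):
        counts = frame([[10, 10], [3, 3], [7, 7]])
        assert np.allclose(be.rle_size_factors(counts), 1.0)

    def test_hand_computed_two_by_two(self):
        # geomeans (8, 18); ratios col0 (0.5, 0.5) col1 (2, 2) -> medians
        counts = frame([[4, 16], [9, 36]])
        sf = be.rle_size_factors(counts)
        assert sf.tolist() == pytest.approx([0.5, 2.0])

    def test_column_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = frame(rng.integers(1, 100, size=(50, 4)))
        sf = be.rle_size_factors(counts)
        scaled = counts.copy()
        scaled["s2"] = counts["s2"] * 3
        sf2 = be.rle_size_factors(scaled)
        # geomeans rescale too, so equivariance holds on factor ratios
        assert sf2["s2"] / sf2["s0"] == pytest.approx(3 * sf["s2"] / sf["s0"])

    def test_no_all_positive_gene_errors(self):
        with pytest.raises(ValueError, match="all-positive"):
            be.rle_size_factors(frame([[0, 5], [5, 0]]))


class TestNbWaldTest:
    def test_group_size_validation(self):
        counts = frame(np.ones((5, 3), dtype=int) * 10)
        groups = pd.Series(["control", "control", "case"], index=counts.columns)
        with pytest.raises(ValueError, match="2 samples"):
            be.nb_wald_test(counts, groups)

    def test_all_zero_gene_untested(self):
        rng = np.random.default_rng(1)
        arr = rng.poisson(50, size=(20, 8))
        arr[3] = 0
        counts = frame(arr)
        groups = pd.Series(["control"] * 4 + ["case"] * 4, index=counts.columns)
        res = be.nb_wald_test(counts, groups)
        assert not res["tested"].iloc[3]
        assert np.isnan(res["p"].iloc[3])
        assert res["tested"].drop(res.index[3]).all()

    def test_recovers_dosage_on_high_count_low_noise_data(self):
        # near-noiseless planted fold change recovered within +-0.05
        rng = np.random.default_rng(2)
        n_genes, lfc = 100, math.log2(1.5)
        base = rng.lognormal(9.0, 0.3, n_genes)
        mu = np.tile(base[:, None], (1, 12)).astype(float)
        mu[:10, 6:] *= 2.0**lfc  # planted genes; the rest anchor the RLE medians
        counts = frame(rng.poisson(mu))
        groups = pd.Series(["control"] * 6 + ["case"] * 6, index=counts.columns)
        res = be.nb_wald_test(counts, groups)
        assert res["log2fc"].iloc[:10].mean() == pytest.approx(lfc, abs=0.05)
        assert res["log2fc"].iloc[10:].abs().mean() < 0.05

    def test_q_values_monotone_in_p(self):
        rng = np.random.default_rng(3)
        counts = frame(rng.poisson(30, size=(300, 8)))
        groups = pd.Series(["control"] * 4 + ["case"] * 4, index=counts.columns)
        res = be.nb_wald_test(counts, groups).dropna().sort_values("p")
        q = res["q"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()
        assert ((q >= 0) & (q <= 1)).all()


class TestClassifyDeg:
    def records(self):
        return pd.DataFrame(
            {
                "log2fc": [2.0, -0.9, -1.5, 1.2],
                "p": [0.001, 0.0005, 0.01, 0.2],
                "q": [0.01, 0.001, 0.03, 0.4],
            },
            index=list("abcd"),
        )

    def test_fdr_rule(self):
        out = be.classify_deg(self.records())
        assert out.loc["a", "direction"] == "up"
        assert out.loc["b", "direction"] == "ns"  # |lfc| below threshold
        assert out.loc["c", "direction"] == "down"
        assert out.loc["d", "direction"] == "ns"  # q above cutoff

    def test_raw_p_preset(self):
        out = be.classify_deg(self.records(), use_raw_p=True, p_thresh=0.055)
        assert out.loc["c", "direction"] == "down"
        assert out.loc["d", "direction"] == "ns"

    def test_planted_partition_recovery(self):
        rng = np.random.default_rng(4)
        n = 300
        lfc = np.zeros(n)
        lfc[:50], lfc[50:100] = 1.5, -1.5
        base = rng.lognormal(6, 0.5, n)
        mu = np.tile(base[:, None], (1, 12)).astype(float)
        mu[:, 6:] *= 2.0**lfc[:, None]
        counts = frame(sd._nb_draw(rng, mu, 0.02))
        groups = pd.Series(["control"] * 6 + ["case"] * 6, index=counts.columns)
        out = be.classify_deg(be.nb_wald_test(counts, groups))
        called_up = set(out.index[out["direction"] == "up"])
        called_down = set(out.index[out["direction"] == "down"])
        true_up = set(out.index[:50])
        true_down = set(out.index[50:100])
        precision = len((called_up & true_up) | (called_down & true_down)) / max(
            len(called_up | called_down), 1
        )
        assert precision >= 0.95
        assert len(called_up & true_up) / 50 >= 0.8


class TestVst:
    def test_zero_maps_to_zero(self):
        assert be.vst(frame([[0, 0], [10, 10]]), dispersion=0.5).iloc[0].tolist() == [0, 0]

    def test_closed_form_alpha_one(self):
        counts = frame([[1, 1], [5, 5]])
        v = be.vst(counts, dispersion=1.0)
        # (2/sqrt(1)) * asinh(sqrt(1*1)) = 2 ln(1 + sqrt 2)
        assert v.iloc[0, 0] == pytest.approx(2 * math.log(1 + math.sqrt(2)), abs=1e-9)

    def test_small_alpha_limit_is_sqrt(self):
        counts = frame([[4, 4], [9, 9]])
        v = be.vst(counts, dispersion=1e-6)
        assert v.iloc[0, 0] == pytest.approx(2 * math.sqrt(4), abs=1e-3)
        assert v.iloc[1, 0] == pytest.approx(2 * math.sqrt(9), abs=1e-3)

    def test_monotone(self):
        x = frame(np.arange(20).reshape(10, 2))
        v = be.vst(x, dispersion=0.3,
                   size_factors=pd.Series([1.0, 1.0], index=x.columns))
        assert (np.diff(v.to_numpy(), axis=0) > 0).all()

    def test_nonpositive_dispersion_errors(self):
        with pytest.raises(ValueError, match="dispersion"):
            be.vst(frame([[1, 2], [3, 4]]), dispersion=0.0)


class TestSampleDistances:
    def make_vst(self, n_samples=6, seed=0):
        rng = np.random.default_rng(seed)
        return frame(rng.normal(5, 1, size=(100, n_samples)))

    def test_duplicate_sample_distance_zero(self):
        v = self.make_vst()
        v["dup"] = v["s0"]
        d = be.sample_distances(v)
        assert d.distances.loc["s0", "dup"] == 0.0
        assert np.allclose(d.distances, d.distances.T)
        assert np.allclose(np.diag(d.distances), 0.0)

    def test_sample_permutation_invariance(self):
        v = self.make_vst()
        d1 = be.sample_distances(v).distances
        perm = list(reversed(v.columns))
        d2 = be.sample_distances(v[perm]).distances
        assert np.allclose(d1.loc[perm, perm], d2)

    def test_separated_groups_split_at_top(self):
        rng = np.random.default_rng(5)
        v = frame(rng.normal(5, 0.5, size=(200, 8)))
        v.iloc[:, 4:] += 4.0  # well-separated second group
        d = be.sample_distances(v)
        left, right = be.dendrogram_top_split(d.linkage, v.columns)
        assert {frozenset(left), frozenset(right)} == {
            frozenset(v.columns[:4]), frozenset(v.columns[4:]),
        }

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError, match="3 samples"):
            be.sample_distances(self.make_vst(n_samples=2))
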