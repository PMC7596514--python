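"""Filter rules, the containment merge rule, and the consensus oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stemcnv.cnv_consensus import (
    CnvCall,
    PlatformRules,
    annotate_event,
    build_consensus,
    filter_calls,
    pair_compare,
    same_event,
)
from tests.conftest import tiny_gene_model


def call(chrom="chr1", start=0, end=1000, type="gain", platform="aCGH",
         sample="s1", **kw):
    return CnvCall(chrom, start, end, type, platform, sample, **kw)


class TestFilterCalls:
    def test_snp_size_cutoff(self):
        c = call(platform="SNP", start=0, end=4_000, n_markers=6)
        assert filter_calls([c]) == []

    def test_snp_marker_minimum(self):
        c = call(platform="SNP", start=0, end=20_000, n_markers=4)
        assert filter_calls([c]) == []
        ok = call(platform="SNP", start=0, end=20_000, n_markers=5)
        assert filter_calls([ok]) == [ok]

    def test_wes_probability_and_ratio(self):
        bad_prob = call(platform="WES", call_prob=0.85, log2ratio=0.6)
        bad_ratio = call(platform="WES", call_prob=0.95, log2ratio=0.3)
        ok = call(platform="WES", call_prob=0.95, log2ratio=0.6)
        assert filter_calls([bad_prob, bad_ratio, ok]) == [ok]

    def test_cytoscan_thresholds(self):
        small = call(platform="CytoScanHD", start=0, end=100_000, n_markers=30)
        few = call(platform="CytoScanHD", start=0, end=200_000, n_markers=25)
        ok = call(platform="CytoScanHD", start=0, end=200_000, n_markers=26)
        assert filter_calls([small, few, ok]) == [ok]

    @pytest.mark.parametrize("chrom", ["chrX", "chrY"])
    def test_sex_chromosomes_removed_all_platforms(self, chrom):
        calls = [call(chrom=chrom, platform=p, n_markers=100, call_prob=0.99,
                      log2ratio=0.6)
                 for p in ("aCGH", "SNP", "WES")]
        assert filter_calls(calls) == []

    def test_centromere_exclusion(self):
        import pandas as pd

        cen = pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [1500]})
        rules = PlatformRules(centromeres=cen)
        spanning = call(start=400, end=2000)
        clear = call(start=2000, end=3000)
        assert filter_calls([spanning, clear], rules) == [clear]

    def test_empty_input(self):
        assert filter_calls([]) == []

    def test_unknown_platform_errors(self):
        with pytest.raises(ValueError, match="platform"):
            filter_calls([call(platform="nanopore")])

    def test_missing_metric_named_in_error(self):
        with pytest.raises(ValueError, match="n_markers"):
            filter_calls([call(platform="SNP", start=0, end=20_000)])

    def test_idempotent(self):
        calls = [
            call(platform="SNP", start=0, end=20_000, n_markers=10),
            call(platform="WES", call_prob=0.95, log2ratio=0.7),
            call(platform="aCGH"),
        ]
        once = filter_calls(calls)
        assert filter_calls(once) == once


class TestSameEvent:
    def test_containment_true(self):
        a = call(start=30_000_000, end=31_500_000)
        b = call(start=30_200_000, end=31_400_000)
        assert same_event(a, b) and same_event(b, a)

    def test_partial_overlap_false(self):
        a = call(start=30_000_000, end=31_000_000)
        b = call(start=30_500_000, end=31_500_000)
        assert not same_event(a, b)
        # the reciprocal-overlap fallback accepts the same pair
        assert same_event(a, b, min_reciprocal_overlap=0.5)

    def test_type_mismatch(self):
        a = call(type="gain")
        b = call(type="loss")
        assert not same_event(a, b)

    def test_chromosome_mismatch(self):
        assert not same_event(call(chrom="chr1"), call(chrom="chr2"))


class TestPairCompare:
    def test_empty_control_all_acquired(self):
        case = [call(sample="case1")]
        parts = pair_compare([], case)
        assert parts["acquired"] == case and not parts["shared"]

    def test_identical_call_shared(self):
        ctrl = [call(sample="ctrl1")]
        case = [call(sample="case1")]
        parts = pair_compare(ctrl, case)
        assert parts["shared"] == case and not parts["acquired"] and not parts["lost"]

    def test_mixed_samples_error(self):
        with pytest.raises(ValueError, match="mixes samples"):
            pair_compare([call(sample="a"), call(sample="b")], [])

    def test_unmatched_case_call_always_acquired(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            ctrl = _random_calls(rng, 5, sample="c")
            case = _random_calls(rng, 5, sample="k")
            parts = pair_compare(ctrl, case)
            for cs in case:
                has_partner = any(
                    cs.platform == ct.platform and same_event(cs, ct) for ct in ctrl
                )
                if not has_partner:
                    assert cs in parts["acquired"]
            assert len(parts["acquired"]) + len(parts["shared"]) == len(case)


def _random_calls(rng, n, sample="s"):
    out = []
    for i in range(n):
        start = int(rng.integers(0, 50)) * 1000
        length = int(rng.integers(1, 20)) * 1000
        out.append(
            call(
                chrom=f"chr{int(rng.integers(1, 3))}",
                start=start,
                end=start + length,
                type="gain" if rng.random() < 0.7 else "loss",
                platform=("aCGH", "SNP", "WES")[int(rng.integers(0, 3))],
                sample=sample,
                n_markers=50,
                call_prob=0.99,
                log2ratio=0.8,
            )
        )
    return out


def _oracle_components(calls):
    """Brute-force transitive closure of same_event by repeated merging."""
    groups = [{i} for i in range(len(calls))]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if any(
                    same_event(calls[i], calls[j])
                    for i in groups[a]
                    for j in groups[b]
                ):
                    groups[a] |= groups[b]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(g) for g in groups}


class TestBuildConsensus:
    def test_nested_chain_union_intersection(self):
        calls = [
            call(start=29_900_000, end=31_600_000, platform="aCGH"),
            call(start=30_100_000, end=31_500_000, platform="SNP"),
            call(start=30_000_000, end=31_450_000, platform="WES"),
        ]
        events = build_consensus(calls)
        assert len(events) == 1
        e = events[0]
        assert e.support == {"aCGH", "SNP", "WES"}
        assert e.outer == (29_900_000, 31_600_000)
        assert e.core == (30_100_000, 31_450_000)
        assert e.significant

    def test_single_platform_not_significant(self):
        events = build_consensus([call(platform="SNP")])
        assert len(events) == 1 and not events[0].significant

    def test_min_support_configurable(self):
        calls = [call(platform="aCGH"), call(platform="SNP")]
        assert build_consensus(calls, min_support=2)[0].significant
        assert not build_consensus(calls, min_support=3)[0].significant

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            calls = _random_calls(rng, int(rng.integers(1, 21)))
            events = build_consensus(calls)
            pos = {id(c): i for i, c in enumerate(calls)}
            got = {
                frozenset(pos[id(c)] for c in e.member_calls) for e in events
            }
            assert got == _oracle_components(calls)

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=30, deadline=None)
    def test_row_order_invariance(self, r):
        rng = np.random.default_rng(r.randint(0, 10**6))
        calls = _random_calls(rng, 12)
        base = build_consensus(calls)
        shuffled = list(calls)
        r.shuffle(shuffled)
        perm = build_consensus(shuffled)
        key = lambda e: (e.chrom, e.outer, e.core, e.type, frozenset(e.support))
        assert sorted(map(key, base)) == sorted(map(key, perm))


class TestAnnotateEvent:
    def test_gene_overlap_including_single_bp(self):
        gm = tiny_gene_model()
        e = build_consensus([call(chrom="chr1", start=199, end=400)])[0]
        annotate_event(e, gm)
        assert e.genes == ["A"]  # 1 bp overlap with A[100,200); B starts at 500

    def test_no_overlap_empty(self):
        gm = tiny_gene_model()
        e = build_consensus([call(chrom="chr1", start=200, end=499)])[0]
        annotate_event(e, gm)
        assert e.genes == []

    def test_candidate_region_and_genes(self):
        gm = tiny_gene_model()
        e = build_consensus([call(chrom="chr1", start=0, end=1000)])[0]
        annotate_event(e, gm, candidate_region=("chr1", 100, 600),
                       candidate_genes=["A", "C"])
        assert e.in_core_region and e.candidate_hits == ["A"]

    def test_missing_chromosome_warns(self):
        gm = tiny_gene_model()
        e = build_consensus([call(chrom="chr9", start=0, end=1000)])[0]
        with pytest.warns(UserWarning, match="chr9"):
            annotate_event(e, gm)
        assert e.genes == []


def test_noiseless_study_yields_one_significant_event_per_case(study):
    """Planted-truth recovery: exactly the planted region, in every case."""
    import stemcnv.synthetic_data as sd
    from stemcnv.cnv_consensus import calls_from_frame

    cfg, gm, net, truth = study
    cfg0 = sd.SyntheticStudyConfig(seed=9, breakpoint_jitter=0, fp_per_sample=0)
    frame = sd.simulate_platform_calls(cfg0, truth)
    calls = filter_calls(calls_from_frame(frame))
    for i in range(cfg0.n_samples_per_group):
        case = [c for c in calls if c.sample == f"case{i + 1}"]
        parts = pair_compare([], case)
        events = build_consensus(parts["acquired"])
        sig = [e for e in events if e.significant]
        assert len(sig) == 1
        assert sig[0].outer == (cfg0.cnv_start, cfg0.cnv_end)
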