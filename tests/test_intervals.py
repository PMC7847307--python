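"""Peak catalog construction and region-set definitions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gsckit as g
from gsckit.intervals import Interval, PeakCall, SamplePeaks, merge_intervals


def mk_sample(sid, triples, state=None):
    return SamplePeaks(
        sid,
        [PeakCall(Interval("chr1", s, e), q=q, signal=sig) for (s, e, q, sig) in triples],
        state=state,
    )


intervals_strategy = st.lists(
    st.tuples(st.integers(0, 500), st.integers(1, 60)).map(
        lambda t: Interval("chr1", t[0], t[0] + t[1])
    ),
    min_size=1,
    max_size=30,
)


class TestBuildCatalog:
    def test_single_sample_disjoint_calls(self):
        s = mk_sample("a", [(10, 20, 0.01, 2.0), (30, 40, 0.02, 3.0)])
        cat = g.build_catalog([s])
        assert [(r.start, r.end) for r in cat.regions] == [(10, 20), (30, 40)]
        assert cat.occupancy(0.05).all()
        assert cat.signal.tolist() == [[2.0, 3.0]]

    def test_overlapping_calls_merge_across_samples(self):
        a = mk_sample("a", [(10, 20, 0.01, 2.0)])
        b = mk_sample("b", [(15, 25, 0.02, 5.0)])
        cat = g.build_catalog([a, b])
        assert [(r.start, r.end) for r in cat.regions] == [(10, 25)]
        assert cat.occupancy(0.05).all()

    def test_disjoint_union_count(self):
        # 3 + 2 + 1 unique disjoint calls across three samples -> 6 regions
        a = mk_sample("a", [(0, 10, 0.01, 1), (20, 30, 0.01, 1), (40, 50, 0.01, 1)])
        b = mk_sample("b", [(60, 70, 0.01, 1), (80, 90, 0.01, 1)])
        c = mk_sample("c", [(100, 110, 0.01, 1)])
        cat = g.build_catalog([a, b, c])
        # brute-force union of base pairs
        covered = set()
        for s in (a, b, c):
            for call in s.calls:
                covered |= set(range(call.interval.start, call.interval.end))
        n_blocks = sum(
            1 for x in covered if x - 1 not in covered
        )
        assert cat.n_regions == 6 == n_blocks

    def test_min_q_max_signal_within_region(self):
        s = mk_sample("a", [(10, 20, 0.04, 2.0), (18, 30, 0.01, 7.0)])
        cat = g.build_catalog([s])
        assert cat.n_regions == 1
        assert cat.qmat[0, 0] == 0.01
        assert cat.signal[0, 0] == 7.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            g.build_catalog([])

    @given(intervals_strategy)
    def test_merge_idempotent_and_disjoint(self, ivs):
        merged = merge_intervals(ivs)
        assert merge_intervals(merged) == merged
        for r1, r2 in zip(merged, merged[1:]):
            assert r1.end <= r2.start

    @given(intervals_strategy, intervals_strategy)
    def test_occupancy_monotone_in_q(self, ivs_a, ivs_b):
        a = SamplePeaks("a", [PeakCall(iv, q=0.01 + 0.9 * (i % 7) / 7, signal=1.0) for i, iv in enumerate(ivs_a)])
        b = SamplePeaks("b", [PeakCall(iv, q=0.02 + 0.9 * (i % 5) / 5, signal=1.0) for i, iv in enumerate(ivs_b)])
        cat = g.build_catalog([a, b])
        occ1, occ2 = cat.occupancy(0.05), cat.occupancy(0.2)
        assert not (occ1 & ~occ2).any()


class TestExclusiveRegions:
    def _toy(self):
        # region 0: q=0.01 in S1 sample, absent elsewhere
        # region 1: q=0.01 in S1 and q=0.10 in an S2 sample (lenient filter fails)
        s1 = mk_sample("a", [(0, 10, 0.01, 1), (20, 30, 0.01, 1)], state="S1")
        s2 = mk_sample("b", [(20, 30, 0.10, 1)], state="S2")
        s3 = mk_sample("c", [(0, 10, 0.30, 1)], state="S2")
        return g.build_catalog([s1, s2, s3])

    def test_rule_application(self):
        ex = g.exclusive_regions(self._toy())
        assert ex["S1"] == {0}
        assert ex["S2"] == set()

    def test_zero_thresholds_empty(self):
        ex = g.exclusive_regions(self._toy(), q_strict=0.0, q_lenient=0.0)
        assert all(len(v) == 0 for v in ex.values())

    def test_monotone_in_lenient_threshold(self):
        cat = self._toy()
        sizes = [
            sum(len(v) for v in g.exclusive_regions(cat, q_lenient=ql).values())
            for ql in (0.05, 0.2, 0.5)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_unlabeled_sample_errors(self):
        s1 = mk_sample("a", [(0, 10, 0.01, 1)], state="S1")
        s2 = mk_sample("b", [(0, 10, 0.01, 1)])
        with pytest.raises(ValueError, match="unlabeled"):
            g.exclusive_regions(g.build_catalog([s1, s2]))

    def test_recovers_planted_blocks(self, catalog, bulk_cohort):
        _, truth = bulk_cohort
        ex = g.exclusive_regions(catalog)
        for state, planted in truth.exclusive_regions.items():
            recall = len(ex[state] & planted) / len(planted)
            assert recall >= 0.95


class TestSharedRegions:
    def test_majority_threshold_boundary(self):
        # 27 samples; region 0 present in 15, region 1 in 14
        samples = []
        for i in range(27):
            calls = []
            if i < 15:
                calls.append((0, 10, 0.01, 1))
            if i < 14:
                calls.append((20, 30, 0.01, 1))
            if not calls:
                calls.append((40, 50, 0.01, 1))
            samples.append(mk_sample(f"s{i}", calls))
        cat = g.build_catalog(samples)
        shared = g.shared_regions(cat, min_samples=15)
        assert 0 in shared and 1 not in shared

    def test_min_one_returns_all_called(self, catalog):
        shared = g.shared_regions(catalog, min_samples=1)
        assert shared == set(np.flatnonzero(catalog.occupancy(0.05).any(axis=0)).tolist())

    def test_matches_brute_force_on_toy(self):
        samples = [
            mk_sample("a", [(0, 10, 0.01, 1), (20, 30, 0.01, 1)]),
            mk_sample("b", [(20, 30, 0.01, 1), (40, 50, 0.01, 1)]),
            mk_sample("c", [(20, 30, 0.01, 1), (60, 70, 0.2, 1)]),
        ]
        cat = g.build_catalog(samples)
        occ = cat.occupancy(0.05)
        expect = {j for j in range(cat.n_regions) if occ[:, j].sum() >= 2}
        assert g.shared_regions(cat, min_samples=2) == expect


class TestDifferentialStatePeaks:
    def test_identical_signal_empty(self):
        samples = [
            mk_sample(f"s{i}", [(0, 10, 0.01, 3.0), (20, 30, 0.01, 5.0)], state="A" if i < 3 else "B")
            for i in range(6)
        ]
        de = g.differential_state_peaks(g.build_catalog(samples))
        assert all(len(v) == 0 for v in de.values())

    def test_planted_fourfold_recovered(self, rng):
        # 9 state-A vs 18 rest; 50 planted regions with 4x signal in A
        n_regions, n_a, n_b = 200, 9, 18
        base = rng.lognormal(1.0, 0.2, size=(n_a + n_b, n_regions))
        base[:n_a, :50] *= 4.0
        samples = []
        for i in range(n_a + n_b):
            calls = [(j * 100, j * 100 + 50, 0.01, float(base[i, j])) for j in range(n_regions)]
            samples.append(mk_sample(f"s{i}", calls, state="A" if i < n_a else "B"))
        de = g.differential_state_peaks(g.build_catalog(samples))
        recall = len(de["A"] & set(range(50))) / 50
        assert recall >= 0.9
        # false positives among unplanted regions stay rare
        assert len(de["A"] - set(range(50))) <= 10

    def test_single_sample_state_errors(self):
        samples = [mk_sample("a", [(0, 10, 0.01, 1)], state="A")] + [
            mk_sample(f"b{i}", [(0, 10, 0.01, 1)], state="B") for i in range(3)
        ]
        with pytest.raises(ValueError, match="'A'"):
            g.differential_state_peaks(g.build_catalog(samples))


class TestPromoters:
    @pytest.mark.parametrize(
        "tss,strand,expect",
        [
            (10_000, "+", (8_000, 10_500)),
            (10_000, "-", (9_500, 12_000)),
            (100, "+", (0, 600)),
        ],
    )
    def test_window_definition(self, tss, strand, expect):
        ann = [g.GeneAnnotation("g1", "chr1", tss, strand)]
        iv = g.promoter_regions(ann)["g1"]
        assert (iv.start, iv.end) == expect

    def test_promoter_signature_overlap(self, catalog):
        r0 = catalog.regions[0]
        ann = [g.GeneAnnotation("g1", r0.chrom, r0.start + 10, "+")]
        sig = g.promoter_signature("sig", catalog, ann)
        assert 0 in sig.regions


class TestMapSampleToCatalog:
    def test_identical_sample_reproduces_row(self, catalog, bulk_cohort):
        samples, _ = bulk_cohort
        vec = g.map_sample_to_catalog(samples[0], catalog)
        np.testing.assert_allclose(vec, catalog.signal[0])

    def test_no_overlap_zero_vector(self, catalog):
        s = mk_sample("q", [(0, 10, 0.01, 5.0)])
        s.calls = [PeakCall(Interval("chrZ", 0, 10), 0.01, 5.0)]
        assert not g.map_sample_to_catalog(s, catalog).any()

    def test_partial_overlap_toy(self):
        ref = mk_sample("r", [(100, 200, 0.01, 1.0), (300, 400, 0.01, 1.0)])
        cat = g.build_catalog([ref])
        q = mk_sample("q", [(150, 250, 0.01, 9.0), (390, 450, 0.01, 4.0)])
        vec = g.map_sample_to_catalog(q, cat)
        assert vec.tolist() == [9.0, 4.0]
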