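"""Genome binning, the density-fold statistic, exact testing, hotspot calls
and gene association."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varscape import (
    BinCounts,
    CallSet,
    FeatureSet,
    HotspotCall,
    associate_genes,
    call_hotspots,
    count_per_bin,
    fisher_exact_greater,
    fold_ratio,
    make_bins,
)

from conftest import make_variant
from oracles import exact_fisher_greater


class TestMakeBins:
    def test_partial_terminal_bin(self):
        bins = make_bins({"chrA": 2_500_000})
        assert bins.bins == (("chrA", 0, 1_000_000), ("chrA", 1_000_000, 2_000_000),
                             ("chrA", 2_000_000, 2_500_000))

    def test_single_exact_bin(self):
        assert make_bins({"chrA": 1_000_000}).bins == (("chrA", 0, 1_000_000),)

    @pytest.mark.parametrize("sizes", [
        {"chrA": 999_999}, {"chrA": 3_141_592, "chrB": 1}, {"chrA": 10_000_000},
    ])
    def test_bins_tile_exactly(self, sizes):
        bins = make_bins(sizes)
        assert sum(e - s for _, s, e in bins.bins) == sum(sizes.values())
        # no gaps or overlaps within each chromosome
        by_chrom = {}
        for chrom, s, e in bins.bins:
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            assert ivs[0][0] == 0 and ivs[-1][1] == sizes[chrom]
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 == s2

    def test_bad_width(self):
        with pytest.raises(ValueError):
            make_bins({"chrA": 100}, width=0)


class TestCountPerBin:
    def test_one_based_boundary(self):
        bins = make_bins({"chr1": 2_000_000})
        cs = CallSet("t", 1, [make_variant(pos=1_000_000), make_variant(pos=1_000_001)])
        counts = count_per_bin(cs, bins)
        # pos 1,000,000 (1-based) has 0-based coordinate 999,999: first bin
        assert counts.tolist() == [1, 1]

    def test_each_variant_counted_once_and_shuffle_invariant(self):
        bins = make_bins({"chr1": 3_000_000}, width=1_000_000)
        variants = [make_variant(pos=p) for p in
                    random.Random(1).sample(range(1, 3_000_001), 500)]
        counts = count_per_bin(CallSet("t", 1, variants), bins)
        assert counts.sum() == 500
        random.Random(2).shuffle(variants)
        assert count_per_bin(CallSet("t", 1, variants), bins).tolist() == counts.tolist()

    def test_unknown_chromosome_warns(self):
        bins = make_bins({"chr1": 1_000_000})
        cs = CallSet("t", 1, [make_variant(chrom="chrX", pos=5)])
        with pytest.warns(UserWarning):
            counts = count_per_bin(cs, bins)
        assert counts.sum() == 0


class TestFoldRatio:
    @pytest.mark.parametrize("args,expected", [
        ((30, 1000, 10, 1000), 3.0),
        ((10, 1000, 10, 1000), 1.0),
        ((5, 1000, 0, 1000), math.inf),
        ((0, 1000, 10, 1000), 0.0),
    ])
    def test_examples(self, args, expected):
        assert fold_ratio(*args) == expected

    def test_zero_totals_error(self):
        with pytest.raises(ValueError):
            fold_ratio(1, 0, 1, 10)

    @given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 20))
    @settings(max_examples=100)
    def test_scale_invariant(self, na, nb, k):
        total_a, total_b = 1000, 2000
        f1 = fold_ratio(na, total_a, nb, total_b)
        f2 = fold_ratio(na * k, total_a * k, nb * k, total_b * k)
        assert f1 == pytest.approx(f2, rel=1e-12)


class TestFisherExactGreater:
    def test_a_zero_gives_one(self):
        assert fisher_exact_greater(0, 10, 5, 5) == 1.0

    def test_extreme_table_closed_form(self):
        assert fisher_exact_greater(10, 0, 0, 10) == pytest.approx(
            1 / math.comb(20, 10), rel=1e-12)

    def test_large_margin_matches_enumeration(self):
        assert fisher_exact_greater(10, 990, 10, 990) == pytest.approx(
            exact_fisher_greater(10, 990, 10, 990), abs=1e-12)

    @pytest.mark.parametrize("table", [
        (3, 7, 2, 8), (1, 1, 1, 1), (12, 3, 4, 9), (0, 5, 5, 0), (7, 0, 3, 4),
    ])
    def test_small_tables_match_enumeration(self, table):
        assert fisher_exact_greater(*table) == pytest.approx(
            exact_fisher_greater(*table), abs=1e-14)

    def test_monotone_in_a_with_margins_fixed(self):
        # enrichment can only get more significant as a grows
        r1, r2, m = 30, 40, 25
        ps = [fisher_exact_greater(a, r1 - a, m - a, r2 - (m - a))
              for a in range(max(0, m - r2), min(r1, m) + 1)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_greater(-1, 5, 5, 5)


def _counts(per_a, per_b, width=1_000_000):
    bins = make_bins({"chr1": width * len(per_a)}, width=width)
    a = np.array(per_a)
    b = np.array(per_b)
    return BinCounts(bins=bins, per_bin_a=a, total_a=int(a.sum()),
                     per_bin_b=b, total_b=int(b.sum()))


class TestCallHotspots:
    def test_fold_boundary_inclusive(self):
        # bin 0: fold exactly 1.5 with overwhelming significance
        counts = _counts([450, 550], [300, 700])
        calls = call_hotspots(counts)
        assert calls[0].fold == pytest.approx(1.5)
        assert calls[0].p <= 0.05 and calls[0].is_hotspot

    def test_high_fold_weak_p_not_hotspot(self):
        counts = _counts([3, 997], [1, 999])
        calls = call_hotspots(counts)
        assert calls[0].fold == pytest.approx(3.0)
        assert calls[0].p > 0.05 and not calls[0].is_hotspot

    def test_sub_threshold_fold_not_hotspot_despite_tiny_p(self):
        counts = _counts([14_000, 86_000], [10_000, 90_000])
        calls = call_hotspots(counts)
        assert calls[0].fold == pytest.approx(1.4)
        assert calls[0].p < 1e-10 and not calls[0].is_hotspot

    def test_flag_consistent_with_thresholds(self):
        rng = np.random.default_rng(0)
        counts = _counts(rng.poisson(200, 20).tolist(), rng.poisson(200, 20).tolist())
        for h in call_hotspots(counts, fold_min=1.2, p_max=0.1):
            assert h.is_hotspot == (h.fold >= 1.2 and h.p <= 0.1)

    def test_fdr_column_never_gates_status(self):
        counts = _counts([450, 550], [300, 700])
        with_f = call_hotspots(counts, with_fdr=True)
        without = call_hotspots(counts, with_fdr=False)
        assert [h.is_hotspot for h in with_f] == [h.is_hotspot for h in without]


class TestAssociateGenes:
    HOT = HotspotCall(chrom="chr1", start=1_000_000, end=2_000_000, n_cohort=1,
                      n_reference=1, fold=2.0, p=0.001, is_hotspot=True)

    def _genes(self, *intervals):
        return FeatureSet(name="genes",
                          intervals=[("chr1", s, e) for s, e in intervals],
                          names=[f"G{i}" for i in range(len(intervals))])

    def test_gene_inside_hotspot(self):
        got = associate_genes([self.HOT], self._genes((1_200_000, 1_300_000)))
        assert got[("chr1", 1_000_000, 2_000_000)] == ["G0"]

    def test_gene_abutting_flank_boundary_is_associated(self):
        # flank window starts at 995,000; a gene ending exactly there touches
        got = associate_genes([self.HOT], self._genes((990_000, 995_000)), flank=5_000)
        assert got[("chr1", 1_000_000, 2_000_000)] == ["G0"]

    def test_gene_just_beyond_flank_not_associated(self):
        got = associate_genes([self.HOT], self._genes((990_000, 994_999)), flank=5_000)
        assert got[("chr1", 1_000_000, 2_000_000)] == []

    def test_downstream_flank_symmetric(self):
        got = associate_genes([self.HOT], self._genes((2_005_000, 2_010_000)), flank=5_000)
        assert got[("chr1", 1_000_000, 2_000_000)] == ["G0"]

    def test_non_hotspot_bins_not_reported(self):
        cold = HotspotCall(chrom="chr1", start=0, end=1_000_000, n_cohort=1,
                           n_reference=1, fold=1.0, p=0.9, is_hotspot=False)
        got = associate_genes([cold], self._genes((100, 200)))
        assert got == {}


class TestEndToEndRecovery:
    def test_planted_bins_recovered_small(self):
        from varscape import SyntheticConfig, generate

        cfg = SyntheticConfig(seed=42, chrom_sizes={"chr1": 5_000_000},
                              background_rate=5e-4, n_samples_cohort=4,
                              n_samples_reference=4, planted_bins=((2, 3.0),),
                              n_sv=5, n_rp_intervals=20, n_genes=10)
        ds = generate(cfg)
        counts = BinCounts.from_callsets(ds.cohort, ds.reference, cfg.bins())
        hot = [i for i, h in enumerate(call_hotspots(counts)) if h.is_hotspot]
        assert hot == [2]
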