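"""Classification, MRR, hard filtering, and format round-trips."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varscape import (
    CallSet,
    FilterThresholds,
    SampleCall,
    VarClass,
    classify_variant,
    compute_mrr,
    filter_callset,
    read_bed,
    read_chrom_sizes,
    read_vcf,
    write_bed,
    write_vcf,
)
from varscape.core_io import MalformedInputError, MultiAllelicError, write_chrom_sizes

from conftest import make_variant


class TestClassifyVariant:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            ("A", "G", VarClass.SNP),
            ("A", "AT", VarClass.INSERTION),
            ("ACGTACGT", "A", VarClass.DELETION),
            ("A", "A" + "T" * 50, VarClass.INSERTION),  # 50 bp: still an indel
            ("A" + "T" * 51, "A", VarClass.SV_DEL),     # 51 bp: SV territory
            ("A", "A" + "T" * 51, VarClass.SV_DUP),
        ],
    )
    def test_sequence_resolved(self, ref, alt, expected):
        assert classify_variant(ref, alt) is expected

    @pytest.mark.parametrize("sv_type,expected", [
        ("DEL", VarClass.SV_DEL), ("DUP", VarClass.SV_DUP), ("INV", VarClass.SV_INV),
    ])
    def test_sv_typed(self, sv_type, expected):
        assert classify_variant(None, None, sv_type=sv_type, sv_len=5000) is expected

    def test_multi_allelic_rejected(self):
        with pytest.raises(MultiAllelicError, match="split required"):
            classify_variant("A", "G,T")

    def test_every_biallelic_record_gets_exactly_one_class(self):
        # partition: varying sizes on both sides of the indel/SV boundary
        for size in [1, 2, 10, 50, 51, 200]:
            ins = classify_variant("A", "A" + "C" * size)
            dele = classify_variant("A" + "C" * size, "A")
            assert ins in (VarClass.INSERTION, VarClass.SV_DUP)
            assert dele in (VarClass.DELETION, VarClass.SV_DEL)
            assert (size <= 50) == (ins is VarClass.INSERTION)
            assert (size <= 50) == (dele is VarClass.DELETION)


class TestComputeMRR:
    @pytest.mark.parametrize("ad,expected", [
        ((10, 30), 0.25), ((20, 20), 0.5), ((0, 40), 0.0),
    ])
    def test_examples(self, ad, expected):
        assert compute_mrr(ad) == pytest.approx(expected)

    def test_zero_depth_undefined(self):
        with pytest.raises(ValueError):
            compute_mrr((0, 0))

    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    @settings(max_examples=200)
    def test_symmetric_and_bounded(self, r, a):
        if r + a == 0:
            return
        v = compute_mrr((r, a))
        assert v == compute_mrr((a, r))
        assert 0.0 <= v <= 0.5


def _single_call_variant(qual, dp, gq, ad, gt=(0, 1)):
    return make_variant(qual=qual, calls=[SampleCall(gt=gt, dp=dp, gq=gq, ad=ad)])


class TestFilterCallset:
    def _run_one(self, variant, th=FilterThresholds()):
        cs = CallSet(label="t", n_samples=1, variants=[variant])
        return len(filter_callset(cs, th))

    def test_boundary_values_pass(self):
        # qual=30, dp=20, gq=20, mrr=8/40=0.2: every criterion at its boundary
        v = _single_call_variant(qual=30.0, dp=20, gq=20, ad=(8, 32))
        assert self._run_one(v) == 1

    @pytest.mark.parametrize("kwargs", [
        dict(qual=29.9, dp=20, gq=20, ad=(8, 32)),   # qual just below
        dict(qual=30.0, dp=19, gq=20, ad=(8, 32)),   # depth just below
        dict(qual=30.0, dp=20, gq=19, ad=(8, 32)),   # GQ just below
        dict(qual=30.0, dp=20, gq=20, ad=(7, 33)),   # MRR 0.175 just below
    ])
    def test_just_below_boundary_removed(self, kwargs):
        assert self._run_one(_single_call_variant(**kwargs)) == 0

    def test_hom_alt_calls_skip_mrr(self):
        v = _single_call_variant(qual=50, dp=30, gq=60, ad=(0, 30), gt=(1, 1))
        assert self._run_one(v) == 1

    def test_missing_genotypes_excluded(self):
        v = make_variant(qual=50, calls=[SampleCall(gt=None, dp=30, gq=60, ad=(15, 15))])
        assert self._run_one(v) == 0

    def test_one_passing_sample_suffices(self):
        v = make_variant(qual=50, calls=[
            SampleCall(gt=(0, 1), dp=5, gq=10, ad=(2, 3)),
            SampleCall(gt=(0, 1), dp=30, gq=60, ad=(14, 16)),
        ])
        cs = CallSet(label="t", n_samples=2, variants=[v])
        assert len(filter_callset(cs)) == 1

    def test_subset_and_idempotent(self, small_dataset):
        cs = small_dataset.cohort
        once = filter_callset(cs)
        twice = filter_callset(once)
        assert set(v.key for v in once.variants) <= cs.keys
        assert [v.key for v in twice.variants] == [v.key for v in once.variants]


class TestVcfRoundTrip:
    def test_keys_and_bytes_stable(self, small_dataset, tmp_path):
        p1 = write_vcf(small_dataset.cohort, tmp_path / "a.vcf",
                       chrom_sizes=small_dataset.chrom_sizes)
        cs = read_vcf(p1)
        assert cs.keys == small_dataset.cohort.keys
        assert cs.n_samples == small_dataset.cohort.n_samples
        p2 = write_vcf(cs, tmp_path / "b.vcf", chrom_sizes=small_dataset.chrom_sizes)
        assert p1.read_bytes() == p2.read_bytes()

    def test_qual_and_fields_preserved(self, small_dataset, tmp_path):
        p = write_vcf(small_dataset.cohort, tmp_path / "c.vcf",
                      chrom_sizes=small_dataset.chrom_sizes)
        cs = read_vcf(p)
        for orig, back in zip(small_dataset.cohort.variants[:50], cs.variants[:50]):
            assert (orig.chrom, orig.pos, orig.ref, orig.alt) == \
                   (back.chrom, back.pos, back.ref, back.alt)
            assert back.qual == pytest.approx(orig.qual, abs=1e-3)
            assert [c.gt for c in back.per_sample] == [c.gt for c in orig.per_sample]
            assert [c.ad for c in back.per_sample] == [c.ad for c in orig.per_sample]

    def test_empty_vcf_body(self, tmp_path):
        empty = CallSet(label="empty", n_samples=1, variants=[])
        p = write_vcf(empty, tmp_path / "e.vcf", chrom_sizes={"chr1": 1000})
        assert len(read_vcf(p)) == 0

    def test_sv_vcf_round_trip(self, small_dataset, tmp_path):
        p = write_vcf(small_dataset.cohort_sv, tmp_path / "sv.vcf",
                      chrom_sizes=small_dataset.chrom_sizes)
        back = read_vcf(p)
        for orig, got in zip(small_dataset.cohort_sv.variants, back.variants):
            assert got.var_class is orig.var_class
            assert got.sv_end == orig.sv_end


class TestBed:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t1000000\n")
        fs = read_bed(p)
        assert fs.intervals == [("chr1", 0, 1_000_000)]

    def test_round_trip_identity(self, tmp_path):
        content = "chr1\t0\t100\nchr1\t500\t900\nchr2\t10\t20\n"
        p = tmp_path / "in.bed"
        p.write_text(content)
        out = write_bed(read_bed(p), tmp_path / "out.bed")
        assert out.read_text() == content

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\tx\t200\n")
        with pytest.raises(MalformedInputError, match="bad.bed:2"):
            read_bed(p)

    def test_unknown_chromosome_warns_and_skips(self, tmp_path):
        p = tmp_path / "b.bed"
        p.write_text("chr1\t0\t100\nchrUn\t0\t50\n")
        with pytest.warns(UserWarning, match="chrUn"):
            fs = read_bed(p, chrom_sizes={"chr1": 1000})
        assert len(fs) == 1

    def test_scored_track(self, tmp_path):
        p = tmp_path / "rp.bed"
        p.write_text("chr1\t0\t100\t.\t0.75\nchr1\t200\t300\t.\t0.1\n")
        fs = read_bed(p, score_column=True)
        assert fs.scores == [0.75, 0.1]

    def test_chrom_sizes_round_trip(self, tmp_path):
        sizes = {"chr1": 1_000_000, "chr2": 500}
        p = write_chrom_sizes(sizes, tmp_path / "sizes.tsv")
        assert read_chrom_sizes(p) == sizes
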