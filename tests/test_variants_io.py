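from __future__ import annotations

import pytest

from conftest import CONTEXT_SEQ, write_vcf_text
from resa.errors import ReferenceMismatchError, VcfFormatError
from resa.variants_io import (
    BASES,
    COMPLEMENT,
    SBS96_LABELS,
    CellCall,
    ExonIntervals,
    VariantKey,
    load_site_list,
    parse_cell_vcf,
    sbs96_class_from_context,
    trinucleotide_context,
    write_cell_vcf,
)


class TestVariantKey:
    def test_rejects_non_snv_and_identity(self):
        with pytest.raises(ValueError):
            VariantKey("chr1", 100, "CT", "C")
        with pytest.raises(ValueError):
            VariantKey("chr1", 100, "C", "C")

    def test_value_equality_and_ordering(self):
        a = VariantKey("chr1", 100, "C", "T")
        assert a == VariantKey("chr1", 100, "C", "T")
        assert a != VariantKey("chr1", 100, "C", "A")
        assert a < VariantKey("chr1", 101, "A", "G")


class TestCellCall:
    def test_ad_sum_must_not_exceed_dp(self):
        key = VariantKey("chr1", 1, "C", "T")
        with pytest.raises(ValueError):
            CellCall(key, "c1", "G", dp=5, ad_ref=4, ad_alt=3, qual=10.0)

    def test_pl_min_normalized_on_ingest(self):
        key = VariantKey("chr1", 1, "C", "T")
        call = CellCall(key, "c1", "G", dp=10, ad_ref=6, ad_alt=4, qual=10.0, pl=(94, 10, 130))
        assert call.pl == (84, 0, 120)

    def test_vaf_undefined_at_zero_depth(self):
        key = VariantKey("chr1", 1, "C", "T")
        call = CellCall(key, "c1", "G", dp=0, ad_ref=0, ad_alt=0, qual=1.0)
        assert call.vaf is None


class TestParseCellVcf:
    def test_standard_row_maps_all_fields(self, tmp_path):
        p = write_vcf_text(
            tmp_path / "a.vcf",
            ["chr1\t100\t.\tC\tT\t84.3\tPASS\tDP=10;FS=1.2;QD=8.4\tGT:AD:PL\t0/1:6,4:84,0,120"],
        )
        (call,) = parse_cell_vcf(p, "G", "cellX")
        assert call.key == VariantKey("chr1", 100, "C", "T")
        assert (call.dp, call.ad_ref, call.ad_alt) == (10, 6, 4)
        assert call.vaf == pytest.approx(0.4)
        assert call.qual == pytest.approx(84.3, abs=1e-3)
        assert call.pl == (84, 0, 120)
        assert call.fs == pytest.approx(1.2, abs=1e-3)
        assert call.qd == pytest.approx(8.4, abs=1e-3)
        assert call.pass_flag and call.cell_id == "cellX" and call.caller == "G"

    def test_multiallelic_split_conserves_alt_alleles(self, tmp_path):
        p = write_vcf_text(
            tmp_path / "m.vcf",
            ["chr1\t200\t.\tA\tT,G\t50\tPASS\tDP=12\tGT:AD:PL\t1/2:5,3,2:30,0,40,50,60,70"],
        )
        calls = parse_cell_vcf(p, "G", "c")
        assert len(calls) == 2
        by_alt = {c.key.alt: c for c in calls}
        assert by_alt["T"].ad_alt == 3 and by_alt["G"].ad_alt == 2
        assert all(c.dp == 12 for c in calls)
        # PL triples extracted per alt from the standard genotype ordering
        assert by_alt["T"].pl == (30, 0, 40)
        assert by_alt["G"].pl == (0, 20, 40)  # (30,50,70) min-normalized

    def test_indel_skipped(self, tmp_path):
        p = write_vcf_text(
            tmp_path / "i.vcf",
            [
                "chr1\t300\t.\tCT\tC\t50\tPASS\tDP=8\tGT:AD:PL\t0/1:5,3:30,0,40",
                "chr1\t400\t.\tC\tT\t50\tPASS\tDP=8\tGT:AD:PL\t0/1:5,3:30,0,40",
            ],
        )
        calls = parse_cell_vcf(p, "G", "c")
        assert [c.key.pos for c in calls] == [400]

    def test_secondary_caller_drops_non_pass_rows(self, tmp_path):
        rows = [
            "chr1\t100\t.\tC\tT\t50\tPASS\tDP=8\tGT:AD:PL\t0/1:5,3:30,0,40",
            "chr1\t200\t.\tA\tG\t50\tq_fail\tDP=8\tGT:AD:PL\t0/1:5,3:30,0,40",
        ]
        p = write_vcf_text(tmp_path / "s.vcf", rows)
        s_calls = parse_cell_vcf(p, "S", "c")
        assert [c.key.pos for c in s_calls] == [100]
        g_calls = parse_cell_vcf(p, "G", "c")
        assert [(c.key.pos, c.pass_flag) for c in g_calls] == [(100, True), (200, False)]

    def test_missing_dp_is_fatal_and_names_the_field(self, tmp_path):
        p = write_vcf_text(
            tmp_path / "nodp.vcf",
            ["chr1\t100\t.\tC\tT\t50\tPASS\tFS=1.0\tGT:AD:PL\t0/1:5,3:30,0,40"],
        )
        with pytest.raises(VcfFormatError, match="DP"):
            parse_cell_vcf(p, "G", "c")

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            parse_cell_vcf(tmp_path / "nope.vcf", "G", "c")


class TestRoundTrip:
    def test_write_then_parse_preserves_all_modeled_fields(self, tmp_path):
        calls = [
            CellCall(VariantKey("chr1", 50, "C", "T"), "c1", "G", dp=10, ad_ref=6, ad_alt=4,
                     qual=84.25, pl=(84, 0, 120), fs=1.5, qd=8.25, pass_flag=True),
            CellCall(VariantKey("chr1", 90, "A", "G"), "c1", "G", dp=4, ad_ref=2, ad_alt=2,
                     qual=10.0, pl=(12, 0, 40), fs=None, qd=None, pass_flag=False),
        ]
        path = tmp_path / "rt.vcf"
        write_cell_vcf(calls, path, {"chr1": 1000})
        back = parse_cell_vcf(path, "G", "c1")
        assert len(back) == len(calls)
        for a, b in zip(sorted(calls, key=lambda c: c.key), back):
            assert a.key == b.key
            assert (a.dp, a.ad_ref, a.ad_alt, a.pl, a.pass_flag) == (
                b.dp, b.ad_ref, b.ad_alt, b.pl, b.pass_flag)
            assert b.qual == pytest.approx(a.qual, abs=1e-3)
            for x, y in ((a.fs, b.fs), (a.qd, b.qd)):
                assert (x is None) == (y is None)
                if x is not None:
                    assert y == pytest.approx(x, abs=1e-3)


class TestSiteList:
    def test_tsv_duplicates_collapse(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("chr1\t100\nchr1\t100\n")
        sl = load_site_list(p, "editing")
        assert len(sl) == 1
        assert VariantKey("chr1", 100, "C", "T") in sl  # site-level match
        assert VariantKey("chr1", 101, "C", "T") not in sl

    def test_vcf_snv_only_ingest(self, tmp_path):
        rows = [
            "chr1\t100\t.\tC\tT\t50\tPASS\tDP=8\tGT:AD:PL\t0/1:5,3:30,0,40",
            "chr1\t200\t.\tA\tG\t50\tPASS\tDP=8\tGT:AD:PL\t0/1:5,3:30,0,40",
            "chr1\t300\t.\tG\tC\t50\tPASS\tDP=8\tGT:AD:PL\t0/1:5,3:30,0,40",
            "chr1\t400\t.\tCT\tC\t50\tPASS\tDP=8\tGT:AD:PL\t0/1:5,3:30,0,40",
        ]
        p = write_vcf_text(tmp_path / "g.vcf", rows)
        sl = load_site_list(p, "germline_population")
        assert len(sl) == 3
        assert VariantKey("chr1", 100, "C", "T") in sl
        assert VariantKey("chr1", 100, "C", "G") not in sl  # allele-level match

    def test_missing_path_fatal_and_empty_ok(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_site_list(tmp_path / "nope.tsv", "editing")
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert len(load_site_list(p, "editing")) == 0

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tpos\nchr1\t100\nchr1\toops\n")
        with pytest.raises(VcfFormatError, match="line 3"):
            load_site_list(p, "editing")


class TestTrinucleotideContext:
    def test_pyrimidine_reference_direct(self, context_fasta):
        ctx, cls = trinucleotide_context(VariantKey("chr1", 3, "C", "A"), context_fasta)
        assert ctx == "ACA"
        assert cls == 0 and SBS96_LABELS[cls] == "A[C>A]A"

    def test_purine_reference_reverse_complements(self, context_fasta):
        # G>T in context AGT folds to A[C>A]T
        ctx, cls = trinucleotide_context(VariantKey("chr1", 5, "G", "T"), context_fasta)
        assert ctx == "AGT"
        assert SBS96_LABELS[cls] == "A[C>A]T"

    def test_reference_mismatch_is_fatal(self, context_fasta):
        with pytest.raises(ReferenceMismatchError):
            trinucleotide_context(VariantKey("chr1", 3, "T", "A"), context_fasta)

    def test_n_context_is_undefined(self, context_fasta):
        assert CONTEXT_SEQ[10] == "N"
        _, cls = trinucleotide_context(VariantKey("chr1", 10, CONTEXT_SEQ[9], "C"), context_fasta)
        assert cls is None

    def test_strand_collapse_over_all_contexts(self):
        """Classifying a substitution on either strand gives the same class."""
        for ref in BASES:
            for alt in BASES:
                if alt == ref:
                    continue
                for five in BASES:
                    for three in BASES:
                        direct = sbs96_class_from_context(ref, alt, five + ref + three)
                        flipped = sbs96_class_from_context(
                            COMPLEMENT[ref],
                            COMPLEMENT[alt],
                            COMPLEMENT[three] + COMPLEMENT[ref] + COMPLEMENT[five],
                        )
                        assert direct == flipped


class TestExonIntervals:
    def test_merge_and_halfopen_membership(self, tmp_path):
        bed = tmp_path / "e.bed"
        bed.write_text("chr1\t10\t20\nchr1\t15\t30\nchr2\t0\t5\n")
        ivs = ExonIntervals.from_bed(bed)
        assert ivs.n_intervals == 2
        assert ivs.total_bases == 25
        assert ivs.contains("chr1", 11)  # 1-based: first covered base
        assert ivs.contains("chr1", 30) and not ivs.contains("chr1", 31)
        assert not ivs.contains("chr1", 10)
        assert not ivs.contains("chr3", 1)
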