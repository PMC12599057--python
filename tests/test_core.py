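"""Domain types, coordinate conversions, and format round-trips."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pansv_atlas import io as pio
from pansv_atlas.core import GenomicInterval, SVRecord, interval_overlap

VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=A01,length=1000000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="x">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="x">
##INFO=<ID=END,Number=1,Type=Integer,Description="x">
##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="x">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=DR,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=DV,Number=1,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tacc1
"""


def _write_vcf(tmp_path, lines):
    p = tmp_path / "test.vcf"
    p.write_text(VCF_HEADER + "".join(line + "\n" for line in lines))
    return str(p)


class TestGenomicInterval:
    def test_invariants(self):
        iv = GenomicInterval("A01", 100, 200)
        assert iv.length == 100
        with pytest.raises(ValueError):
            GenomicInterval("A01", 200, 200)
        with pytest.raises(ValueError):
            GenomicInterval("A01", -1, 10)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 10)

    def test_half_open_overlap(self):
        a = GenomicInterval("A01", 100, 200)
        assert a.overlaps(GenomicInterval("A01", 199, 300))
        assert not a.overlaps(GenomicInterval("A01", 200, 300))
        assert not a.overlaps(GenomicInterval("C01", 100, 200))


class TestReadSvVcf:
    def test_coordinate_conversion(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            ["A01\t101\ts1\tN\t<DEL>\t60\tPASS\tSVTYPE=DEL;END=200;PRECISE\tGT:GQ:DR:DV\t1/1:60:0:20"],
        )
        (rec,) = pio.read_sv_vcf(path)
        assert rec.interval == GenomicInterval("A01", 100, 200)
        assert rec.length == 100
        assert rec.sv_type == "DEL"

    def test_imprecise_flag(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            ["A01\t101\ts1\tN\t<DEL>\t60\tPASS\tSVTYPE=DEL;END=200;IMPRECISE\tGT:GQ:DR:DV\t1/1:60:0:20"],
        )
        (rec,) = pio.read_sv_vcf(path)
        assert rec.precise is False

    def test_af_fallback_from_read_counts(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            ["A01\t101\ts1\tN\t<DEL>\t60\tPASS\tSVTYPE=DEL;END=200;PRECISE\tGT:GQ:DR:DV\t1/1:60:2:18"],
        )
        (rec,) = pio.read_sv_vcf(path)
        assert rec.allele_frequency == pytest.approx(18 / 20)

    def test_af_absent_when_no_reads(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            ["A01\t101\ts1\tN\t<DEL>\t60\tPASS\tSVTYPE=DEL;END=200\tGT:GQ:DR:DV\t./.:0:0:0"],
        )
        (rec,) = pio.read_sv_vcf(path)
        assert rec.allele_frequency is None
        assert rec.genotype == "missing"

    def test_unknown_svtype_skipped_with_warning(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            [
                "A01\t101\ts1\tN\t<DUP>\t60\tPASS\tSVTYPE=DUP;END=200\tGT:GQ:DR:DV\t1/1:60:0:20",
                "A01\t301\ts2\tN\t<DEL>\t60\tPASS\tSVTYPE=DEL;END=400\tGT:GQ:DR:DV\t1/1:60:0:20",
            ],
        )
        with pytest.warns(UserWarning, match="skipped 1"):
            recs = pio.read_sv_vcf(path)
        assert len(recs) == 1

    def test_malformed_record_names_line(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            ["A01\t101\ts1\tN\t<DEL>\t60\tPASS\tSVTYPE=DEL\tGT:GQ:DR:DV\t1/1:60:0:20"],
        )
        with pytest.raises(ValueError, match="line 13"):
            pio.read_sv_vcf(path)

    def test_ins_span_is_one_bp(self, tmp_path):
        path = _write_vcf(
            tmp_path,
            ["A01\t101\ts1\tN\tNACGT\t60\tPASS\tSVTYPE=INS;SVLEN=4;END=101;PRECISE\tGT:GQ:DR:DV\t1/1:60:0:20"],
        )
        (rec,) = pio.read_sv_vcf(path)
        assert rec.interval == GenomicInterval("A01", 100, 101)
        assert rec.alt_sequence == "ACGT"
        assert rec.length == 4


class TestVcfRoundTrip:
    def test_roundtrip_preserves_all_fields(self, small_cohort, tmp_path):
        acc = small_cohort.accessions[0]
        original = small_cohort.callsets[acc]["A"]
        path = tmp_path / "rt.vcf"
        pio.write_sv_vcf(original, str(path), acc, small_cohort.panel.chrom_lengths)
        back = pio.read_sv_vcf(str(path))
        assert len(back) == len(original)
        for a, b in zip(original, back):
            assert a.interval == b.interval
            assert (a.sv_type, a.length, a.filter_status) == (
                b.sv_type,
                b.length,
                b.filter_status,
            )
            assert (a.precise, a.genotype, a.gq, a.dr, a.dv) == (
                b.precise,
                b.genotype,
                b.gq,
                b.dr,
                b.dv,
            )
            assert a.qual == pytest.approx(b.qual, rel=1e-6)
            assert (a.alt_sequence or "") == (b.alt_sequence or "")
            if a.allele_frequency is None:
                assert b.allele_frequency is None
            else:
                assert a.allele_frequency == pytest.approx(
                    b.allele_frequency, rel=1e-5
                )


class TestReadGeneModels:
    GFF = (
        "##gff-version 3\n"
        "A01\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
        "A01\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=m1;Parent=g1\n"
        "A01\tsrc\tCDS\t1101\t1300\t.\t+\t0\tID=c1;Parent=m1\n"
        "A01\tsrc\tCDS\t1501\t1800\t.\t+\t0\tID=c2;Parent=m1\n"
    )

    def test_gene_coordinates_and_grouping(self, tmp_path):
        p = tmp_path / "t.gff3"
        p.write_text(self.GFF)
        (gene,) = pio.read_gene_models(str(p))
        assert gene.interval == GenomicInterval("A01", 1000, 2000)
        assert len(gene.cds) == 2
        assert gene.cds[0] == GenomicInterval("A01", 1100, 1300)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("##gff-version 3\n")
        assert pio.read_gene_models(str(p)) == []

    def test_orphan_cds_attached_to_singleton(self, tmp_path):
        p = tmp_path / "orphan.gff3"
        p.write_text(
            "##gff-version 3\n"
            "A01\tsrc\tCDS\t501\t700\t.\t+\t0\tID=cx;Parent=ghost\n"
        )
        with pytest.warns(UserWarning, match="synthetic singleton"):
            genes = pio.read_gene_models(str(p))
        assert len(genes) == 1
        assert genes[0].gene_id.startswith("orphan:")
        assert genes[0].cds[0] == GenomicInterval("A01", 500, 700)


class TestReadCoverageBedgraph:
    def test_uniform_depth(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("".join(f"A01\t{i * 1000}\t{(i + 1) * 1000}\t40\n" for i in range(10)))
        track = pio.read_coverage_bedgraph(str(p), 1000)
        cb = track.bins["A01"]
        assert len(cb.depths) == 10
        assert np.allclose(cb.depths, 40.0)

    def test_length_weighted_mean(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("A01\t0\t500\t20\nA01\t500\t1000\t60\n")
        track = pio.read_coverage_bedgraph(str(p), 1000)
        assert track.bins["A01"].depths[0] == pytest.approx(40.0)

    def test_trailing_partial_bin_keeps_true_width(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("A01\t0\t1000\t10\nA01\t1000\t1400\t30\n")
        track = pio.read_coverage_bedgraph(str(p), 1000)
        cb = track.bins["A01"]
        assert cb.widths[-1] == 400
        assert cb.depths[-1] == pytest.approx(30.0)

    def test_unsorted_or_overlapping_raises(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("A01\t5000\t6000\t10\nA01\t0\t1000\t10\n")
        with pytest.raises(ValueError, match="overlapping or unsorted"):
            pio.read_coverage_bedgraph(str(p), 1000)
        p.write_text("A01\t0\t1000\t10\nA01\t500\t1500\t10\n")
        with pytest.raises(ValueError, match="overlapping or unsorted"):
            pio.read_coverage_bedgraph(str(p), 1000)


class TestIntervalOverlap:
    def test_boundary_semantics(self):
        a = [GenomicInterval("A01", 100, 200)]
        assert interval_overlap(a, [GenomicInterval("A01", 199, 300)]) == [(0, 0)]
        assert interval_overlap(a, [GenomicInterval("A01", 200, 300)]) == []
        assert interval_overlap(a, [GenomicInterval("C01", 100, 200)]) == []

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["A01", "C01"]),
                st.integers(0, 400),
                st.integers(1, 80),
            ),
            max_size=60,
        ),
        st.lists(
            st.tuples(
                st.sampled_from(["A01", "C01"]),
                st.integers(0, 400),
                st.integers(1, 80),
            ),
            max_size=60,
        ),
    )
    def test_agrees_with_brute_force(self, raw_a, raw_b):
        a = [GenomicInterval(c, s, s + l) for c, s, l in raw_a]
        b = [GenomicInterval(c, s, s + l) for c, s, l in raw_b]
        expected = sorted(
            (i, j)
            for i, ia in enumerate(a)
            for j, ib in enumerate(b)
            if ia.chrom == ib.chrom and ia.start < ib.end and ib.start < ia.end
        )
        assert interval_overlap(a, b) == expected


class TestSVRecordInvariants:
    def test_ins_sequence_length_must_match(self):
        with pytest.raises(ValueError):
            SVRecord(
                interval=GenomicInterval("A01", 10, 11),
                sv_type="INS",
                length=5,
                accession_id="x",
                alt_sequence="ACGT",
            )

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            SVRecord(
                interval=GenomicInterval("A01", 10, 11),
                sv_type="DUP",
                length=5,
                accession_id="x",
            )
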