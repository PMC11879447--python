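import gzip
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdnascan.genome_io import (
    AnnotationTrack,
    BedParseError,
    FastaParseError,
    GenomicInterval,
    complement_track,
    intersect_bp,
    merge_intervals,
    read_bed,
    read_fasta,
    read_gff_genes,
    reciprocal_overlap_filter,
    total_bp,
    write_bed,
    write_fasta,
)
from hdnascan.genome_io import SequenceRecord


def _track(pairs, chrom="chr1", name="t"):
    return AnnotationTrack(name, [GenomicInterval(chrom, s, e) for s, e in pairs])


def _bitmap_bp(track, size=10_000):
    cov = np.zeros(size, dtype=bool)
    for iv in track.intervals:
        cov[iv.start : iv.end] = True
    return int(cov.sum())


class TestGenomicInterval:
    def test_rejects_inverted_and_empty(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_length(self):
        assert len(GenomicInterval("chr1", 10, 20)) == 10


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">chr1\nACGT\n")
        recs = read_fasta(p)
        assert len(recs) == 1 and recs[0].id == "chr1" and recs[0].seq == "ACGT"

    def test_two_records_in_order(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">b\nAC\n>a\nGT\n")
        assert [r.id for r in read_fasta(p)] == ["b", "a"]

    def test_round_trip_preserves_case(self, tmp_path, random_seq):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 5000).lower()[:2500] + random_seq(rng, 2500)
        p = tmp_path / "g.fa"
        write_fasta([SequenceRecord("chrX", seq)], p)
        back = read_fasta(p)
        assert back[0].seq == seq

    def test_gzip(self, tmp_path):
        p = tmp_path / "a.fa.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">c\nACGTN\n")
        assert read_fasta(p)[0].seq == "ACGTN"

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGT\n>c\nAC\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_fasta(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.fa"
        p.write_text("")
        assert read_fasta(p) == []


class TestBed:
    def test_basic_interval(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\n")
        t = read_bed(p)
        assert t.intervals == [GenomicInterval("chr1", 10, 20)]
        assert not t.consolidated

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    def test_metadata_columns_retained(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t5\tpeak1\t100\t+\t0.004\n")
        t = read_bed(p)
        assert t.metadata[0] == ("peak1", "100", "+", "0.004")
        assert float(t.metadata[0][3]) == 0.004

    @pytest.mark.parametrize(
        "line,msg",
        [("chr1\t20\t10\n", "start >= end"), ("chr1\tx\t10\n", "non-integer")],
    )
    def test_parse_errors_name_line(self, tmp_path, line, msg):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t5\n" + line)
        with pytest.raises(BedParseError, match=f"line 2.*{msg}"):
            read_bed(p)

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        for seed in range(3):
            starts = np.sort(rng.integers(0, 9000, size=50))
            t = _track([(int(s), int(s) + int(rng.integers(1, 100))) for s in starts])
            p = tmp_path / f"r{seed}.bed"
            write_bed(t, p)
            back = read_bed(p)
            assert [(iv.start, iv.end) for iv in back.intervals] == [
                (iv.start, iv.end) for iv in t.intervals
            ]

    def test_serialization_half_open(self, tmp_path):
        p = tmp_path / "a.bed"
        write_bed(_track([(10, 20)]), p)
        assert p.read_text() == "chr1\t10\t20\n"

    def test_empty_track_writes_empty_file(self, tmp_path):
        p = tmp_path / "a.bed"
        write_bed(_track([]), p)
        assert p.read_text() == ""


class TestGff:
    GFF = (
        "##gff-version 3\n"
        "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=gplus\n"
        "chr1\tsrc\tgene\t101\t200\t.\t-\t.\tID=gminus\n"
    )

    def test_plus_strand_conversion(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(self.GFF)
        anchors = {a.gene_id: a for a in read_gff_genes(p)}
        assert anchors["gplus"].tss == 100 and anchors["gplus"].tes == 199

    def test_minus_strand_flips(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(self.GFF)
        anchors = {a.gene_id: a for a in read_gff_genes(p)}
        assert anchors["gminus"].tss == 199 and anchors["gminus"].tes == 100

    def test_missing_strand_skipped(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("##gff-version 3\nchr1\tsrc\tgene\t1\t10\t.\t.\t.\tID=g\n")
        assert read_gff_genes(p) == []


class TestMerge:
    def test_empty(self):
        assert merge_intervals(_track([])).intervals == []

    def test_overlap(self):
        m = merge_intervals(_track([(1, 5), (3, 8)]))
        assert [(iv.start, iv.end) for iv in m.intervals] == [(1, 8)]

    def test_bookended_intervals_merge(self):
        m = merge_intervals(_track([(1, 5), (5, 9)]))
        assert [(iv.start, iv.end) for iv in m.intervals] == [(1, 9)]

    def test_idempotent_and_bitmap_oracle(self):
        rng = np.random.default_rng(42)
        starts = rng.integers(0, 9900, size=1000)
        t = _track([(int(s), int(s) + int(rng.integers(1, 80))) for s in starts])
        m = merge_intervals(t)
        assert m.consolidated
        assert total_bp(m) == _bitmap_bp(t)
        m2 = merge_intervals(m)
        assert [(iv.start, iv.end) for iv in m2.intervals] == [
            (iv.start, iv.end) for iv in m.intervals
        ]

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 50)).map(
                lambda t: (t[0], t[0] + t[1])
            ),
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_merge_bp_never_exceeds_raw(self, pairs):
        t = _track(pairs)
        assert total_bp(merge_intervals(t)) <= sum(e - s for s, e in pairs)


class TestIntersect:
    def test_simple_overlap(self):
        _, bp = intersect_bp(_track([(0, 10)]), _track([(5, 15)]))
        assert bp == 5

    def test_disjoint(self):
        _, bp = intersect_bp(_track([(0, 10)]), _track([(20, 30)]))
        assert bp == 0

    def test_bitmap_oracle_and_symmetry(self):
        rng = np.random.default_rng(3)
        a = _track([(int(s), int(s) + int(rng.integers(1, 60))) for s in rng.integers(0, 9900, 300)])
        b = _track([(int(s), int(s) + int(rng.integers(1, 60))) for s in rng.integers(0, 9900, 300)])
        _, ab = intersect_bp(a, b)
        _, ba = intersect_bp(b, a)
        ca = np.zeros(10_000, dtype=bool)
        cb = np.zeros(10_000, dtype=bool)
        for iv in a.intervals:
            ca[iv.start : iv.end] = True
        for iv in b.intervals:
            cb[iv.start : iv.end] = True
        assert ab == ba == int((ca & cb).sum())

    def test_bedtools_cross_check(self, tmp_path):
        rng = np.random.default_rng(9)
        a = _track([(int(s), int(s) + int(rng.integers(1, 60))) for s in rng.integers(0, 9900, 200)])
        b = _track([(int(s), int(s) + int(rng.integers(1, 60))) for s in rng.integers(0, 9900, 200)])
        pa, pb = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(merge_intervals(a), pa)
        write_bed(merge_intervals(b), pb)
        merged = subprocess.run(
            ["bedtools", "merge", "-i", str(pa)], capture_output=True, text=True, check=True
        ).stdout.strip().splitlines()
        ours = merge_intervals(a).intervals
        assert [(l.split("\t")[1], l.split("\t")[2]) for l in merged] == [
            (str(iv.start), str(iv.end)) for iv in ours
        ]
        inter = subprocess.run(
            ["bedtools", "intersect", "-a", str(pa), "-b", str(pb)],
            capture_output=True, text=True, check=True,
        ).stdout.strip().splitlines()
        bt_bp = sum(int(l.split("\t")[2]) - int(l.split("\t")[1]) for l in inter if l)
        _, our_bp = intersect_bp(a, b)
        assert our_bp == bt_bp


class TestReciprocalOverlap:
    def test_kept_when_both_sides_pass(self):
        a, b = _track([(0, 100)]), _track([(50, 150)])
        kept = reciprocal_overlap_filter(a, b, 0.2)
        assert [(iv.start, iv.end) for iv in kept.intervals] == [(0, 100)]

    def test_dropped_on_one_sided_overlap(self):
        # 100/1000 = 0.1 on the a side fails the 20% requirement
        a, b = _track([(0, 1000)]), _track([(900, 1000)])
        assert reciprocal_overlap_filter(a, b, 0.2).intervals == []

    def test_disjoint_empty(self):
        assert reciprocal_overlap_filter(_track([(0, 10)]), _track([(20, 30)]), 0.5).intervals == []

    def test_frac_out_of_range(self):
        with pytest.raises(ValueError):
            reciprocal_overlap_filter(_track([(0, 10)]), _track([(0, 10)]), 0.0)


class TestComplement:
    def test_partitions_chromosome(self):
        t = merge_intervals(_track([(10, 20), (30, 40)]))
        c = complement_track(t, {"chr1": 50})
        assert [(iv.start, iv.end) for iv in c.intervals] == [(0, 10), (20, 30), (40, 50)]
        assert total_bp(t) + total_bp(c) == 50
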