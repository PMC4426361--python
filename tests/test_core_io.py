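import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dotkit.core_io import (
    GeneModel,
    GenomicInterval,
    RepeatFragment,
    SeqRecord,
    merge_same_class,
    overlap_bases,
    read_bed12,
    read_fasta,
    read_repeatmasker_out,
    revcomp,
    union_intervals,
    write_bed12,
)


def iv(start, end, chrom="c", strand="."):
    return GenomicInterval(chrom, start, end, strand)


class TestSeqRecord:
    def test_length(self):
        assert len(SeqRecord("a", "ACGT")) == 4

    @pytest.mark.parametrize("bad", ["acgt", "ACRT", "ACG-"])
    def test_rejects_bad_alphabet(self, bad):
        with pytest.raises(ValueError):
            SeqRecord("a", bad)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            SeqRecord("", "ACGT")
        with pytest.raises(ValueError):
            SeqRecord("a", "")


class TestReadFasta:
    def test_basic(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nacgt\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].id == "a"
        assert recs[0].sequence == "ACGT"

    def test_two_records(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACGT\n>b\nNNN\n")
        recs = read_fasta(p)
        assert [len(r) for r in recs] == [4, 3]

    def test_ambiguity_to_n(self, tmp_path, caplog):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACRT\n")
        with caplog.at_level("WARNING"):
            recs = read_fasta(p)
        assert recs[0].sequence == "ACNT"
        assert "1 non-ACGTN" in caplog.text

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "nope.fa")


class TestBed12:
    def _line(self, **kw):
        d = dict(
            chrom="c", start=0, end=1000, name="g1|g1.t1", score=0, strand="+",
            thick_start=100, thick_end=900, rgb="0,0,0", count=2,
            sizes="200,200", starts="0,800",
        )
        d.update(kw)
        return "\t".join(
            str(d[k])
            for k in ("chrom", "start", "end", "name", "score", "strand",
                      "thick_start", "thick_end", "rgb", "count", "sizes", "starts")
        ) + "\n"

    def test_thick_clipping(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text(self._line())
        (m,) = read_bed12(p)
        assert [(e.start, e.end) for e in m.coding_exons] == [(100, 200), (800, 900)]
        assert m.gene_id == "g1" and m.transcript_id == "g1.t1"

    def test_no_coding_region_errors(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text(self._line(thick_start=500, thick_end=500))
        with pytest.raises(ValueError, match="no coding region"):
            read_bed12(p)

    def test_middle_block_unclipped(self, tmp_path):
        # hand-clipped: [0,200)->[100,200), [400,500) inside, [800,1000)->[800,900)
        p = tmp_path / "g.bed"
        p.write_text(self._line(count=3, sizes="200,100,200", starts="0,400,800"))
        (m,) = read_bed12(p)
        assert [(e.start, e.end) for e in m.coding_exons] == [
            (100, 200), (400, 500), (800, 900),
        ]

    def test_block_count_mismatch(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text(self._line(count=3))
        with pytest.raises(ValueError, match="blockCount"):
            read_bed12(p)

    def test_unsorted_blocks(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text(self._line(sizes="200,100", starts="800,0"))
        with pytest.raises(ValueError, match="unsorted"):
            read_bed12(p)

    def test_roundtrip(self, tmp_path):
        model = GeneModel(
            "g", "g.t2", "c", "-",
            [iv(10, 40, strand="-"), iv(100, 160, strand="-"), iv(300, 330, strand="-")],
        )
        p = tmp_path / "rt.bed"
        write_bed12([model], p)
        (back,) = read_bed12(p)
        assert [(e.start, e.end) for e in back.coding_exons] == [
            (e.start, e.end) for e in model.coding_exons
        ]
        assert back.strand == "-"
        assert (back.gene_id, back.transcript_id) == ("g", "g.t2")


RM_HEADER = (
    "   SW  perc perc perc  query     position in query    matching repeat\n"
    "score  div. del. ins.  sequence  begin end (left)     repeat class/family\n"
    "\n"
)


class TestRepeatMaskerOut:
    def test_coordinates_and_class(self, tmp_path):
        p = tmp_path / "r.out"
        p.write_text(
            RM_HEADER
            + " 1000 10.0 0.0 0.0 chr1 101 200 (500) + Helena LINE/CR1 1 100 (0) 1\n"
            + "  900 11.0 0.0 0.0 chr1 300 350 (400) C DNAREP1 DNA/Helitron 1 50 (0) 2\n"
        )
        frags = read_repeatmasker_out(p)
        assert frags[0].interval.start == 100 and frags[0].interval.end == 200
        assert frags[0].repeat_class == "LINE"
        assert frags[1].interval.strand == "-"
        assert frags[1].repeat_class == "DNA"

    def test_headers_only(self, tmp_path):
        p = tmp_path / "r.out"
        p.write_text(RM_HEADER)
        assert read_repeatmasker_out(p) == []

    def test_end_before_start(self, tmp_path):
        p = tmp_path / "r.out"
        p.write_text(RM_HEADER + " 1 1 1 1 chr1 200 100 (0) + x DNA 1 1 (0) 1\n")
        with pytest.raises(ValueError, match="end < start"):
            read_repeatmasker_out(p)


def frag(start, end, rclass, chrom="c", name=""):
    return RepeatFragment(GenomicInterval(chrom, start, end), rclass, name)


class TestMergeSameClass:
    def test_same_class_union(self):
        out = merge_same_class([frag(0, 100, "DNA"), frag(50, 150, "DNA")])
        assert [(f.interval.start, f.interval.end) for f in out] == [(0, 150)]

    def test_different_class_untouched(self):
        out = merge_same_class([frag(0, 100, "DNA"), frag(50, 150, "LTR")])
        assert len(out) == 2
        assert {(f.interval.start, f.interval.end) for f in out} == {(0, 100), (50, 150)}

    def test_bookended_merge(self):
        out = merge_same_class(
            [frag(0, 10, "DNA"), frag(10, 20, "DNA"), frag(30, 40, "DNA")]
        )
        assert [(f.interval.start, f.interval.end) for f in out] == [(0, 20), (30, 40)]

    def test_idempotent_and_order_independent(self, rng):
        frags = [
            frag(int(s), int(s) + int(l), cls)
            for s, l, cls in zip(
                rng.integers(0, 5000, 60), rng.integers(1, 400, 60),
                rng.choice(["DNA", "LTR", "LINE"], 60),
            )
        ]
        once = merge_same_class(frags)
        assert merge_same_class(once) == once
        shuffled = list(frags)
        rng.shuffle(shuffled)
        assert merge_same_class(shuffled) == once
        assert sum(len(f.interval) for f in once) <= sum(len(f.interval) for f in frags)


class TestOverlapBases:
    def test_simple(self):
        assert overlap_bases([iv(0, 100)], [iv(50, 150)]) == 50

    def test_disjoint(self):
        assert overlap_bases([iv(0, 10)], [iv(20, 30)]) == 0

    def test_split(self):
        assert overlap_bases([iv(0, 10), iv(20, 30)], [iv(5, 25)]) == 10

    def test_symmetry_and_bound(self, rng):
        a = [iv(int(s), int(s) + int(l)) for s, l in
             zip(rng.integers(0, 900, 20), rng.integers(1, 120, 20))]
        b = [iv(int(s), int(s) + int(l)) for s, l in
             zip(rng.integers(0, 900, 20), rng.integers(1, 120, 20))]
        ab = overlap_bases(a, b)
        assert ab == overlap_bases(b, a)
        assert ab <= min(
            sum(len(x) for x in union_intervals(a)),
            sum(len(x) for x in union_intervals(b)),
        )

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_matches_per_base_oracle(self, data):
        mk = st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 60)), min_size=1, max_size=10
        )
        a = [iv(s, s + l) for s, l in data.draw(mk)]
        b = [iv(s, s + l) for s, l in data.draw(mk)]
        in_a = np.zeros(600, dtype=bool)
        in_b = np.zeros(600, dtype=bool)
        for x in a:
            in_a[x.start : x.end] = True
        for x in b:
            in_b[x.start : x.end] = True
        assert overlap_bases(a, b) == int(np.sum(in_a & in_b))


def test_revcomp():
    assert revcomp("ACGTN") == "NACGT"
    assert revcomp(revcomp("GATTACA")) == "GATTACA"


def test_gene_model_invariants():
    with pytest.raises(ValueError, match="not sorted"):
        GeneModel("g", "t", "c", "+", [iv(100, 200), iv(0, 50)])
    with pytest.raises(ValueError, match="overlapping"):
        GeneModel("g", "t", "c", "+", [iv(0, 100), iv(50, 150)])
    m = GeneModel("g", "t", "c", "+", [iv(100, 200), iv(300, 400)])
    assert len(m.span) == 300
    assert m.coding_region_size == 200
    assert [(i.start, i.end) for i in m.introns] == [(200, 300)]


def test_read_gff3(tmp_path):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "c\tsrc\tgene\t101\t1000\t.\t+\t.\tID=gene1\n"
        "c\tsrc\tmRNA\t101\t1000\t.\t+\t.\tID=tx1;Parent=gene1\n"
        "c\tsrc\tCDS\t101\t200\t.\t+\t0\tID=cds1;Parent=tx1\n"
        "c\tsrc\tCDS\t801\t900\t.\t+\t2\tID=cds2;Parent=tx1\n"
    )
    from dotkit.core_io import read_gff3

    (m,) = read_gff3(gff)
    assert m.gene_id == "gene1" and m.transcript_id == "tx1"
    assert [(e.start, e.end) for e in m.coding_exons] == [(100, 200), (800, 900)]
    assert m.strand == "+"
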