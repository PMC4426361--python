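"""Domain types, interval algebra, and readers/writers for standard formats.

All coordinates are 0-based half-open (BED native).  Formats with other
conventions (RepeatMasker ``.out``, GFF3) are converted on read so no
other module ever sees a 1-based coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, upper case."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("empty record id")
        if not self.sequence:
            raise ValueError(f"zero-length record {self.id!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chrom")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, order=True)
class RepeatFragment:
    """A located repeat copy with a class label (e.g. DNA, LTR, DINE-1)."""

    interval: GenomicInterval
    repeat_class: str
    repeat_name: str = ""

    def __post_init__(self) -> None:
        if not self.repeat_class:
            raise ValueError("empty repeat_class")


@dataclass
class GeneModel:
    """Coding-exon chain of one isoform.  UTRs are deliberately absent."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    coding_exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not self.coding_exons:
            raise ValueError(f"gene {self.gene_id}: no coding exons")
        for ex in self.coding_exons:
            if ex.chrom != self.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chrom")
        starts = [ex.start for ex in self.coding_exons]
        if starts != sorted(starts):
            raise ValueError(f"gene {self.gene_id}: exons not sorted")
        for a, b in zip(self.coding_exons, self.coding_exons[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        if self.coding_region_size < 3:
            raise ValueError(f"gene {self.gene_id}: coding region < 3 bp")

    @property
    def span(self) -> GenomicInterval:
        """Start codon to stop codon, introns included."""
        return GenomicInterval(
            self.chrom,
            self.coding_exons[0].start,
            self.coding_exons[-1].end,
            self.strand,
        )

    @property
    def coding_region_size(self) -> int:
        return sum(len(ex) for ex in self.coding_exons)

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.coding_exons, self.coding_exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def extract_cds(self, genome: SeqRecord) -> str:
        """Spliced coding sequence read 5'->3' on the coding strand."""
        parts = [genome.sequence[ex.start : ex.end] for ex in self.coding_exons]
        cds = "".join(parts)
        return revcomp(cds) if self.strand == "-" else cds


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read FASTA; upper-case and collapse non-ACGTN characters to N.

    The number of collapsed characters is logged as a warning so silent
    data corruption is visible.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SeqRecord] = []
    n_ambiguous = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        cleaned = "".join(c if c in VALID_BASES else "N" for c in seq)
        n_ambiguous += sum(1 for a, b in zip(seq, cleaned) if a != b)
        records.append(SeqRecord(id=rec.id, sequence=cleaned))
    if n_ambiguous:
        log.warning("%s: %d non-ACGTN characters mapped to N", path, n_ambiguous)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED12

def _parse_gene_name(name: str) -> tuple[str, str]:
    # convention: "gene|transcript" in the BED name field; otherwise both.
    if "|" in name:
        gene, tx = name.split("|", 1)
        return gene, tx
    return name, name


def read_bed12(path: str | Path) -> list[GeneModel]:
    """Read 12-column BED into coding-exon-only gene models.

    Blocks are clipped to the thick ([thickStart, thickEnd)) region;
    blocks entirely outside it are dropped.
    """
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns, got {len(cols)}")
            chrom = cols[0]
            chrom_start, chrom_end = int(cols[1]), int(cols[2])
            name, strand = cols[3], cols[5]
            thick_start, thick_end = int(cols[6]), int(cols[7])
            block_count = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            starts = [int(x) for x in cols[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(f"{path}:{lineno}: blockCount mismatch")
            if starts != sorted(starts):
                raise ValueError(f"{path}:{lineno}: unsorted blocks")
            if thick_start > thick_end:
                raise ValueError(f"{path}:{lineno}: thickStart > thickEnd")
            if thick_start == thick_end:
                raise ValueError(f"{path}:{lineno}: no coding region")
            exons: list[GenomicInterval] = []
            for size, rel in zip(sizes, starts):
                b_start = chrom_start + rel
                b_end = b_start + size
                if b_end > chrom_end:
                    raise ValueError(f"{path}:{lineno}: block extends past chromEnd")
                s = max(b_start, thick_start)
                e = min(b_end, thick_end)
                if s < e:
                    exons.append(GenomicInterval(chrom, s, e, strand))
            gene_id, tx_id = _parse_gene_name(name)
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    transcript_id=tx_id,
                    chrom=chrom,
                    strand=strand,
                    coding_exons=exons,
                )
            )
    return models


def write_bed12(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write coding-exon models as BED12 (thick region == full span)."""
    with open(path, "w") as fh:
        for m in models:
            span = m.span
            sizes = ",".join(str(len(ex)) for ex in m.coding_exons)
            rels = ",".join(str(ex.start - span.start) for ex in m.coding_exons)
            name = m.transcript_id if m.gene_id == m.transcript_id else f"{m.gene_id}|{m.transcript_id}"
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(span.start),
                        str(span.end),
                        name,
                        "0",
                        m.strand,
                        str(span.start),
                        str(span.end),
                        "0,0,0",
                        str(len(m.coding_exons)),
                        sizes,
                        rels,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (CDS features only) from GFF3.

    CDS features are grouped by their Parent (the mRNA id); the gene id
    comes from the mRNA's own Parent when present.  Coordinates convert
    from 1-based inclusive to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            continue
        parents = mrna.attributes.get("Parent", [mrna.id])
        exons = [
            GenomicInterval(f.seqid, f.start - 1, f.end, f.strand) for f in cds
        ]
        models.append(
            GeneModel(
                gene_id=parents[0],
                transcript_id=mrna.id,
                chrom=cds[0].seqid,
                strand=mrna.strand,
                coding_exons=exons,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Repeat annotation readers / writers

def read_repeatmasker_out(path: str | Path) -> list[RepeatFragment]:
    """Read RepeatMasker ``.out``; 1-based inclusive -> 0-based half-open.

    The repeat class is the class/family column truncated at the first
    "/"; the complement marker "C" becomes strand "-".
    """
    frags: list[RepeatFragment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            cols = line.split()
            # header lines start with "SW"/"score" or are the blank ruler
            if cols[0] in ("SW", "score") or cols[0].startswith("="):
                continue
            if len(cols) < 11:
                raise ValueError(f"{path}:{lineno}: malformed row ({len(cols)} columns)")
            begin, end = int(cols[5]), int(cols[6])
            if end < begin:
                raise ValueError(f"{path}:{lineno}: end < start")
            strand = "-" if cols[8] == "C" else "+"
            repeat_name = cols[9]
            repeat_class = cols[10].split("/")[0]
            frags.append(
                RepeatFragment(
                    interval=GenomicInterval(cols[4], begin - 1, end, strand),
                    repeat_class=repeat_class,
                    repeat_name=repeat_name,
                )
            )
    return frags


def read_repeat_bed(path: str | Path) -> list[RepeatFragment]:
    """Read BED6+1 repeat annotations (7th column = repeat class)."""
    frags: list[RepeatFragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            if len(cols) < 7:
                raise ValueError(f"{path}:{lineno}: expected >= 7 columns")
            frags.append(
                RepeatFragment(
                    interval=GenomicInterval(cols[0], int(cols[1]), int(cols[2]), cols[5]),
                    repeat_class=cols[6],
                    repeat_name=cols[3],
                )
            )
    return frags


def write_repeat_bed(frags: Iterable[RepeatFragment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in sorted(frags, key=lambda f: (f.interval.chrom, f.interval.start, f.interval.end)):
            iv = f.interval
            fh.write(
                "\t".join(
                    [iv.chrom, str(iv.start), str(iv.end), f.repeat_name or f.repeat_class,
                     "0", iv.strand if iv.strand != "." else "+", f.repeat_class]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Interval algebra

def union_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union per chromosome; book-ended intervals merge.  Strand is dropped."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def merge_same_class(fragments: Sequence[RepeatFragment]) -> list[RepeatFragment]:
    """Union overlapping/book-ended fragments within (chrom, repeat_class).

    Fragments of different classes never merge, even when they overlap.
    Merged fragment names are the comma-joined distinct input names.
    """
    groups: dict[tuple[str, str], list[RepeatFragment]] = {}
    for f in fragments:
        groups.setdefault((f.interval.chrom, f.repeat_class), []).append(f)
    merged: list[RepeatFragment] = []
    for (chrom, rclass), frags in groups.items():
        frags.sort(key=lambda f: (f.interval.start, f.interval.end))
        cur_s, cur_e = frags[0].interval.start, frags[0].interval.end
        names = [frags[0].repeat_name] if frags[0].repeat_name else []
        for f in frags[1:]:
            if f.interval.start <= cur_e:
                cur_e = max(cur_e, f.interval.end)
                if f.repeat_name and f.repeat_name not in names:
                    names.append(f.repeat_name)
            else:
                merged.append(
                    RepeatFragment(GenomicInterval(chrom, cur_s, cur_e), rclass, ",".join(names))
                )
                cur_s, cur_e = f.interval.start, f.interval.end
                names = [f.repeat_name] if f.repeat_name else []
        merged.append(
            RepeatFragment(GenomicInterval(chrom, cur_s, cur_e), rclass, ",".join(names))
        )
    merged.sort(key=lambda f: (f.interval.chrom, f.interval.start, f.interval.end, f.repeat_class))
    return merged


def total_bases(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in union_intervals(intervals)) if intervals else 0


def overlap_bases(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Bases in the intersection of union(a) and union(b); symmetric."""
    if not a or not b:
        return 0
    ua = union_intervals(a)
    ub = union_intervals(b)
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in ub:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    total = 0
    for iv in ua:
        for other in by_chrom_b.get(iv.chrom, ()):
            lo = max(iv.start, other.start)
            hi = min(iv.end, other.end)
            if lo < hi:
                total += hi - lo
    return total


def clip_intervals(
    intervals: Iterable[GenomicInterval], region: GenomicInterval
) -> list[GenomicInterval]:
    """Clip each interval to a region, dropping those outside it."""
    out = []
    for iv in intervals:
        if iv.chrom != region.chrom:
            continue
        lo = max(iv.start, region.start)
        hi = min(iv.end, region.end)
        if lo < hi:
            out.append(GenomicInterval(iv.chrom, lo, hi, iv.strand))
    return out
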