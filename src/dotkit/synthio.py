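"""Seeded synthetic genomes, gene models, codon-usage cohorts, and
ortholog tables with planted, recoverable ground truth.

Everything is driven by one integer seed through numpy's PCG64 streams:
the same config always yields byte-identical output.  Planted features
(transposon fragments, dinucleotide runs, gene structures, codon-mixture
weights, reversals, wanderers) are returned alongside the data so every
downstream scanner can be tested against exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from dotkit.codon import CodonUsageTable, FAMILIES, STOP_CODONS
from dotkit.core_io import (
    GeneModel,
    GenomicInterval,
    RepeatFragment,
    SeqRecord,
    revcomp,
)

_AMINO_ACIDS = tuple(sorted(FAMILIES))
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# distributions

def sample_dist(rng: np.random.Generator, spec: Mapping, size: int) -> np.ndarray:
    """Draw integers from a named distribution spec.

    Kinds: constant(value), uniform_int(low, high), poisson(lam, min),
    geometric(p, min).  Results are clamped to the spec's ``min`` when
    present.
    """
    kind = spec["kind"]
    if kind == "constant":
        out = np.full(size, int(spec["value"]))
    elif kind == "uniform_int":
        out = rng.integers(int(spec["low"]), int(spec["high"]) + 1, size=size)
    elif kind == "poisson":
        out = rng.poisson(float(spec["lam"]), size=size)
    elif kind == "geometric":
        out = rng.geometric(float(spec["p"]), size=size)
    else:
        raise ValueError(f"unknown distribution kind {kind!r}")
    if "min" in spec:
        out = np.maximum(out, int(spec["min"]))
    return out.astype(int)


# ---------------------------------------------------------------------------
# codon regime helpers

def preferred_codon_table(ending: str = "C") -> dict[str, str]:
    """One 'optimal' codon per amino acid: prefer codons ending in
    ``ending``, falling back to the alphabetically first codon."""
    table = {}
    for aa, codons in FAMILIES.items():
        hits = [c for c in codons if c.endswith(ending)]
        table[aa] = hits[0] if hits else codons[0]
    return table


def antipreferred_codon_table(preferred: Mapping[str, str] | None = None) -> dict[str, str]:
    """Per family, a codon guaranteed different from the preferred one
    (single-codon families keep their only codon).  Useful for planting
    a mutation-driven bias that is disjoint from the reference set's
    optimal codons."""
    preferred = preferred or preferred_codon_table()
    table = {}
    for aa, codons in FAMILIES.items():
        if len(codons) == 1:
            table[aa] = codons[0]
        else:
            table[aa] = next(c for c in reversed(codons) if c != preferred[aa])
    return table


def codon_table_from_preferences(
    preferred: Mapping[str, str], weight: float = 70.0, total: float = 100.0
) -> CodonUsageTable:
    """A codon-usage table giving each family's preferred codon
    ``weight`` counts out of ``total`` (rest split evenly) — a moderate,
    fully-observed reference for relative-adaptiveness computation."""
    counts: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        k = len(codons)
        if k == 1:
            counts[codons[0]] = total
            continue
        for c in codons:
            counts[c] = weight if c == preferred[aa] else (total - weight) / (k - 1)
    return CodonUsageTable(counts)


def sample_codon_table(
    rng: np.random.Generator,
    n_codons: int,
    lam: float,
    optimal: Mapping[str, str],
) -> CodonUsageTable:
    """Codon counts for one synthetic gene.

    Amino acids are uniform; within each synonymous family the codon is
    the designated optimal one with probability lam + (1-lam)/k and any
    family member uniformly otherwise — i.e. the lam-mixture of an
    optimal table and a uniform table.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must be in [0, 1]")
    aa_counts = rng.multinomial(n_codons, np.full(len(_AMINO_ACIDS), 1.0 / len(_AMINO_ACIDS)))
    counts: dict[str, float] = {}
    for aa, cnt in zip(_AMINO_ACIDS, aa_counts):
        if cnt == 0:
            continue
        codons = FAMILIES[aa]
        k = len(codons)
        if k == 1:
            counts[codons[0]] = counts.get(codons[0], 0.0) + cnt
            continue
        opt = optimal[aa]
        probs = np.array([lam * (c == opt) + (1.0 - lam) / k for c in codons])
        for c, v in zip(codons, rng.multinomial(cnt, probs)):
            if v:
                counts[c] = counts.get(c, 0.0) + v
    return CodonUsageTable(counts)


def generate_codon_tables(
    seed: int,
    n_genes: int,
    n_codons: int,
    lambdas: Sequence[float],
    optimal: Mapping[str, str] | None = None,
) -> dict[str, CodonUsageTable]:
    """A cohort of per-gene codon tables; ``lambdas`` gives the true
    mixture weight per gene (cycled if shorter than n_genes)."""
    rng = np.random.default_rng([seed, 777])
    optimal = optimal or preferred_codon_table()
    out = {}
    for i in range(n_genes):
        lam = float(lambdas[i % len(lambdas)])
        out[f"g{i:04d}"] = sample_codon_table(rng, n_codons, lam, optimal)
    return out


# ---------------------------------------------------------------------------
# config

@dataclass
class SynthConfig:
    seed: int = 0
    region_length: int = 100_000
    background_gc: float = 0.40
    transposon_library: Sequence[tuple[str, str, str]] = ()
    target_transposon_density: float = 0.0
    dinucleotide_runs: Sequence[tuple[str, int, int]] = ()
    n_genes: int = 0
    exon_count_distribution: Mapping = field(
        default_factory=lambda: {"kind": "poisson", "lam": 2.0, "min": 1}
    )
    exon_size_distribution: Mapping = field(
        default_factory=lambda: {"kind": "uniform_int", "low": 60, "high": 400}
    )
    intron_size_distribution: Mapping = field(
        default_factory=lambda: {"kind": "uniform_int", "low": 60, "high": 500}
    )
    codon_regime: float = 0.0
    lambda_mixture: Sequence[tuple[float, float]] | None = None  # (weight, lam)
    optimal_codons: Mapping[str, str] = field(default_factory=preferred_codon_table)
    n_reversals: int = 0
    n_wanderers: int = 0
    region_id: str = "synth_chr"

    def __post_init__(self) -> None:
        for name, v in (
            ("background_gc", self.background_gc),
            ("target_transposon_density", self.target_transposon_density),
            ("codon_regime", self.codon_regime),
        ):
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} outside [0, 1]")
        for name, v in (
            ("region_length", self.region_length),
            ("n_genes", self.n_genes),
            ("n_reversals", self.n_reversals),
            ("n_wanderers", self.n_wanderers),
        ):
            if v < 0:
                raise ValueError(f"{name} negative")


def default_transposon_library(seed: int = 20_000) -> list[tuple[str, str, str]]:
    """A small deterministic toy library including a DINE-1-like class."""
    rng = np.random.default_rng(seed)

    def consensus(length: int, gc: float) -> str:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return "".join(_BASES[i] for i in rng.choice(4, size=length, p=p))

    return [
        ("DINE1_like", "DINE-1", consensus(400, 0.35)),
        ("Helena_like", "LINE", consensus(1200, 0.40)),
        ("Gypsy_like", "LTR", consensus(1500, 0.45)),
        ("Pogo_like", "DNA", consensus(800, 0.40)),
    ]


# ---------------------------------------------------------------------------
# genome generation

@dataclass
class PlantedRun:
    dinucleotide: str
    units: int
    interval: GenomicInterval


@dataclass
class SyntheticGenome:
    """A mutable synthetic chromosome plus its planted truth."""

    config: SynthConfig
    _seq: np.ndarray  # uint8 ASCII
    repeats: list[RepeatFragment]
    repeat_seqs: list[str]
    runs: list[PlantedRun]
    occupied: list[tuple[int, int]]

    @property
    def record(self) -> SeqRecord:
        return SeqRecord(
            id=self.config.region_id, sequence=self._seq.tobytes().decode("ascii")
        )

    def free_gaps(self) -> list[tuple[int, int]]:
        L = len(self._seq)
        occ = sorted(self.occupied)
        gaps = []
        prev = 0
        for s, e in occ:
            if s > prev:
                gaps.append((prev, s))
            prev = max(prev, e)
        if prev < L:
            gaps.append((prev, L))
        return gaps

    def _place(self, rng: np.random.Generator, length: int) -> int | None:
        """Pick a uniform free start position for a feature of ``length``."""
        gaps = [(s, e) for s, e in self.free_gaps() if e - s >= length]
        if not gaps:
            return None
        caps = np.array([e - s - length + 1 for s, e in gaps], dtype=float)
        gi = rng.choice(len(gaps), p=caps / caps.sum())
        return int(gaps[gi][0] + rng.integers(0, int(caps[gi])))

    def write(self, start: int, seq: str) -> None:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        self._seq[start : start + len(seq)] = arr
        self.occupied.append((start, start + len(seq)))


def _background(cfg: SynthConfig) -> SyntheticGenome:
    rng = np.random.default_rng([cfg.seed, 0])
    L = cfg.region_length
    gc = cfg.background_gc
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    seq = codes[rng.choice(4, size=L, p=p)].copy()
    return SyntheticGenome(
        config=cfg, _seq=seq, repeats=[], repeat_seqs=[], runs=[], occupied=[]
    )


def plant_transposons(sg: SyntheticGenome, rng: np.random.Generator) -> None:
    cfg = sg.config
    L = cfg.region_length
    target = cfg.target_transposon_density
    tol = 0.02
    if target > 0:
        if not cfg.transposon_library:
            raise ValueError("target density > 0 but transposon library empty")
        if min(len(c) for _, _, c in cfg.transposon_library) < 50:
            raise ValueError("library consensus shorter than 50 bp")
        planted = 0
        while planted < target * L:
            name, rclass, cons = cfg.transposon_library[
                rng.integers(0, len(cfg.transposon_library))
            ]
            flen = int(rng.integers(50, len(cons) + 1))
            if planted + flen > (target + tol) * L:
                flen = int(math.ceil(target * L - planted))
                if flen < 50:
                    break
                flen = min(flen, len(cons))
            off = int(rng.integers(0, len(cons) - flen + 1))
            frag = cons[off : off + flen]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = revcomp(frag)
            start = sg._place(rng, flen)
            if start is None:
                break
            sg.write(start, frag)
            sg.repeats.append(
                RepeatFragment(
                    GenomicInterval(cfg.region_id, start, start + flen, strand),
                    rclass,
                    name,
                )
            )
            sg.repeat_seqs.append(frag)
            planted += flen
        density = planted / L
        if abs(density - target) > tol:
            raise ValueError(
                f"target density {target} unreachable (achieved {density:.3f})"
            )


def plant_dinucleotide_runs(sg: SyntheticGenome, rng: np.random.Generator) -> None:
    cfg = sg.config
    for dinuc, units, copies in cfg.dinucleotide_runs:
        dinuc = dinuc.upper()
        if len(dinuc) != 2 or any(c not in _BASES for c in dinuc):
            raise ValueError(f"invalid dinucleotide {dinuc!r}")
        guard_left = next(b for b in _BASES if b != dinuc[1])
        guard_right = next(b for b in _BASES if b != dinuc[0])
        for _ in range(copies):
            total = 2 * units + 2
            start = sg._place(rng, total)
            if start is None:
                raise ValueError("region too small for requested dinucleotide runs")
            sg.write(start, guard_left + dinuc * units + guard_right)
            sg.runs.append(
                PlantedRun(
                    dinucleotide=dinuc,
                    units=units,
                    interval=GenomicInterval(
                        cfg.region_id, start + 1, start + 1 + 2 * units
                    ),
                )
            )


def generate_genome(cfg: SynthConfig) -> SyntheticGenome:
    """Background + planted transposon fragments + dinucleotide runs.

    Fragment bases reach the target density within +-2 percentage
    points; runs are guarded on both sides so their maximal-run lengths
    are exactly recoverable.  Same config => byte-identical genome.
    """
    sg = _background(cfg)
    rng = np.random.default_rng([cfg.seed, 3])
    plant_transposons(sg, rng)
    plant_dinucleotide_runs(sg, rng)
    return sg


def generate_region(cfg: SynthConfig):
    """Genes first, then repeats and runs in the remaining space
    (including introns, which repeats may overwrite — coding exons are
    never touched).  Returns (genome, gene models, true lambdas)."""
    sg = _background(cfg)
    models, lambdas = generate_gene_models(cfg, sg)
    rng = np.random.default_rng([cfg.seed, 3])
    plant_transposons(sg, rng)
    plant_dinucleotide_runs(sg, rng)
    return sg, models, lambdas


# ---------------------------------------------------------------------------
# gene generation

def _sample_lambda(rng: np.random.Generator, cfg: SynthConfig) -> float:
    if cfg.lambda_mixture is None:
        return cfg.codon_regime
    weights = np.array([w for w, _ in cfg.lambda_mixture], dtype=float)
    lams = [lam for _, lam in cfg.lambda_mixture]
    return float(lams[rng.choice(len(lams), p=weights / weights.sum())])


def _sample_cds(
    rng: np.random.Generator, n_codons: int, lam: float, optimal: Mapping[str, str]
) -> str:
    """ATG + (n_codons - 2) mixture-sampled sense codons + stop."""
    if n_codons < 3:
        raise ValueError("CDS needs >= 3 codons")
    parts = ["ATG"]
    aas = rng.choice(len(_AMINO_ACIDS), size=n_codons - 2)
    us = rng.random(n_codons - 2)
    for ai, u in zip(aas, us):
        aa = _AMINO_ACIDS[ai]
        codons = FAMILIES[aa]
        if u < lam:
            parts.append(optimal[aa])
        else:
            parts.append(codons[rng.integers(0, len(codons))])
    parts.append(sorted(STOP_CODONS)[rng.integers(0, len(STOP_CODONS))])
    return "".join(parts)


def generate_gene_models(
    cfg: SynthConfig, genome: SyntheticGenome
) -> tuple[list[GeneModel], dict[str, float]]:
    """Plant ``cfg.n_genes`` genes into the genome's free gaps.

    Exon counts/sizes and intron sizes follow the config distributions;
    the CDS starts with ATG, ends with a stop, has no internal stop, and
    its codons follow the lam-mixture regime.  Minus-strand genes are
    written reverse-complemented.  Returns the models and the true
    per-gene lambda.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    models: list[GeneModel] = []
    lambdas: dict[str, float] = {}
    for i in range(cfg.n_genes):
        n_ex = max(1, int(sample_dist(rng, cfg.exon_count_distribution, 1)[0]))
        exon_sizes = np.maximum(sample_dist(rng, cfg.exon_size_distribution, n_ex), 10)
        total = int(exon_sizes.sum())
        pad = (3 - total % 3) % 3
        if total + pad < 9:
            pad += 9 - (total + pad)
            pad += (3 - (total + pad) % 3) % 3
        exon_sizes[-1] += pad
        total += pad
        intron_sizes = (
            np.maximum(sample_dist(rng, cfg.intron_size_distribution, n_ex - 1), 10)
            if n_ex > 1
            else np.array([], dtype=int)
        )
        span = total + int(intron_sizes.sum())
        start = genome._place(rng, span)
        if start is None:
            raise ValueError(f"region too small for requested genes (placed {i})")
        exons = []
        pos = start
        for k, es in enumerate(exon_sizes):
            exons.append(GenomicInterval(cfg.region_id, pos, pos + int(es)))
            pos += int(es)
            if k < n_ex - 1:
                pos += int(intron_sizes[k])
        strand = "+" if rng.random() < 0.5 else "-"
        lam = _sample_lambda(rng, cfg)
        cds = _sample_cds(rng, total // 3, lam, cfg.optimal_codons)
        to_write = cds if strand == "+" else revcomp(cds)
        cursor = 0
        for ex in exons:
            genome.write(ex.start, to_write[cursor : cursor + len(ex)])
            cursor += len(ex)
        # introns stay unoccupied: repeats may be planted inside them
        gene_id = f"g{i:04d}"
        exons = [
            GenomicInterval(cfg.region_id, ex.start, ex.end, strand) for ex in exons
        ]
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                chrom=cfg.region_id,
                strand=strand,
                coding_exons=exons,
            )
        )
        lambdas[gene_id] = lam
    return models, lambdas


# ---------------------------------------------------------------------------
# ortholog tables

def random_reversals(
    rng: np.random.Generator, n_genes: int, k: int
) -> list[tuple[int, int]]:
    out = []
    for _ in range(k):
        i = int(rng.integers(0, n_genes))
        j = int(rng.integers(0, n_genes))
        out.append((min(i, j), max(i, j)))
    return out


def generate_ortholog_table(cfg: SynthConfig):
    """Two-species ortholog table: species B's order is species A's
    after ``n_reversals`` random signed reversals, then ``n_wanderers``
    genes are moved to other element labels in B.

    Returns (OrthologTable, reversal list, wanderer gene-id set).
    """
    from dotkit.synteny import OrthologTable, apply_reversal

    n = cfg.n_genes
    if n < 2:
        raise ValueError("n_genes must be >= 2")
    if cfg.n_wanderers > n:
        raise ValueError("n_wanderers > n_genes")
    rng = np.random.default_rng([cfg.seed, 2])
    gene_ids = [f"g{i:04d}" for i in range(n)]
    strands_a = ["+" if rng.random() < 0.5 else "-" for _ in range(n)]

    signed = list(range(1, n + 1))
    reversals = random_reversals(rng, n, cfg.n_reversals)
    for i, j in reversals:
        signed = apply_reversal(signed, i, j)

    wanderer_idx = (
        sorted(rng.choice(n, size=cfg.n_wanderers, replace=False).tolist())
        if cfg.n_wanderers
        else []
    )
    wanderer_genes = {gene_ids[i] for i in wanderer_idx}
    other_elements = ["A", "B", "C", "D", "E"]

    rows = []
    for i, g in enumerate(gene_ids):
        rows.append(
            {
                "gene_id": g, "species": "spA", "element": "F",
                "scaffold": "scfA", "position": i + 1, "strand": strands_a[i],
            }
        )
    pos_f = 0
    element_pos = {e: 0 for e in other_elements}
    for entry in signed:
        idx = abs(entry) - 1
        g = gene_ids[idx]
        flipped = entry < 0
        strand = strands_a[idx]
        if flipped:
            strand = "-" if strand == "+" else "+"
        if g in wanderer_genes:
            elem = other_elements[int(rng.integers(0, len(other_elements)))]
            element_pos[elem] += 1
            position = element_pos[elem]
        else:
            elem = "F"
            pos_f += 1
            position = pos_f
        rows.append(
            {
                "gene_id": g, "species": "spB", "element": elem,
                "scaffold": f"scfB_{elem}", "position": position, "strand": strand,
            }
        )
    import pandas as pd

    table = OrthologTable(pd.DataFrame(rows))
    return table, reversals, wanderer_genes
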