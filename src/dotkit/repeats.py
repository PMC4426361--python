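"""Repeat-side scanners: k-mer occurrence spectra, dinucleotide-run
tables, sliding-window repeat density, and masked-fraction summaries."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from dotkit.core_io import (
    GenomicInterval,
    RepeatFragment,
    SeqRecord,
    clip_intervals,
    merge_same_class,
    overlap_bases,
    union_intervals,
)

DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")


@dataclass
class KmerSpectrum:
    """Histogram: occurrence count -> number of distinct k-mers with that
    count.  Windows containing N are excluded from scanning."""

    k: int
    histogram: dict[int, int]

    @property
    def total_windows(self) -> int:
        return sum(count * n for count, n in self.histogram.items())

    @property
    def distinct_kmers(self) -> int:
        return sum(self.histogram.values())


def kmer_spectrum(seqs: Iterable[SeqRecord] | SeqRecord, k: int = 13) -> KmerSpectrum:
    """Tally each k-mer of the given strand (no canonicalization) and
    histogram the occurrence counts."""
    if isinstance(seqs, SeqRecord):
        seqs = [seqs]
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter[str] = Counter()
    any_window = False
    for rec in seqs:
        s = rec.sequence
        if len(s) < k:
            continue
        any_window = True
        # iterate over N-free stretches only
        pos = 0
        while pos < len(s):
            n_at = s.find("N", pos)
            stretch_end = n_at if n_at != -1 else len(s)
            for i in range(pos, stretch_end - k + 1):
                counts[s[i : i + k]] += 1
            pos = stretch_end + 1
    if not any_window:
        raise ValueError(f"k={k} larger than every sequence")
    hist: Counter[int] = Counter(counts.values())
    return KmerSpectrum(k=k, histogram=dict(sorted(hist.items())))


@dataclass
class DinucRunTable:
    """Per-dinucleotide run statistics.

    ``matches[d][u]``: number of (potentially overlapping) occurrences of
    the dinucleotide d repeated u times consecutively.
    ``maximal_runs[d][u]``: number of maximal phase-aligned runs of
    exactly u units.  The cumulative (>= u) match table gets a +1
    pseudocount for semi-log plotting.
    """

    min_units: int
    max_units: int
    matches: dict[str, dict[int, int]]
    maximal_runs: dict[str, dict[int, int]]

    def cumulative_plus_one(self, dinuc: str) -> dict[int, int]:
        out: dict[int, int] = {}
        acc = 0
        for u in range(self.max_units, self.min_units - 1, -1):
            acc += self.matches[dinuc].get(u, 0)
            out[u] = acc + 1
        return dict(sorted(out.items()))


def _maximal_runs(seq: str, dinuc: str) -> list[tuple[int, int]]:
    """(start, units) of every maximal phase-aligned run of ``dinuc``
    with >= 2 units."""
    runs: list[tuple[int, int]] = []
    n = len(seq)
    for i in range(n - 1):
        if not (seq[i] == dinuc[0] and seq[i + 1] == dinuc[1]):
            continue
        # maximal start: not preceded by another unit of the same dinuc
        if i >= 2 and seq[i - 2] == dinuc[0] and seq[i - 1] == dinuc[1]:
            continue
        j = i + 2
        while j < n - 1 and seq[j] == dinuc[0] and seq[j + 1] == dinuc[1]:
            j += 2
        units = (j - i) // 2
        if units >= 2:
            runs.append((i, units))
    return runs


def scan_dinucleotide_runs(
    seq: SeqRecord | str, min_units: int = 2, max_units: int = 100
) -> DinucRunTable:
    """Tabulate dinucleotide repeats of ``min_units``..``max_units`` units.

    Overlapping matches are counted (a maximal run of L units contains
    L - u + 1 matches of u units); maximal runs are additionally tallied
    once at their exact length for planted-truth recovery.
    """
    if min_units > max_units:
        raise ValueError("min_units > max_units")
    s = seq.sequence if isinstance(seq, SeqRecord) else seq.upper()
    matches: dict[str, dict[int, int]] = {d: {} for d in DINUCLEOTIDES}
    maximal: dict[str, dict[int, int]] = {d: {} for d in DINUCLEOTIDES}
    for d in DINUCLEOTIDES:
        for _start, units in _maximal_runs(s, d):
            if units >= min_units:
                maximal[d][units] = maximal[d].get(units, 0) + 1
            for u in range(min_units, min(units, max_units) + 1):
                matches[d][u] = matches[d].get(u, 0) + (units - u + 1)
    return DinucRunTable(
        min_units=min_units, max_units=max_units, matches=matches, maximal_runs=maximal
    )


def window_density(
    fragments: Sequence[RepeatFragment],
    region: GenomicInterval,
    window: int = 1000,
    step: int = 500,
) -> list[tuple[GenomicInterval, float]]:
    """Sliding-window repeat density over a region.

    Coverage uses same-class merging followed by a cross-class union, so
    overlapping fragments never count twice.  The final partial window is
    normalized by its own length.
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    covered = union_intervals(
        [f.interval for f in merge_same_class(list(fragments))
         if f.interval.chrom == region.chrom]
    ) if fragments else []
    covered = clip_intervals(covered, region)
    out: list[tuple[GenomicInterval, float]] = []
    start = region.start
    while start < region.end:
        end = min(start + window, region.end)
        win = GenomicInterval(region.chrom, start, end)
        cov = overlap_bases([win], covered) if covered else 0
        out.append((win, cov / (end - start)))
        start += step
        if end == region.end:
            break
    return out


def masked_fraction(
    fragments: Sequence[RepeatFragment],
    region: GenomicInterval,
    by_class: bool = True,
) -> dict[str, float]:
    """Fraction of a region covered by repeats, per class and in total.

    Per-class coverage merges same-class fragments; "total" is the union
    across classes (so total <= sum of per-class fractions).
    """
    merged = merge_same_class(list(fragments)) if fragments else []
    merged = [
        RepeatFragment(iv, f.repeat_class, f.repeat_name)
        for f in merged
        for iv in clip_intervals([f.interval], region)
    ]
    L = len(region)
    out: dict[str, float] = {}
    if by_class:
        classes = sorted({f.repeat_class for f in merged})
        for c in classes:
            ivs = [f.interval for f in merged if f.repeat_class == c]
            out[c] = sum(len(iv) for iv in union_intervals(ivs)) / L
    all_ivs = [f.interval for f in merged]
    out["total"] = (
        sum(len(iv) for iv in union_intervals(all_ivs)) / L if all_ivs else 0.0
    )
    return out
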