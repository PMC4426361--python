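"""Codon-usage statistics: codon counting, Wright's effective number of
codons (Nc), the codon adaptation index (CAI) with a self-consistent
dominant-bias reference set, the no-bias CAI baseline, and a LOESS-based
slope-sign call separating selection-driven from mutation-driven bias.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

log = logging.getLogger(__name__)

# --- standard genetic code -------------------------------------------------

_std = _BioCodonTable.unambiguous_dna_by_id[1]
GENETIC_CODE: dict[str, str] = dict(_std.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_std.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))

FAMILIES: dict[str, tuple[str, ...]] = {}
for codon, aa in sorted(GENETIC_CODE.items()):
    FAMILIES.setdefault(aa, ())
    FAMILIES[aa] = FAMILIES[aa] + (codon,)

#: family-size census of the standard code: {1: 2, 2: 9, 3: 1, 4: 5, 6: 3}
FAMILY_SIZES: dict[int, int] = {}
for aa, codons in FAMILIES.items():
    FAMILY_SIZES[len(codons)] = FAMILY_SIZES.get(len(codons), 0) + 1

SINGLE_CODON_AAS = frozenset(aa for aa, c in FAMILIES.items() if len(c) == 1)  # M, W
#: codons eligible for CAI: sense codons minus single-codon families (59)
CAI_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if GENETIC_CODE[c] not in SINGLE_CODON_AAS
)


@dataclass
class CodonUsageTable:
    """Counts over the 61 sense codons (stops never appear here)."""

    counts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(SENSE_CODONS)
        if bad:
            raise ValueError(f"non-sense codons in table: {sorted(bad)}")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def family_counts(self, aa: str) -> dict[str, float]:
        return {c: self.counts.get(c, 0.0) for c in FAMILIES[aa]}

    def family_frequencies(self, aa: str) -> dict[str, float]:
        fc = self.family_counts(aa)
        tot = sum(fc.values())
        if tot == 0:
            return {c: 0.0 for c in fc}
        return {c: v / tot for c, v in fc.items()}

    def __add__(self, other: "CodonUsageTable") -> "CodonUsageTable":
        out = dict(self.counts)
        for c, v in other.counts.items():
            out[c] = out.get(c, 0.0) + v
        return CodonUsageTable(out)


def pooled_table(tables: Iterable[CodonUsageTable]) -> CodonUsageTable:
    out: dict[str, float] = {}
    for t in tables:
        for c, v in t.counts.items():
            out[c] = out.get(c, 0.0) + v
    return CodonUsageTable(out)


def count_codons(cds: str) -> tuple[CodonUsageTable, int]:
    """Count sense codons of a CDS.

    The terminal stop codon is dropped; codons containing N are skipped
    (their number is returned); an internal stop is an error.

    Returns (table, n_skipped).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    counts: dict[str, float] = {}
    skipped = 0
    for i, codon in enumerate(codons):
        if "N" in codon:
            skipped += 1
            continue
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon index {i}")
        if codon not in GENETIC_CODE:
            raise ValueError(f"invalid codon {codon!r} at codon index {i}")
        counts[codon] = counts.get(codon, 0.0) + 1.0
    if skipped:
        log.debug("count_codons: skipped %d N-containing codons", skipped)
    return CodonUsageTable(counts), skipped


# --- effective number of codons -------------------------------------------

@dataclass
class NcResult:
    nc: float
    imputed_f3: bool = False

    def __float__(self) -> float:
        return self.nc


def effective_number_of_codons(table: CodonUsageTable) -> NcResult:
    """Wright's Nc from codon counts.

    Per amino acid with n codons counted and within-family frequencies
    p_i, the homozygosity estimate is F = (n * sum(p_i^2) - 1) / (n - 1).
    Families with n <= 1 or F <= 0 are skipped.  F values are averaged
    within family-size classes and Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 6-fold
    and 3-fold terms; an unobserved 3-fold class is imputed as
    (F2 + F4) / 2.  The value is reported unclamped (it may exceed 61).
    """
    if table.total < 1:
        raise ValueError("empty codon table")
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in FAMILIES.items():
        k = len(codons)
        if k == 1:
            continue
        fc = table.family_counts(aa)
        n = sum(fc.values())
        if n <= 1:
            continue
        p2 = sum((v / n) ** 2 for v in fc.values())
        f_hat = (n * p2 - 1.0) / (n - 1.0)
        if f_hat > 0:
            f_by_class[k].append(f_hat)
    means = {k: (sum(v) / len(v) if v else None) for k, v in f_by_class.items()}
    if means[2] is None or means[4] is None or means[6] is None:
        raise ValueError("Nc undefined: a multi-codon family-size class has no usable family")
    imputed = False
    if means[3] is None:
        means[3] = (means[2] + means[4]) / 2.0
        imputed = True
    nc = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return NcResult(nc=nc, imputed_f3=imputed)


# --- CAI -------------------------------------------------------------------

@dataclass
class RelativeAdaptiveness:
    """w values per codon; the most frequent reference codon of every
    synonymous family has w = 1."""

    w: dict[str, float]

    def __post_init__(self) -> None:
        for aa, codons in FAMILIES.items():
            ws = [self.w[c] for c in codons]
            if abs(max(ws) - 1.0) > 1e-12:
                raise ValueError(f"family {aa}: max w != 1")
            if min(ws) <= 0:
                raise ValueError(f"family {aa}: non-positive w")


def relative_adaptiveness(
    reference: CodonUsageTable, zero_floor: float = 0.5
) -> RelativeAdaptiveness:
    """w(codon) = family frequency / max family frequency.

    Codons unobserved in the reference receive ``zero_floor`` counts
    before frequencies are computed, keeping every w strictly positive.
    """
    w: dict[str, float] = {}
    for aa, codons in FAMILIES.items():
        fc = reference.family_counts(aa)
        floored = {c: (v if v > 0 else zero_floor) for c, v in fc.items()}
        mx = max(floored.values())
        for c in codons:
            w[c] = floored[c] / mx
    return RelativeAdaptiveness(w)


def cai(table: CodonUsageTable, w: RelativeAdaptiveness) -> float:
    """Geometric mean of w over the gene's codons, excluding stop codons
    (absent from the table by construction) and the Met/Trp families."""
    log_sum = 0.0
    n = 0.0
    for codon, count in table.counts.items():
        if GENETIC_CODE[codon] in SINGLE_CODON_AAS:
            continue
        log_sum += count * math.log(w.w[codon])
        n += count
    if n == 0:
        raise ValueError("no CAI-eligible codons")
    return math.exp(log_sum / n)


def no_bias_cai(w: RelativeAdaptiveness) -> float:
    """CAI of a hypothetical gene using every eligible codon equally
    often: exp(mean of ln w over the 59 eligible codons).  Families are
    thereby weighted by their codon counts."""
    logs = [math.log(w.w[c]) for c in CAI_CODONS]
    return math.exp(sum(logs) / len(logs))


def select_reference_set(
    tables: Mapping[str, CodonUsageTable],
    top_fraction: float = 0.1,
    max_iter: int = 20,
) -> tuple[list[str], CodonUsageTable, bool]:
    """Self-consistent dominant-bias reference set.

    Start from w of the pooled table of all genes; repeatedly score all
    genes by CAI and re-estimate w from the pooled top ``top_fraction``
    until the selected set is stable.  Returns (gene ids, pooled
    reference table, converged flag).
    """
    if len(tables) < 10:
        raise ValueError(f"need >= 10 genes, got {len(tables)}")
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    gene_ids = sorted(tables)
    n_top = max(1, int(round(top_fraction * len(gene_ids))))
    ref = pooled_table(tables.values())
    selected: list[str] = []
    converged = False
    for _ in range(max_iter):
        w = relative_adaptiveness(ref)
        # stable sort on (-CAI, gene_id): deterministic tie-break order
        scored = sorted(gene_ids, key=lambda g: (-cai(tables[g], w), g))
        new = sorted(scored[:n_top])
        if new == selected:
            converged = True
            break
        selected = new
        ref = pooled_table(tables[g] for g in selected)
    if not converged:
        log.warning("reference-set iteration did not converge in %d rounds", max_iter)
    return selected, ref, converged


# --- LOESS regime call -----------------------------------------------------

SPAN_GRID = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95)


@dataclass
class LoessFit:
    fitted: np.ndarray
    slopes: np.ndarray
    hat_diag: np.ndarray

    @property
    def trace(self) -> float:
        return float(self.hat_diag.sum())


def _loess_local_linear(
    x: np.ndarray, y: np.ndarray, span: float, robust_weights: np.ndarray
) -> LoessFit:
    """Local-linear fit with tricube kernel at every sample point."""
    n = len(x)
    k = max(3, int(math.ceil(span * n)))
    fitted = np.empty(n)
    slopes = np.empty(n)
    hat = np.empty(n)
    order = np.argsort(x)
    xs = x[order]
    for i in range(n):
        d = np.abs(x - x[i])
        # bandwidth = distance to the k-th nearest neighbour
        h = np.partition(d, k - 1)[k - 1]
        if h <= 0:
            h = max(np.max(d) * 1e-9, 1e-12)
        u = np.clip(d / h, 0.0, 1.0)
        w = (1.0 - u**3) ** 3 * robust_weights
        sw = w.sum()
        if sw <= 0:
            fitted[i] = y[i]
            slopes[i] = 0.0
            hat[i] = 1.0
            continue
        xc = x - x[i]
        s0, s1, s2 = sw, (w * xc).sum(), (w * xc * xc).sum()
        det = s0 * s2 - s1 * s1
        if det <= 1e-300:
            fitted[i] = (w * y).sum() / sw
            slopes[i] = 0.0
            hat[i] = w[i] / sw
            continue
        # intercept row of (X'WX)^-1 X'W
        li = (s2 - s1 * xc) * w / det
        fitted[i] = float(li @ y)
        slopes[i] = float(((s0 * xc - s1) * w / det) @ y)
        hat[i] = li[i]
    return LoessFit(fitted=fitted, slopes=slopes, hat_diag=hat)


def _fit_with_robustness(
    x: np.ndarray, y: np.ndarray, span: float, robust_iters: int = 4
) -> LoessFit:
    rw = np.ones_like(y)
    fit = _loess_local_linear(x, y, span, rw)
    for _ in range(robust_iters):
        resid = y - fit.fitted
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = np.clip(resid / (6.0 * s), -1.0, 1.0)
        rw = (1.0 - u**2) ** 2
        fit = _loess_local_linear(x, y, span, rw)
    return fit


def _gcv(y: np.ndarray, fit: LoessFit) -> float:
    n = len(y)
    rss = float(np.sum((y - fit.fitted) ** 2))
    denom = n - fit.trace
    if denom <= 0:
        return math.inf
    return n * rss / denom**2


@dataclass
class RegimeCall:
    """LOESS curve of CAI on Nc plus the slope-sign verdict."""

    nc: np.ndarray
    fitted_cai: np.ndarray
    span: float
    slopes: np.ndarray
    n_negative: int
    n_positive: int
    verdict: str  # selection | mutational_bias | mixed


def loess_regime(
    nc_values: Sequence[float],
    cai_values: Sequence[float],
    span_grid: Sequence[float] = SPAN_GRID,
    majority: float = 0.6,
) -> RegimeCall:
    """Fit CAI ~ Nc by robust local-linear LOESS (span chosen by GCV)
    and call the bias regime from the sign of the local slope: mostly
    negative -> selection, mostly positive -> mutational_bias."""
    x = np.asarray(nc_values, dtype=float)
    y = np.asarray(cai_values, dtype=float)
    if len(x) < 20:
        raise ValueError("need >= 20 genes")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all Nc equal")
    best: tuple[float, float, LoessFit] | None = None
    for span in span_grid:
        fit = _fit_with_robustness(x, y, span)
        score = _gcv(y, fit)
        if best is None or score < best[0]:
            best = (score, span, fit)
    assert best is not None
    _, span, fit = best
    n_neg = int(np.sum(fit.slopes < 0))
    n_pos = int(np.sum(fit.slopes > 0))
    n = len(x)
    if n_neg > majority * n:
        verdict = "selection"
    elif n_pos > majority * n:
        verdict = "mutational_bias"
    else:
        verdict = "mixed"
    return RegimeCall(
        nc=x,
        fitted_cai=fit.fitted,
        span=span,
        slopes=fit.slopes,
        n_negative=n_neg,
        n_positive=n_pos,
        verdict=verdict,
    )
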