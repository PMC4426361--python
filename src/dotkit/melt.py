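"""Nearest-neighbor DNA melting temperatures and the metagene profile.

Tm is computed per 9-bp window (step 1 bp) from a pinned thermodynamic
parameter table shipped with the package, then gene-body tracks are
rescaled to a fixed number of bins and aggregated across genes by the
per-position median, with fixed-length flanks kept at 1-bp resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from dotkit.core_io import GeneModel, SeqRecord, revcomp

GAS_CONSTANT = 1.98717  # cal / (mol K)
DEFAULT_WINDOW = 9
DEFAULT_DNA_CONC_NM = 50.0
DEFAULT_SALT_MM = 50.0


def _load_nn_table() -> tuple[dict[str, tuple[float, float]], tuple[float, float]]:
    stacks: dict[str, tuple[float, float]] = {}
    init = (0.0, 0.0)
    text = resources.files("dotkit.data").joinpath("nn_breslauer1986.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("stack\t"):
            continue
        name, dh, ds = line.split("\t")
        if name == "init":
            init = (float(dh), float(ds))
        else:
            stacks[name] = (float(dh), float(ds))
    # fill in reverse-complement stacks
    comp = str.maketrans("ACGT", "TGCA")
    for name in list(stacks):
        rc = name.translate(comp)[::-1]
        stacks.setdefault(rc, stacks[name])
    assert len(stacks) == 16
    return stacks, init


NN_STACKS, NN_INIT = _load_nn_table()


def nn_tm(
    window: str,
    dna_conc_nm: float = DEFAULT_DNA_CONC_NM,
    salt_mm: float = DEFAULT_SALT_MM,
    length: int = DEFAULT_WINDOW,
) -> float:
    """Duplex melting temperature (deg C) of a short window.

    Tm = dH / (dS + R ln(C/4)) - 273.15 + 16.6 log10([Na+]), with dH and
    dS summed over nearest-neighbor stacks plus the initiation term from
    the shipped table.
    """
    window = window.upper()
    if len(window) != length:
        raise ValueError(f"expected {length}-mer, got length {len(window)}")
    if any(c not in "ACGT" for c in window):
        raise ValueError(f"non-ACGT character in window {window!r}")
    dh, ds = NN_INIT
    for i in range(len(window) - 1):
        h, s = NN_STACKS[window[i : i + 2]]
        dh += h
        ds += s
    conc = dna_conc_nm * 1e-9
    na = salt_mm * 1e-3
    tm_k = (dh * 1000.0) / (ds + GAS_CONSTANT * math.log(conc / 4.0))
    return tm_k - 273.15 + 16.6 * math.log10(na)


@dataclass
class TmTrack:
    """One Tm per window start (step 1); NaN marks N-containing windows."""

    chrom: str
    start: int
    values: np.ndarray


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_STACK_DH = np.zeros(16)
_STACK_DS = np.zeros(16)
for _st, (_h, _s) in NN_STACKS.items():
    _idx = _BASE_CODE[ord(_st[0])] * 4 + _BASE_CODE[ord(_st[1])]
    _STACK_DH[_idx] = _h
    _STACK_DS[_idx] = _s


def _tm_values(seq: str, window: int, dna_conc_nm: float, salt_mm: float) -> np.ndarray:
    """Vectorized sliding-window Tm; windows containing N are NaN.

    Matches ``nn_tm`` exactly on N-free windows (same table, same
    formula, evaluated with cumulative sums instead of a per-window
    loop).
    """
    n = len(seq) - window + 1
    if n <= 0:
        return np.full(0, np.nan)
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    valid = codes >= 0
    safe = np.where(valid, codes, 0)
    stacks = safe[:-1] * 4 + safe[1:]
    stack_ok = valid[:-1] & valid[1:]
    dh = np.where(stack_ok, _STACK_DH[stacks], 0.0)
    ds = np.where(stack_ok, _STACK_DS[stacks], 0.0)
    k = window - 1  # stacks per window
    csum_h = np.concatenate([[0.0], np.cumsum(dh)])
    csum_s = np.concatenate([[0.0], np.cumsum(ds)])
    csum_ok = np.concatenate([[0], np.cumsum(stack_ok.astype(np.int64))])
    win_h = csum_h[k:] - csum_h[:-k] + NN_INIT[0]
    win_s = csum_s[k:] - csum_s[:-k] + NN_INIT[1]
    win_ok = (csum_ok[k:] - csum_ok[:-k]) == k
    conc = dna_conc_nm * 1e-9
    na = salt_mm * 1e-3
    with np.errstate(invalid="ignore", divide="ignore"):
        tm = (win_h * 1000.0) / (win_s + GAS_CONSTANT * math.log(conc / 4.0))
    tm = tm - 273.15 + 16.6 * math.log10(na)
    return np.where(win_ok, tm, np.nan)[:n]


def tm_track(
    genome: SeqRecord,
    start: int = 0,
    end: int | None = None,
    window: int = DEFAULT_WINDOW,
    dna_conc_nm: float = DEFAULT_DNA_CONC_NM,
    salt_mm: float = DEFAULT_SALT_MM,
) -> TmTrack:
    end = len(genome) if end is None else end
    if end - start < window:
        raise ValueError(f"region shorter than window ({end - start} < {window})")
    seq = genome.sequence[start:end]
    return TmTrack(
        chrom=genome.id,
        start=start,
        values=_tm_values(seq, window, dna_conc_nm, salt_mm),
    )


def rebin_track(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Average a 1-bp track into ``n_bins`` equal-width bins.

    Fractional bin boundaries are handled by coverage weighting, so the
    mean over bins equals the mean of the raw track exactly (mass
    conservation).  NaN positions carry zero weight; an all-NaN bin is
    NaN.
    """
    m = len(values)
    if m == 0:
        return np.full(n_bins, np.nan)
    edges = np.linspace(0.0, m, n_bins + 1)
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        i0, i1 = int(math.floor(lo)), int(math.ceil(hi))
        idx = np.arange(i0, min(i1, m))
        w = np.minimum(idx + 1.0, hi) - np.maximum(idx.astype(float), lo)
        v = values[idx]
        ok = ~np.isnan(v)
        if np.any(ok):
            out[b] = float(np.sum(w[ok] * v[ok]) / np.sum(w[ok]))
    return out


@dataclass
class MetageneProfile:
    """Median Tm per position: fixed flanks at 1-bp resolution, body
    rescaled to ``body_bins`` bins.  ``n_genes`` counts the genes with a
    defined value at each position."""

    upstream: np.ndarray
    body: np.ndarray
    downstream: np.ndarray
    n_upstream: np.ndarray
    n_body: np.ndarray
    n_downstream: np.ndarray
    n_genes_total: int


def gene_profile(
    model: GeneModel,
    genome: SeqRecord,
    flank: int = 2000,
    body_bins: int = 3000,
    window: int = DEFAULT_WINDOW,
    dna_conc_nm: float = DEFAULT_DNA_CONC_NM,
    salt_mm: float = DEFAULT_SALT_MM,
    orient: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(upstream[flank], body_bins, downstream[flank]) Tm vectors for one
    gene, read 5'->3' on the coding strand when ``orient`` is set.

    Flank positions beyond the sequence ends, N windows, and the final
    ``window - 1`` downstream positions (whose windows do not exist) are
    NaN.
    """
    span = model.span
    ext_start = span.start - flank
    ext_end = span.end + flank
    lo = max(ext_start, 0)
    hi = min(ext_end, len(genome))
    seq = "N" * (lo - ext_start) + genome.sequence[lo:hi] + "N" * (ext_end - hi)
    if orient and model.strand == "-":
        seq = revcomp(seq)
    vals = _tm_values(seq, window, dna_conc_nm, salt_mm)
    # pad so every window-start position up to ext length has an entry
    track = np.concatenate([vals, np.full(window - 1, np.nan)])
    upstream = track[:flank]
    body = track[flank : flank + len(span)]
    downstream = track[flank + len(span) : flank + len(span) + flank]
    return upstream, rebin_track(body, body_bins), downstream


def metagene(
    genes: Sequence[GeneModel],
    genome: SeqRecord,
    flank: int = 2000,
    body_bins: int = 3000,
    window: int = DEFAULT_WINDOW,
    dna_conc_nm: float = DEFAULT_DNA_CONC_NM,
    salt_mm: float = DEFAULT_SALT_MM,
    orient: bool = True,
) -> MetageneProfile:
    """Median-aggregate per-gene Tm profiles into a metagene."""
    eligible = [g for g in genes if len(g.span) >= window]
    if not eligible:
        raise ValueError("no genes with span >= window")
    ups, bods, downs = [], [], []
    for g in eligible:
        u, b, d = gene_profile(
            g, genome, flank, body_bins, window, dna_conc_nm, salt_mm, orient
        )
        ups.append(u)
        bods.append(b)
        downs.append(d)
    u = np.vstack(ups)
    b = np.vstack(bods)
    d = np.vstack(downs)

    def _agg(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = np.sum(~np.isnan(mat), axis=0)
        med = np.full(mat.shape[1], np.nan)
        cols = np.nonzero(n > 0)[0]
        if len(cols):
            med[cols] = np.nanmedian(mat[:, cols], axis=0)
        return med, n

    mu, nu = _agg(u)
    mb, nb = _agg(b)
    md, nd = _agg(d)
    return MetageneProfile(
        upstream=mu,
        body=mb,
        downstream=md,
        n_upstream=nu,
        n_body=nb,
        n_downstream=nd,
        n_genes_total=len(eligible),
    )
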