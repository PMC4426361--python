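"""Per-gene architecture features (most comprehensive isoform) and the
rank-based group-comparison statistics used to contrast gene cohorts."""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dotkit.core_io import (
    GeneModel,
    RepeatFragment,
    overlap_bases,
    union_intervals,
)

log = logging.getLogger(__name__)

FEATURE_COLUMNS = (
    "coding_span",
    "intron_repeat_size",
    "coding_region_size",
    "n_coding_exons",
    "median_coding_exon_size",
    "median_intron_size",
    "nc",
    "cai",
)


@dataclass
class GeneFeatureVector:
    """The eight per-gene characteristics feeding the multivariate stage."""

    gene_id: str
    coding_span: int
    intron_repeat_size: int
    coding_region_size: int
    n_coding_exons: int
    median_coding_exon_size: float
    median_intron_size: float
    nc: float
    cai: float
    single_exon: bool = False

    def __post_init__(self) -> None:
        if self.coding_span < self.coding_region_size:
            raise ValueError(f"{self.gene_id}: span < coding region")
        if self.n_coding_exons < 1:
            raise ValueError(f"{self.gene_id}: no exons")


def select_comprehensive_isoform(
    models: Sequence[GeneModel],
) -> dict[str, GeneModel]:
    """Per gene, the isoform with the largest coding region; ties break
    to the lexicographically smallest transcript_id (logged)."""
    best: dict[str, GeneModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if cur is None:
            best[m.gene_id] = m
            continue
        if m.coding_region_size > cur.coding_region_size:
            best[m.gene_id] = m
        elif m.coding_region_size == cur.coding_region_size and m.transcript_id < cur.transcript_id:
            log.info(
                "gene %s: isoform size tie, keeping %s over %s",
                m.gene_id, m.transcript_id, cur.transcript_id,
            )
            best[m.gene_id] = m
    return best


def extract_features(
    model: GeneModel,
    repeats: Sequence[RepeatFragment],
    nc: float,
    cai: float,
) -> GeneFeatureVector:
    """Build the eight-characteristic vector for one gene.

    intron_repeat_size is the coverage of the cross-class union of
    repeat fragments clipped to the introns (a base inside two repeat
    classes counts once).  Single-exon genes record median_intron_size 0
    with a flag rather than a missing value.
    """
    span = model.span
    introns = model.introns
    if introns and repeats:
        rep_union = union_intervals([f.interval for f in repeats])
        intron_repeat = overlap_bases(introns, rep_union)
    else:
        intron_repeat = 0
    exon_sizes = [len(ex) for ex in model.coding_exons]
    single = len(model.coding_exons) == 1
    return GeneFeatureVector(
        gene_id=model.gene_id,
        coding_span=len(span),
        intron_repeat_size=intron_repeat,
        coding_region_size=model.coding_region_size,
        n_coding_exons=len(model.coding_exons),
        median_coding_exon_size=float(statistics.median(exon_sizes)),
        median_intron_size=0.0 if single else float(
            statistics.median([len(iv) for iv in introns])
        ),
        nc=nc,
        cai=cai,
        single_exon=single,
    )


def feature_table(vectors: Sequence[GeneFeatureVector]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": v.gene_id,
            **{c: getattr(v, c) for c in FEATURE_COLUMNS},
            "single_exon": v.single_exon,
        }
        for v in vectors
    ]
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# Kruskal-Wallis and post-hoc comparisons

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis rank-sum test with mid-rank tie correction.

    Returns (H, df, p) with p from the chi-square approximation.  When
    every observation is identical the tie-corrected H is defined as 0
    with p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    h = 12.0 / (n_total * (n_total + 1)) * sum(
        np.sum(ranks[offset : offset + s]) ** 2 / s
        for offset, s in zip(np.cumsum([0] + sizes[:-1]), sizes)
    ) - 3.0 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n_total**3 - n_total)
    df = len(groups) - 1
    if tie_term == 0.0:  # all observations identical
        return 0.0, df, 1.0
    h /= tie_term
    return float(h), df, float(stats.chi2.sf(h, df))


def kw_posthoc(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise multiple comparisons after Kruskal-Wallis.

    Pair (i, j) is significant when the absolute mean-rank difference
    exceeds z(1 - alpha / (k (k - 1))) * sqrt(N (N + 1) / 12 *
    (1/n_i + 1/n_j)) — the Siegel-Castellan critical difference.
    """
    if not isinstance(groups, Mapping):
        groups = {f"g{i}": g for i, g in enumerate(groups)}
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    sizes = [len(a) for a in arrays]
    if any(s == 0 for s in sizes):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    offset = 0
    for s in sizes:
        mean_ranks.append(float(np.mean(ranks[offset : offset + s])))
        offset += s
    k = len(names)
    z = stats.norm.ppf(1.0 - alpha / (k * (k - 1)))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            obs = abs(mean_ranks[i] - mean_ranks[j])
            crit = z * np.sqrt(
                n_total * (n_total + 1) / 12.0 * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "obs_diff": obs,
                    "critical_diff": float(crit),
                    "significant": bool(obs > crit),
                }
            )
    return pd.DataFrame(rows)
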