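"""Stage orchestration: run the scanners over configured analysis
regions and emit deterministic TSV/JSON reports."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from dotkit import codon as codon_mod
from dotkit import genes as genes_mod
from dotkit import melt as melt_mod
from dotkit import outliers as outliers_mod
from dotkit import repeats as repeats_mod
from dotkit import synteny as synteny_mod
from dotkit.core_io import (
    GenomicInterval,
    read_bed12,
    read_fasta,
    read_repeat_bed,
    read_repeatmasker_out,
)

log = logging.getLogger(__name__)

STAGES = ("repeats", "genes", "codon", "melt", "outliers", "synteny")

DEFAULT_PARAMS: dict[str, Any] = {
    "window": 1000,          # repeat-density window (bp)
    "step": 500,             # repeat-density step (bp)
    "kmer_k": 13,
    "run_min_units": 2,
    "run_max_units": 100,
    "tm_window": 9,
    "dna_conc_nm": 50.0,
    "salt_mm": 50.0,
    "flank": 2000,
    "body_bins": 3000,
    "chi2_quantile": 0.975,
    "n_features": 8,
    "top_fraction": 0.1,
    "sd_seed": 0,
    "orient_metagene": True,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


@dataclass
class RegionSpec:
    label: str
    fasta: Path
    genes: Path | None = None
    repeats: Path | None = None
    orthologs: Path | None = None

    @classmethod
    def from_dict(cls, d: Mapping[str, Any], base: Path) -> "RegionSpec":
        def p(key):
            return (base / d[key]) if key in d and d[key] else None

        if "label" not in d or "fasta" not in d:
            raise ValueError("region needs 'label' and 'fasta'")
        return cls(
            label=str(d["label"]),
            fasta=base / d["fasta"],
            genes=p("genes"),
            repeats=p("repeats"),
            orthologs=p("orthologs"),
        )


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def _load_repeats(path: Path):
    if path.suffix == ".out":
        return read_repeatmasker_out(path)
    return read_repeat_bed(path)


def _codon_stats(region: RegionSpec, params: Mapping[str, Any]):
    genome = read_fasta(region.fasta)[0]
    models = read_bed12(region.genes)
    chosen = genes_mod.select_comprehensive_isoform(models)
    tables: dict[str, codon_mod.CodonUsageTable] = {}
    skipped: dict[str, int] = {}
    for gid, model in sorted(chosen.items()):
        cds = model.extract_cds(genome)
        tables[gid], skipped[gid] = codon_mod.count_codons(cds)
    ref_ids, ref_table, converged = codon_mod.select_reference_set(
        tables, top_fraction=float(params["top_fraction"])
    )
    w = codon_mod.relative_adaptiveness(ref_table)
    rows = []
    for gid, table in sorted(tables.items()):
        try:
            nc_res = codon_mod.effective_number_of_codons(table)
            nc_val, imputed = nc_res.nc, nc_res.imputed_f3
        except ValueError:  # gene too short to populate a family-size class
            nc_val, imputed = float("nan"), False
        rows.append(
            {
                "gene_id": gid,
                "n_codons": int(table.total),
                "nc": nc_val,
                "nc_f3_imputed": imputed,
                "cai": codon_mod.cai(table, w),
                "in_reference_set": gid in set(ref_ids),
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    return genome, chosen, df, w, ref_ids, converged


def run_pipeline(
    config: Mapping[str, Any], outdir: str | Path, base_dir: str | Path = "."
) -> dict[str, Any]:
    """Execute the configured stages for every region.

    Returns a summary dict (also written to ``summary.json``).  Any
    stage failure aborts with a :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir)
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params", {}))
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    regions = [RegionSpec.from_dict(r, base) for r in config.get("regions", [])]
    if not regions:
        raise ValueError("no regions configured")
    labels = [r.label for r in regions]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate region labels")

    summary: dict[str, Any] = {"seed": seed, "params": params, "regions": {}}
    for region in regions:
        rsum: dict[str, Any] = {}
        rdir = outdir / region.label
        rdir.mkdir(parents=True, exist_ok=True)
        if not region.fasta.exists():
            raise PipelineError("input", f"missing FASTA {region.fasta}")

        codon_cache = None

        def codon_stats():
            nonlocal codon_cache
            if codon_cache is None:
                if region.genes is None or not region.genes.exists():
                    raise PipelineError(
                        "codon", f"region {region.label}: missing gene file"
                    )
                codon_cache = _codon_stats(region, params)
            return codon_cache

        if "repeats" in stages:
            if region.repeats is None or not region.repeats.exists():
                raise PipelineError(
                    "repeats", f"region {region.label}: missing repeat file"
                )
            try:
                genome = read_fasta(region.fasta)[0]
                frags = _load_repeats(region.repeats)
                whole = GenomicInterval(genome.id, 0, len(genome))
                dens = repeats_mod.window_density(
                    frags, whole, int(params["window"]), int(params["step"])
                )
                _write_tsv(
                    pd.DataFrame(
                        [
                            {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                             "density": d}
                            for iv, d in dens
                        ]
                    ),
                    rdir / "repeat_density.tsv",
                )
                frac = repeats_mod.masked_fraction(frags, whole)
                _write_tsv(
                    pd.DataFrame(
                        [{"repeat_class": k, "fraction": v} for k, v in sorted(frac.items())]
                    ),
                    rdir / "masked_fraction.tsv",
                )
                spec = repeats_mod.kmer_spectrum(genome, int(params["kmer_k"]))
                _write_tsv(
                    pd.DataFrame(
                        [{"count": c, "n_kmers": m} for c, m in sorted(spec.histogram.items())]
                    ),
                    rdir / "kmer_spectrum.tsv",
                )
                runs = repeats_mod.scan_dinucleotide_runs(
                    genome, int(params["run_min_units"]), int(params["run_max_units"])
                )
                rows = []
                for d in repeats_mod.DINUCLEOTIDES:
                    cum = runs.cumulative_plus_one(d)
                    for u in range(runs.min_units, runs.max_units + 1):
                        rows.append(
                            {
                                "dinucleotide": d,
                                "units": u,
                                "matches": runs.matches[d].get(u, 0),
                                "cumulative_plus_1": cum[u],
                            }
                        )
                _write_tsv(pd.DataFrame(rows), rdir / "dinucleotide_runs.tsv")
                rsum["repeats"] = {"masked_fraction": frac}
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("repeats", f"{region.label}: {exc}") from exc

        if "codon" in stages:
            try:
                _, _, df, w, ref_ids, converged = codon_stats()
                _write_tsv(df, rdir / "codon_stats.tsv", index=True)
                usage_rows = [
                    {
                        "codon": c,
                        "aa": codon_mod.GENETIC_CODE[c],
                        "w": w.w[c],
                    }
                    for c in codon_mod.SENSE_CODONS
                ]
                _write_tsv(pd.DataFrame(usage_rows), rdir / "relative_adaptiveness.tsv")
                regime: dict[str, Any] = {
                    "reference_set": list(ref_ids),
                    "reference_converged": bool(converged),
                    "no_bias_cai": codon_mod.no_bias_cai(w),
                }
                finite = df[df["nc"].notna()]
                if len(finite) >= 20:
                    call = codon_mod.loess_regime(finite["nc"].values, finite["cai"].values)
                    regime.update(
                        {
                            "span": call.span,
                            "verdict": call.verdict,
                            "n_negative_slope": call.n_negative,
                            "n_positive_slope": call.n_positive,
                        }
                    )
                else:
                    regime["verdict"] = None
                _write_json(regime, rdir / "codon_regime.json")
                rsum["codon"] = {"verdict": regime.get("verdict")}
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("codon", f"{region.label}: {exc}") from exc

        if "genes" in stages:
            try:
                genome, chosen, df, _, _, _ = codon_stats()
                frags = (
                    _load_repeats(region.repeats)
                    if region.repeats and region.repeats.exists()
                    else []
                )
                usable = set(df[df["nc"].notna()].index)
                vectors = [
                    genes_mod.extract_features(
                        model, frags, df.loc[gid, "nc"], df.loc[gid, "cai"]
                    )
                    for gid, model in sorted(chosen.items())
                    if gid in usable
                ]
                ftable = genes_mod.feature_table(vectors)
                _write_tsv(ftable, rdir / "gene_features.tsv", index=True)
                rsum["genes"] = {"n_genes": len(ftable)}
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("genes", f"{region.label}: {exc}") from exc

        if "melt" in stages:
            try:
                genome, chosen, _, _, _, _ = codon_stats()
                profile = melt_mod.metagene(
                    list(chosen.values()),
                    genome,
                    flank=int(params["flank"]),
                    body_bins=int(params["body_bins"]),
                    window=int(params["tm_window"]),
                    dna_conc_nm=float(params["dna_conc_nm"]),
                    salt_mm=float(params["salt_mm"]),
                    orient=bool(params["orient_metagene"]),
                )
                rows = []
                for section, vals, ns in (
                    ("upstream", profile.upstream, profile.n_upstream),
                    ("body", profile.body, profile.n_body),
                    ("downstream", profile.downstream, profile.n_downstream),
                ):
                    for i, (v, n) in enumerate(zip(vals, ns)):
                        rows.append(
                            {
                                "section": section,
                                "index": i,
                                "median_tm": v if np.isfinite(v) else "",
                                "n_genes": int(n),
                            }
                        )
                _write_tsv(pd.DataFrame(rows), rdir / "tm_metagene.tsv")
                rsum["melt"] = {"n_genes": profile.n_genes_total}
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("melt", f"{region.label}: {exc}") from exc

        if "outliers" in stages:
            try:
                genome, chosen, df, _, _, _ = codon_stats()
                frags = (
                    _load_repeats(region.repeats)
                    if region.repeats and region.repeats.exists()
                    else []
                )
                usable = set(df[df["nc"].notna()].index)
                vectors = [
                    genes_mod.extract_features(
                        model, frags, df.loc[gid, "nc"], df.loc[gid, "cai"]
                    )
                    for gid, model in sorted(chosen.items())
                    if gid in usable
                ]
                ftable = genes_mod.feature_table(vectors)
                fcols = list(genes_mod.FEATURE_COLUMNS)
                raw = ftable[fcols].values.astype(float)
                keep = raw.std(axis=0, ddof=1) > 0
                dropped = [c for c, k in zip(fcols, keep) if not k]
                if dropped:
                    log.warning(
                        "%s: dropping constant feature columns %s", region.label, dropped
                    )
                X = outliers_mod.standardize(raw[:, keep])
                md = outliers_mod.mahalanobis(X)
                sd = outliers_mod.stahel_donoho(X, seed=int(params["sd_seed"]))
                res = outliers_mod.dd_classify(
                    md, sd.rd, p=X.shape[1], quantile=float(params["chi2_quantile"])
                )
                _write_tsv(res.to_frame(index=ftable.index), rdir / "distance_distance.tsv",
                           index=True)
                _write_json(
                    {
                        "cutoff": res.cutoff,
                        "n_outlier_md": int(res.outlier_md.sum()),
                        "n_outlier_rd": int(res.outlier_rd.sum()),
                        "seed": int(params["sd_seed"]),
                        "dropped_constant_features": dropped,
                        "p": int(X.shape[1]),
                    },
                    rdir / "distance_distance.json",
                )
                rsum["outliers"] = {"n_outlier_rd": int(res.outlier_rd.sum())}
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("outliers", f"{region.label}: {exc}") from exc

        if "synteny" in stages and region.orthologs is not None:
            try:
                table = synteny_mod.OrthologTable.read_tsv(region.orthologs)
                report = synteny_mod.find_wanderers(table)
                species = table.species
                pair_reports = {}
                for a, b in [
                    (x, y) for i, x in enumerate(species) for y in species[i + 1:]
                ]:
                    order, shared = synteny_mod.shared_signed_order(table, a, b)
                    blocks, mean_size = synteny_mod.syntenic_blocks(order)
                    dist = synteny_mod.reversal_distance(order)
                    scenario = synteny_mod.reversal_scenario(order)
                    pair_reports[f"{a}|{b}"] = {
                        "n_shared": len(shared),
                        "signed_order": order,
                        "n_blocks": len(blocks),
                        "mean_block_size": mean_size,
                        "reversal_distance": dist,
                        "scenario": [list(s) for s in scenario],
                    }
                _write_json(
                    {
                        "pairs": pair_reports,
                        "wanderers": report.wanderers.to_dict("records"),
                        "other_moves": report.other_moves.to_dict("records"),
                        "unplaced": report.unplaced.to_dict("records"),
                    },
                    rdir / "synteny.json",
                )
                rsum["synteny"] = {
                    k: v["reversal_distance"] for k, v in pair_reports.items()
                }
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("synteny", f"{region.label}: {exc}") from exc

        summary["regions"][region.label] = rsum

    _write_json(summary, outdir / "summary.json")
    return summary
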