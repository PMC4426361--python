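"""Demo dataset materialization: two contrasting synthetic regions (a
repeat-dense, large-gene "F-like" region and a euchromatic "D-like"
reference) plus a two-species ortholog table, with truth tables and a
ready-to-run pipeline config."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from dotkit.core_io import write_bed12, write_fasta, write_repeat_bed
from dotkit.synthio import (
    SynthConfig,
    default_transposon_library,
    generate_ortholog_table,
    generate_region,
)


def f_like_config(seed: int, region_length: int, n_genes: int) -> SynthConfig:
    """Repeat-dense region: ~35% transposons, long genes, biased runs."""
    return SynthConfig(
        seed=seed,
        region_id="F_synth",
        region_length=region_length,
        background_gc=0.35,
        transposon_library=default_transposon_library(),
        target_transposon_density=0.30,
        dinucleotide_runs=(("CA", 15, 3), ("AT", 20, 3)),
        n_genes=n_genes,
        exon_count_distribution={"kind": "poisson", "lam": 3.0, "min": 1},
        exon_size_distribution={"kind": "uniform_int", "low": 120, "high": 400},
        intron_size_distribution={"kind": "uniform_int", "low": 150, "high": 800},
        codon_regime=0.1,
    )


def d_like_config(seed: int, region_length: int, n_genes: int) -> SynthConfig:
    """Euchromatic reference: ~6% transposons, compact genes, high bias."""
    return SynthConfig(
        seed=seed + 1,
        region_id="D_synth",
        region_length=region_length,
        background_gc=0.45,
        transposon_library=default_transposon_library(),
        target_transposon_density=0.06,
        dinucleotide_runs=(("CA", 8, 3),),
        n_genes=n_genes,
        exon_count_distribution={"kind": "poisson", "lam": 2.0, "min": 1},
        exon_size_distribution={"kind": "uniform_int", "low": 80, "high": 300},
        intron_size_distribution={"kind": "uniform_int", "low": 60, "high": 300},
        codon_regime=0.6,
    )


def write_region(cfg: SynthConfig, outdir: Path, label: str) -> dict:
    genome, models, lambdas = generate_region(cfg)
    write_fasta([genome.record], outdir / f"{label}.fasta")
    write_bed12(models, outdir / f"{label}.genes.bed")
    write_repeat_bed(genome.repeats, outdir / f"{label}.repeats.bed")
    truth = pd.DataFrame(
        [
            {"gene_id": gid, "true_lambda": lam, "strand": m.strand,
             "n_exons": len(m.coding_exons)}
            for (gid, lam), m in zip(sorted(lambdas.items()), models)
        ]
    )
    truth.to_csv(outdir / f"{label}.gene_truth.tsv", sep="\t", index=False,
                 lineterminator="\n")
    runs = pd.DataFrame(
        [
            {"dinucleotide": r.dinucleotide, "units": r.units,
             "start": r.interval.start, "end": r.interval.end}
            for r in genome.runs
        ]
    )
    runs.to_csv(outdir / f"{label}.run_truth.tsv", sep="\t", index=False,
                lineterminator="\n")
    return {
        "label": label,
        "fasta": f"{label}.fasta",
        "genes": f"{label}.genes.bed",
        "repeats": f"{label}.repeats.bed",
    }


def write_demo_dataset(
    outdir: Path, seed: int = 1, n_genes: int = 30, region_length: int = 150_000
) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    regions = [
        write_region(f_like_config(seed, region_length, n_genes), outdir, "F"),
        write_region(d_like_config(seed, region_length, n_genes), outdir, "D_base"),
    ]
    ortho_cfg = SynthConfig(seed=seed + 2, n_genes=40, n_reversals=5, n_wanderers=2)
    table, reversals, wanderers = generate_ortholog_table(ortho_cfg)
    table.write_tsv(outdir / "orthologs.tsv")
    pd.DataFrame(
        {"reversal_start": [i for i, _ in reversals],
         "reversal_end": [j for _, j in reversals]}
    ).to_csv(outdir / "ortholog_truth_reversals.tsv", sep="\t", index=False,
             lineterminator="\n")
    pd.DataFrame({"wanderer_gene": sorted(wanderers)}).to_csv(
        outdir / "ortholog_truth_wanderers.tsv", sep="\t", index=False,
        lineterminator="\n",
    )
    regions[0]["orthologs"] = "orthologs.tsv"
    config = {
        "seed": seed,
        "stages": ["repeats", "genes", "codon", "melt", "outliers", "synteny"],
        "params": {"body_bins": 300, "flank": 500},
        "regions": regions,
    }
    cfg_path = outdir / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config, sort_keys=False))
    return cfg_path
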