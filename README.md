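# dotkit

A toolkit for the comparative characterization of repeat-dense genomic
regions (such as the *Drosophila* dot chromosome) against euchromatic
reference regions. It bundles the analysis stages such a comparison
needs, exercised end-to-end on synthetic genomes with planted,
recoverable ground truth:

- **`core_io`** — domain types (sequences, intervals, repeat fragments,
  coding-exon gene models), interval algebra (class-aware merging,
  union/intersection coverage), and readers/writers for FASTA, BED12,
  BED6+class, and RepeatMasker `.out`. All internal coordinates are
  0-based half-open.
- **`synthio`** — seeded generators for synthetic chromosomes
  (background GC, planted transposon fragments to a target density,
  guarded dinucleotide runs), gene models with configurable
  exon/intron-size distributions and codon-mixture regimes, per-gene
  codon-usage cohorts, and two-species ortholog tables related by a
  known number of signed reversals plus "wanderer" gene moves.
- **`repeats`** — k-mer occurrence spectra (default k=13),
  dinucleotide-run tables (overlapping matches and maximal runs, 2–100
  units, with the +1-pseudocount cumulative form), sliding-window
  repeat density (1 kb window / 500 bp step), and masked-fraction
  summaries with same-class merging before cross-class union.
- **`genes`** — the eight per-gene characteristics of the most
  comprehensive isoform (coding span, intron repeat size, coding region
  size, exon count, median exon/intron size, Nc, CAI), plus the
  Kruskal-Wallis rank-sum test with tie correction and the
  Siegel-Castellan multiple-comparison procedure.
- **`codon`** — codon counting, Wright's effective number of codons,
  relative adaptiveness with a 0.5 zero-count floor, CAI, the no-bias
  CAI baseline, a self-consistent dominant-bias reference-set
  iteration, and a robust local-linear LOESS (span by GCV) whose slope
  sign calls the bias regime (selection vs. mutational bias).
- **`melt`** — nearest-neighbor 9-bp melting temperatures from a pinned
  thermodynamic table (Breslauer 1986 parameters shipped in
  `dotkit/data/`), per-gene Tm tracks, and the metagene profile with
  2-kb flanks and a 3000-bin body normalization (median-aggregated).
- **`outliers`** — column standardization, classical Mahalanobis
  distance, the Stahel-Donoho robust distance via projection-pursuit
  outlyingness, and chi-square-cutoff Distance-Distance classification
  (cutoff sqrt(chi2 0.975, 8 df) = 4.19).
- **`synteny`** — wanderer-gene detection and hotspot windows, syntenic
  block statistics, the exact Hannenhalli-Pevzner signed reversal
  distance (cycles, hurdles, fortress) with scenario reconstruction,
  and a vectorized breadth-first-search oracle for small n.
- **`pipeline` / `cli`** — YAML/TOML-configured orchestration of all
  stages over one or more analysis regions with deterministic TSV/JSON
  outputs.

## CLI

Materialize a complete synthetic demo dataset (two contrasting regions
plus an ortholog table and a ready-to-run config):

```sh
dotkit fixtures --outdir demo --seed 1
dotkit all --config demo/config.yaml --outdir demo/out
```

Individual stages run the same way (`dotkit repeats|genes|codon|melt|
outliers|synteny --config ... --outdir ...`). Every analysis parameter
(window=1000, step=500, k=13, Tm window=9, flank=2000, body_bins=3000,
chi-square quantile=0.975, ...) is a named config key under `params:`.
Re-running with the same config and seed reproduces byte-identical
outputs. Exit codes: 0 ok, 1 user error, 2 internal error.

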