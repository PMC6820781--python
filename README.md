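# famex

A toolkit for characterizing unstable TTTTA/TTTCA pentanucleotide repeat
expansions from single-molecule and short-read data:

- **repeat decomposition** (`famex.decompose`) — anchor a long read at a
  configured locus via flank alignment and decompose the expansion into
  exact motif runs and gaps, with per-motif-class sizes, dot plots, and
  per-individual summaries;
- **short-read screening** (`famex.screen`) — classify 150-bp reads
  (spanning / anchored in-repeat / fully in-repeat), cluster spanning unit
  counts into alleles, and call expansions;
- **combing analysis** (`famex.combing`) — classify fiber-FISH signal
  patterns (B/Y/R/W/G tokens) into normal / undefined / pathogenic alleles,
  size expansions as `Yp − Yn + R + W` against a per-individual baseline,
  assign configurations C1–C6, flag micro-rearrangements, and summarize per
  individual (including the per-allele → per-cell rearrangement
  conversion);
- **haplotype dating** (`famex.dating`) — generations to the MRCA from the
  genetic length of a shared core haplotype (Gamma/exponential breakpoint
  model with an exact chi-square interval);
- **phenotype statistics** (`famex.phenostats`) — Pearson correlations with
  Fisher-z intervals over onset ages and expansion-part sizes (a packaged
  10-individual cohort table is included), plus ΔΔCt relative expression
  with a rank-sum group comparison;
- **synthetic data** (`famex.simulate`) — seeded generators for somatic
  allele populations, noisy long reads, paired short reads, combing
  measurement tables, and phenotype cohorts, all with truth tables so every
  stage is testable offline.

## Command line

The `famex` entry point exposes one subcommand per stage:

```sh
famex simulate longreads --seed 1 --n-cells 50 --n-reads 20 --out reads.fastq
famex decompose --reads reads.fastq --out decomp.tsv
famex simulate combing --seed 1 --n-cells 100 --out comb.tsv
famex comb --measurements comb.tsv --out-alleles alleles.tsv --out-summary summary.tsv
famex screen --reads R1.fastq,R2.fastq --out screen.tsv
famex date --cm 0.35 --lineages 2 --gen-years 20
famex correlate --out corr.tsv            # packaged cohort table by default
famex expression --ct ct.tsv --controls c1,c2 --out expr.tsv
famex run --config pipeline.json          # full simulate -> analyze pipeline
```

`famex run` takes a JSON config (`locus`, `seed`, `outdir`, per-stage
parameter blocks; unknown keys rejected) and writes every stage's TSV plus
a manifest with the config hash and seed. Custom loci are JSON files with
flank sequences, motifs, reference coordinates, and classification
thresholds (see `famex.locus.LocusConfig`).

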