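# oncotrace

Longitudinal multi-sample tumor DNA+RNA analysis, built as a tested,
reusable pipeline with a first-class synthetic-data generator:

- **simulate** — seeded miniature multi-sample tumor dataset (one normal,
  a diagnostic metastasis, four primary-tumor sections, an index
  metastasis): DNA pileups with founder and index-private mutations,
  window coverage and heterozygous-site counts over a near-tetraploid
  genome with LOH, gain, a focal hemizygous deletion and a
  chromothripsis-like oscillating region, structural junctions, RNA gene
  and allele counts, and a two-condition perturbation expression matrix.
  Every output is byte-reproducible from one integer seed, with a full
  ground-truth table.
- **somatic** — paired tumor/normal small-variant calling with a binomial
  log-likelihood-ratio somatic score, panel-of-normals filtering, coding
  annotation, VCF output, and mutation-rate-per-Mb arithmetic.
- **validation** — the ultra-deep amplicon presence rule (strictly >5
  variant reads and >1% variant fraction) and shared / private-to-index /
  partial timeline classification.
- **cnv** — windowed tumor/normal log2 coverage ratios, circular binary
  segmentation (recursive max-t arcs with permutation significance),
  lesser allele fraction, LOH/gain/loss flags, and fine-scale focal
  deletion detection with base-level breakpoint refinement.
- **rearrange** — junction typing from endpoint orientations and
  chromothripsis-like region scoring (junction density, major copy-number
  states, oscillations).
- **expression** — RPKM, RNA mutant-allele fraction, and expressed-driver
  classification of mutated genes (candidate requires expression and a
  mutant transcript fraction above 30% in all required samples).
- **enrichment** — perturbation response statistics CE_T = log2 X_T −
  log2 X_0 and DCE_T = CE_mt − CE_wt, gene ranking, and a weighted
  Kolmogorov–Smirnov gene-set enrichment test with gene-label
  permutations, NES, permutation p-values, and an NES-ratio FDR.

## CLI

All stages are exposed under one entry point:

```sh
oncotrace simulate --outdir data --seed 1
oncotrace call-somatic --pileups data/pileups.tsv --normal NORM --tumor Met2 \
    --panel data/panel.tsv --models data/genes.bed --coding data/coding.fa \
    --out calls.vcf
oncotrace validate --amplicons amplicons.tsv --index Met2 \
    --early Met1,PT1,PT2,PT3,PT4 --out classes.tsv
oncotrace cnv --tumor-cov tumor.tsv --normal-cov normal.tsv \
    --hets data/het_sites.tsv --out cnvout
oncotrace chromothripsis --junctions data/junctions.bedpe \
    --segments cnvout.seg --regions chr3:500000-3000000 --out report.tsv
oncotrace integrate --dna calls.vcf --rna-genes data/rna_genes.tsv \
    --rna-sites data/rna_sites.tsv --samples Met1,PT1,Met2 --out report.tsv
oncotrace perturb-gsea --matrix data/perturbation.tsv --gmt sets.gmt \
    --timepoint 1 --nperm 10000 --seed 7 --out gsea.tsv
```

`oncotrace cnv` expects per-window coverage tables for a single sample
(columns `chrom`, `start`, `end`, `coverage`); split the simulator's
`coverage.tsv` by its `sample` column.

## Conventions

Variant records are 1-based inclusive (VCF style); windows, exons, and
junction intervals are 0-based half-open (BED style). Coverage log ratios
are normalized per sample by total coverage, so values are relative to
the genome-average DNA content.
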