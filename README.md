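# ripnet

Analysis pipeline for RIP-seq (RNA immunoprecipitation sequencing) screens
of multiple tagged RNA-binding proteins (RBPs), with protein co-IP
integration. Everything runs end to end on seeded synthetic data with known
ground truth, so each stage is testable offline.

Stages:

- **`ripnet.annotation`** — gene models from GTF + FASTA, collapse of
  isoforms into unambiguous 5′UTR/CDS/3′UTR/intron region partitions,
  isoform-aware unique 7-mer location indexes, RPKM expressed-gene universe.
- **`ripnet.simulate`** — seeded synthetic fixtures: a multi-isoform
  transcriptome with planted sequence motifs, negative-binomial gene- and
  intron-level count tables with planted enriched targets (IP replicates vs
  shared controls), planted protein complexes whose preys' mRNAs are
  co-targets, and gene sets enriched for planted high-occupancy RNAs.
- **`ripnet.diffbind`** — median-of-ratios normalization, trended NB
  dispersion shrinkage, per-replicate conditional exact-style NB enrichment
  test, and target calling at local IDR ≤ 0.10 with fold change ≥ 1.5 in
  both replicates; identical machinery for intron-level counts.
- **`ripnet.idr`** — two-replicate reproducibility: rank-based Gaussian
  copula mixture fit by EM (local and global irreproducible discovery
  rates).
- **`ripnet.occupancy`** — gene × RBP binding matrix, high-occupancy-target
  (HOT) RNA statistics under an exact Poisson-binomial null (conditioned on
  being bound at least once), pairwise target-set overlaps, generic
  hypergeometric/binomial set enrichment, class rank-sum comparisons, and
  down-the-rank-list enrichment curves.
- **`ripnet.motif`** — per-bait 7-mer hypergeometric enrichment (targets vs
  expressed non-targets), weighted seed-aligned PWM, transcriptome scan with
  the top-quantile k-mers, and per-locus gene-region binomial z-scores.
- **`ripnet.network`** — typed RBP→gene edges (rna / protein / both),
  per-bait cross-regulation overlap with Fisher-combined evidence, and
  gene-vs-intron target concordance (Jaccard, Spearman).

## CLI

One entry point with subcommands; all options can come from a YAML config
(`--config`) with flag overrides:

```sh
ripnet simulate --seed 1 --outdir out            # write a fixture dataset
ripnet calls    --outdir out --config cfg.yaml   # NB test + IDR + thresholds
ripnet occupancy --outdir out                    # binding matrix, HOT stats
ripnet motif    --outdir out --config cfg.yaml   # k-mer enrichment, PWM, z-scores
ripnet network  --outdir out --config cfg.yaml   # PPI/RNA integration
ripnet all      --seed 1 --outdir out            # full pipeline on a fixture
```

Outputs are TSV/BED/JSON (plus a MEME-format PWM and GraphML network) and
are deterministic given the seed; each stage writes a provenance JSON.
Missing inputs or invalid thresholds exit with status 2.

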