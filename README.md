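# mosaicall

Detection and cohort analysis of low-allele-fraction somatic SNVs in
sorted cell populations from deep targeted sequencing.

The package implements:

- **`mosaicall.simulate`** — synthetic deep-sequencing cohorts:
  negative-binomial depths around a configurable mean (~1100×),
  beta-distributed site-specific error rates with within-site
  overdispersion, germline heterozygous sites shared within donors,
  and somatic clones planted at configurable VAF with cell-type
  specificity and an arm-specific carrier probability. Ground truth is
  emitted alongside the counts.
- **`mosaicall.errormodel`** — site-specific beta-binomial background
  error model in a (mu, rho) parameterization with an explicit binomial
  limit; maximum-likelihood fitting from a method-of-moments start.
- **`mosaicall.calling`** — one-sided likelihood-ratio calling of each
  test sample against a pooled background of the other cell types, with
  Benjamini–Hochberg FDR control per cell-type batch (default q ≤ 0.01).
- **`mosaicall.filters`** — the post-calling cascade (pooled-VAF
  germline rule at 20%, ≥50× coverage, VAF window 0.3%–35%, ≥4 alt
  reads on both strands, indel proximity ≤10 bp, population AF < 1%,
  FDR), plus call-set union with provenance tracking.
- **`mosaicall.annotate`** — ClinVar/OncoKB-style pathogenicity
  classification (P-SNV), four-predictor consensus deleteriousness,
  gene-set tagging (including the 15 classical MAPK/RASopathy genes),
  and panel-normalized mutational burden per sample and per donor.
- **`mosaicall.stats`** — Mann-Whitney / Kruskal–Wallis + Dunn,
  Spearman/Pearson correlation, carrier logistic regression with Wald
  CIs, linear mixed-effects burden modeling (donor random intercept,
  likelihood-ratio term tests, conditional R²), and cumulative
  hypergeometric gene-set enrichment against a panel background.

## Command-line interface

```sh
# full pipeline on a synthetic cohort
mosaicall run-all --config config.yaml --outdir out/ --seed 7

# or stage by stage
mosaicall simulate --config config.yaml --outdir out/ --seed 7
mosaicall call     --pileups out/pileups.tsv --metadata out/metadata.tsv --output out/calls.tsv
mosaicall filter   --calls out/calls.tsv --pileups out/pileups.tsv \
                   --metadata out/metadata.tsv --output out/filtered.tsv
mosaicall annotate --calls out/filtered.tsv --pathogenicity out/pathogenicity.tsv \
                   --sites out/sites.tsv --output out/annotated.tsv
mosaicall burden   --calls out/annotated.tsv --metadata out/metadata.tsv --output out/burden.tsv
mosaicall enrich   --hits hits.txt --background panel_genes.txt --output out/enrichment.tsv
```

A minimal `config.yaml`:

```yaml
seed: 7
simulation:
  n_donors_case: 8
  n_donors_control: 8
  n_sites: 2000
  mean_depth: 1100
  clone_vaf_range: [0.01, 0.10]
  carrier_prob_case: 0.5
  carrier_prob_control: 0.1
background_design:        # test cell type -> pooled background cell types
  microglia: [neuron, glia]
  neuron: [microglia, glia]
  glia: [neuron, microglia]
  blood: [neuron, glia]
filters:
  q_max: 0.01
  min_coverage: 50
```

All tables are plain UTF-8 TSV with a header row and 1-based closed
coordinates; every output carries a `#` provenance header (version,
seed, config hash) and `run-all` writes a JSON manifest with per-stage
timings. Reruns with the same config and seed are byte-identical.

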