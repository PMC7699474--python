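# ploidystrat

Cross-species criss-cross analysis of ploidy-associated transcription:
phylostratigraphy, bivalent-gene statistics, module enrichment and
interaction-network connectivity.

Mammalian species differ in which organs polyploidize: in the design modeled
here, species A carries a polyploid heart and a diploid liver while species B
shows the reverse. Genes whose expression moves in the *same* direction with
respect to ploidy in both tissue pairs reflect ploidy rather than species or
tissue. `ploidystrat` implements that reciprocal (criss-cross) selection and
the downstream analyses around it:

- **synthetic** — generators for annotation tables (16 phylostrata, bivalency
  flags, driver classes), criss-cross expression matrices with planted ploidy
  effects, interaction graphs with boosted connectivity for the planted
  up-set, and a small random DAG ontology. Everything is seeded and
  deterministic, providing a ground-truth test bed.
- **ingest** — tab-separated readers with validation, one-to-one ortholog
  matching restricted to stratum-annotated pairs, `log2(x + 1)` transform and
  per-tissue-pair quantile normalization (mean-of-order-statistics reference,
  ties averaged).
- **crisscross** — per-gene reciprocal log2 fold changes (always polyploid
  minus diploid), concordance calls at configurable linear fold thresholds
  (e.g. 2.0 and 1.3, boundary inclusive), and an optional simplified
  empirical-Bayes moderated t-test (log-variance moment matching).
- **pca** — covariance PCA with samples as variables and genes as statistical
  units; components assigned greedily to tissue/species/ploidy by
  point-biserial correlation of their loadings (|r| >= 0.5), the
  highest-variance leftover labeled batch; gene selection at +/- 2 SD of the
  standardized scores on the ploidy component.
- **strata** — per-stratum distributions and exact binomial shift tests
  against the background, BH-corrected across the 16 strata; optional
  up-vs-down Fisher variant.
- **bivalency** — exact binomial bivalent-gene enrichment computed in log
  space (p-values far below float underflow are reported as log10 p),
  per-stratum bivalency profiles, and the oncogene / tumour-suppressor panel
  with pairwise bivalent-fraction comparisons.
- **ontology** — child->parent DAG propagation (a gene belongs to a term if
  assigned to it or any descendant), hypergeometric enrichment with
  identical-gene-set merging, BH q-values.
- **network** — largest-connected-component summaries (mean degree 2E/V,
  degree-threshold hubs), component retention of gene lists (components of
  size 1 do not count), hub-neighborhood subsetting.
- **pipeline / cli** — one-config orchestration with deterministic,
  machine-readable outputs.

## Command-line usage

```sh
# end-to-end on simulated data (default when no config is given)
ploidystrat run-all --seed 42 --outdir results/demo

# or stage by stage
ploidystrat simulate --seed 1 --outdir sim
ploidystrat ingest --expression-a sim/expression_A.tsv --meta-a sim/samples_A.tsv \
    --expression-b sim/expression_B.tsv --meta-b sim/samples_B.tsv \
    --orthology sim/orthology.tsv --annotation sim/annotation.tsv --outdir out
ploidystrat crisscross --fold 2.0 --fold 1.3 --outdir out
ploidystrat pca --sd 2.0 --outdir out
ploidystrat strata --up out/up_fold_2.tsv --down out/down_fold_2.tsv \
    --annotation sim/annotation.tsv --out out/shift.tsv
ploidystrat bivalency --up out/up_fold_2.tsv --down out/down_fold_2.tsv \
    --annotation sim/annotation.tsv --out out/bivalency.json
```

A YAML config for `run-all` holds either a `simulate:` block (generator
parameters) or an `inputs:` block (file paths), plus `seed`,
`fold_thresholds`, `pca_sd`, `hub_degree` and `outdir`. Exit codes: 0
success, 2 validation error, 3 stage failure. Rerunning the same config and
seed produces a byte-identical `summary.json`.

### File formats

All inputs and outputs are plain tab-separated text. Expression: first column
`gene_id`, remaining columns samples; metadata sidecar with columns
`sample_id, species, tissue, ploidy, batch, replicate`. Annotation:
`gene_id, phylostratum (1-16), bivalent (0/1), driver_class`. Orthology: two
columns `gene_a, gene_b` (one-to-one). Ontology: `child, parent` edge table
plus `gene_id, term` assignments. Networks: 2- or 3-column edge lists
(`gene_a, gene_b[, score]`).

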