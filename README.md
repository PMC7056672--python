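# microgdm

A gut-microbiome case-control analysis toolkit: alpha/beta diversity,
LEfSe-style differential-abundance effect sizes, SparCC compositional
correlation networks, Spearman clinical-index correlation, and a
forward-selection linear-discriminant case classifier with external
validation — exercised end-to-end on a built-in synthetic cohort generator
that emulates a matched-pair 16S study design (98 case + 98 control samples
split into 70/70 discovery and 28/28 validation pairs).

## Modules

| Module | What it does |
| --- | --- |
| `microgdm.io_formats` | Strict TSV/newick readers and writers (OTU table, taxonomy, metadata, tree, distance matrix) with validated round-trips |
| `microgdm.synthetic_cohort` | Log-normal → multinomial cohort generator: spiked genera, matched-pair effects, Gaussian-copula clinical coupling, coalescent tree; plus a Monte-Carlo Bayes-AUC yardstick |
| `microgdm.preprocess_diversity` | Rare-OTU filtering (strict `< 0.005%` rule), rarefaction to fixed depth (default 36,000 reads), rank aggregation, seven alpha indices (Observed, Chao1, ACE, Shannon, Simpson, Heip's evenness, Dominance), Welch group tests, rarefaction curves |
| `microgdm.beta_ordination` | Jaccard, Bray-Curtis, unweighted/weighted UniFrac, PCoA, and PERMANOVA (permutation p-values) |
| `microgdm.lefse_da` | Kruskal-Wallis screen + bootstrapped LDA effect size on per-million abundances (cutoffs p < 0.05, score ≥ 2) |
| `microgdm.sparcc_network` | SparCC basis correlations (log-ratio variances, iterative pair exclusion, Dirichlet resampling), bootstrap pseudo p-values, co-occurrence / co-exclusion edge lists |
| `microgdm.clinical_correlation` | Feature × clinical-index Spearman grid with pairwise-complete missing handling and BH q-values |
| `microgdm.gdm_classifier` | Two-class LDA, LOOCV, greedy forward feature selection, Mann-Whitney AUC with DeLong CIs, frozen external-validation evaluation, combined/genus-only/clinical-only model comparison |
| `microgdm.pipeline` / `microgdm.cli` | End-to-end orchestration with per-stage seed fan-out, plain TSV/JSON stage outputs, and a manifest |

## Command line

```sh
# generate a synthetic cohort
microgdm simulate --seed 1 --out cohort/

# per-stage analyses
microgdm alpha --table cohort/otu.tsv --metadata cohort/metadata.tsv \
    --depth 36000 --min-fraction 0.00005 --seed 1 --out alpha/
microgdm beta --table cohort/otu.tsv --metric bray_curtis \
    --metadata cohort/metadata.tsv --permutations 999 --seed 1 --out beta/
microgdm lefse --table cohort/otu.tsv --metadata cohort/metadata.tsv \
    --p-cutoff 0.05 --lda-cutoff 2 --seed 1 --out lefse.tsv
microgdm sparcc --table cohort/otu.tsv --seed 1 --out sparcc/
microgdm correlate --table cohort/otu.tsv --metadata cohort/metadata.tsv \
    --clinical FGB,GGT --out grid.tsv
microgdm train --table cohort/otu.tsv --metadata cohort/metadata.tsv \
    --clinical FGB,GGT --set discovery --out model.json
microgdm validate --model model.json --table cohort/otu.tsv \
    --metadata cohort/metadata.tsv --clinical FGB,GGT --out roc.tsv

# or the whole pipeline from one YAML config
microgdm run --config pipeline.yaml --out report/
```

The pipeline writes every stage's output as plain TSV/JSON
(`alpha.tsv`, `distance_<metric>.tsv`, `permanova.tsv`, `lefse.tsv`,
`sparcc_corr.tsv`, `network_edges.tsv`, `correlation_grid.tsv`,
`classifier.tsv`, `model.json`) plus a `manifest.json` with the config
hash, per-stage seeds, and runtimes. Reports are byte-identical across
runs at a fixed seed.

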