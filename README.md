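# psoriomics

Paired transcriptome–proteome integration for lesional vs. uninvolved skin
cohorts.

## The problem

Psoriasis studies profile paired biopsies from each patient — one lesional
(PP) and one uninvolved (PN) — with RNA-seq and label-free LC-MS/MS.
Because mRNA levels only modestly predict protein abundance (rank
correlations of 0.4–0.6 are typical in human tissue), the two arms must be
analyzed separately and then integrated: which transcripts and proteins
shift together (high-confidence disease markers), which shift in opposite
directions (e.g. ribosomal proteins elevated while their mRNAs fall), and
which changes are disease-specific rather than generic responses to skin
inflammation.

`psoriomics` implements that full workflow as a tested library plus CLI:

- **RNA-seq arm** — detection filtering (CPM > 0.25 and a positive FPKM
  95%-CI lower bound in ≥ 25% of samples), TMM normalization, per-gene NB
  dispersion by Cox–Reid adjusted profile likelihood with a binned-median
  mean–dispersion trend, and a paired negative-binomial GLM
  likelihood-ratio test (`log μ = patient + condition + offset`,
  χ²₁ on the condition term), BH-adjusted.
- **Proteomics arm** — spectral-count filtering (SpC > 1 in ≥ 4 samples),
  total-count normalization, NSAF = (SpC/MW)/Σ(SpC/MW) absolute abundance,
  and a paired least-squares model on normalized spectral counts.
- **Integration** — gene↔protein matching, Spearman correlation of PP/PN
  fold changes, a 2×2 sign-concordance table with Pearson residuals,
  discordant-pair mining at raw p < 0.10, and the DEGP intersection
  (features significant and same-direction on both arms; fold-change gates
  > 1.50 / < 0.67 at FDR < 0.05).
- **Atlas enrichment** — compartment/cell-type specificity scores against a
  proteome atlas, top-k signature extraction, a 10,000-draw sampling null
  for signature fold changes, and cumulative-overlap curves with
  permutation p-values.
- **GSEA screening** — ordered gene lists by moderated t (empirical-Bayes
  variance shrinkage), rank-sum screening of gene-set pairs across a panel,
  per-DEGP disease-specificity fractions, and stratified GSEA: 10-gene
  sliding windows along the specificity ordering with a Huber-regression
  trend and a permutation p-value.
- **Synthetic data** — a paired-cohort generator with planted fold changes,
  an mRNA–protein log-FC copula with tunable rank coupling, a discordant
  "translation block", atlas and disease-panel generators — all seeded and
  shipping ground truth, so every stage is validated by recovery rather
  than by fiat.

## Worked example

```bash
# materialize a synthetic paired cohort (14 patients, 2000 genes, 600 proteins)
psoriomics simulate --seed 1 --out-dir fixture

# run every stage
cat > config.yaml <<EOF
counts: fixture/counts.tsv
fpkm: fixture/fpkm.tsv
fpkm_ci: fixture/fpkm_ci.tsv
spc: fixture/spc.tsv
design: fixture/design.tsv
id_map: fixture/id_map.tsv
out_dir: results
EOF
psoriomics run-all --config config.yaml
```

The run prints a JSON summary; with seed 1 it includes

```
"n_genes_detected": 2000,
"n_degs": 723,
"n_deps": 268,
"n_pairs": 600,
"fold_change_spearman": 0.277,
"n_degps": 112,
"n_discordant_mrna_down_protein_up": 74
```

meaning: all 2000 genes pass detection; 723 genes and 268 proteins are
differentially expressed between lesional and uninvolved samples at the
default gates; across the 600 matched mRNA–protein pairs the fold changes
correlate at r_s ≈ 0.28; 112 pairs are significant and concordant on both
arms (DEGPs); and 74 pairs show the discordant mRNA-down / protein-up
pattern — which includes 36 of the 40 planted translation-block proteins
(see `fixture/truth_proteins.tsv`).

Stage outputs (`mrna_de.tsv`, `protein_de.tsv`, `pairs.tsv`, `degp.tsv`,
`discordant_*.tsv`, `nsaf.tsv`, `concordance.json`) land in `results/`
together with a `manifest.json` recording the config hash and seed;
re-running the same config reproduces byte-identical outputs.

Individual stages are also available as subcommands (`detect`,
`rnaseq-de`, `proteome-de`, `atlas`, `gsea`, `stratified-gsea`) and as
plain library functions.

## Layout

```
src/psoriomics/
  stats_core.py        shared primitives (BH, Spearman, rank-sum, Huber fit, ...)
  rnaseq_de.py         detection, TMM, paired NB GLM + LRT
  _nbglm.py            batched NB IRLS / Cox-Reid dispersion engine
  proteome_de.py       SpC filtering, normalization, NSAF, paired OLS
  integration.py       pair matching, concordance, discordance, DEGPs
  atlas_enrichment.py  specificity scores, signatures, sampling nulls
  gsea_screen.py       ordered lists, panel screens, stratified GSEA
  synthetic.py         seeded cohort / atlas / panel generators
  pipeline.py, cli.py  config-driven orchestration and the CLI
docs/methods.md        model and design notes
```
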