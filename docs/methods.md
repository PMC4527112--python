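# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the design decisions behind `psoriomics`.

## Study design and notation

The unit of analysis is a paired cohort: `n` patients (default 14), each
contributing one lesional (PP) and one uninvolved (PN) skin sample profiled
on two arms — RNA-seq gene counts and LC-MS/MS spectral counts.  Fold
changes are oriented PP/PN throughout; `log_fc` is log2.  Both
differential-expression tables share one layout (`feature_id`,
`fold_change`, `log_fc`, `raw_p`, `fdr`, `de_class`, `mean_abundance`) and
one classification contract: *increased* iff fold change > 1.50 and
BH-FDR < 0.05, *decreased* iff fold change < 0.67 and FDR < 0.05 (strict
inequalities), otherwise *unchanged*.

## RNA-seq arm

**Detection.** A gene is detected in a sample when CPM > 0.25 and the
lower bound of the 95% FPKM confidence interval is positive; it is
retained when detected in at least ⌈0.25 × n_samples⌉ samples (7 of 28 at
cohort scale).  When no external CI accompanies the FPKM matrix, a
normal-approximation bound `fpkm · max(0, 1 − 1.96/√(count + 0.5))` is
substituted and documented as such (upstream FPKM estimation is out of
scope).

**Normalization.** Weighted trimmed mean of M-values: reference sample by
closest 75th percentile of scaled counts; 30%/5% double trimming on M and
A; inverse asymptotic-variance weights; factors rescaled to geometric mean
1.  During development the implementation was checked against
edgeR's `calcNormFactors` on a composition-bias fixture (agreement to
1e-6); the frozen factors serve as the test oracle.

**Dispersion.** Per gene, the NB2 dispersion maximizes the Cox–Reid
adjusted profile likelihood `ℓ(α) = ℓ̂(α) − ½ log det(XᵀWX)` on a 10-point
log-spaced grid (1e-4 to 5) with quadratic interpolation at the peak,
then is smoothed against average log-CPM by a binned-median trend
(20 quantile bins, linear interpolation).  Trend-only smoothing is used —
no tagwise shrinkage toward the trend; validation is by parameter
recovery and calibration rather than equivalence to any particular
implementation.

**Testing.** Log-link NB GLM with offsets `log(library size × TMM factor)`
and fixed effects for patient and condition, fitted by batched IRLS
(all genes share the design matrix, so the per-gene weighted normal
equations are solved as one stacked linear-algebra call; max 100
iterations, step tolerance 1e-8, damped steps, tiny ridge for rank
safety).  The condition effect is tested by a likelihood-ratio test
against the patient-only model, χ² with 1 df.  Genes that fail to converge
are flagged and assigned p = 1; all-zero genes get fold change 1, p = 1.
With dispersion forced to 0 the procedure reproduces a Poisson GLM LRT to
1e-4 (tested against statsmodels).

## Proteomics arm

Proteins require SpC ≥ 2 in at least 4 samples; keratin contaminants are
kept (they are genuinely abundant in skin) but flagged.  Relative
abundance is total-count-normalized SpC (scaled to the mean sample total —
the simplest defensible reading of Scaffold-style quantitative values,
which are not algorithmically specified anywhere); absolute abundance is
NSAF.  Significance comes from an ordinary least-squares fit of normalized
SpC on patient dummies plus a PP indicator, two-sided t on the PP
coefficient — a Gaussian model applied to count-like data, implemented as
stated because that is the procedure being reproduced; its calibration is
verified empirically (null rejection ≈ 5%).  Fold changes use
`(mean PP + 0.5)/(mean PN + 0.5)`; the pseudocount guards zero PN means.
Filtering precedes normalization (the order matters and is fixed).

## Integration

Pairs come from an inner join through a one-to-one gene↔protein map
(duplicate mappings are an error naming the offenders; unmatched features
are reported with reasons).  The fold-change correlation is Spearman on
log fold changes (a monotone transform of the fold-change axes, so the
statistic is unchanged), with optional per-patient and
abundance-tertile-stratified versions.  The concordance table
cross-classifies pairs by sign of log FC on each arm (exact zeros are
excluded and counted) and carries Pearson residuals whose squares sum to
the χ² statistic.  Discordance uses raw p < 0.10 by default — raw rather
than FDR-adjusted, configurable — with the direction gates applied to the
log-FC signs.  DEGPs are pairs whose two classifications agree and are not
*unchanged*, sorted by protein fold change.

## Atlas enrichment

Specificity of a protein for one atlas context is the signed −log10 p from
a pooled-variance contrast of the context's replicate columns against all
others; a single-column context falls back to a rank-based score (context
rank minus mean elsewhere rank), flagged in the output.  Signatures are
the top k = 12 scores, ties broken lexically for determinism.  Enrichment
of a signature among PP-increased proteins is assessed two ways: (i) mean
log2 FC against a null of 10,000 random same-size draws without
replacement, two-sided with +1 smoothing (the universe size is an explicit
parameter, since detected-protein universes are ambiguous in practice);
(ii) the cumulative-overlap curve C(i) with area statistic
`A = Σ_i [C(i) − i·k/N]/N`, whose maximum is k(N−k)/(2N) and which is
antisymmetric under list reversal, with a position-permutation p-value and
a Wilcoxon rank-sum p reported alongside.

## GSEA screening and stratification

Ordered gene lists condense a two-group comparison to signed scores
−log10(p)·sign(effect) from a moderated t: residual variances are shrunk
toward a prior whose df and scale are estimated by digamma/trigamma moment
matching on log sample variances; prior df 0 recovers the ordinary t
exactly.  Panel screening computes standardized rank-sum enrichments of an
up-set and a down-set per list; the combined statistic is their
difference, with an approximate normal p (the two rank-sums are treated as
independent — adequate for ranking; the spike-in recovery test shows a
planted responder is ranked first at FDR < 0.05).

The specificity fraction of a DEGP is (#diseases with a same-direction
change at p < 0.05) / (#diseases whose platform assays the gene);
"corresponding change" is not precisely defined anywhere, so the
same-direction-significant rule is a parameterized default.  Stratified
GSEA orders PP-increased DEGPs most-specific-first (ties by protein fold
change, then id), slides a 10-gene window at step 1, and scores each
window by the standardized rank-sum of its genes' scores within the target
list.  The left-to-right trend is summarized by the Huber-regression slope
(c = 1.345, IRLS).  Because step-1 windows overlap, neighbouring window
statistics are strongly autocorrelated and a naive regression p-value is
anticonservative by orders of magnitude; the trend p therefore comes from
a permutation null that reshuffles the DEGP ordering (1000 permutations by
default, least-squares slope as the permutation statistic for speed).
This choice is what makes the null false-positive rate land at ≈5%.

## Synthetic-data generator

The generator emulates the *structure* of a paired skin cohort, not any
particular dataset:

- **Counts.** Gene baselines are log-normal (σ = 1.0) scaled to a read
  depth of 2×10⁶ per sample (±15% log-normal depth variation); counts are
  Gamma–Poisson with dispersion 0.06 by default.  That dispersion is the
  *residual within-patient* biological CV (~25%); patient-to-patient
  heterogeneity is modeled separately as gene×patient log-normal effects
  (σ = 0.4) shared by both of a patient's samples — which is exactly what
  makes the paired models outperform unpaired ones, and what the tests
  exercise.
- **Coupling.** `coupling_rho` is defined as the *rank* (Spearman)
  correlation of planted mRNA and protein log FCs; the Gaussian copula is
  therefore planted with Pearson correlation 2·sin(π·ρ/6).  Per-arm
  spreads differ (gene σ = 1.0, protein σ = 0.7 log2 units); rank
  correlation is invariant to that.
- **Planted effects.** DEG spikes (default 10% up, 10% down at fold change
  4) are placed on protein-unmapped genes first, spilling concordantly
  onto mapped pairs only when the unmapped pool is exhausted.  Protein-only
  DEP spikes are biased upward (5% up vs 1% down at fold change 3) and
  placed on low-abundance proteins — as immune-infiltrate proteins are —
  so they barely perturb the per-sample spectral-count total.
- **Translation block.** A configurable set of mapped pairs (default 40)
  is overridden to mRNA fold change 0.7 and protein fold change 1.8, the
  discordant pattern of ribosomal/translation proteins in lesions.
- **Spectral counts.** Protein expected abundance is the mapped gene's
  baseline times a log-normal translation factor (σ = 0.5), scaled to 30
  expected SpC per protein per sample, observed as Poisson.  Sparse
  spectral counting at this depth is adequately Poisson; no extra
  overdispersion is modeled.
- **Atlas / panel.** The atlas plants context-specific proteins with a
  multiplicative effect across replicate columns.  The disease panel
  assigns each DEGP a target specificity fraction uniform on [0, 1],
  realizes responders per disease by that probability, masks genes from
  platforms with probability 0.2, and can emit an induction target list
  whose DEGP scores fall linearly with the target fraction (the planted
  gradient for stratified-GSEA tests).

All randomness flows through named substreams of one seed; every
generator re-run is byte-identical, and every simulated object ships a
ground-truth table sufficient to score recovery.

**What the generator does not emulate.** Real spectral counts carry
shared-peptide ambiguity, peptide-level missingness, and batch structure;
real RNA-seq has GC/length biases and isoform mixing; real disease panels
share platforms and are correlated across diseases.  Passing tests
therefore demonstrate that the pipeline recovers the planted statistical
structure under an idealized observation model — not that any specific
biological conclusion transfers.

Two measurement-level properties are worth knowing when reading simulated
results.  First, total-count normalization of spectral counts makes a
whole-proteome abundance shift unidentifiable: renormalization re-centers
the bulk, so the realized excess of increased over decreased protein calls
is milder than the planted spike imbalance.  Second, under strong
one-directional composition (e.g. 20% of genes at fold change 4 with
patient-level noise) TMM under-corrects, biasing null genes' fold changes
a fraction of a log2 unit downward and inflating their nominal
significance; this is a property of trimmed-mean normalization itself, not
of this implementation, and does not affect balanced or all-null cohorts
(null rejection stays at ≈5%).

## Problem sizes used in validation

Desk-scale defaults (2,000 genes, 600 mapped proteins, 14 patients) keep a
full pipeline run under a second.  The validation suite uses: 200 all-null
cohorts per arm for type-I calibration; a 2,000-pair cohort for coupling
recovery; the 250-gene / 8-patient spiked cohort (dispersion 0.1) for
fold-change recovery; a 2,194-protein atlas with 12-protein signatures;
and 500 null panel fixtures for the stratified-GSEA false-positive rate.

## Known limitations

- The dispersion trend has no tagwise (per-gene posterior) shrinkage;
  very heterogeneous per-gene dispersions are handled only through the
  trend.
- The combined screen statistic's normal p treats the up- and down-set
  rank-sums as independent; panel FDRs are approximate (ranking is
  rank-exact).
- GO-term enrichment is out of scope: the integration stage exposes the
  gene sets, and any user-supplied term↔gene table can be screened with
  `screen_gene_sets`, but no annotation data ships with the package.
- The proteomics model inherits the stated least-squares-on-counts
  simplification; quasi-Poisson or NB alternatives would be natural
  extensions but are not what this pipeline reproduces.
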