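# Methods

This note records the modeling choices, defaults and numerical conventions
behind `drivergnn`, and what the synthetic benchmarks do and do not show.

## Problem setting

Given one tumor cohort — tumor and matched-normal expression, gene-level
methylation β, somatic SNV records with read depths, GISTIC-style CNV calls,
a gene-level table of 11 mutational-heterogeneity covariates — plus a scored
PPI network and gene sets (known drivers, exclusion lists,
cell-proliferation-related genes, CPRGs), the package scores every gene with
a probability of being a driver in that tumor type. Labels are sparse by
construction: known drivers are positive, genes confidently unrelated to
cancer are negative, and everything else is unlabeled but still participates
in message passing.

## Feature engine

All features are computed per gene and min–max scaled per feature across
genes before assembly; constant features map to 0, so every column of the
36-wide matrix lies in [0, 1]. The fixed schema partition is 26 genomic,
3 transcriptomic, 1 epigenomic, 6 network-derived, asserted on every
assembly.

Conventions worth stating explicitly:

- **Fold changes.** Methylation fold change is the plain ratio of group
  means; expression fold change is log2 of the ratio. Both ratios are
  protected with a pseudocount ε = 10⁻⁶ in numerator and denominator; genes
  unmeasured in either group are set to 0 exactly.
- **Differential-expression flag.** Two-sided Wilcoxon rank-sum at α = 0.05
  (the α is a free choice; 0.05 is the conventional level): +1 when tumor
  is significantly above normal, −1 below, 0 otherwise. Groups with fewer
  than 2 values yield 0 with a warning.
- **Outlier counting.** The Grubbs statistic is used one-sided and signed —
  `G_ij > G_p(N)`, no absolute value — so only unusually *high* expression
  counts, and the population for mean/SD is the tumor samples (the
  patient-outlier matrix columns are tumor samples). SD uses ddof = 1;
  constant genes give all-zero rows. N ≥ 3 is required.
- **Mutation features.** Mutation frequency counts *distinct* tumor samples
  with ≥ 1 record; VAF is averaged over all of a gene's records (the
  per-locus definition is aggregated to gene level by the mean); the 12
  base-conversion counts are totals over SNV records only, in the fixed
  order C→A, C→T, C→G, A→T, A→C, A→G, G→C, G→A, G→T, T→A, T→G, T→C.
  Indels and multi-base alleles are kept for frequency/VAF but never enter
  conversion counting.
- **CNV rate.** The per-sample event count is the absolute GISTIC call; an
  all-zero normal denominator is replaced by one pseudo-event (logged)
  rather than producing an infinity.
- **Covariates.** Genes absent from the covariate table are imputed with the
  per-covariate median.
- **Network block.** The bipartite graph uses the same score-filtered PPI as
  the classifier (a second, BioGRID-style network can be supplied for the
  centralities via `centrality_network`). Betweenness is normalized by
  (n−1)(n−2)/2 so it lies in [0, 1]; since all features are min–max scaled
  afterwards, only the ordering matters.

## Labels

Positives come only from the supplied driver list. Rule 1 of the exclusion
logic — "expression associated with known drivers" — is operationalized as
|Spearman ρ| ≥ 0.8 (configurable) with any positive gene, computed over
tumor samples. Rules 2–5 are consumed as gene lists (pathway members, OMIM,
DriverDBV3, NCG). Excluded non-positive genes are unlabeled; by default they
enter training only through message passing. A pseudolabel mode
(`pseudolabel_mode=True`) instead assigns seeded fair-coin 0/1 targets to
unlabeled genes and includes them in the loss; random targets inject label
noise, so the mode is off by default.

## Model and training

Architecture: GAT (single head) → GraphSAGE → GraphSAGE(2) → softmax.
Defaults follow the standard choices of the cited layer families where the
design was open: ELU after attention aggregation, ReLU in SAGE layers,
LeakyReLU slope 0.2, dropout 0.5 between layers, mean neighbor aggregation,
self-loops added for attention stability, Adam with lr 0.01 and weight decay
5·10⁻⁴, 200 epochs, full-graph gradient steps. Layer widths default to
36/64 → 64/128 → 128/2 and are configurable per tumor type. Neighbor
sampling defaults to full neighborhoods (the gene graph is small);
fixed-size uniform sampling without replacement is available.

The split of labeled genes is 70/30 and stratified by class — positive sets
can be very small (tens of genes), and an unstratified split can leave no
positives held out. Probabilities inside the cross-entropy are clamped to
[10⁻⁷, 1−10⁻⁷]. All randomness (init, split, dropout, pseudolabels) derives
from the single `RunConfig.seed`.

The layers and backpropagation are implemented on numpy with a minimal
reverse-mode autodiff engine; message passing uses precomputed sparse
matrices (gather, scatter-add, degree-normalized adjacency). Correctness is
established in the test suite by dense-matrix re-implementations of both
layer types on small graphs (≤ 10⁻⁶ agreement) and central finite
differences through the full model loss.

## Evaluation

The PR curve has one point per distinct score (ties grouped, avoiding
ordering-dependent AP) plus the conventional empty-set anchor (recall 0,
precision 1). Smoothing is the running max from the right; AP averages the
smoothed precision at the 11 recall grid points {0, 0.1, …, 1}, with
unreachable recall contributing 0 and the r = 0 point carrying the global
maximum. AP is invariant to strictly monotone transforms of the scores.

## Proliferation validation

Core-gene selection ranks CPRGs by their number of significantly
coexpressed partners (|ρ| ≥ 0.4 and p < 10⁻³ over tumor samples; the
absolute value is used, and ties break by mean |ρ| then lexicographically)
and keeps the top 20. θ has no intercept — the regression model is
`Ŝ = θ·S` — giving the closed form θ = (S·S̄)/(S·S), which is
scale-consistent: scaling a sample's vector by c divides θ by c. The
Wilcoxon rank-sum test is two-sided, exact for group sizes ≤ 20 and a
tie-corrected normal approximation otherwise; p-values are used raw at 0.05
(no multiplicity correction, matching the candidate-wise decision rule;
Benjamini–Hochberg can be applied downstream on the results table).
Degenerate M/U splits return p = 1 with a flag rather than an error.

## Synthetic data

The generator emulates input *shapes and planted contrasts*, not biology:
log-normal expression with a shared latent factor over the CPRG block (so
core-gene selection has a true answer), Beta(5,5) methylation, Bernoulli
per-gene-per-sample mutations materialized as SNV records with
Poisson(100) depths and Binomial(total, 0.3) alt counts, CNV events at a
per-cell rate with a shared ±1/±2 magnitude distribution, standard-normal
covariates, and a Barabási–Albert PPI graph (m = 3) with drivers placed
preferentially on high-degree nodes (`hub_bias=False` disables this to test
the feature-only regime).

Default study conditions: 2000 genes, 200 tumor + 30 normal samples, 50
drivers, mutation rates 0.25 (driver) vs 0.02 (passenger), +1.5 log2
expression shift, +0.15 β methylation shift, CNV event rates 0.5 vs 0.08,
70% of non-drivers labeled negative, seed 7. Values not fixed by the study
design (methylation shift, CNV rates, CPRG block size 60, depth model) were
chosen once as plausible magnitudes for TCGA-scale cohorts.

Every driver-specific contrast is a parameter, so the matched no-signal
configuration (equal mutation and CNV rates, zero shifts, no hub bias)
removes *all* planted signal; under it the held-out AP falls inside the
random-ranking band, and under defaults it exceeds 5× the prevalence
baseline across seeds. Passing these benchmarks shows the pipeline recovers
the specific contrasts it plants; real cohorts add batch effects, subclonal
structure, correlated mutational processes and annotation noise that the
generator deliberately omits, so synthetic AP values say nothing about
absolute performance on TCGA-like data. The default NPCD stage on synthetic
data typically calls zero candidates — the generator plants no
mutation–proliferation coupling, so an empty table is the correct null
outcome (example 03 shows a planted positive case).

## Problem sizes used in the checks

The bundled tests run the full default instance (2000 genes) for feature
schema, recovery (seeds 7–9) and the null comparison, and reduced instances
(250–400 genes) for pipeline composition and byte-level determinism; the
statistical calibration suites use 500 replicates. These sizes were chosen
so the whole suite completes in a few minutes on one CPU while keeping
every check at the scale its claim requires.

## Known limitations

- Gene identity is the bare case-sensitive symbol; no alias resolution.
- Methylation is consumed gene-level; probe-to-gene aggregation is out of
  scope.
- The MutSigCV covariates are consumed as a table, never recomputed.
- Single-head attention and full-batch training only; adequate at gene-graph
  scale (~20k nodes) but not tuned for larger graphs.
- Training hyperparameters are field-standard defaults, not the result of a
  per-cohort search.
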