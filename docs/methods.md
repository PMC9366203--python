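# Methods

This note documents the statistical models, numerical choices and design
decisions behind `isletview`, and states what the synthetic-data
validation does and does not establish about real donor-islet data.

## QC and normalization

**Sample filter.** Samples with a column sum strictly below
`min_reads = 10,000,000` are removed; the bound is exclusive (a sample
with exactly 10 M reads stays).

**Gene filter.** On the retained samples, FPKM is
`count × 10⁹ / (exonic length × library size)` with exonic length the
merged (union) length of a gene's exon intervals when a GTF supplies
them, else the gene span. Genes are kept when the share of samples with
FPKM > 0 is at least `frac_nonzero = 0.95` **and** mean FPKM exceeds
`min_mean_fpkm = 1.0` (strict). The filter is idempotent on its own
output.

**TMM.** The reference sample is the one whose 75th percentile of
count/library is closest to the mean of those percentiles. For sample j
versus the reference r, over genes with nonzero counts in both:
M_g = log2((y_gj/N_j)/(y_gr/N_r)), A_g = ½·log2 of the product, and the
asymptotic binomial variance v_g = (N_j−y_gj)/(N_j y_gj) +
(N_r−y_gr)/(N_r y_gr). M is doubly trimmed — 30 % of the M distribution
and 5 % of the A distribution from each end, by ranks — and
log2 f_j = Σ M_g/v_g / Σ 1/v_g over the retained genes. Factors are
rescaled to geometric mean 1. When the largest |M| is below 10⁻⁶ the
factor is exactly 1 (identical-composition shortcut). The implementation
is checked against edgeR's `calcNormFactors(method="TMM")` at 10⁻⁶ in
the test suite.

**log₂-CPM.** `log2((count + 0.5)/(lib × factor + 1) × 10⁶)`. The prior
count 0.5 and the `+2·prior` in the denominator keep zeros finite and
make the transform scale-invariant up to the prior term (to ~10⁻³ for
counts in the hundreds and above).

**Precision weights.** Per gene, an OLS fit of log₂-CPM on the study
design yields residual standard deviations; the trend of
sqrt(sd) against average log₂ count is smoothed by lowess (span 0.5,
`statsmodels`), and each observation's weight is the trend's predicted
standard deviation at that observation's fitted log₂ count, raised to
−4. With fewer than 10 genes the trend degenerates to its mean (flat
fallback). Weights are clipped at 10⁻¹² from below to remain positive.

**Batch adjustment** (applied on the eQTL path only, see Open choices)
is the parametric empirical-Bayes location/scale correction: per-gene
standardization protecting any covariates, per-batch effect estimates,
shrinkage of locations toward a normal batch-level prior and of scales
toward an inverse-gamma prior by moment matching, iterated to relative
tolerance 10⁻⁴ (max 100 iterations), then removal. A single-batch input
is returned unchanged; a batch with one sample is an error. The
implementation is checked against `sva::ComBat` at 10⁻³.

## Phenotype association

Donors are assigned glycemic strata from HbA1c (NGSP %): NGT < 6.0,
IGT in [6.0, 6.5), T2D at ≥ 6.5 or on clinical diagnosis. Boundary
convention (lower inclusive, upper exclusive) is pinned but
configurable. Donors who are T2D by HbA1c alone are excluded from the
T2D-versus-control contrast while keeping their stratum — both the
categorical and continuous HbA1c analyses still use them.

Each phenotype (T2D status, stratum, HbA1c, BMI, stimulatory index) is
fitted separately: intercept + phenotype encoding + purity + sex + age.
Rows missing the phenotype are dropped only for that phenotype's
analysis. Constant covariates are dropped with a warning; genuine rank
deficiency is an error naming the collinear columns.

Inference is weighted least squares per gene with the voom-style
weights. Variance moderation follows the standard empirical-Bayes
scheme: the prior df d₀ and variance s₀² are obtained by matching the
mean and variance of log s²_g to the theoretical moments of a log scaled
F distribution, with the trigamma inverse solved by Newton iteration
(relative tolerance 10⁻⁸). The moderated variance is
s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) and tests use d₀ + d degrees of
freedom (normal/χ² limits when d₀ = ∞, which occurs when the observed
spread of log-variances is no larger than chi-square sampling alone
predicts). At d₀ = 0 the statistic reduces to the ordinary t (verified
in tests). `moderation=False` gives exact per-gene WLS, used for oracle
testing.

For the stratum phenotype (two dummies, NGT reference) the reported p is
a joint moderated F test of both columns; per-contrast slopes are
emitted alongside. `r2` is the partial coefficient of determination of
the phenotype term given the covariates — the relative drop in weighted
residual sum of squares — since a per-gene "R²" is otherwise ambiguous
under covariate adjustment.

BH adjustment (step-up with monotonicity) is delegated to
`statsmodels.stats.multitest.multipletests`; the test suite pins it to a
brute-force step-up oracle at 10⁻¹². Percentage rank is
100·rank(p)/n with average ranks on ties.

## Empirical coexpression null

Spearman correlation is Pearson on average ranks. The null draws
`n_pairs = 1,000,000` unordered non-self gene pairs uniformly **with**
replacement from the filtered universe (collisions are immaterial at
this universe size) and stores the sorted |ρ|. The empirical p of an
observed ρ is the fraction of background pairs with |ρ_bg| ≥ |ρ| —
two-sided on the absolute value, with the signed ρ still reported. A
zero count is floored at 1/n_pairs so −log₁₀ transforms stay finite; a
raw-proportion mode (`floor=False`) exists for literal reproduction.
The null records a SHA-256 digest of the gene universe and refuses
queries against a different universe.

## cis-eQTL scan

Pairs are gene × variant on the same chromosome with the variant inside
[start − 2 Mb, end + 2 Mb], boundary inclusive (a TSS-anchored window is
available behind `anchor="tss"`). Distance is 0 in the gene body, signed
outward otherwise. Expression and dosage are residualized on the
covariates (at least an intercept; by default nothing more, batch having
been removed upstream), the per-pair correlation r of the residuals is
converted to t = r√(d/(1 − r²)) on d = n − 1 − rank(nuisance incl.
intercept) df, and beta is the regression slope in log₂-CPM per alt
allele (the effect allele is always alt). BH runs across **all** tests
in the scan, not per gene. Pairs whose dosage is constant after
residualization are skipped and counted. The vectorized path is pinned
to independent per-pair regressions at 10⁻⁸. Per-gene summaries take
the smallest p as lead (ties: smaller |distance|, then variant id) and
report the top 10.

## Bootstrap enrichment

For a set S and target gene t, the statistic is the mean over S of the
empirical coexpression p versus t. B = 10,000 random sets of size |S|
are drawn uniformly without replacement (within a set) from the universe
excluding t — the query set's own genes are *not* excluded — and
p_boot = (1 + #{null ≤ observed})/(B + 1), one-sided for enrichment
(small means), with an optional doubled-tail two-sided mode. The
add-one rule keeps p_boot positive and the result bit-reproducible for
a given seed.

## Reports and segments

A gene report is assembled purely by copying numbers from upstream
tables (annotation, rank panel, purity panel, association panels,
hormone panel, top-100 coexpressed, top-10 eQTLs, optional cell-type
lookup); any missing panel is marked absent with a reason, and a gene
removed by QC raises an error naming the filtering step. JSON output is
deterministic (sorted keys, floats rounded at 10 digits). The
expression-rank panel uses the **mean** log₂-CPM (median behind a flag),
ranked descending so the top gene of 200 is "top 0.5 %". Reports are
static JSON/TSV; no plotting layer is included — the documents carry all
panel data and plotting would add no logic.

Cross-tissue segments classify islet-expressed genes (call: CPM ≥ 1 in
strictly more than 80 % of a tissue's samples) by their tissue
combination: A islet-only, B +liver, C +muscle, D +fat, E fat+liver,
F liver+muscle, G fat+muscle, H all four. Non-islet genes carry no
segment, so segment counts over a gene set always sum to its
islet-expressed count.

## Synthetic cohort generator

The generator emulates a donor-islet cohort at the study's composition:
188 donors — 33 clinical T2D, 25 T2D by HbA1c ≥ 6.5 % only, 30 IGT —
with HbA1c drawn consistently with each stratum (NGT ~ N(5.4, 0.3)
truncated below 6; IGT uniform on [6, 6.5); T2D 6.5 + Exp(0.8)). The
default gene universe is 2,000 genes — a desk-scale stand-in for the
~14,000 genes a real cohort retains — laid out round-robin over 22
chromosomes at 1 Mb spacing so cis windows behave realistically.

Per-gene baseline abundance is log-normal (log₂ sd 1.5). Effects add on
the log₂ mean:

- **Purity**: donor purity ~ U[40, 100], except T2D donors whose upper
  bound drops by 15 points — a deliberate purity–status confound. Half
  of the genes (`frac_purity_genes = 0.5`, mirroring the observed share
  of purity-correlated transcripts) receive a loading ~ N(0, 0.02) per
  purity percent; negative loadings play the role of exocrine genes.
  The loading scale makes the confound strong enough that omitting the
  covariate inflates T2D false positives several-fold while keeping
  adjusted analyses calibrated.
- **Differential expression**: `n_de_genes = 100` genes at
  `de_log2fc = 1` with random sign, applied to the whole T2D stratum.
- **Coexpression modules**: one module of 30 genes anchored on each
  hormone gene (INS, GCG, SST, PPY, IAPP, GHRL); members share a
  standard-normal donor factor at loading 1.0 (log₂ units per factor SD).
- **eQTLs**: 50 genes receive 5 candidate variants within ±1 Mb (one
  causal at beta = 1.0 log₂ per alt allele, dosage ~ Binomial(2, MAF),
  MAF ~ U[0.1, 0.5]) plus 2 decoy variants placed beyond 2.5 Mb to
  exercise the window boundary structurally.
- **Batches**: 3 batches with per-gene location shifts ~ N(0, 0.3) and
  scale factors exp(N(0, 0.1)) applied to an extra per-observation
  N(0, 0.2) noise term, so both halves of the location/scale correction
  are exercised.

Counts are gamma–Poisson (negative binomial, dispersion 0.1 — CV ≈ 32 %
at high abundance, typical of bulk RNA-seq biological replicates) at a
donor depth ~ U[15 M, 40 M]; abundances are renormalized to the depth,
so composition effects are real. The tissue-panel generator produces
fat/islet/liver/muscle samples with 5 % of genes strongly specific per
tissue (off-tissue abundance far below the 1-CPM call) and the rest
ubiquitous.

**What the generator does not emulate** — and hence what passing tests
do not establish for real data: linkage disequilibrium among variants,
realistic gene-length and GC composition, library-preparation artifacts,
count outliers/sample swaps, cell-type mixtures beyond the single purity
axis, and non-linear phenotype effects. Calibration and recovery results
are statements about the model class, not guarantees on any particular
cohort.

## Open choices, pinned

- **MAF filter** for eQTL variants defaults to 0.05 (configurable); no
  such filter is inherent to the method.
- **Batch in association**: batch is excluded from the association
  design by default and removed only on the eQTL path; both are flags.
- **Strata test**: joint F of both stratum dummies, with per-contrast
  slopes also reported.
- **Pair sampling** for the null: with replacement, self-pairs excluded.
- **Enrichment null sets**: query genes not excluded from the sampling
  pool.
- **Problem sizes**: tests and the acceptance script run cohorts of a
  few hundred to 2,000 genes and 60–188 donors, and scale the pair count
  (20,000–200,000) and bootstrap iterations (200–10,000) accordingly;
  these sizes are large enough for the calibration bands and recovery
  thresholds being checked while keeping runs reproducible on a laptop.

## Known limitations

- The moderated-F path reports the sign of the first contrast alongside
  the joint statistic; a full per-contrast moderated analysis requires
  separate single-dummy fits.
- ComBat-style adjustment is parametric only.
- The eQTL scan fits one variant at a time (no conditional analysis or
  fine-mapping) and codes dosage additively.
- `cyvcf2` handles VCF parsing; exotic VCF features (phased ploidy > 2,
  symbolic alleles) are untested.
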