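# Methods

This note documents the statistical models the package implements, the
defaults and why, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Conventions

- **Scale.** All expression and accessibility analysis happens on the
  log2 scale. Linear expression is floored at 1 before the transform, so
  log2 values are ≥ 0 and a "not detected" measurement maps to 0.
- **Fold change** is the difference of group means of log2 values
  (female − male unless stated), i.e. the log2 ratio of geometric means.
  The alternative reading — log2 of the ratio of arithmetic linear
  means — is *not* used: every stored value is already log2 and the
  paired statistic operates on log2 differences, so the
  difference-of-log-means convention keeps the effect estimate and the
  test statistic aligned.
- **Standard deviations** use the n−1 denominator everywhere
  (`preprocess.SD_DDOF`).
- **Genomic coordinates** are 0-based half-open (BED convention).
- Factor levels (sex F/M, stimulation, tissue) are canonicalized at the
  I/O boundary; downstream code assumes clean levels.

## Preprocessing

*Noise filter*: a gene is kept iff its log2 expression is **strictly**
above the threshold in at least `min_samples` samples. Typical settings
pair a threshold of 5–6 log2 units with `min_samples` equal to the
smallest comparison group (6 for the main paired designs, 2–3 for small
cohorts). Boundary equality drops the gene.

*Z-normalization* (per gene: subtract mean, divide by sample SD) is
applied before PCA, correlation and heatmap-style analyses. A
zero-variance gene is an error, never a silent division: the caller
decides whether to drop it.

*Median-of-ratios* size factors (for raw counts): s_j = median over
genes expressed in all samples of count_gj / geometric mean_g. *Quantile
normalization* (for accessibility indices) forces every column onto the
mean sorted profile, ties receiving the mean of the implicated reference
values. *Median polish* (for probe-to-gene summarization) follows
Tukey's classic order — rows swept first — with max_iter = 10,
tol = 1e-6.

*PCA* treats samples as observations and genes as variables, on the
z-normalized matrix. Whether to standardize or merely center genes
before PCA is a genuine choice; we standardize, and note that variance
fractions differ between the two. Component signs are fixed by making
the largest-|loading| gene positive, so results are reproducible; tests
are written sign-invariantly. A gene "contributes" to a component when
its |coefficient| exceeds 0.05. The *first sex-separating component* is
the smallest index whose female and male scores differ by a paired
t-test at pFDR < 0.05 (BH across the components tested); the
significance gate is this package's choice — the underlying analysis
idiom reports the pFDR without stating one.

## Differential expression

**Pairing.** Within each stratum of the blocking keys (cell type,
dataset, age group), females and males are matched; when several
replicates exist the within-stratum matching is uniform-random, driven
by a seed, and surplus samples are reported unpaired. Strata with one
sex contribute nothing — that is a design property, not an error.

**Paired t.** Classical two-sided paired t on within-pair differences,
df = n_pairs − 1. **Unpaired t** defaults to Welch (unequal variances);
pooled variance is available by flag, since nothing forces either
choice at these sample sizes.

**Degeneracy.** A gene whose within-pair differences have zero variance
is flagged; it gets p = 1 when the mean difference is also zero, and the
smallest positive float when the groups differ exactly (an infinite t).
This keeps FDR vectors complete without NaN propagation and treats the
paired and unpaired paths identically.

**Calling.** SDEG ⇔ pFDR < 0.2 ∧ |log2 FC| > log2 1.5, both strict,
partitioned by sign into female- and male-higher lists. The
IFN-stimulation variant uses pFDR < 0.05 and 2-fold. BH is implemented
as stated (step-up, via `statsmodels.multipletests`), not Storey's
q-value.

**Two-way ANOVA** (sex × tissue, with interaction) uses Type III sums
of squares under sum-to-zero contrasts — robust to the unbalanced 2–3
replicate designs tissue comparisons produce — computed by comparing
residual sums of squares of the full model against models dropping one
effect's columns; Type II is available by flag. Verified against
`statsmodels.anova_lm(typ=3)` on unbalanced data. A sex-effect gene
must pass pFDR < 0.2 **and** show a >1.5-fold change with consistent
sign in *every* tissue; an interaction gene for tissue T needs the
interaction pFDR, the fold change in T, and an expression gate. Two
gate variants exist because the analysis idiom is attested both ways:
the default requires expression above threshold in *all* female or all
male samples of T (`all_one_sex`); `two_samples` requires any two
samples of T. We default to the stricter rule and expose the other
rather than guessing which produced any particular published count.
Per-tissue contrasts are computed from cell means; the exact post-ANOVA
multiple-comparison procedure being unspecified upstream, this is
documented as our resolution.

## Permutation machinery

Two designs mirror the two randomizations a paired sex comparison
admits: `within_pair_flip` (swap each pair's labels with probability
1/2; the null for paired statistics, preserving all confounding
structure) and `group_label_shuffle` (uniform relabeling at fixed group
sizes; the null for unpaired statistics). The method is permutation —
resampling *without* replacement — even where the literature calls such
procedures "bootstrap".

Monte-Carlo p-values use (r+1)/(B+1), which is never zero; the raw
exceedance count is stored so a "< 1/B" statement remains recoverable.
When the assignment space has at most 2¹⁴ members the null is
enumerated exhaustively and p = r/N over the full space (which contains
the identity, so p > 0). Two-sided statistics are permuted on
|statistic|; intrinsically one-sided statistics (e.g. an SDEG count)
use the upper tail. `paired_t_signflip_pvalues` vectorizes the
sign-flip null of the paired t across all genes at once, exploiting the
invariance of Σd² under sign flips.

## Enrichment

The pre-ranked enrichment score is the signed maximum deviation of the
weighted KS walk: hits advance by |score|^p normalized over hits
(p = 1 by default, the standard "weighted" setting), misses retreat by
1/(N − N_hits). Peak ties within 1e-9 resolve to the earliest position.
The null for each set is B = 1000 random same-size gene sets drawn from
the ranked universe — the standard pre-ranked null, since phenotype
permutation does not exist for a user-supplied ranking. NES divides ES
by the mean same-sign null magnitude; nominal p is the same-sign null
tail; the FDR q follows the original sign-stratified pooled-null
scheme, with BH available by flag for cross-checking. Size limits
default to 15–500 after restriction to the ranked universe; excluded
sets are reported, not dropped silently. Ranked-list ties keep stable
input order.

Over-representation p-values are upper-tail hypergeometric,
P(X ≥ overlap), against a fixed expressed-gene background supplied by
the caller (e.g. 10,264 genes for a tissue-macrophage analysis).

## Signature shift tests

These treat *genes* as the unit of inference, which ignores inter-gene
correlation and makes analytic p-values anti-conservative — the reason
every analytic shift p is designed to be co-reported with a permutation
p. The permutation shuffles gene-set membership labels (which genes
carry the signature), the natural exchangeability for a gene-level
statistic; shuffling sample labels instead is the documented
alternative. Signature genes are first filtered to those expressed
above the noise threshold in ≥ 3 samples. The paired stimulation
comparison computes, per gene, the stimulated-minus-unstimulated fold
change separately within each sex and tests the per-gene female−male
difference of those fold changes with a paired t across genes.

## Differential accessibility

For OCR i with overall mean intensity m_i, the window holds every
*other* OCR j with |m_j − m_i| ≤ w/2, where w = 1 log2 unit by default
(the focal OCR is left out so its own difference cannot inflate its
null scale; a full-width ±1 window is available by flag). The scale is
σ_i = 1.4826 × MAD of the window's female−male differences — the
normal-consistency conversion, needed because z-scores are referred to
the standard normal. Windows are computed on the pooled (both-sex) mean
intensity. Windows smaller than min_window = 50 expand symmetrically to
the nearest OCRs in intensity and are flagged; a zero window MAD falls
back to the global MAD (flagged); a zero global MAD is an error. The
method assumes most OCRs are not differential, so the windowed spread
estimates the null. DO calling and gene-body fold-change comparisons
reuse the differential-expression conventions (BH, strict thresholds,
Welch + permutation).

The min_window floor and the leave-one-out window are this package's
choices where the underlying procedure leaves them open; both vanish
asymptotically in dense intensity ranges.

## Cross-species comparison

Ortholog relations are resolved to one-to-one by keeping, per human
symbol, the highest-confidence pairing and dropping contested mouse
symbols (reported, not silent). The joined universe is human genes with
qFDR < 0.05 whose mouse ortholog is expressed (> 0) in ≥ 3 mouse
samples. At each fold-change threshold t (strict >; t = 0 is pure sign
concordance), the hypergeometric parameterization is: population = the
joined universe, successes = mouse same-direction genes, draws = human
same-direction genes, observed = their overlap. The p at threshold t
deliberately keeps the population fixed at the full joined universe. A
binomial sign test is available as an alternative parameterization. The
human cohort gene filter removes a gene only when it is below the
per-sample 10% expression quantile in more than 2/3 of males **and**
more than 2/3 of females — the conjunction reading; low expression in
one sex alone (a plausible sex effect) never removes a gene.

## Synthetic data

The generator simulates directly on the log2 scale rather than through
a count model: log2 value = gene baseline (N(8, 1.5²)) + cell-type
effect (N(0, 2²) — deliberately the dominant axis) + dataset batch
(N(0, 0.4²)) + age effect (N(0, 0.2²)) + ±half the planted sex effect
+ N(0, 0.3²) residual, floored at 0. Defaults emulate a two-dataset
design with three replicates per (sex, cell type, dataset) — six
female/male pairs per cell type after pairing on dataset and age, the
sample size at which the analyses here operate. Planted sex effects are
pan-immune or cell-type-scoped; sex-chromosome labels are metadata only
(no X-inactivation mechanism is modeled). The ISG module adds a small
female-upward baseline shift, a large IFN induction (mean 3 log2
units), and a female-specific extra induction — the sex × IFN
interaction. The ATAC generator draws OCR mean intensities uniformly
and gives replicates normal noise whose SD halves per +2 log2 units of
intensity (0.5 at the dim end), the heteroscedasticity that motivates
the windowed test. A negative-binomial count mode exists solely to
exercise the median-of-ratios path.

For planted-effect recovery experiments, effect magnitudes are drawn
uniformly on [0.8, 4.0] log2 units with random sign: from just above
the SDEG fold-change criterion up to the ~16-fold scale that X-linked
sex markers reach. What the generator does *not* emulate: inter-gene
correlation (each gene's noise is independent, so gene-level shift
tests are better calibrated here than on real data — on real data the
permutation p is the trustworthy one), cell-type frequency differences
between sexes, count-level technical artifacts, and read-level noise.
Passing tests therefore certify the statistical machinery, not the
biology of any particular dataset.

## Problem sizes in the validation suite

The acceptance-style checks run at sizes chosen to make their
statistical assertions meaningful while staying desk-scale: 10,000
genes × 6 pairs for null calibration, 20,000 OCRs for accessibility
calibration, 20 simulations of 40 planted effects for recovery, 100
simulations for shift-test power, and 100 datasets for
Monte-Carlo-versus-exhaustive permutation agreement. Exact-agreement
checks (t-tests, BH, hypergeometric, enrichment score, median polish)
use ≥ 1000 random small instances against brute-force references
implemented independently in the test suite.

## Known limitations

- Gene-level analytic shift p-values are anti-conservative under
  inter-gene correlation; always prefer the co-reported permutation p
  on real data.
- The ANOVA caller computes per-tissue contrasts from cell means, not
  from a formal post-hoc procedure with family-wise control.
- The MAD-windowed test assumes the large majority of OCRs are null
  within every intensity window; a locus-dense region of true
  differences would inflate the local scale and cost power.
- Surrogate-variable / empirical-Bayes moderated human DE models are
  consumed as precomputed tables, never fit here.
- The GSEA FDR q follows the original pooled-null scheme, which is
  known to be conservative for small collections; the BH flag exists
  for sensitivity analysis.
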