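# Methods

## The two strategies

Both strategies start from a table of non-negative integer read counts
over exon bins (disjoint exonic intervals of a flattened gene model,
keyed `geneID:exonBin`) with samples in two groups.

**Gene-based (conventional).** Exon counts are summed per gene and the
summed counts are tested directly; genes are ranked by the BH-adjusted
p-value of that single test.

**Exon-based.** Each exon is tested on its own, and the per-exon results
(x_i, p_i) — log2 fold change and two-sided p-value — are combined per
gene into the signed log-p median

    m = median_i [ sgn(x_i) * (-ln p_i) ],    i = 1..n exons.

Natural logarithms are used throughout: under the null each summand is
then exactly a standard Laplace variate (see below), which yields a
closed-form null for odd n. The reported `median_p = exp(-|m|)` is a
p-value-scale magnitude and is invariant to the choice of log base. The
aggregation is deliberately test-agnostic: any per-exon testing tool can
be substituted by providing its (exon_id, log2fc, pvalue) table, and the
`aggregator` option accepts `mean` as an alternative summary, though the
median is the default precisely because of its robustness to single
deviant exons.

## Filtering

Before either strategy runs, exons whose mean count across **all**
samples (groups pooled) is not strictly greater than `min_avg = 1` are
removed; genes keep at least `min_exons = 2` surviving exons or are
dropped; single-exon genes are dropped regardless of expression, since
testing their one exon and testing their gene-level count are the same
analysis. The filter is idempotent and its tallies are logged. The
pooled-mean reading (rather than mean-of-group-means) is the simplest
interpretation of an "overall average" rule; both the cutoff and the
minimum exon count are configurable.

By default the gene-based strategy sums over **all** exons of retained
genes, not just the exons that survived the filter, so the summed count
represents the gene's full signal; `sum_filtered_exons_only=True`
restricts the sum to surviving exons.

## Normalization and the built-in test

Library-size normalization uses trimmed-mean-of-M-values (TMM) scaling
factors: the reference sample is the one whose upper-quartile count
fraction is closest to the mean; per-feature log-ratios M against the
reference are doubly trimmed (30% on M, 5% on A, rank-based) and averaged
with delta-method precision weights, excluding features with a zero count
in either sample; factors are rescaled to geometric mean 1 (enforced to
1e-12). The implementation was validated once against the canonical R
implementation on a fixed fixture; those reference factors are frozen in
the test suite. Expression is then log2 counts-per-million with a prior
count of 0.5 on effective library sizes:
`log2((y + 0.5) / (eff_lib + 1) * 1e6)`.

The built-in test is a trend-free empirical-Bayes moderated t on log-CPM:
per-feature pooled two-group variances s2 with df = n1 + n2 - 2 are
shrunk toward a scaled inverse-chi-square prior (d0, s0^2) fitted by the
log-scale method of moments (digamma/trigamma relations, Newton inversion
of the trigamma); the posterior variance is
`(d0 s0^2 + df s2) / (d0 + df)` and the reference distribution a t with
d0 + df degrees of freedom (normal when d0 is infinite). One special
case: when every s2 is identical there is no sampling noise to de-bias,
so the prior scale is taken to be that common value rather than the
bias-corrected `exp(mean(e))` that the moment estimator would return for
a degenerate spread. No mean-variance precision weighting is applied in
this version; for the count depths the defaults simulate, the per-exon
type-I error is calibrated (checked at alpha = 0.01 and 0.05 in the
suite), and the strategy contract only requires *a* calibrated member of
the moderated-t family — external tests can replace it entirely.

## The null distribution of m

Significance of m is assessed against the null in which the exon p-values
are independent Uniform(0,1) and the signs are independent fair coin
flips (the symmetric reading of "taking the directions into account").
Then S = sgn * (-ln U) has density e^(-|s|)/2 — standard Laplace — and
the null of m is the distribution of a Laplace median:

- **odd n** (and n = 1): with q(t) = P(S >= t) = e^(-t)/2,
  `P(|m| >= t) = 2 * sum_{k >= (n+1)/2} C(n,k) q^k (1-q)^(n-k)`,
  evaluated through the binomial survival function. Spot value:
  n = 3, t = 1 gives 0.178109...
- **even n** (median = mean of the two central order statistics): Monte
  Carlo, 2 x 10^6 replicates per n with a fixed recorded seed, tabulated
  on a log-spaced t grid with log-linear tail interpolation. Beyond the
  largest simulated value the log-tail is extrapolated linearly with a
  slope fitted by least squares over the extreme-tail knots (empirical
  tail below 500/reps); individual knots there rest on a handful of draws
  and would give unstable pairwise slopes. Extrapolated tails are
  order-of-magnitude accurate only; they affect genes that are already
  far beyond any calling threshold, while the calibration-relevant region
  (null_p above ~1e-4) lies well inside the grid. Tables are cached in
  memory per (n, reps, seed) and optionally on disk as JSON with exact
  float round-trip, so reloads are bit-identical.

The gene's null p-value is `null_p = P(|M_n| >= |m|)`; BH adjustment over
all scored genes gives `fdr`; and `final_score = max(median_p, fdr)` is
used for ranking and calling. The max rule implements the requirement
that the back-transformed median p-value itself be below any FDR level
the gene is reported at. p-values are clamped to [1e-300, 1] before the
log transform (clamping is logged); sgn(0) = 0, so a zero fold change
contributes a zero score.

Calling criteria (defaults): final score < 0.05, |median log2 FC| >=
log2(1.5), >= 5 tested exons, and — exon-based only — median_p < 0.05.
Fold-change thresholds phrased on the linear scale ("at least 1.5-fold")
are applied as log2 cutoffs.

## Synthetic data

The generator draws, per gene, a log-normal baseline expression
(meanlog 6.0, sdlog 1.2: median ~400 expected reads per gene), a uniform
2–15 exon count, and a symmetric Dirichlet (alpha = 5) usage vector
spreading the gene's expression over its exons. A fraction `de_fraction`
(default 0.1) of genes receives a common exon-wise log2 fold change
sign * N(1, 0.25^2); each exon of a DE gene independently becomes an
"outlier" with probability `outlier_exon_prob` (default 0.1), receiving
an opposite-sign effect of magnitude N(2, 0.5^2) — a splice-like deviant
signal without modelling isoforms. Sample depths are log-normal
multipliers (sdlog 0.15), and counts are negative binomial with
`var = mu + phi mu^2`, phi = 0.1 constant by default (a mean-dependent
dispersion can be passed as a hook; heterogeneous-cohort regimes are
emulated by inflating phi and the depth spread, with no attempt to model
population structure). Group-1 means are the baseline; group-2 means are
multiplied by 2^lfc, so the tested contrast estimates lfc directly.

`make_outlier_gene_case` builds the canonical failure mode as a focused
experiment: one signal gene whose n-1 exons change by +1 log2 unit while
one exon carries half the gene's reads and moves 4 log2 units the other
way, embedded among 200 null genes (7 vs 7 samples, gene mean 2000) so
that the FDR machinery operates on a realistic universe. The deviant exon
dominates the sum — the summed-count fold change collapses toward zero —
while the median of the exon scores is untouched by it.

What the simulation does **not** emulate: read-level effects (positional
bias, mappability), correlated exon usage within genes, isoform
structure, and real biological covariance between samples. Passing the
simulation-based checks therefore shows the statistical machinery behaves
as designed under its stated model, not that the strategy's advantage
carries any particular effect size on a given real dataset.

## Evaluation

Gold standards follow the validation-assay convention: genes detected in
at least 3 of 4 replicate measurements in at least one group enter; those
with |log2 FC| above a stringency cutoff are positives, below 0.2
negatives, in between unlabeled. ROC curves ignore unlabeled genes; the
headline metric is the trapezoidal partial AUC over false-positive rate
in [0, 0.2] divided by 0.2, so a perfect ranking scores 1.0 and an
exchangeable-random ranking 0.1 in expectation. (The McClish-corrected
partial AUC offered by common ML libraries is a different standardization
and is not used.) Empirical FDR of a detection list is the fraction of
gold-labeled detections that are negatives, after removing detections
with analysis |log2 FC| < 0.2; the random baseline redraws equally sized
gene sets from all scored genes (configurable universe) and averages.
The discrepancy report lists genes with more than 3 exons where one
strategy is significant (p, or median p, below 0.05) with a fold change
above 2, while the other strategy points the opposite direction or
differs in p by more than 0.1 (gene-based p against exon-based final
score, both on the probability scale), annotated with the median and
standard deviation of the exon-level fold changes.

## Problem sizes and numerical choices

The self-checks run at desk scale, chosen to keep the whole suite fast
while leaving the statistical conclusions stable: null calibration at
2000 genes x 3 seeds (5 vs 5), the outlier study at 25 seeds, the ranking
comparison at 3000 genes x 10 seeds (7 vs 7), and the Monte Carlo null
oracle at 10^7 draws. Stochastic assertions use fixed seeds; Monte Carlo
comparisons are asserted within 3 standard errors with the SE computed
from the analytic value (robust when the empirical count is zero).

Known limitations: the even-n null is tabulated, not exact; the built-in
test ignores any mean-variance trend (low-count exons lean on the shrunk
prior); TMM assumes most features are not differential; and the max rule
makes the final score a conservative hybrid — it is a ranking device, not
a p-value.
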