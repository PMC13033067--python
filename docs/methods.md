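# Methods

This note records the statistical model behind each pipeline stage, the
defaults that matter, what the synthetic cohorts do and do not emulate,
and the numerical choices a maintainer would want to know about.

## Progression-tracking normalization

Late-stage (advanced) tumor expression is referenced against the average
early-stage profile of the same cohort. With early matrix `E` over `r`
early samples and advanced matrix `A`,

    m_i = (1/r) * Σ_k E[i, k]          (per-gene early mean)
    L[i, j] = ln( A[i, j] / m_i )      (log-ratio of each late sample)

`L` exposes expression change accumulated along disease progression: a
gene that has not moved since the early stage sits at 0, down-regulation
is negative. Inputs must be on the count-plus-one scale (every entry
≥ 1, i.e. undone log2(count+1) values), which keeps the ratio and the
logarithm defined without pseudocounts; entries below 1 are an error,
never silently clamped. Genes are aligned by identifier, and a mismatch
between the early and late gene sets is an error listing the symmetric
difference.

`L` is natural-log by definition. The differential-expression stage owns
any base conversion: when it receives `L` it divides the group contrast
by ln 2 so fold-change thresholds are on the conventional log2 scale.
The conversion affects only the reported LFC; t and p are scale
invariant.

## Subtype discovery

Samples (not genes) are clustered on the cosine distance
`d(a,b) = 1 − a·b / (‖a‖‖b‖)` between their progression profiles, with
Ward agglomeration. Because "Ward on a precomputed non-Euclidean
distance" is a known dialect issue, both recurrences are available:
`variant="D2"` (default) runs the Lance–Williams update on squared
distances (R `hclust` ward.D2, scipy `ward`), `variant="D"` on the raw
distances (ward.D).

The number of subtypes k is chosen by cutting the dendrogram at each
candidate k in 2..min(10, n−1) and maximizing the mean silhouette width
computed from the same distance matrix; singleton clusters score 0, and
ties prefer the smallest k. Subtypes are named by descending size —
`L`(arge) and `S`(mall) for k = 2 — with size ties broken by the
smallest leaf index in dendrogram order. Concordance between two
labelings (e.g. full transcriptome vs. a reduced panel) is the fraction
of co-assigned samples under the best label bijection (Hungarian
assignment; an exhaustive-permutation oracle backs it in tests).

## Differential expression

One moderated-t engine serves two branches.

*mRNA branch* (continuous): the progression matrix is tested directly —
no count filtering or between-sample normalization — contrasting the
smaller subtype S against the reference L. Calls: `up` if
LFC ≥ 1.5 and BH-adjusted p < .05, `down` if LFC ≤ −1.5, else `ns`
(LFC cutoffs inclusive, alpha exclusive).

*count branch* (miRNA-style): features are filtered by the
group-aware rule (CPM above the cutoff implied by `min_count = 10` at
the median library size in at least as many samples as the smallest
group, and total count ≥ 15), libraries are TMM-normalized, log2-CPM is
computed with a 0.5 prior count, and a mean–variance precision weighting
(lowess trend of √sd against mean log-CPM, evaluated at
depth-adjusted fitted values, weights = trend⁻⁴) feeds a weighted
moderated test. Significance: adjusted p ≤ .05 and |LFC| ≥ 1.

The empirical-Bayes moderation estimates a prior (d0, s0²) by matching
moments of log s_g² to a scaled-F distribution: with
e_g = log s_g² − ψ(d/2) + log(d/2), the prior df solves
ψ′(d0/2) = var(e) − ψ′(d/2) (trigamma inversion by Newton iteration,
tolerance 1e−8, ≤ 50 steps), and s0² = exp(mean(e) + ψ(d0/2) − log(d0/2)).
When the log-variances are underdispersed (var(e) ≤ ψ′(d/2)) the prior
is infinitely strong and located at the arithmetic mean of the observed
variances. Posterior variances are
s̃² = (d0·s0² + d·s²)/(d0 + d); the moderated t uses d0 + d degrees of
freedom capped at the pooled residual df of all features. The
implementation reproduces the reference empirical-Bayes implementation
in R (limma `lmFit`/`eBayes`) to machine precision on shared fixtures,
and the TMM factors reproduce edgeR `calcNormFactors` likewise; both
cross-checks run as tests.

Benjamini–Hochberg adjustment is the plain step-up procedure
(sort, scale by n/i, cumulative minimum from the top, cap at 1).

## Signature selection (SVM-RFE)

A linear SVM (C = 5) is fitted and the feature with the smallest
absolute weight is dropped, iterating down to one feature; above 100
features 10 % of the remainder is dropped per iteration, below that one
per iteration (keeps small problems exact and large ones fast). Panel
sizes are scored by *nested* repeated stratified cross-validation (7
splits × 7 repeats): the elimination is re-run inside every training
fold and each visited size is scored on the held-out fold, reusing the
SVM already fitted for the elimination step. This avoids the selection
bias of scoring full-data panels — with 200 candidate features that
bias saturates CV accuracy at 1.0 for every panel size and makes the
size choice meaningless. The selected size maximizes mean CV accuracy
(smallest on ties, favoring parsimony) and is realized by a final
elimination pass over all samples, which also yields the ranking
(1 = retained longest; batch-eliminated features share a rank).

A caveat that shapes the recovery tests: when planted informative
features are *redundant* (i.i.d. shifts of several SD each), small
panels already classify perfectly, the accuracy curve ties at 1.0 from
roughly three features upward, and the smallest-tie rule correctly
returns a subset of the informative features rather than all of them —
recovering *every* informative feature is only a well-posed demand when
each feature is necessary. The recovery tests therefore plant a
complementary block: five features sharing mean-centered noise, so
their sum separates the classes exactly while every strict subset stays
noisy. Under that construction the selector returns exactly the planted
block with CV accuracy ≈ 1 in essentially every seed.

Cross-dataset validation intersects a panel with the genes present in
both cohorts (microarray platforms lack some RNA-seq genes), gene-wise
z-scores each dataset independently (sample sd, ddof = 1; constant
features map to zero with a warning), trains a linear SVM (C = 5) on
the discovery cohort and applies it frozen to the validation cohort.
Reported: confusion matrix, accuracy, F1 with the smaller subtype as
positive class, ROC AUC from the SVM decision function, and Euclidean
silhouette widths of the external labels in the panel space.

## Immune deconvolution and association analyses

Cell-type fractions are estimated per bulk sample by constrained least
squares on the genes shared with a reference signature matrix:

    min_f Σ_g w_g (b_g − Σ_c f_c S_gc)²   s.t.  f_c ≥ 0,  Σ_c f_c ≤ 1

after rescaling the bulk column and every signature column to a common
total, which makes the estimate invariant to sequencing depth. The sum
constraint is enforced through a non-negative slack component appended
to the design (penalty-weighted equality row, weight 1e4 on the
normalized scale); the slack is reported as `otherCells`, the
unexplained tumor/uncharacterized remainder, and every row of the
fraction table is renormalized to sum to exactly 1 (drift guard 1e−8).
Per-gene weights default to 1 (inverse-variance weights accepted);
optional per-cell-type multipliers support mRNA-per-cell rescaling.
Identifiability caveat: content whose profile is well explained by a
non-negative combination of the signatures is absorbed into the
fractions, so `otherCells` is only meaningful when the unexplained
component (tumor) is concentrated off the marker genes — true for
marker-style signatures, and the regime the recovery tests exercise.

Downstream associations: Kruskal–Wallis (tie-corrected, BH across cell
types) compares fractions between subtypes, with the all-ties case
defined as H = 0, p = 1; Spearman correlations (average ranks,
two-sided p, BH across the tested features; constant vectors flagged
and excluded from the family) relate fractions to driver-gene
expression; gene-set scores are per-sample means of gene-wise z-scored
expression (population sd, ddof = 0, matching the common scipy
convention — the validation z-scoring deliberately uses ddof = 1
instead); purity-adjusted models are OLS fits of
`response ~ subtype + otherCells` with two-sided coefficient t-tests
and BH across the response family, erroring on rank-deficient designs
with a message naming the collinearity.

## Annotation summaries

Over-representation uses the one-sided hypergeometric tail
P(X ≥ k) for the overlap k between a query and each gene set, both
intersected with a user-chosen universe (default: all genes of the
expression matrix), BH across sets. MAF summaries tally, per gene:
altered samples, frequency as a percent of a fixed cohort (cohort
samples absent from the MAF count as unmutated; MAF samples outside the
cohort are an error), total variants, per-classification counts, and
multi-hit samples (≥ 2 variants of the gene in one sample); genes are
ranked by total variant count and the top N (default 20) kept.
miRNA–target edges are retained only when the miRNA is significant,
the target is in the supplied driver list, and the support type is
exactly "Functional MTI" — weaker annotations such as
"Functional MTI (Weak)" are dropped.

## Synthetic cohorts

The generator emulates a two-stage bulk RNA-seq cohort: 47 early-stage
reference samples and 39 late-stage samples split into latent subtypes
of 23 (`L`) and 16 (`S`), over 2 000 genes. Components:

* gene base means log-normal (ln-mean 4.0, ln-sd 1.2);
* negative-binomial counts, shared dispersion 0.08 (BCV ≈ 0.28,
  within the usual bulk RNA-seq range), log-normal library-size factors
  (ln-sd 0.05, modest depth variation);
* a planted subtype block: 200 genes shifted by log2 FC −2 in the
  smaller subtype (tumor-level effect);
* a shared accumulated-progression program: 300 genes shifted by
  |log2 FC| = 1 (random sign) in *all* late samples, with a per-sample
  log-normal(0, 0.15) depth factor. This is the common early-to-late
  change the log-ratio transform is designed to expose, and it is what
  gives late samples directional coherence in log-ratio space. Without
  it, the unshifted subtype's log-ratio vectors are near-isotropic in
  direction, cosine distances between them carry no cluster structure,
  and silhouette-based k-selection fragments the cohort — a geometric
  property of the distance, not a defect of the clustering code;
* immune mixing: bulk = (1 − Σf)·tumor + Σ_c f_c·signature_c in linear
  space over 4 cell types (CD4/CD8 T, B, NK), signatures built from the
  base profile with 30 exclusive 8× markers per type; total immune
  fraction ≈ N(0.2, 0.03), composition Dirichlet (concentration 30),
  and +0.04 added to each T-cell fraction in subtype S (the smaller
  subtype is the immune-infiltrated one). True fractions are recorded;
* per-gene somatic mutations drawn Bernoulli at per-subtype
  frequencies; defaults span the range reported for recurrently mutated
  colon-cancer genes (APC 0.83/0.75, TP53 0.78/0.50, KRAS 0.43/0.44,
  TTN 0.26/0.44, …); 20 % of mutated gene–sample pairs receive a second
  variant so multi-hit summaries are exercised. Mutated gene symbols are
  independent of the synthetic expression gene ids;
* the `+1` offset is applied last, so outputs satisfy the
  count-plus-one invariant exactly.

What the generator does *not* emulate: gene–gene co-expression beyond
the planted programs, realistic marginal distributions of any specific
cohort, co-mutation structure, batch effects, or platform differences.
Passing recovery tests therefore demonstrates that each stage inverts
the generative structure it assumes — not performance on real tumors.

Two study conditions are fixed choices rather than tunable dials: the
clustering-recovery condition uses the full default cohort (mixing on),
while differential-expression calibration uses cohorts with
`n_cell_types = 0`, because linear immune mixing attenuates the
realized bulk fold-change below the planted tumor-level LFC — "planted
LFC = −2" is the true effect of the tested contrast only in unmixed
cohorts.

A smaller generator produces miRNA-style count matrices (500 features,
20 + 20 samples, 25 features planted at log2 FC +3) for the count
branch.

## Numerical choices and degenerate inputs

* All randomness flows from one integer seed through
  `numpy.random.default_rng`; equal seeds give byte-identical outputs.
* Trigamma inversion: Newton, tolerance 1e−8, ≤ 50 iterations, with the
  asymptotic branches 1/√y (y > 1e7) and 1/y (y < 1e−6).
* TMM: reference sample = upper-quartile closest to the mean
  upper-quartile; 30 %/5 % double trim on M/A; delta-method inverse
  weights; factors rescaled to geometric mean 1; identical columns or a
  pure depth change give factors of exactly 1.
* Zero-variance features: a feature identical in both groups gets
  LFC = 0, t = 0, p = 1; an all-constant feature matrix is rejected by
  the panel selector as "no informative features".
* All-zero distances (identical samples) make silhouette-based k
  selection a hard error rather than an arbitrary answer.
* Fraction tables are renormalized post-solve; the NNLS penalty row
  enforces the sum constraint to well below the 1e−8 guard.

## Problem sizes

Recovery and calibration checks run at desk scale: 2 000 genes,
47 + 39 samples, 20 seeds for clustering recovery and null DE
calibration, 3 seeds for planted-effect DE, 100 mixtures for
deconvolution, 20 seeds at n = 80 samples × 200 features for panel
recovery. These sizes keep the full suite and the acceptance script
each within a few minutes on one core while leaving every statistical
margin wide (the binomial error of a 19/20 criterion at the observed
per-seed success rates is small).
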