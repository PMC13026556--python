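# Methods

## Model and procedure

The pipeline compares co-expression between two sample cohorts, "tumor"
(T) and "control" (C), over a small gene panel. Co-expression between genes
i and j within a cohort is Spearman's rank correlation ρ across that
cohort's samples, computed on log2-normalized values with average
(fractional) ranks for ties. The differential statistic per pair is

    Z_ij = (arctanh ρ_T − arctanh ρ_C) / sqrt(1/(n_T − 3) + 1/(n_C − 3)),

the classical two-sample test for equality of correlations after Fisher's
variance-stabilizing transform. Under H0 (equal population correlations)
Z is approximately N(0, 1); the default edge rule Z ≥ 3 is one-sided and
targets *gains* of co-expression in the tumor cohort, with candidate pairs
additionally restricted to ρ_T > 0 (the `positive_only` mask, on by
default) so that a negative link becoming less negative is never called a
gain. Correlations with |ρ| ≥ 1 − 1e−15 are clamped before the arctanh so
perfectly monotone pairs stay finite.

Fisher's variance 1/(n − 3) is exact for Pearson correlations of Gaussian
data; Spearman's asymptotic variance is ≈ 1.06/(n − 3). The uncorrected
denominator is the default (it is the form the statistic is usually quoted
in); `variance_correction=True` applies the 1.06 factor, which shrinks
every Z by √1.06 ≈ 3%. The practical consequence of the default is a
slightly anti-conservative null: simulation at n = 145/255 puts the
empirical per-pair rate of Z ≥ 3 at ~1.4 × 10⁻³ against the nominal
1.35 × 10⁻³, comfortably inside a factor of two.

## Preprocessing

Raw counts are subset to the panel, then genes whose **total count across
samples is strictly below 500** are dropped (a sum of exactly 500 is
kept). Size factors are median-of-ratios: reference genes are those with
no zero in any sample; each sample's factor is the median over reference
genes of count / geometric-mean. Values become log2(count/factor + 1).
The +1 pseudo-count is a deliberate choice (it keeps zeros finite and
maps count 0 to exactly 0); it is configurable in the sense that any
monotone offset leaves all Spearman-based stages unchanged — only the
fold-change scale feels it.

A caveat the simulation exposed: with very small panels (≈10 genes) the
median-of-ratios estimate is itself noisy, and dividing by a noisy factor
perturbs cross-sample ranks enough to attenuate true correlations
noticeably. At the intended panel scale (≈40–60 genes) the effect is
minor. For real data normalized genome-wide upstream, normalize before
subsetting.

## Hub calling

Node degree is counted in the thresholded differential network. The hub
rule selects the top (100 − p)% of *connected* nodes (degree ≥ 1) by
degree, p = 80 by default: the cutoff is the degree of the k-th most
connected node with k = max(1, ⌊(100 − p)/100 · n⌋), and every node at or
above the cutoff is a hub, so ties at the cutoff are included. Direct
consequences: a star's center is the unique hub; if all degrees are equal
every connected node is a hub; p = 0 makes every connected node a hub;
isolated panel genes never enter the distribution. The rule is invariant
to node relabeling.

## Cross-cohort validation

The validation cohort's pairwise Z values are thresholded not at 3 but at
the candidate value (among its distinct Z scores) whose resulting network
density is closest to the discovery network's density, ties broken toward
the stricter threshold — so the two networks are compared at matched
sparsity rather than matched nominal significance (the cohorts differ in
size, hence in power). Agreement is summarized by (a) the Spearman
correlation of node degrees over shared genes with at least `min_degree`
links in either network (default 5; the restriction is exposed because
low-degree nodes carry mostly tie noise), and (b) the partition of the two
hub sets into only-discovery / shared / only-validation.

## Differential expression annotation

Per gene: log2FC is the difference of means on the log2 scale; the test is
Welch's two-sample t-test (pooled-variance optional); adjustment is
Benjamini–Hochberg across the panel. The DE flag is the conjunction
|log2FC| ≥ 1.5 AND adj-p < 0.05 — a gene at log2FC 1.4 is never flagged
regardless of significance. Two-sided testing is assumed.

## Stratification and survival

Fuzzy C-means (c = 2, fuzzifier m = 2, tolerance 1e−6 on the maximum
membership change, ≤ 300 iterations) clusters subjects on the joint
expression of the selected marker genes; centroids are initialized on
distinct observed subjects drawn from the seed, making runs
deterministic. Hard labels are argmax memberships, ties to the lower
cluster index. The cluster with the lower mean of the *summed* marker
expression is tagged "low", the other "high"; an exact tie raises rather
than guessing. Joint 2-D clustering with sum-based tagging was chosen over
clustering a pre-summed score: it lets the two markers carry unequal
variance without one dominating the distance.

The median-split alternative labels each subject hi/lo per marker, "high"
meaning strictly above the per-marker median (exact-median values go low —
deterministic and conservative); explicit thresholds can replace the
medians, e.g. cytometry positivity cutoffs.

Survival curves are Kaplan–Meier product-limit estimates (via lifelines)
honoring right-censoring; groups are compared with the two-group log-rank
test (1-df chi-square). The hazard ratio is Mantel–Haenszel,
HR = (O₁/E₁)/(O₂/E₂) from the log-rank observed/expected tables, with
95% CI exp(log HR ± 1.96·√(1/E₁ + 1/E₂)) — the form commonly reported by
clinical graphing software, preferred here over Cox regression for
transparency at two groups; under heavy censoring or very unbalanced
groups the O/E estimator is mildly attenuated toward 1.

## Synthetic data

The generator draws a latent multivariate Gaussian per cohort and maps it
through the Gaussian copula to negative-binomial marginals
(var = μ + αμ², default μ = 100, α = 0.5, i.e. strong biological
overdispersion typical of across-subject tumor data). Rank correlations
survive the copula exactly up to discretization ties: a latent Pearson ρ
yields Spearman (6/π)·arcsin(ρ/2).

Planted structure, with defaults chosen to mirror the target study design
(39 genes, 145 tumor / 255 control samples, one hub with 8 neighbors at
latent ρ = 0.7):

- **Hubs** exist only in the tumor cohort's latent correlation. Each
  neighbor loads on the hub's latent variable, so hub–neighbor correlation
  is ρ and neighbor–neighbor correlation is ρ². The latter is not a bug: a
  hub-spoke correlation of 0.7 with 8 spokes and *zero* spoke–spoke
  correlation is not a positive-semidefinite matrix. Ground truth records
  only hub–neighbor pairs as planted edges; hub neighborhoods are disjoint
  so degree-based recovery is unambiguous.
- **Low-count genes** get means small enough that expected totals sit
  under the 500-count filter in both cohorts.
- **DE genes** are unstructured genes whose tumor mean is multiplied by
  2^shift (default shift 3).
- **Survival**: each tumor subject is independently assigned high/low
  (p = 0.5); event times are exponential with the high group's hazard
  multiplied by the configured ratio (defaults: baseline 0.055/month ≈
  12.6-month median, ratio 4); censored subjects (probability 0.2) are cut
  at a uniform fraction of their event time. The high group's *marker
  genes* (by default two unstructured genes, so the shift cannot disturb
  planted hubs) have their means multiplied by 2^2, which is what lets
  expression-based stratification recover the planted groups — at default
  noise the recovered grouping agrees with truth for ≈88% of subjects, so
  the estimated hazard ratio is attenuated from the planted 4 toward ~2.5–3
  (misclassification bias), as the acceptance report shows.

What the simulation does **not** emulate: per-sample sequencing-depth
variation (all samples share expected depth, so size factors hover near 1
and normalization is exercised but not strictly required), batch effects,
gene-specific dispersions, library composition bias, and covariate-linked
censoring. Passing tests therefore demonstrate correctness of the
statistics and recovery under the stated generative model, not robustness
to those real-data complications.

## Numerical and design details

- Spearman matrices: constant genes yield ρ = 0 (with a warning) instead
  of NaN; the diagonal is forced to 1.
- Z at exactly the threshold is retained (≥, not >).
- Degenerate inputs raise early with specific messages: < 4 samples (the
  variance needs n − 3 > 0), empty networks at hub calling, all genes
  filtered, no zero-free reference gene for size factors, constant markers
  at median split, ties at cluster tagging.
- All randomness flows from explicit integer seeds via numpy Generators;
  pipeline reports are byte-identical across reruns of the same config
  and seed.

## Problem sizes used in the test-suite and acceptance report

Simulation-based checks run at the study scale (39 genes, 145/255/109
samples) with replicate counts chosen to keep the full suite under a
minute on one core: 50 seeds for hub recovery, 200 for null calibration in
the tests (100 in the acceptance script), 100 for hazard-ratio recovery at
n = 200 + 200, 500 label permutations for log-rank calibration. Monte
Carlo tolerances in tests are stated next to each assertion (typically
3 standard errors or the prescribed factor-of-two band on tail rates).
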