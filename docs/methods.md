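# Methods

## Model

All comparative machinery rests on one statistical model. A continuous
trait evolving by Brownian motion (BM) on a rooted tree with branch
lengths in time units makes the tip values multivariate normal,

    x ~ MVN(mu * 1, sigma2 * C),

where C(i, j) is the path length from the root to the most recent common
ancestor of tips i and j (so the diagonal is the root-to-tip distance, and
on an ultrametric tree equals the tree depth everywhere). Pagel's lambda
multiplies the off-diagonal of C while leaving the diagonal alone:
lambda = 1 is pure BM covariance, lambda = 0 is complete phylogenetic
independence. The analysis scale is log10 throughout — species richness,
mean range size and mean abundance are all strongly right-skewed, and the
log transform is applied before any model fitting, correlation or ANOVA.

Given lambda, the remaining parameters have a closed generalized-least-
squares profile: mu_hat = (1' C^-1 x)/(1' C^-1 1) and
sigma2_hat = (x - mu_hat)' C^-1 (x - mu_hat)/n (maximum likelihood, not
REML, so AIC values are comparable across covariance structures under the
shared mean model). The lambda search is therefore one-dimensional.

### Numerical policy

* All solves use Cholesky factorization. If factorization fails, jitter of
  1e-10 x mean(diag) is added once; a second failure raises with the
  condition number. Constant traits yield sigma2_hat = 0 and are returned
  with a degenerate-fit flag rather than an error.
* The lambda profile on [0, 1] can be monotone (maximum on a boundary) or
  multimodal with narrow interior peaks — both occur on small trees with
  short branches. The optimizer therefore evaluates a 21-point coarse grid
  first and refines with bounded scalar minimization (absolute tolerance
  1e-8 on lambda) inside the bracketing interval, always also checking the
  endpoints 0 and 1.
* lambda > 1 is rejected rather than allowing the PSD-feasible upper bound:
  the model set compared here is {0, MLE in [0,1], 1}, and values above 1
  produce ill-conditioned covariances on ultrametric trees.
* AIC counts k = 2 parameters (mu, sigma2) for the fixed-lambda models and
  k = 3 when lambda is estimated. Delta-AIC is AIC(best) - AIC(model), so
  the best model reads 0 and worse models negative.

## Independent contrasts

Felsenstein's recursion is run on a strictly binary tree (multifurcations
are first resolved into zero-length branches; the resolution pairs adjacent
children using a seeded generator, preserves leaf order, and provably
leaves the induced covariance untouched, so any resolution gives identical
correlations — a property the tests check). Each internal node contributes
one standardized contrast (x_i - x_j)/sqrt(b_i + b_j); the node takes the
precision-weighted daughter average, written in the reciprocal-free form
(x_i b_j + x_j b_i)/(b_i + b_j) so single zero-length daughters are exact,
and the parent branch is lengthened by b_i b_j/(b_i + b_j). When *both*
daughters have zero length the contrast is undefined; the default policy
adds 1e-8 x tree depth to both branches (strict mode raises instead).
Contrast orientation is deterministic — the daughter subtree containing
the lexicographically smallest tip label is the minuend — and immaterial
to every downstream statistic.

Contrast correlations are uncentered, r = sum(u v)/sqrt(sum(u^2) sum(v^2)),
with the regression through the origin, because each contrast's sign is an
arbitrary orientation choice. The two-sided p uses t = r sqrt(df/(1-r^2))
with df = n_contrasts - 1 (the origin-forced regression estimates one
parameter). Raw correlations use the ordinary centered Pearson r with
df = n - 2.

## Ancestral states and the node scan

Under BM the maximum-likelihood value at an internal node equals the GLS
estimate after re-rooting the tree there. The implementation exploits the
estimate being a fixed linear map of the tips: a tip-to-root pass computes
each node's below-subtree estimate and variance, a root-to-tip pass folds
in the rest of the tree, and running both passes on the identity basis
yields a weight matrix W with one row per internal node, so a full
reconstruction is W @ x and a permutation replicate is one matrix-vector
product. The root row reproduces mu_hat exactly; every row is verified in
the tests against dense re-rooted GLS on explicitly constructed
covariances.

The scan shuffles the trait-to-tip assignment (over the matched tips only)
n_perm times — default 1,000 — with one child seed-stream per replicate,
so parallel and serial execution agree and the scan is bit-reproducible
given the seed. For each node, prob_smaller is the fraction of replicates
reconstructing a strictly smaller value than observed. A node is flagged
"high" when the observed value strictly exceeds 97.5% of the replicates
and "low" when it falls strictly below 97.5% of them; ties (within
floating-point resolution, 1e-9 relative) count toward neither tail, which
keeps both flags conservative and means a constant trait flags nothing.
No correction for testing many nodes is applied — the per-node 2.5%/97.5%
thresholds are the procedure being emulated — but reports carry node
counts so users can post-correct.

## Clade comparison

The across-clade analysis is deliberately non-phylogenetic: one-way ANOVA
with the major clade as grouping factor, R^2 = SSB/SST as effect size, and
Tukey's HSD for pairwise location. Clade sizes are very unequal (few
Magnoliid genera against hundreds of Rosids), so the Tukey-Kramer
standard-error form is used; the studentized-range computation is
delegated to scipy.stats.tukey_hsd and cross-checked in the tests against
a Monte-Carlo null of the maximum pairwise statistic.

## Synthetic data: what it emulates and what it does not

The generator exists so every stage can be exercised and calibrated
without the external species-level range and abundance compilations the
real analysis consumes.

* **Trees** are birth-death simulations conditioned on the number of
  extant tips (dendropy), defaults birth 1.0 / death 0.2 per Myr, rescaled
  to a root depth of 135 Myr — an angiosperm-scale crown age. The
  simulator stops at the birth event reaching the target tip count, which
  would leave a zero-length cherry and a singular covariance, so all
  terminal branches are extended by one exponential waiting time with rate
  n(b+d), exactly the distribution of time to the next event; the tree
  stays ultrametric with strictly positive branches.
* **Traits** are drawn per trait t as mu_t + sqrt(sigma2_t) L_t z_t with
  L_t the Cholesky factor of the lambda-transformed covariance; cross-trait
  dependence comes from giving the per-tip standard-normal innovations the
  target correlation matrix before transport. Defaults are the study
  conditions: lambda = 0.3 for all three characteristics (the intermediate
  signal regime), root values (1.0, 5.3, 6.2) on the log10 scale — a
  10-species median genus, unit-free range areas around 2x10^5, abundances
  around 1.6 million individuals — and rates sigma2 = (0.0027, 0.0022,
  0.0047) per Myr, giving log10-scale tip spreads of roughly 0.6, 0.55 and
  0.8 at depth 135. The trait correlation matrix has richness-range -0.50,
  richness-abundance -0.45 and range-abundance +0.50, matching the
  observed sign structure.
* **Richness** is generated on the log scale, back-transformed and rounded
  to an integer count with a floor of 1; its log10 column is the log of
  the integer, so the table's log transform is exact. The rounding adds
  a small quantization noise at low counts, which slightly widens the
  spread of lambda estimates for richness relative to the continuous
  traits.
* **The study-scale preset** grafts four independently simulated clade
  subtrees (crown ages 100-108 Myr) onto a fixed backbone with the root at
  135 Myr, so the four major clades are exactly monophyletic with sizes
  Rosids 284, Asterids 190, Monocots 94, Magnoliids 63 (631 genera), and
  masks abundance for a random 138 genera, leaving 493 with an estimate —
  the per-characteristic sample sizes the analyses must handle.
* **Temporal resolution.** The preset enforces a 1-Myr floor on branch
  lengths. A dated all-compatible consensus tree carries posterior-median
  node ages, so effectively simultaneous splits do not survive the
  smoothing; raw birth-death simulations, by contrast, routinely contain
  internal branches orders of magnitude shorter. This matters because
  under intermediate lambda the BM standardization underestimates sister
  divergence across short branches by a factor ~(1-lambda)·2T/b, so
  without the floor a handful of near-zero branches dominate the
  uncentered contrast correlation (the effective number of contrasts
  collapses from hundreds to below ten) and its sign becomes unstable
  between realizations. With the floor the preset's contrast correlations
  are stable in sign and magnitude across seeds.

What passing tests on this generator do **not** show: the generator's
traits are exactly multivariate normal on the log scale with a
homogeneous-rate, exact-lambda covariance, missingness is completely at
random, and the taxonomy is clean. Real range and abundance compilations
have heavy-tailed errors, abundance observable only for species reaching
plot-survey size thresholds (missingness correlated with the trait
itself), rate heterogeneity across lineages, and synonymy noise — none of
which the tests probe.

## Problem sizes

The acceptance suite runs at sizes chosen to give tight Monte-Carlo bounds
while keeping the default test run short: 50 random 8-tip trees for oracle
equivalence (grid resolution 0.01 in lambda); 100 replicates of 200-tip
pure-birth trees per generating lambda in {0, 0.3, 0.7, 1} for recovery;
100 replicates at n = 300 for model selection; 200 datasets x 500
permutations at n = 200 for scan calibration, 100 replicates for scan
power; 2,000 null datasets for the ANOVA rejection rate; and the full
631-genus preset for the end-to-end emulation. The entire suite completes
in a few minutes on one CPU.

## Known limitations

* Only Pagel's lambda is implemented as a signal statistic; no Blomberg's
  K, Ornstein-Uhlenbeck or early-burst models, and no measurement-error
  extension.
* Contrast p-values assume the BM standardization is correct; under
  intermediate lambda the contrasts are heteroscedastic and the effective
  sample size is smaller than n - 1, so those p-values are approximate
  (the package reports them as the classical procedure defines them).
* The node scan tests each node marginally; nested significant nodes are
  all reported, and deciding which of a chain of flagged ancestors is "the"
  shifted lineage is left to the user.
* Tree inference, dating and consensus construction are out of scope; the
  tree is an input.
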