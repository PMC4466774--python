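# Methods

## Problem setting

Genomic selection fits a model from whole-genome marker genotypes
(`X`, n individuals × p markers, allele counts 0/1/2 or dominant 0/1,
0/2 codes) to a quantitative trait `y`, then scores unphenotyped
candidates.  Breeders ultimately keep only the top k candidates, so the
operational question is a *ranking* one: did the model place the
highest-breeding-value individuals at the head of the list?  This
package treats genomic selection explicitly as learning-to-rank and
evaluates it with top-k measures, while keeping the classical
regression view (MSE, Pearson r) available.

Everything assumes the n ≪ p regime typical of breeding panels
(hundreds of phenotyped lines, thousands of markers), which is why both
kernel models work in the n-dimensional dual.

## Evaluation measures

Global measures are built on the strict preference set
`P(y) = {(i, j) : y_i > y_j}`: pairwise accuracy `|C|/|P|` and
Kendall's τ `(|C| − |D|)/|P|`, where C and D are the pairs the
predicted scores order correctly and incorrectly.  On a tie-free
reference τ = 2·pa − 1 exactly.  This is the classical τ-a with the
strict-preference denominator, *not* the tie-corrected τ-b of general
statistics libraries; the choice is deliberate and documented so the
two are not silently conflated.  Pairwise accuracy on a binary
reference equals ROC AUC, which the tests exploit as an independent
cross-check.

Top-k quality uses DCG@k = Σ_{i≤k} g(y_{π_i}) d(i) and its normalized
ratio NDCG@k against the ideal ordering, plus Mean NDCG@K (the mean
over k = 1..K).  Defaults: linear gain g(y) = y (traits are unbounded,
exponential gain would explode), logarithmic discount
d(i) = 1/log₂(i+1), and k ∈ {1, 5, 10} in the benchmark reports;
exponential gain and unit discount are available options.

Numerical conventions, all chosen for determinism in batch use:

* score ties in the induced permutation break by ascending original
  index (stable sort);
* NDCG demands nonnegative gains; negative traits raise and the
  `shift_nonnegative` helper subtracts the dataset minimum once per
  dataset (a constant offset that no pair-based measure and no NDCG
  ordering is sensitive to — only raw DCG changes);
* an all-zero reference has ideal DCG 0; NDCG is defined as 0 with a
  warning rather than NaN so a degenerate CV fold cannot abort a run;
* Pearson on a constant vector raises instead of returning 0 — masking
  a zero-variance input would corrupt model selection.

## Models

**RKHS / kernel ridge regression.**  Dual solve
`(K + λI)α = y_centered`, prediction `h(x) = ȳ + Σ_i α_i κ(x, x_i)`.
The trait is centered and the training mean restored at prediction —
the fixed population-mean effect of a mixed model; without it the
penalty shrinks the overall trait level toward zero, which visibly
hurts traits shifted nonnegative.  With a linear kernel this is
exactly primal ridge / GBLUP (verified against a primal solve and
scikit-learn's KernelRidge).  λ (and σ for the RBF kernel) are tuned
by grid cross-validation on the same nested protocol as the other
methods; likelihood-based auto-tuning (REML) is intentionally out of
scope and no equivalence is claimed.

**RankSVM (pairwise).**  Kernelized squared-hinge objective
`f(α) = (λ/2) αᵀKα + Σ_{(i,j)∈P(y)} max(0, 1 − αᵀK_i + αᵀK_j)²`,
with λ = |P(y)|·λ̃ so regularization tracks the number of loss terms.
The objective is differentiable and strictly convex; L-BFGS-B from
α = 0 with a 500-iteration cap and gradient tolerance 1e−5·n finds the
unique minimum.  Gradient correctness is held to central finite
differences at 1e−4 relative error.  Only the squared (r = 2) hinge is
implemented; the non-differentiable r = 1 variant would need
subgradient machinery and is omitted.

**RBF kernel parameterization.**  κ(a, b) = exp(−γ‖a−b‖²) with
γ = 1/(4pσ²), so σ is comparable across marker counts; the σ grid is
the 10 values {0.1, …, 1.0} (σ = 0 is undefined and excluded).

**GBRT.**  Squared-loss boosting from the training-mean base model;
each stage tree fits the residuals, gets an exact line-search weight
`⟨e, t⟩/⟨t, t⟩`, and is shrunk by the learning rate.  Training MSE is
provably non-increasing and the lr = 1 / unlimited-depth limit
interpolates tie-free data; both are tested.

**LambdaMART.**  Same staged machinery, but stage targets are the
λ-gradient of NDCG@k: per preference pair,
`|ΔNDCG_ij| / (1 + exp(s_i − s_j))` pushes the preferred item up and
its partner down (antisymmetric, so the vector sums to zero), with
ΔNDCG the swap delta `|(g_i − g_j)(d(r_i) − d(r_j))|/idealDCG` and
discounts zeroed beyond rank k — pairs wholly below the top k
contribute nothing.  Two open choices were settled as follows: ΔNDCG
is normalized by the ideal DCG so stage gradients are scale-free, and
stage weight is the learning rate alone (the λ surrogate has no
primitive objective to line-search).  The sign convention follows the
preference direction (preferred item pushed up) with λ_ji = −λ_ij.

**McRank.**  Training traits are discretized into B equal-width bins
(left-closed/right-open, last bin closed; empty bins dropped with B
reduced), each training value replaced by its bin mean, and candidates
ranked by expected trait value Σ_r Pr(y = b_r|x)·b_r.  The multiclass
variant fits one classifier over bin labels; the ordinal variant fits
B−1 binary classifiers on the cumulative cuts {y ≤ b_r} vs
{y ≥ b_{r+1}} and differences the cumulative estimates.  Independent
cut classifiers can produce non-monotone cumulatives; negative
differences are clipped to zero and the vector renormalized — the
minimal repair that preserves a probability vector (rows verified to
sum to 1 at 1e−9 across B ∈ {3..20}).  A cut with an empty side falls
back to the class prior with a warning.  The default classifier is a
random forest, which outperforms logistic regression on marker data.

**Random forests** enter through scikit-learn behind the tree-learner
contract (bootstrap + feature-subset randomization); the package adds
nothing to RF itself.

Default ensemble settings: 300 trees, feature fraction 0.6, depth grid
{3, 5, 10}, learning-rate grid {0.001, 0.01, 0.1, 1.0} with 0.1 as the
practical default; McRank bin grid {3..20}; RankSVM λ̃ grid 15
log-spaced values in [1e−6, 1e6].

## Benchmark protocol

Randomized cross-validation: per iteration an 80/20 split (default 10
iterations), identical for every method — the split sequence is a pure
function of (n, master seed, iteration).  Hyper-parameters are chosen
by 5-fold CV inside the training split, maximizing the *same* measure
used for evaluation (minimizing for MSE); ties break to the earlier
grid point, and a grid point whose fit fails anywhere is scored worst
and logged.  Splits are simple random without stratification.  A
method failing on a split is recorded as missing and excluded from
averages with a warning rather than aborting the run.  Reports round
to 3 decimals.  Cross-dataset summaries: per-measure method ranking
(1 = best, average ranks on ties, averaged across datasets) and a
measure-agreement matrix (Spearman ρ between per-method mean scores,
averaged across datasets; needs ≥ 3 methods).

## Synthetic data

The simulator generates what the methods assume and nothing more:
Hardy–Weinberg genotypes (allele frequency per marker uniform over the
MAF range, genotype Binomial(2, f)), a small set of causal markers
with standard-normal additive effects (optionally products of
consecutive QTL pairs for an epistatic component), and Gaussian noise
with variance var(g)(1 − h²)/h² so realized heritability matches the
request; traits are shifted nonnegative at generation.  Genotypes,
effects and noise use independent deterministic streams, so changing
h² regenerates only the noise.  An optional block-duplication mode
(markers copied with 5% flip noise) is a parametric stand-in for
linkage disequilibrium.

What the simulator does *not* emulate: realistic LD decay, population
structure, multi-allelic QTL, dominance, genotype-by-environment
interaction.  Tests passing on this generator therefore demonstrate
algorithmic correctness and high-signal recovery, not field
performance on real panels, where marker–QTL relationships are more
complex.

Because the noise is independent of the genetic values g, the Pearson
correlation of g with the trait approaches √h² — the ceiling on any
marker-based predictor's accuracy; the test suite checks this at
h² ∈ {0.25, 0.5, 0.8} within ±0.05 at n = 1000.

## Problem sizes in the shipped checks

The packaged verification runs use deliberately small instances chosen
to exercise every property while staying quick to re-run: exhaustive
DCG optimality at n = 6 (all 720 orders), RankSVM
gradient/optimality at n = 15, dual/primal equivalence at (50, 20) and
(20, 200), end-to-end CV recovery at n = 200, p = 50, 10 QTL, h² = 1
with fixed λ values inside the protocol (at h² = 1 the outcome is
insensitive to λ over a wide range, so singleton grids keep the nested
loop honest without redundant refits), and the heritability ceiling at
n = 1000.

## Known limitations

* No genotype imputation or allele-frequency filtering: missing
  genotypes are an error by design.
* No REML variance-component estimation; ridge/RKHS tuning is grid CV.
* RankSVM r = 1 (absolute hinge) is not implemented.
* Kendall's τ here is not τ-b; comparisons with tied references differ
  from standard library values.
* NDCG conventions (ties, zero ideal) are package decisions where the
  definitions are silent; they are documented above and frozen by
  tests.
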