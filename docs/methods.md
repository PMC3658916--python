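# Methods

## The conditional likelihood

Each category's 2×2 table (selected/unselected × in/out of category) is
modelled by two independent binomials, X₁ ~ Bin(n, π₁) for the selected
arm and X₂ ~ Bin(N−n, π₂) for the unselected arm.  Reparametrizing with
θ = logit(π₁) − logit(π₂) (natural-log odds ratio; φ = θ·log₂e on the
log2 scale) and λ = logit(π₂), the category size S = X₁+X₂ carries almost
no information about θ, and conditioning on S removes λ exactly.  The
conditional law of T = X₁ given S = s is Fisher's noncentral
hypergeometric distribution on the support [max(0, s+n−N), min(s, n)].

All pmf evaluation is in log-space: log binomial coefficients via
log-gamma and a log-sum-exp normalizer over the support.  This is required
at the benchmark scale (N = 10,000, category sizes in the thousands),
where naive binomial coefficients overflow.  Outcomes outside the support
return probability 0 rather than raising, which keeps mixture sums simple.
The implementation is cross-checked in the tests against exact integer
arithmetic and against `scipy.stats.nchypergeom_fisher`, which is never
used as the implementation path.

The two-sided Fisher exact p-value sums every outcome whose null mass is
at most the observed one; "at most" uses a fixed relative tie tolerance of
1+1e-7 so that discrete ties are counted identically across platforms and
reports are bit-reproducible.

## Estimators

**BBE.**  The nonlocal FDR at level α is estimated by min(mα/#{p_j ≤ α}, 1),
with the conservative value 1 when there are no discoveries (the 0/0 case
is left open by the defining formula; returning 1 is the choice consistent
with the estimator's conservatism).  BBE assigns the category with rank
r ≤ m/2 the value min(m·p₍₂ᵣ₎/(2r), 1), where p₍ₖ₎ is the k-th order
statistic — the rank-doubling reading of the construction — and 1 to the
upper half.  Ties in p-values keep input order (stable ranking), making
the output deterministic.  With m = 1 the estimate is 1.

**MLE2 / MLE3.**  The k-component parametric mixture places weight Π₀ on
the null pmf f₀ and weights Π₁..Π_{k−1} on sign-symmetrized components
g_θ = (f_θ + f_{−θ})/2 with magnitudes θ_j ∈ [0, 10] (the symmetrization
makes negative magnitudes redundant; the box matches the constraint under
which the estimator is defined).  Type-II maximum likelihood maximizes
Σ_i log Σ_j Π_j g_{θ_j}(t_i|s_i).  The surface is multimodal, so the fit
uses multi-start L-BFGS on transformed parameters (logit of θ/10, softmax
weights; default 10 restarts, seeded), one start coming from a coarse
lattice scan.  Because softmax cannot reach the simplex boundary, the
interior optimum is compared post hoc against exact boundary candidates
(all-null; zeroed vanishing weights; for k = 2 the pure-alternative scalar
fit) and the best is kept, with a switch threshold of 1e-7 nats so exact
likelihood ties resolve toward the interior fit.  A component whose fitted
magnitude falls below 1e-6 is indistinguishable from the null — along the
θ→0 ridge the weight split is unidentifiable — so its weight is merged
into Π₀, which also enforces the pairwise-distinctness constraint against
θ₀ = 0.  For k = 3 the magnitudes are reported in increasing order with a
minimum separation of 1e-6.  Boundary fits (Π̂₀ ∈ {0, 1}) are returned
as-is with a warning flag; they are legitimate optima of the marginal
likelihood.  The LFDR is the posterior null probability under the fitted
mixture; the companion empirical-Bayes Bayes factor inverts the
posterior-odds identity, BF = [(1−LFDR)/LFDR]·Π₀/(1−Π₀), so the
round-trip through LFDR = [1 + BF(1−Π₀)/Π₀]⁻¹ is exact.

**HBE / HBE-EN.**  p-values are clamped to [1e-12, 1−1e-12] (exact 1 is
routine for discrete tests) and mapped to z = Φ⁻¹(p), one-tailed exactly
as defined — no folding.  The marginal density is fitted by Poisson
regression of histogram bin counts on an orthogonalized polynomial basis
(defaults: 120 bins over the data range padded by 1% per side, 7 degrees
of freedom), normalized to unit mass on the grid; these defaults follow
standard practice for histogram-based two-group fits and are exposed as
parameters.  The estimate is min(f̂₀(z)/f̂(z), 1) with f̂₀ either the
standard normal (theoretical null) or a normal fitted to the central
portion of the z-values by truncated maximum likelihood (empirical null;
default central fraction 0.5 via empirical quantiles, vacuous truncation
at fraction ≥ 1 reducing to the plain MLE).  The printed estimator carries
no Π₀ factor; an optional `pi0` multiplier is available but off by
default.  Note the truncated-ML scale estimate is unbiased but noisy at a
central-50% window (sampling SD ≈ 0.11 at m = 10,000 null z-values), and
with m = 2 the quantile window contains no data points at all, so the
empirical-null variant fails there by design and is recorded as missing by
the benchmark harness.  These estimators target large-scale inference;
their small-m output is documented as unreliable rather than patched.

**NMLE.**  For a single table, the NML predictive under hypothesis set ℋ
is f†(t|s; ℋ) = max_{θ∈ℋ} f_θ(t|s) / K†(ℋ) with
K†(ℋ) = Σ_y max_{θ∈ℋ} f_θ(y|s); its regret is constant over the support
and equal to log K† (the minimax equalizer property, verified in the
tests).  The alternative set ℝ∖{0} is open, so its supremum is taken over
the closure: for interior outcomes the score equation is solved by bounded
scalar optimization on θ ∈ [−50, 50] (log f is concave in θ; tolerance
1e-10), and outcomes at the support endpoints take the analytic limit
sup f = 1 as θ → ±∞ (represented by ±∞ sentinels) instead of evaluating a
large θ.  The NML ratio BF† = f†(t|s; alt)/f†(t|s; null) approximates the
Bayes factor; combined with a user-supplied Π₀ it gives the only estimator
defined for m = 1.  The CLI default Π₀ is 0.5 and is always echoed in the
output metadata; report columns flag Bayes factors above 10 and 100 as
strong and overwhelming evidence.

## Synthetic data and truth oracle

The generator emulates a microarray-style enrichment study: N = 10,000
reference genes, n = 200 selected, m categories, 20 replicate datasets per
condition.  For category i with log2 odds ratio φ_i: π₁ ~ Uniform(0, 1)
(as specified by the benchmark design, with no truncation, even though it
produces some very large categories), π₂ = π₁/(π₁ + (1−π₁)2^{φ_i}), then
x₁ ~ Bin(n, π₁) and x₂ ~ Bin(N−n, π₂).  Each (category, replicate) pair
draws from its own seeded substream, so datasets are reproducible and
stable when m or the replicate count changes.

Configurations: the asymmetric ramp φ_i = 5i/[m(1−Π₀)] over the enriched
block; the symmetric double ramp (up to +5 over the first half of the
block, then down to −5); and a literal catalogue of small-m settings
(m = 2, 4, 8, 32).  The ramp formulas are defined for a 100-category
study; replacing 100 by m is this package's documented generalization, and
the enriched-block length uses round(m(1−Π₀)).  Two catalogue rows for
m = 32 are internally inconsistent as printed (their non-zero counts do
not match their Π₀ labels, and one negative arm has magnitudes unlike its
positive arm); they are embedded verbatim, and the truth model is instead
derived from the φ vector itself — Π₀ as the fraction of zero entries and
the enriched list as the non-zero θ = φ·ln 2 values — so the oracle is
always self-consistent with the generated data.

The true LFDR of an observed (t, s) uses the two-group posterior with
f₀ the central hypergeometric and f₁ the equal-weight average of
f_{θ_j} over the J enriched, signed log-odds values (the signed components,
not their symmetrized versions, matching the generator).

**Bias metric.**  Signed errors (estimate − truth) are averaged over
categories and replicates first and the absolute value is taken last —
"bias" as a term of art; mean absolute error is available behind
`aggregate="mae"`.  Estimator failures on a replicate are warnings, not
errors, and are excluded from that estimator's mean.  Summaries report the
lowest-|bias| estimator per (m, Π₀) and each estimator's worst case over
Π₀ per m.

## Problem sizes and numerical choices

The shipped benchmarks use 20 replicates per condition, the full Π₀ grid
{0.5, 0.6, 0.7, 0.8, 0.9, 0.94} at m = 100 for both ramp schemes, and the
Π₀ = 1 catalogue rows at m ∈ {2, 4, 8, 32}; mixture fits inside the
m = 100 benchmark use 4 optimizer restarts (spot-checked against the
10-restart default to give the same optima on this data), and per-dataset
support matrices are cached so a whole dataset's mixture likelihood is a
single vectorized pass per component.  Null-proportion recovery runs
m = 1,000 categories over 20 seeds.

## Limitations

* The verbal description of π₁, π₂ as conditional probabilities "given the
  category" does not match the binomial sampling model that defines the
  generator; the model is implemented literally.
* The histogram estimators are known to be strongly biased in the 2–100
  category regime (this reproduces in the benchmark); they are included
  for comparison, not recommendation.
* NMLE's output depends entirely on the supplied Π₀; it is only
  advantageous when Π₀ is known or m = 1.
* Categories are opaque identifiers: no GO DAG parsing, ancestor
  relations, or annotation retrieval.
* No model-selection criterion chooses between k = 2 and k = 3; both are
  exposed and compared empirically.
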