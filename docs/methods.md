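# Methods

## Scope and model

`randeval` evaluates restricted randomization procedures for a two-arm
parallel-group trial with a continuous normal endpoint, 1:1 target allocation,
a fixed sample size N and a final pooled-variance two-sample t test at level
α. The response model is

    y_i = μ_E T_i + μ_C (1 − T_i) + τ_i + ε_i,   ε_i ~ N(0, σ²) i.i.d.,

with T_i = 1 for the experimental arm and τ a fixed, unobserved per-patient
bias shift. Everything the package computes follows from the conditional
distribution of the t statistic given the allocation sequence **T** and τ.

Assumptions worth stating explicitly: homoscedastic normal errors; the bias
acts additively on the mean response; the recruiter (selection bias) knows or
can reconstruct all previous assignments but never the upcoming one; the time
trend depends on the enrollment position, not on calendar time or center.

## Randomization procedures

All eight procedures are driven by one primitive: the conditional probability
that patient i receives E, as a function of the position i−1 and the running
state (imbalance D = N_E − N_C, or the within-block counts for PBR). In
particular:

* CR — fair coin, P = 1/2 always.
* EBC(p) — p toward the under-represented arm, 1/2 at balance; p ∈ [1/2, 1].
* UD(α, β) — P(E) = (α + β·N_C(i−1)) / (2α + β·(i−1)); the degenerate urn
  α = β = 0 is defined as a fair coin.
* BSD(a) — fair coin while |D| < a, deterministic at |D| = a.
* CHEN(a, p) — EBC(p) while |D| < a, deterministic at |D| = a.
* MP(a) — uniform over all sequences with max|D(i)| ≤ a; the classical variant
  additionally forces D(N) = 0. Sampling and conditional probabilities come
  from exact suffix path counts f(i, d) computed by dynamic programming with
  arbitrary-precision integers (cost O(N·a), cached per (N, a, variant)), so
  MP sampling is exact rather than rejection-based.
* RAR — P(E) = (N/2 − N_E(i−1)) / (N − i + 1): uniform over balanced
  sequences.
* PBR(b) — RAR applied within successive blocks of size b; because every
  completed block is balanced, the block-local state is derivable from the
  global count, which keeps the sampler a pure function of (i, N_E(i−1)).

Both MP variants are provided because published case studies are ambiguous
about whether terminal balance was enforced; the terminal-balance variant is
the default. Divisibility requirements (even N for RAR and terminal-balance
MP, N divisible by b for PBR, even b) are validation errors, never silent
truncation — the setting is strict 1:1 allocation.

Monte-Carlo generation is vectorized across sequences: one uniform variate per
patient per sequence, consumed in enrollment order, so a seed fully determines
the draw and streams are comparable across procedures. Exhaustive enumeration
(depth-first over the allocation tree, pruning zero-probability branches) is
guarded by a size limit (default N ≤ 20).

## Bias models

Selection bias follows the convergence strategy. With guessing threshold
q = 1/2 (the default and the worst case for balance-forcing procedures):

    τ_i = η · sign(N_E(i−1) − N_C(i−1)).

For q > 1/2 the recruiter acts only on confident guesses. With
p_E(i−1) = (N_E_target − N_E(i−1)) / (N − i + 1) the fraction of remaining
allocations to E, the implemented policy is

    τ_i = η · ( 1{p_E(i−1) ≤ 1 − q} − 1{p_E(i−1) ≥ q} ),

with non-strict comparisons. This form was chosen so that q = 1/2 reproduces
the sign rule *exactly* (at p_E = 1/2 the two indicators cancel) and so that
q = 1 behaves sensibly (the recruiter acts only once one arm's allocations are
exhausted). It requires a procedure with a fixed terminal split; requesting
q > 1/2 for a procedure without one is a validation error.

Time trends are normalized so the maximum shift equals θ, making θ comparable
across shapes: linear θ·i/N, stepwise θ·1{i ≥ c}, logarithmic
θ·log(i)/log(N). The joint model is the elementwise sum of the two
components; a multiplicative combination is deliberately out of scope.

Only the additive direction convention matters for per-sequence quantities;
the procedure-level summaries are invariant to flipping the sign of η because
every implemented procedure is symmetric under relabelling E ↔ C.

## Exact type-I error

For a fixed (**T**, τ) the t statistic under H₀ is doubly non-central t with
df = N − 2,

    δ = (1/σ)·√(N_E N_C/N)·(μ_E − μ_C + τ̄_E − τ̄_C),
    λ = (1/σ²)·(Σ τ_i² − N_E τ̄_E² − N_C τ̄_C²).

λ is the within-arm sum of squares of τ over σ², hence non-negative; it is
clamped at 0 against floating-point noise. The 1/σ² scaling of λ follows the
non-central χ² definition and is validated against response-level simulation.

The CDF is evaluated through the Poisson mixture over the denominator: with
W ~ χ²_df(λ) decomposed as a central χ² with df + 2J degrees of freedom,
J ~ Poisson(λ/2),

    F(x; df, δ, λ) = Σ_j  P(J = j) · F_nct( x·√((df+2j)/df); df + 2j, δ ),

because conditionally T = T′·√(df/(df+2j)) with T′ singly non-central t on
df + 2j degrees of freedom. The series is truncated once the cumulative
Poisson weight reaches 1 − 1e−10 (hard cap 10·(1+λ) + 200 terms; exceeding it
raises a diagnostic error). The singly non-central t CDF comes from
`scipy.special.nctdtr`.

Two independent validation routes are built in: a quadrature oracle that
integrates the defining probability E_W[Φ(x√(W/df) − δ)] against the
non-central χ² density (agreement ≤ 1e−6 is asserted in the tests), and a
response-level simulator that draws from the model, applies the t test and
counts rejections (agreement within 3 binomial SEs is asserted, including at
the full case-study size N = 130).

The two-sided rejection probability uses the lower-tail central-t quantile
t_df(α/2):

    ω(δ, λ) = F(t_df(α/2); df, δ, λ) + F(t_df(α/2); df, −δ, λ),

which equals α exactly at (0, 0) and is symmetric in the sign of δ. The
scalar path memoizes on (|δ|, λ, df, α) — under selection bias alone only a
handful of distinct pairs occur — and the batch path collapses duplicate
(|δ|, λ) rows and evaluates the whole Poisson mixture vectorized across
sequences, which is what makes r = 100000 sequences at N = 130 a matter of
seconds.

Sequences that put every patient on one arm (possible under CR) leave the t
statistic undefined. By convention their ω is 0 (the test never rejects);
they are counted and reported separately rather than silently dropped. At
N = 130 their probability is ~2⁻¹²⁹ and they never arise in practice; the
convention matters only at small N.

## Procedure assessment

Monte-Carlo mode draws r sequences independently (with replacement in
sequence space; default r = 100000, which gives two reliable decimals for
P(ω ≤ α) and three for the mean), computes ω per sequence, and reports the
mean, P(ω ≤ α), quantiles, the empirical SE of the mean and the binomial SE
√(p(1−p)/r). Exact mode enumerates all positive-probability sequences and
weights by their exact probabilities — necessary for EBC/UD/BSD/CHEN, whose
sequences are not equiprobable.

The level-preservation comparison uses ω ≤ α + 1e−9: the tolerance exists
solely so the analytically exact no-bias case (ω = α for every sequence)
counts as level-preserving despite floating-point representation.

The sensitivity grid re-runs the assessment over (η, θ) values — paired lists
(the ±50% design) or a full cross product — reusing the same base seed in
every cell, so cells differ only through the bias parameters and a 1×1 grid
reproduces the single assessment bit for bit.

The report generator ranks procedures by P(ω ≤ α), breaking ties by smaller
mean ω and then by stricter imbalance control (smaller attainable max |D|).
The rationale for the last tie-break: among procedures indistinguishable in
level preservation, the one that also protects power through balance is
preferable.

## Design utilities

Effect size is |μ_E − μ_C|/sd_pooled. Sample size inverts the exact
non-central-t power function (non-centrality d·√(n_E n_C/(n_E+n_C))) starting
from the normal approximation, returning the smallest per-group n whose power
reaches the target — the exact computation matters: the normal approximation
misses the printed case-study answer by one patient. Terminal imbalance under
CR is an exact binomial tail; the "imbalance of x%" phrasing common in design
discussions is ambiguous between a patient-count difference and an arm share,
so the function takes an explicit absolute difference d and the caller decides
the reading.

The selection-effect estimator fits, by least squares, the two-way
main-effects model with the guessing covariate
s_i = sign(N_E(i−1) − N_C(i−1)) added to the treatment indicator:
y ~ 1 + T + s. η̂ is the coefficient of s, σ̂ the residual SD on N − 3
degrees of freedom, γ̂ = η̂/σ̂. A rank check rejects sequences for which s is
collinear with the design (η not identifiable). Unbiasedness of η̂ is
verified on synthetic data (1000 replicates at N = 130) in the test suite.

## What the synthetic data do and do not show

All validation data in the tests are generated from the package's own response
model: normal errors, exactly additive bias, a recruiter who always follows
the convergence strategy. Passing tests therefore demonstrate internal
correctness (the analytic ω equals the rejection rate of the simulated t test;
exact and Monte-Carlo assessments agree; the estimator recovers η under the
model), not that real trials obey the model: real selection bias is
intermittent and misclassified, real trends are not smooth functions of the
enrollment index, and real responses have unequal variances. The model is
best read as a tractable worst case for unconscious selection.

## Numerical choices and limitations

* Series truncation 1e−10 of Poisson mass; quadrature oracle tolerance 1e−11;
  duplicate collapse of (|δ|, λ) uses exact float equality (the values lie on
  a lattice generated by the τ arithmetic, so no rounding is applied).
* P(ω ≤ α) is *extremely* boundary-sensitive for procedures whose
  ω-distribution straddles α: in the case-study setting roughly a fifth of CR
  sequences have ω within ±5·10⁻⁴ of 0.05, so a change of 2·10⁻⁴ in ω — far
  below any scientifically meaningful scale — moves the metric by ~0.04.
  Comparisons of this metric across software at more than ~0.05 resolution are
  therefore only meaningful if both implementations compute ω to well below
  10⁻⁴ accuracy; the package computes it to ~10⁻⁹ and validates against
  simulation. The mean type-I error has no such fragility.
* MP rows depend on the terminal-balance variant; both are exposed and both
  are exact. The variant changes P(ω ≤ α) at the second decimal in the
  case-study setting.
* The evaluation covers the null hypothesis only; power under bias, multi-arm
  designs, survival endpoints, covariate-adaptive procedures and
  randomization-based inference are out of scope.
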