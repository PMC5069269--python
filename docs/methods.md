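# Methods

## Model and likelihood reduction

Lifetimes `t_1 ≤ … ≤ t_N` with failure indicators `δ_k` (1 = failure,
0 = right-censored) are modelled as iid Weibull `W(α, β)`.  Writing
`n = Σ δ_k` for the failure count, the censored-data log-likelihood
reduces — after dropping parameter-free constants — to

    L(α, β) = (θ(β)/α)^β + β ln(α/τ) − ln β,
    ln τ = (1/n) Σ δ_k ln t_k,
    θ(β) = ((1/n) Σ_{k=1..N} t_k^β)^{1/β},

where the θ sum runs over **all** N times (censored units contribute
their survival exposure) while the divisor is the failure count.  Only
the stationary point of `L` is meaningful — the reduction involves an
unstated sign/scale convention — and that stationary point is the MLE:
`α* = θ(β*)`, with `β*` the root of the shape equation

    1/β₁ − 1/β − Σ ln(t_N/t_k) t_k^β / Σ t_k^β = 0,
    β₁ = ((1/n) Σ δ_k ln(t_N/t_k))⁻¹.

The package never interprets the absolute value of `L`; a test verifies
its stationary point coincides with the shape-equation root by direct
grid refinement.

## Existence, uniqueness, bounds

On the normalized scale `x_k = (t_k/t_N)^β₁ ∈ (0, 1]`, `ζ = β/β₁`, the
shape equation is `Z(ζ) = 1 − 1/ζ + r(ζ) = 0` where `r(ζ)` is the
`x^ζ`-weighted mean of `ln x_k`.  `dr/dζ` is the corresponding weighted
variance, hence nonnegative, and strictly positive when some `x_k < 1`
(guaranteed by input validation), so `Z` increases strictly from −∞
(ζ → 0⁺) to 1 (ζ → ∞) and has exactly one root `ζ* > 1`.  When
`1 + r(1) > 0` the sharper bracket `1 + r(1) < 1/ζ* < 1` applies;
otherwise only `ζ* ∈ (1, ∞)` is available (`ZetaBounds.informative`
distinguishes the cases).  `r` and the Newton weights are evaluated in
log space (`exp(ζ ln x − max)`) so extreme shapes cannot overflow; `θ`
uses log-sum-exp for the same reason.

## The perturbation series

Substituting `ζ = 1 + z` and Taylor-expanding each term of the shape
equation, then dividing by `Σ x_k[(ln x_k)² + ln x_k + 1]`, gives
`Σ_{m≥0} σ_m z^m/m! = 0` with

    σ_m = Σ x_k (ln x_k)^{m−1} [(ln x_k)² + m ln x_k + m]
          / Σ x_k [(ln x_k)² + ln x_k + 1].

Two structural facts the implementation relies on:

- `σ₁ = 1` exactly (numerator ≡ denominator at m = 1).
- `−1 < σ₀ < 0` for every valid sample.  This is sometimes treated as an
  unproven assumption, but it is elementary: the denominator minus the
  magnitude of the numerator equals `Σ x_k (ln x_k + 1)² ≥ 0`, and the
  numerator `Σ x_k ln x_k` is strictly negative whenever some `x_k < 1`.
  The code still checks it at runtime (and a property test asserts it on
  random samples) because the quality of the series depends on how far
  `ε = −σ₀` sits below 1, not merely on the bound holding.

The root is expanded as `z = Σ_q ε^q ξ_q`.  Balancing powers of ε yields
a triangular system: `ξ₁ = 1/σ₁`, and for Q ≥ 2

    σ₁ ξ_Q = − Σ_{m=2..Q} (σ_m/m!) Σ_{q₁+…+q_m=Q} ξ_{q₁}…ξ_{q_m},

the inner sum over ordered compositions of Q into m positive parts.  The
implementation enumerates compositions recursively (cached per (Q, m)),
so any truncation order is available; the familiar order-4 closed forms
(`ξ₂ = −σ₂/2`, `ξ₃ = σ₂²/2 − σ₃/6`,
`ξ₄ = −5σ₂³/8 + 5σ₃σ₂/12 − σ₄/24`) are verified symbolically against an
independent sympy expansion, and a random order-6 case against a generic
symbolic triangular solve.  Finally `β* = β₁(1 + z)`, `α* = θ(β*)`.

**Default truncation order Q = 4.**  This matches the explicit published
formula; on the embedded grinder data (ε = 0.224) order 4 agrees with the
iterative root to 4–5 significant digits, and the error decreases
monotonically from Q = 1 to Q = 4.  `order` is a public parameter.

If `ε` falls outside (0, 1) — impossible for valid input but reachable
through hand-built `SigmaCoefficients` — a `SmallParameterWarning` is
emitted, the series value is still returned, and `series_valid=False`
flags that callers should prefer the Newton–Raphson solver.

## Newton–Raphson reference solver

Iterates directly on β with the analytic derivative
`g'(β) = 1/β² + Var_w(ln t)`, `w ∝ t^β` (strictly positive, so steps are
always defined).  The stopping rule is the absolute parameter update
`|Δβ| < tol`, default `tol = 0.001` — the tolerance could equally be put
on `|Z|`; the update criterion was chosen and is what the reported
iteration counts refer to.  Iteration counts are reported but not
asserted in tests (they are implementation detail).  The default start
is the perturbative estimate rounded **up** to the next integer, a rule
that in practice lands within one unit of the root; `beta0` overrides
it.  Non-convergence within 100 iterations raises with the last iterate
in the message.  An independent cross-check against
`lifelines.WeibullFitter` (direct likelihood maximization) agrees to
four digits on the grinder data.

## L-moments comparison estimator

Sample L-moments use the standard unbiased probability-weighted-moment
estimators (`l₁ = b₀`, `l₂ = 2b₁ − b₀`).  Matching the Weibull
population identities `λ₁ = αΓ(1 + 1/β)`, `λ₂/λ₁ = 1 − 2^{−1/β}` gives

    β = −ln 2 / ln(1 − l₂/l₁),    α = l₁ / Γ(1 + 1/β).

L-moments have no canonical censored-data version, so the censoring
policy is explicit: `"ignore-flags"` (default) treats every recorded
time as a failure — the naive application whose upward shape bias under
heavy censoring the study is designed to expose — and
`"failures-only"` drops censored records.  A ratio `l₂/l₁ ∉ (0, 1)`
raises `EstimationError`.

## Simulation design

One design point = (M units, failure probability p, truth (α, β)).  The
common censoring time is the p-quantile `C = F⁻¹(p; α, β)` (p = 1 gives
`C = ∞`, i.e. complete data); each of M inverse-CDF draws is kept as a
failure if ≤ C, else recorded as C with the censored flag.  Inverse-CDF
sampling means the generator is exactly the model under test, and a
single integer seed makes a whole study bit-for-bit reproducible (grid
points receive independent spawned child seeds).  Defaults are the
conditions of the reference study: truth (α, β) = (3.0, 1.5), η = 100
replicates per point, p ∈ {1.0, 0.8, 0.2} giving censoring rates
0/20/80 %, sample sizes from the grid {10, 20, 50, 100, 500, 1000}.
Bias and MSE are the plain Monte-Carlo means of the error and squared
error per parameter.  Degenerate replicates (e.g. zero failures at
M = 10, 80 % censoring) are resampled once, then skipped and counted in
`n_failed`; tests and the acceptance checks use M ≥ 100 where this never
triggers.

What the generator emulates — a homogeneous fleet observed from a common
start to a single fixed censoring time — is deliberately idealized.
Real fleets have staggered installation (left truncation), heterogeneous
populations, and inspection-interval rounding; none of these are
modelled, so passing recovery tests demonstrate correctness of the
estimator under its own assumptions, not robustness to their violation.

## Known limitations

- **Complete samples at large M.**  The small parameter is not uniformly
  small: for complete data `t_N` is an increasingly extreme order
  statistic, the normalized spread grows, and ε climbs toward 1
  (ε ≈ 0.84 at M = 1000 under `W(3, 1.5)`).  The order-4 series then
  undershoots the exact MLE root systematically (shape bias ≈ −0.12 at
  M = 1000, versus ≈ −0.02…−0.05 at M = 100), so the bias does **not**
  vanish with sample size on complete data — it is a truncation bias,
  not a sampling one.  Under moderate censoring the censoring time caps
  `t_N`, ε stays near 0.4, and the series matches the iterative root to
  ~10⁻⁵ relative; this is the regime the estimator is built for.  For
  complete large samples, raise `order` or use `newton_raphson_fit`.
  A dedicated test pins this behavior.
- Ties in times are allowed; the only hard degeneracies (no failures,
  all times equal, all failures at the maximum) are rejected on input.
- No standard errors or confidence intervals are provided; the fit
  reports point estimates and series diagnostics only.
- All arithmetic is double precision; the series coefficients are exact
  rational combinations evaluated in floating point, adequate for the
  4–5 significant digits the method targets.

## Problem sizes used in the checks

The deterministic data-set checks run in milliseconds.  The stochastic
checks use: 200 random samples (M ∈ [10, 60)) for monotonicity/bracket
properties; η = 100 replicates at M ∈ {100, 1000}, censoring rates
{0, 20 %} for the recovery trends; 100 replicates of M = 500 for mean
recovery.  These sizes give binomial/Monte-Carlo noise well below the
asserted margins while keeping the full suite under a minute of compute.
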