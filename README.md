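# weibull-perturb

Closed-form maximum-likelihood estimation of the two-parameter Weibull
distribution from complete and right-censored lifetime data.

Reliability engineers and survival analysts routinely fit the Weibull
distribution `W(α, β)` — density `f(t) = (β t^(β−1)/α^β) exp(−(t/α)^β)` —
to data where some units are still alive at the end of observation
(right censoring).  The scale MLE has a closed form, `α* = θ(β*)` with
`θ(β) = ((1/n) Σ_k t_k^β)^(1/β)`, but the shape MLE is classically the
root of a transcendental equation solved by iteration or by eye from a
plot.

This package computes that root **explicitly**.  With the pivot estimate

    β₁ = ((1/n) Σ_k δ_k ln(t_N/t_k))⁻¹

and the normalized data `x_k = (t_k/t_N)^β₁`, the shape equation becomes
a power series `Σ_m σ_m z^m / m! = 0` in `z = β/β₁ − 1`, whose
coefficients `σ_m` are simple weighted sums of the `x_k`.  Since
`σ₁ = 1` identically and `ε = −σ₀ ∈ (0, 1)`, the root expands as a
series in ε; truncated at fourth order,

    β* = β₁ [ 1 − σ₀ − (σ₂/2)σ₀² + (σ₃/6 − σ₂²/2)σ₀³
              + (5σ₃σ₂/12 − 5σ₂³/8 − σ₄/24)σ₀⁴ ].

Both parameters then come from direct array reductions — no starting
value, no iteration.  The package also ships:

- the score diagnostics `Z(ζ)`, `r(ζ)` proving the root exists, is
  unique, and is bracketed;
- a Newton–Raphson reference solver (with the "series estimate rounded
  up to the next integer" starting rule);
- a closed-form L-moments comparison estimator;
- a Monte-Carlo bias/MSE study design for time-censored fleets;
- two embedded reference data sets (a 20-unit grinder endurance test and
  a 100-unit transformer fleet).

## Worked example

Fit the embedded grinder data (20 units, 12 failures, test stopped at
152.7 hours) with every estimator:

```sh
$ weibull-perturb -q fit --fixture case1 --method all
method: perturbative
alpha:  162.223
beta:   1.64667
sample: N=20, n=12, censoring rate 40.0%
beta1:  1.33561   zeta*: 1.2329
sigma:  -0.2244, 1.0000, -0.3398, 0.3618, -0.3321

method: nr
alpha:  162.223
beta:   1.64667
sample: N=20, n=12, censoring rate 40.0%
iterations: 4

method: lmoments
alpha:  126.922
beta:   2.74151
sample: N=20, n=12, censoring rate 40.0%
```

The closed-form series (`perturbative`) and the iterative solver (`nr`)
agree to five digits: the characteristic life is about 162 hours and the
shape β ≈ 1.65 indicates a mildly increasing failure rate.  The σ line
shows the series inputs (note σ₁ = 1 exactly, and ε = 0.2244 is small, so
fourth order is ample here).  The naive L-moments fit ignores the
censoring flags and overstates the shape — the degradation that motivates
a censoring-aware estimator.

The same API is available from Python:

```python
import weibull_perturb as wp

fit = wp.fit(wp.case1_fixture(), order=4)
fit.params            # WeibullParams(alpha=162.223..., beta=1.64666...)
fit.solution.epsilon  # 0.2244... , the small parameter
```

A Monte-Carlo comparison over sample sizes and censoring rates:

```sh
weibull-perturb study --M-grid 10,20,50,100,500,1000 --cr-grid 0,0.2,0.8 \
    --eta 100 --seed 1 --out study.csv
```

writes a tidy table of bias and MSE per (estimator, M, CR).

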