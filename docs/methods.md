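# Methods

## The model

The FRL-X family tilts a baseline lifetime distribution `F(x; ξ)` through

```
G(x; σ, ξ) = 1 − log(1 + σ − σ F) / log(1 + σ),   σ > 0.
```

Writing `ρ = σ/(1+σ) < 1`, the transform is a logarithmic mixture of the
exponentiated baselines `F^(i+1)`: expanding `1/(1 − ρF)` geometrically gives

```
μ'_r = (1/log(1+σ)) Σ_{i≥0} ρ^(i+1) η_{r,i},    η_{r,i} = ∫ x^r f F^i dx,
```

which is the series the `frlx_moment` evaluator sums. The extra parameter
re-weights probability mass toward the lower tail (for large `σ`) without
changing the support, which is what bends a monotone baseline hazard into a
unimodal one. Two exponent extensions are provided: an inner exponent `θ`
replaces `F` by `F^θ` (exponentiated baseline) and an outer exponent `η`
raises the survival ratio, `G = 1 − [log(1+σ−σF^θ)/log(1+σ)]^η`. Setting
`θ = 1` and/or `η = 1` reduces these exactly to the simpler families, and the
implementation realizes the reductions bit-for-bit (same code path, exponent
fixed at 1).

Key closed forms used throughout:

- survival `S = log(1 + σ(1−F)) / log(1+σ)`, hazard `h = σf / [(1+σ−σF)
  log(1+σ−σF)]`;
- quantile `Q(u) = F⁻¹((1+σ − (1+σ)^(1−u))/σ)` — sampling is exact inverse
  transform, no rejection step;
- residual life: the implemented quantity is the defining ratio
  `S(x+t)/S(t)`. (A printed variant of this formula elsewhere divides by
  `log(1+σ−σF(x))`, i.e. evaluates the denominator at the offset instead of
  at the elapsed time; that form is not the conditional survival of `X−t`
  given `X>t` and is not used.)

The truncated-moment characterization implemented in
`characterization_check` states that, with `q₁ = 1+σ−σF` and `q₂ = q₁F`, the
family is the unique law satisfying `E[q₂(X)|X≥x] = ½(1+F(x))·E[q₁(X)|X≥x]`.
Both sides are computed by independent adaptive quadratures; passing a wrong
weight function (e.g. a constant ½) breaks the identity by a detectable
margin, which the tests use as a negative control.

## Numerical policy

- Series (moments, mgf): stop when a term contributes `< 1e−12` of the
  running sum, hard cap `1e5` terms; convergence is geometric because
  `ρ < 1`. The mgf is the exponential series over raw moments (cap 400
  orders) and raises `ArithmeticError` on divergence — e.g. any `t > 0` with
  a Weibull baseline of shape `α < 1`, whose mgf does not exist.
- Quadrature: `scipy.integrate.quad` with absolute/relative tolerance
  `1e−10`; semi-infinite supports use its infinite-interval transform.
- Guards: baseline cdf values are clipped to `[0,1]` against rounding
  overshoot; log arguments floored at `1e−300`; probability-integral
  transforms clamped to `[1e−12, 1−1e−12]` so Anderson-Darling stays finite.
- Quantile endpoints: `u = 0` and `u = 1` map to the support bounds
  (infinities returned, not raised); interior levels are computed via
  `expm1`/`log1p` so both tails keep full precision.
- `x < 0` returns cdf 0 / pdf 0 (lifetime convention) rather than raising.
- Weibull convention everywhere: `F = 1 − exp(−γ x^α)` with a rate-like `γ`
  multiplying `x^α`, so fitted tables are comparable across all registered
  models.

## Estimation

The FRL-X log-likelihood for a complete sample is

```
ℓ = n log σ − n log log(1+σ) + Σ log f(xᵢ; ξ) − Σ log(1 + σ − σF(xᵢ; ξ)),
```

maximized by L-BFGS-B under box constraints (all parameters `≥ 1e−8`, no
upper bound). The `−log log(1+σ)` term is a per-observation constant and is
multiplied by `n`; the `σ`-score is

```
∂ℓ/∂σ = n/σ − n/((1+σ)log(1+σ)) − Σ (1−Fᵢ)/(1 + σ − σFᵢ),
```

with the summation over observations applied to every data-dependent term
(note the minus sign on the sum — differentiation of `−log(1+σ−σF)`).
Analytic scores are supplied for `frlw`, `weibull` and `exponential`;
other models use centered finite differences. Non-finite likelihoods during
line search return a large finite penalty so the optimizer backtracks
instead of aborting. Convergence uses the customary `factr = 1e7` relative
reduction criterion (`ftol ≈ 2.22e−9`) with up to 200 iterations. Default
starts are a method-of-moments Weibull shape/rate (the classic
`CV^−1.086` approximation) with unit values for extra parameters, plus
seeded multiplicative log-normal multistart jitter; Monte Carlo study fits
start at the true values with a single start. Standard errors are square
roots of the diagonal of the inverse observed information, the Hessian being
computed numerically (`statsmodels.tools.numdiff.approx_hess`); a
non-positive-definite information matrix yields flagged NaNs and a warning.

### Weak identifiability of σ — a structural fact, not a bug

The likelihood surface of the FRL-W model is nearly flat along a
`σ–(α, γ)` ridge: increasing `σ` while drifting `α` down and `γ` up changes
the density very little. Quadrature of the expected information gives
per-observation asymptotic variances of roughly `(2.1, 2100, 9.6)` for
`(α, σ, γ)` at `(0.7, 1.3, 0.4)` and `(8.1, 2700, 45)` at `(1.4, 1.6, 1.2)`,
so even at `n = 1000` the asymptotic standard deviation of `σ̂` is about
1.4–1.6, and at small `n` the profile likelihood in `σ` is frequently
monotone — the MLE escapes to the upper boundary and the sampling
distribution of `σ̂` is extremely heavy-tailed. Consequences visible in this
package's own outputs:

- Monte Carlo MSE cells for `σ` (and, at large `n`, the `α`/`γ` cells) are
  orders of magnitude larger than the small historical table values this
  study format descends from; an independent re-run of the same protocol in
  R (`optim`, L-BFGS-B, truth starts) reproduces *our* numbers, and the
  information bound above shows no estimator of this model could produce
  σ-MSEs of order `1e−2` at `n = 1000`.
- Point recovery of `σ` (and to a lesser degree `γ`) to tight absolute
  tolerances is not an achievable benchmark; recovery tests are therefore
  asserted at the information-theoretic scale (multiples of the
  Cramér-Rao standard error computed by quadrature in the test itself).
- Reported standard errors for `σ` on real-sized samples are legitimately
  huge; that is information, not failure.

## Goodness of fit

All three statistics act on the sorted probability-integral transform
`zᵢ = G(x₍ᵢ₎)` in their standard forms:

```
AD = −n − (1/n) Σ (2i−1)[log zᵢ + log(1 − z₍n−i+1₎)]
CM = 1/(12n) + Σ [zᵢ − (2i−1)/(2n)]²
KS = maxᵢ max(i/n − zᵢ, zᵢ − (i−1)/n)
```

KS p-values use the asymptotic Kolmogorov distribution; a parametric
bootstrap (`ks_pvalue_bootstrap`) is available when parameters were
estimated from the same data — with estimated parameters the asymptotic
p-value is conservative (too few rejections), which is why the calibration
test in the suite evaluates the test at the true parameters, where the
empirical size at the nominal 5% level is close to nominal (measured 3% at
`n = 100` over 500 samples). Model comparison fits every requested model and
ranks by `(KS, AD, CM)` ascending, keeping non-converged models in the table
flagged rather than dropping them. Because the Marshall-Olkin and
alpha-power Weibull tilts can mimic FRL-W closely, rank-1 recovery of the
generating family from `n = 500` samples is far from certain (roughly 60% in
our own measurements) — comparison tables should be read together with the
parameter estimates and their standard errors.

The scaled TTT transform is `(i/n, [Σ_{j≤i} x₍ⱼ₎ + (n−i)x₍ᵢ₎]/Σ x₍ⱼ₎)`;
concave curves diagnose increasing hazard, an S shape a unimodal hazard.

## Monte Carlo harness and the synthetic data

`run_mc_study` draws each replicate by exact inverse-transform sampling from
the *fitted family itself* — the generator emulates precisely the study
conditions of the bias/MSE evaluation (true parameter sets
`(0.7, 1.3, 0.4)` and `(1.4, 1.6, 1.2)`, 1000 replications, truth-started
fits), not real clinical data: no censoring, no covariates, no measurement
rounding, and i.i.d. sampling. Passing tests therefore demonstrate the
internal consistency of sampler + likelihood + optimizer, not robustness to
the messiness of real survival data. Seeding spawns one `SeedSequence`
substream per (sample size, replicate), so every cell is independently
reproducible and results are independent of execution order. Non-converged
replicates are excluded from a cell's averages with their count reported; a
cell in which every replicate fails raises. The acceptance script runs the
full 1000 replications per cell (about half a minute on one CPU); the
in-suite reproduction test uses 200 replications at sample sizes
25/100/400/1000, which keeps the default test run to a few tens of seconds
while leaving the Monte Carlo standard errors small enough to be meaningful.

## Known limitations

- No censoring support: the likelihood assumes complete samples.
- The mgf evaluator requires a light-tailed baseline at `t > 0`.
- The removable singularity of the alpha-power Weibull at `α₁ = 1` is not
  special-cased; `α₁ = 1` is a domain error (fit bounds keep the optimizer
  off the point in practice).
- Asymptotic KS p-values are conservative after fitting; use the bootstrap
  option when calibrated p-values matter.
- `σ` is weakly identified throughout the family (see above); interpret it
  jointly with `(α, γ)`, not in isolation.
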