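# frlx

Lifetime modelling with the **flexible reduced logarithmic (FRL-X) family** of
distributions — a one-extra-parameter transform of any baseline lifetime
distribution, aimed at right-skewed biomedical data (remission times, survival
times) whose hazard is *unimodal* rather than monotone.

Given a baseline cdf `F(x; ξ)` the family is

```
G(x; σ, ξ) = 1 − log(1 + σ − σ F(x; ξ)) / log(1 + σ),        σ > 0,
g(x; σ, ξ) = σ f(x; ξ) / [ log(1 + σ) · (1 + σ − σ F(x; ξ)) ].
```

Taking the two-parameter Weibull baseline `F(x) = 1 − exp(−γ x^α)` gives the
**FRL-Weibull (FRL-W)** distribution with parameters `(α, σ, γ)`. The quantile
function is closed-form,

```
Q(u) = F⁻¹( (1 + σ − (1+σ)^(1−u)) / σ ),
```

so inverse-transform sampling is exact. `σ → 0` recovers the baseline and
`σ = 1` is an ordinary interior point (the log-transformed family).

The package provides:

- `frlx.family` — the generic transform over any `BaselineModel`: cdf, pdf,
  survival, hazard, quantile, sampling, series/quadrature moments, mgf,
  residual-life ratios, and a truncated-moment characterization check;
- `frlx.models` — fit-ready registry: `frlw`, plain `weibull`, `aptw`
  (alpha-power-transformed Weibull), `mow` (Marshall-Olkin Weibull),
  `exponential`, and the exponent-extended families `frle-w`, `efrl-w`,
  `efrle-w`;
- `frlx.estimation` — maximum likelihood via box-constrained L-BFGS-B with
  analytic scores where available, multistart, observed-information standard
  errors;
- `frlx.gof` — Anderson-Darling, Cramér-von Mises, Kolmogorov-Smirnov (with
  asymptotic and parametric-bootstrap p-values), scaled-TTT coordinates, and
  ranked multi-model comparison;
- `frlx.mc` — a reproducible Monte Carlo harness for estimator bias/MSE
  tables;
- a `frlx` console script with `fit`, `gof`, `compare`, `simulate`, `tables`
  subcommands.

## Worked example

Fit the FRL-W distribution to 128 synthetic remission times drawn from the
unimodal-hazard regime the family targets, and check the fit:

```python
import numpy as np
from frlx import get_model, fit_mle, gof_report

frlw = get_model("frlw")
x = frlw.rvs(128, (1.3269, 12.978, 0.003), np.random.default_rng(42))

fit = fit_mle(x, "frlw")
print(fit.estimates)        # {'alpha': 1.4930, 'sigma': 12.1302, 'gamma': 0.0014}
print(fit.standard_errors)  # {'alpha': 0.1893, 'sigma': 19.774,  'gamma': 0.0017}
print(fit.loglik)           # -704.54

print(gof_report(x, "frlw", fit.theta))
# GofReport(model='frlw', n=128, cm=0.0439, ad=0.2806, ks=0.0530, ks_pvalue=0.8650)
```

The Weibull shape and the FRL parameter are recovered near their generating
values; the very large standard error on `σ` is real — the likelihood of this
family is nearly flat in `σ` (see `docs/methods.md`) — and the KS p-value of
0.86 says the fitted cdf tracks the sample closely.

The same from the shell, plus a small estimator study:

```sh
frlx fit --model frlw --input remission.txt
frlx compare --models frlw,weibull,aptw,mow --input remission.txt
frlx simulate --model frlw --params 0.7 1.3 0.4 --n 25,100 --reps 100 --seed 7
```

`simulate` prints a bias/MSE table per sample size (columns
`n, parameter, mle, mse, bias`) and records the seed in its JSON report so
every table is regenerable.

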