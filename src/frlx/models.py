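"""Concrete lifetime models exposed through a uniform fit-ready contract.

Weibull convention used throughout: ``F(x) = 1 - exp(-gamma * x**alpha)`` —
``gamma`` multiplies ``x**alpha`` directly (a rate-like scale), so fitted
parameter tables are comparable across every model here.

Models in the registry:

===========  ==============================  ==============================
key          parameters (order)              family
===========  ==============================  ==============================
``frlw``     alpha, sigma, gamma             FRL transform of the Weibull
``weibull``  alpha, gamma                    plain two-parameter Weibull
``aptw``     alpha1, alpha, gamma            alpha-power-transformed Weibull
``mow``      alpha, gamma, sigma             Marshall-Olkin Weibull
``frle-w``   theta, alpha, sigma, gamma      exponentiated-baseline extension
``efrl-w``   eta, alpha, sigma, gamma        outer-exponent extension
``efrle-w``  theta, eta, alpha, sigma, gamma both extensions
===========  ==============================  ==============================

Negative ``x`` values get cdf 0 / pdf 0 (lifetime support convention) rather
than an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import special

from .family import BaselineModel, FRLXParams, frlx_cdf, frlx_logpdf, frlx_pdf

__all__ = [
    "FRLWParams",
    "ExtendedParams",
    "ParametricModel",
    "MODEL_REGISTRY",
    "get_model",
    "weibull_baseline",
    "frlw_cdf",
    "frlw_pdf",
    "frlw_logpdf",
    "frlw_quantile",
    "weibull_cdf",
    "weibull_pdf",
    "aptw_cdf",
    "aptw_pdf",
    "mow_cdf",
    "mow_pdf",
    "extended_cdf",
    "extended_pdf",
]


def _positive(name, value):
    if not (np.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a positive finite real, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class FRLWParams:
    """FRL-Weibull parameters: Weibull shape ``alpha``, FRL ``sigma``, rate ``gamma``."""

    alpha: float
    sigma: float
    gamma: float

    def __post_init__(self):
        _positive("alpha", self.alpha)
        _positive("sigma", self.sigma)
        _positive("gamma", self.gamma)

    def as_frlx(self) -> FRLXParams:
        return FRLXParams(sigma=self.sigma, xi=(self.alpha, self.gamma))


@dataclass(frozen=True)
class ExtendedParams:
    """Extended-family parameters: inner exponent ``theta``, outer exponent ``eta``.

    ``theta = 1`` and/or ``eta = 1`` reduce exactly to the simpler families.
    """

    theta: float
    eta: float
    sigma: float
    xi: tuple = ()

    def __post_init__(self):
        _positive("theta", self.theta)
        _positive("eta", self.eta)
        _positive("sigma", self.sigma)
        object.__setattr__(self, "xi", tuple(float(v) for v in np.atleast_1d(self.xi)))


# ---------------------------------------------------------------------------
# Weibull baseline (rate parameterization: gamma multiplies x**alpha)
# ---------------------------------------------------------------------------

def _wei_cdf(x, xi):
    a, g = xi
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        out = -np.expm1(-g * np.power(np.maximum(x, 0.0), a))
    return np.where(x > 0.0, out, 0.0)


def _wei_pdf(x, xi):
    a, g = xi
    x = np.asarray(x, dtype=float)
    xp = np.maximum(x, LOGPDF_TINY)
    t = np.power(xp, a)
    out = a * g * np.power(xp, a - 1.0) * np.exp(-g * t)
    return np.where(x > 0.0, out, 0.0)


def _wei_logpdf(x, xi):
    a, g = xi
    x = np.asarray(x, dtype=float)
    xp = np.maximum(x, LOGPDF_TINY)
    out = math.log(a) + math.log(g) + (a - 1.0) * np.log(xp) - g * np.power(xp, a)
    return np.where(x > 0.0, out, -np.inf)


def _wei_quantile(u, xi):
    a, g = xi
    u = np.asarray(u, dtype=float)
    return np.power(-np.log1p(-u) / g, 1.0 / a)


def _wei_dlogpdf(x, xi):
    """Rows (d/d alpha, d/d gamma) of the log-density, shape (2, n)."""
    a, g = xi
    x = np.asarray(x, dtype=float)
    lx = np.log(x)
    t = np.power(x, a)
    return np.stack([1.0 / a + lx * (1.0 - g * t), 1.0 / g - t])


def _wei_dcdf(x, xi):
    """Rows (d/d alpha, d/d gamma) of the cdf, shape (2, n)."""
    a, g = xi
    x = np.asarray(x, dtype=float)
    t = np.power(x, a)
    e = np.exp(-g * t)
    return np.stack([e * g * t * np.log(x), e * t])


def _wei_validate(xi):
    a, g = xi
    _positive("alpha", a)
    _positive("gamma", g)


LOGPDF_TINY = 1e-300

_WEIBULL_BASELINE = BaselineModel(
    name="weibull",
    param_names=("alpha", "gamma"),
    support=(0.0, np.inf),
    cdf_fn=_wei_cdf,
    pdf_fn=_wei_pdf,
    quantile_fn=_wei_quantile,
    logpdf_fn=_wei_logpdf,
    dlogpdf_dxi=_wei_dlogpdf,
    dcdf_dxi=_wei_dcdf,
    validate_xi=_wei_validate,
)


def weibull_baseline() -> BaselineModel:
    """The two-parameter Weibull baseline with ``F = 1 - exp(-gamma x**alpha)``."""
    return _WEIBULL_BASELINE


# ---------------------------------------------------------------------------
# FRL-Weibull, written out directly (the generic transform is the cross-check)
# ---------------------------------------------------------------------------

def _frlw_theta(params):
    if isinstance(params, FRLWParams):
        return params.alpha, params.sigma, params.gamma
    a, s, g = params
    return float(a), float(s), float(g)


def frlw_cdf(x, params):
    """FRL-W cdf ``1 - log(1 + sigma*exp(-gamma x**alpha)) / log(1 + sigma)``."""
    a, s, g = _frlw_theta(params)
    x = np.asarray(x, dtype=float)
    e = np.exp(-g * np.power(np.maximum(x, 0.0), a))
    out = 1.0 - np.log1p(s * e) / math.log1p(s)
    return np.where(x > 0.0, out, 0.0)


def frlw_pdf(x, params):
    a, s, g = _frlw_theta(params)
    x = np.asarray(x, dtype=float)
    xp = np.maximum(x, LOGPDF_TINY)
    t = np.power(xp, a)
    e = np.exp(-g * t)
    out = a * s * g * np.power(xp, a - 1.0) * e / (math.log1p(s) * (1.0 + s * e))
    return np.where(x > 0.0, out, 0.0)


def frlw_logpdf(x, params):
    a, s, g = _frlw_theta(params)
    x = np.asarray(x, dtype=float)
    xp = np.maximum(x, LOGPDF_TINY)
    t = np.power(xp, a)
    out = (
        math.log(a) + math.log(s) + math.log(g)
        - math.log(math.log1p(s))
        + (a - 1.0) * np.log(xp)
        - g * t
        - np.log1p(s * np.exp(-g * t))
    )
    return np.where(x > 0.0, out, -np.inf)


def frlw_sf(x, params):
    a, s, g = _frlw_theta(params)
    x = np.asarray(x, dtype=float)
    e = np.exp(-g * np.power(np.maximum(x, 0.0), a))
    out = np.log1p(s * e) / math.log1p(s)
    return np.where(x > 0.0, out, 1.0)


def frlw_quantile(u, params):
    a, s, g = _frlw_theta(params)
    u = np.asarray(u, dtype=float)
    if np.any((u < 0.0) | (u > 1.0) | ~np.isfinite(u)):
        raise ValueError("quantile levels must lie in [0, 1]")
    # Baseline level: 1 - W = ((1+s)**(1-u) - 1)/s, then invert the Weibull.
    one_minus_w = np.expm1(math.log1p(s) * (1.0 - u)) / s
    one_minus_w = np.clip(one_minus_w, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        return np.power(-np.log(one_minus_w) / g, 1.0 / a)


def _frlw_score(data, theta):
    """Analytic gradient of the total log-likelihood in (alpha, sigma, gamma)."""
    a, s, g = theta
    x = np.asarray(data, dtype=float)
    n = x.size
    lx = np.log(x)
    t = np.power(x, a)
    e = np.exp(-g * t)          # 1 - F
    D = 1.0 + s * e             # 1 + sigma - sigma*F
    L = math.log1p(s)
    d_alpha = np.sum(1.0 / a + lx * (1.0 - g * t) + s * e * g * t * lx / D)
    d_sigma = n / s - n / ((1.0 + s) * L) - np.sum(e / D)
    d_gamma = np.sum(1.0 / g - t + s * e * t / D)
    return np.array([d_alpha, d_sigma, d_gamma])


# ---------------------------------------------------------------------------
# Competitors: Weibull, alpha-power-transformed Weibull, Marshall-Olkin Weibull
# ---------------------------------------------------------------------------

def weibull_cdf(x, theta):
    return _wei_cdf(x, theta)


def weibull_pdf(x, theta):
    return _wei_pdf(x, theta)


def _weibull_score(data, theta):
    a, g = theta
    x = np.asarray(data, dtype=float)
    lx = np.log(x)
    t = np.power(x, a)
    return np.array([np.sum(1.0 / a + lx * (1.0 - g * t)), np.sum(1.0 / g - t)])


def _check_aptw(theta):
    a1, a, g = theta
    _positive("alpha1", a1)
    if a1 == 1.0:
        raise ValueError("aptw requires alpha1 != 1")
    _positive("alpha", a)
    _positive("gamma", g)


def aptw_cdf(x, theta):
    """Alpha-power-transformed Weibull cdf ``(alpha1**W - 1)/(alpha1 - 1)``."""
    _check_aptw(theta)
    a1, a, g = theta
    W = _wei_cdf(x, (a, g))
    return np.expm1(W * math.log(a1)) / (a1 - 1.0)


def aptw_pdf(x, theta):
    _check_aptw(theta)
    a1, a, g = theta
    W = _wei_cdf(x, (a, g))
    w = _wei_pdf(x, (a, g))
    return math.log(a1) / (a1 - 1.0) * np.exp(W * math.log(a1)) * w


def aptw_logpdf(x, theta):
    _check_aptw(theta)
    a1, a, g = theta
    la1 = math.log(a1)
    W = _wei_cdf(x, (a, g))
    # log(alpha1)/(alpha1 - 1) > 0 on both sides of 1
    return math.log(la1 / (a1 - 1.0)) + W * la1 + _wei_logpdf(x, (a, g))


def aptw_quantile(u, theta):
    _check_aptw(theta)
    a1, a, g = theta
    u = np.asarray(u, dtype=float)
    W = np.log1p(u * (a1 - 1.0)) / math.log(a1)
    return _wei_quantile(np.clip(W, 0.0, 1.0), (a, g))


def mow_cdf(x, theta):
    """Marshall-Olkin Weibull cdf ``W / (sigma + (1 - sigma) W)``."""
    a, g, s = theta
    W = _wei_cdf(x, (a, g))
    return W / (s + (1.0 - s) * W)


def mow_pdf(x, theta):
    a, g, s = theta
    W = _wei_cdf(x, (a, g))
    w = _wei_pdf(x, (a, g))
    return s * w / np.square(s + (1.0 - s) * W)


def mow_logpdf(x, theta):
    a, g, s = theta
    W = _wei_cdf(x, (a, g))
    return math.log(s) + _wei_logpdf(x, (a, g)) - 2.0 * np.log(s + (1.0 - s) * W)


def mow_quantile(u, theta):
    a, g, s = theta
    u = np.asarray(u, dtype=float)
    W = s * u / (1.0 - (1.0 - s) * u)
    return _wei_quantile(np.clip(W, 0.0, 1.0), (a, g))


# ---------------------------------------------------------------------------
# Extended families: exponentiated baseline (theta) and outer exponent (eta)
# ---------------------------------------------------------------------------

def extended_cdf(x, params: ExtendedParams, base: BaselineModel):
    """cdf ``1 - [log(1 + sigma*(1 - F**theta)) / log(1 + sigma)]**eta``."""
    s, th, et = params.sigma, params.theta, params.eta
    F = np.clip(base.cdf(x, params.xi), 0.0, 1.0)
    ratio = np.log1p(s * (1.0 - np.power(F, th))) / math.log1p(s)
    return 1.0 - np.power(ratio, et)


def extended_pdf(x, params: ExtendedParams, base: BaselineModel):
    """Analytic density of the doubly-extended family (chain rule)."""
    s, th, et = params.sigma, params.theta, params.eta
    x = np.asarray(x, dtype=float)
    F = np.clip(base.cdf(x, params.xi), 0.0, 1.0)
    f = base.pdf(x, params.xi)
    L = math.log1p(s)
    Fth = np.power(F, th)
    A = np.log1p(s * (1.0 - Fth))
    with np.errstate(divide="ignore", invalid="ignore"):
        Fpow = np.where(F > 0.0, np.power(F, th - 1.0), 0.0 if th >= 1.0 else np.inf)
        # A == 0 means the cdf has saturated to 1 in double precision; the
        # density there is below resolution, so report 0 rather than the
        # spurious infinity (A/L)**(eta-1) would give for eta < 1.
        ratio_pow = np.where(A > 0.0, np.power(np.maximum(A, 1e-300) / L, et - 1.0),
                             0.0)
        out = et * ratio_pow * s * th * Fpow * f / (L * (1.0 + s * (1.0 - Fth)))
    return np.where((f > 0.0) & (A > 0.0), out, 0.0)


def extended_quantile(u, params: ExtendedParams, base: BaselineModel):
    s, th, et = params.sigma, params.theta, params.eta
    u = np.asarray(u, dtype=float)
    if np.any((u < 0.0) | (u > 1.0) | ~np.isfinite(u)):
        raise ValueError("quantile levels must lie in [0, 1]")
    inner_sf = np.power(1.0 - u, 1.0 / et)          # A/L level
    one_minus_Fth = np.expm1(math.log1p(s) * inner_sf) / s
    Fth = np.clip(1.0 - one_minus_Fth, 0.0, 1.0)
    return base.quantile(np.power(Fth, 1.0 / th), params.xi)


def extended_logpdf(x, params: ExtendedParams, base: BaselineModel):
    with np.errstate(divide="ignore"):
        return np.log(extended_pdf(x, params, base))


# ---------------------------------------------------------------------------
# Registry: a uniform contract so estimation / gof / simulation stay model-agnostic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParametricModel:
    """Fit-ready model: named parameters plus vectorized evaluators.

    ``score`` (gradient of the total log-likelihood) is optional; models
    without one are fitted with finite-difference gradients.
    """

    name: str
    param_names: tuple
    logpdf: Callable
    cdf: Callable
    pdf: Callable
    quantile: Callable
    validate: Callable
    default_start: Callable
    score: Callable | None = None

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def rvs(self, n: int, theta, rng) -> np.ndarray:
        """Inverse-transform sample of size ``n`` from a seeded generator."""
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        if n < 1:
            raise ValueError(f"sample size must be positive, got {n}")
        return self.quantile(rng.uniform(0.0, 1.0, size=int(n)), theta)

    def theta_dict(self, theta) -> dict:
        return dict(zip(self.param_names, (float(v) for v in theta)))


def _weibull_mom_start(data):
    """Method-of-moments Weibull start: shape from the CV, then the rate."""
    x = np.asarray(data, dtype=float)
    m, sd = float(np.mean(x)), float(np.std(x))
    cv = sd / m if m > 0 and sd > 0 else 1.0
    alpha = max(cv ** -1.086, 0.05)  # classic closed-form CV approximation
    lam = m / special.gamma(1.0 + 1.0 / alpha)
    gamma = lam ** -alpha
    return alpha, gamma


def _all_positive_validator(names):
    def validate(theta):
        for nm, v in zip(names, theta):
            _positive(nm, v)
    return validate


def _frlw_validate(theta):
    FRLWParams(*theta)


def _aptw_start(data):
    a, g = _weibull_mom_start(data)
    return (2.0, a, g)


MODEL_REGISTRY: dict = {}


def _register(model: ParametricModel):
    MODEL_REGISTRY[model.name] = model
    return model


_register(ParametricModel(
    name="frlw",
    param_names=("alpha", "sigma", "gamma"),
    logpdf=frlw_logpdf,
    cdf=frlw_cdf,
    pdf=frlw_pdf,
    quantile=frlw_quantile,
    validate=_frlw_validate,
    default_start=lambda data: (*_insert_sigma(_weibull_mom_start(data)),),
    score=_frlw_score,
))


def _insert_sigma(ag):
    a, g = ag
    return (a, 1.0, g)


_register(ParametricModel(
    name="weibull",
    param_names=("alpha", "gamma"),
    logpdf=_wei_logpdf,
    cdf=_wei_cdf,
    pdf=_wei_pdf,
    quantile=_wei_quantile,
    validate=_wei_validate,
    default_start=_weibull_mom_start,
    score=_weibull_score,
))

_register(ParametricModel(
    name="aptw",
    param_names=("alpha1", "alpha", "gamma"),
    logpdf=aptw_logpdf,
    cdf=aptw_cdf,
    pdf=aptw_pdf,
    quantile=aptw_quantile,
    validate=_check_aptw,
    default_start=_aptw_start,
))

_register(ParametricModel(
    name="mow",
    param_names=("alpha", "gamma", "sigma"),
    logpdf=mow_logpdf,
    cdf=mow_cdf,
    pdf=mow_pdf,
    quantile=mow_quantile,
    validate=_all_positive_validator(("alpha", "gamma", "sigma")),
    default_start=lambda data: (*_weibull_mom_start(data), 1.0),
))


def _extended_model(name, with_theta, with_eta):
    exponents = (("theta",) if with_theta else ()) + (("eta",) if with_eta else ())
    names = exponents + ("alpha", "sigma", "gamma")

    def unpack(theta):
        vals = dict(zip(names, theta))
        return ExtendedParams(
            theta=vals.get("theta", 1.0),
            eta=vals.get("eta", 1.0),
            sigma=vals["sigma"],
            xi=(vals["alpha"], vals["gamma"]),
        )

    base = weibull_baseline()
    return ParametricModel(
        name=name,
        param_names=names,
        logpdf=lambda x, th: extended_logpdf(x, unpack(th), base),
        cdf=lambda x, th: extended_cdf(x, unpack(th), base),
        pdf=lambda x, th: extended_pdf(x, unpack(th), base),
        quantile=lambda u, th: extended_quantile(u, unpack(th), base),
        validate=lambda th: unpack(th),
        default_start=lambda data: tuple([1.0] * len(exponents))
        + _insert_sigma(_weibull_mom_start(data)),
    )


_register(ParametricModel(
    name="exponential",
    param_names=("lam",),
    logpdf=lambda x, th: np.where(np.asarray(x, dtype=float) > 0,
                                  math.log(th[0]) - th[0] * np.asarray(x, dtype=float),
                                  -np.inf),
    cdf=lambda x, th: np.where(np.asarray(x, dtype=float) > 0,
                               -np.expm1(-th[0] * np.asarray(x, dtype=float)), 0.0),
    pdf=lambda x, th: np.where(np.asarray(x, dtype=float) > 0,
                               th[0] * np.exp(-th[0] * np.asarray(x, dtype=float)), 0.0),
    quantile=lambda u, th: -np.log1p(-np.asarray(u, dtype=float)) / th[0],
    validate=_all_positive_validator(("lam",)),
    default_start=lambda data: (1.0 / float(np.mean(data)),),
    score=lambda data, th: np.array(
        [len(data) / th[0] - float(np.sum(data))]
    ),
))

_register(_extended_model("frle-w", with_theta=True, with_eta=False))
_register(_extended_model("efrl-w", with_theta=False, with_eta=True))
_register(_extended_model("efrle-w", with_theta=True, with_eta=True))


def get_model(name) -> ParametricModel:
    """Look up a registered model by name (or pass one through unchanged)."""
    if isinstance(name, ParametricModel):
        return name
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(MODEL_REGISTRY))
        raise KeyError(f"unknown model {name!r}; registered models: {known}") from None
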