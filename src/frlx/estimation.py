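"""Maximum-likelihood fitting of any registered model.

The log-likelihood of an FRL-X model for a complete sample x_1..x_n is

    n log sigma - n log log(1+sigma)
      + sum_i log f(x_i; xi) - sum_i log(1 + sigma - sigma F(x_i; xi)),

maximized under box constraints (all parameters > 0) with L-BFGS-B, using the
analytic score where the model provides one and finite differences otherwise.
Standard errors come from the inverse of the numerically-differentiated
observed information at the optimum.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import optimize
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from .models import ParametricModel, get_model

__all__ = [
    "FitConfig",
    "FitResult",
    "log_likelihood",
    "score",
    "fit_mle",
    "standard_errors",
]

# Penalty returned to the optimizer when the likelihood is non-finite: large
# but finite, so L-BFGS-B backtracks instead of aborting the line search.
_PENALTY = 1e10
_LOWER_BOUND = 1e-8


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for :func:`fit_mle`.

    ``start``: explicit initial parameter vector, or None for the model's
    default rule (method-of-moments Weibull shape/rate, unit extras).
    ``multistart``: number of additional jittered starts; the best final
    likelihood wins.  Jitter is multiplicative log-normal with scale
    ``jitter_scale``, drawn from ``seed`` so fits are deterministic.
    """

    start: tuple | None = None
    lower_bound: float = _LOWER_BOUND
    upper_bound: float | None = None
    maxiter: int = 200
    ftol: float = 2.22e-9  # the customary L-BFGS-B factr=1e7 criterion
    gtol: float = 1e-8
    multistart: int = 5
    jitter_scale: float = 0.25
    seed: int = 0
    compute_se: bool = True


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    model: str
    estimates: dict
    standard_errors: dict
    loglik: float
    converged: bool
    n_obs: int
    n_starts: int = 1
    message: str = ""

    @property
    def theta(self) -> np.ndarray:
        return np.array(list(self.estimates.values()))

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_row(self) -> dict:
        """Flat row (estimate + SE per parameter) for comparison tables."""
        row: dict = {"model": self.model, "loglik": self.loglik,
                     "converged": self.converged, "n_obs": self.n_obs}
        for name, est in self.estimates.items():
            row[name] = est
            row[f"se_{name}"] = self.standard_errors.get(name, float("nan"))
        return row


def log_likelihood(data, theta, model) -> float:
    """Total log-likelihood; samples hitting zero density give ``-inf``."""
    model = get_model(model)
    x = np.asarray(data, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = model.logpdf(x, theta)
    ll = np.asarray(ll)
    if np.any(np.isneginf(ll)):
        return -np.inf
    return float(np.sum(ll))


def score(data, theta, model) -> np.ndarray:
    """Gradient of the total log-likelihood (analytic when available)."""
    model = get_model(model)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("score requires interior (strictly positive) parameters")
    if model.score is not None:
        return np.asarray(model.score(np.asarray(data, dtype=float), theta))
    return approx_fprime(theta, lambda th: log_likelihood(data, th, model),
                         centered=True).ravel()


def _objective(model, data):
    def nll(theta):
        val = log_likelihood(data, theta, model)
        return _PENALTY if not np.isfinite(val) else -val
    return nll


def _gradient(model, data):
    if model.score is None:
        return None

    def grad(theta):
        val = log_likelihood(data, theta, model)
        if not np.isfinite(val):
            return np.zeros(len(theta))
        return -np.asarray(model.score(np.asarray(data, dtype=float), theta))
    return grad


def _starts(model, data, config):
    base = np.array(config.start if config.start is not None
                    else model.default_start(np.asarray(data, dtype=float)),
                    dtype=float)
    starts = [base]
    if config.multistart > 1:
        rng = np.random.default_rng(config.seed)
        for _ in range(config.multistart - 1):
            jitter = np.exp(rng.normal(0.0, config.jitter_scale, size=base.size))
            starts.append(np.maximum(base * jitter, config.lower_bound * 10))
    return starts


def fit_mle(data, model, config: FitConfig | None = None) -> FitResult:
    """Box-constrained quasi-Newton maximum-likelihood fit.

    Deterministic given (data, config); non-convergence after every start is
    reported through ``converged=False``, never as an exception.
    """
    model = get_model(model)
    config = config or FitConfig()
    x = np.asarray(data, dtype=float)
    if x.size < model.n_params:
        raise ValueError(
            f"need at least {model.n_params} observations to fit "
            f"{model.name!r}, got {x.size}"
        )
    bounds = [(config.lower_bound, config.upper_bound)] * model.n_params
    nll = _objective(model, x)
    grad = _gradient(model, x)

    best = None
    n_tried = 0
    for start in _starts(model, x, config):
        n_tried += 1
        res = optimize.minimize(
            nll, start, jac=grad, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.maxiter, "ftol": config.ftol,
                     "gtol": config.gtol},
        )
        if best is None or res.fun < best.fun:
            best = res

    loglik = -float(best.fun)
    converged = bool(best.success and np.isfinite(loglik))
    estimates = model.theta_dict(best.x)
    result = FitResult(
        model=model.name,
        estimates=estimates,
        standard_errors={},
        loglik=loglik,
        converged=converged,
        n_obs=int(x.size),
        n_starts=n_tried,
        message=str(best.message),
    )
    if config.compute_se and converged:
        result.standard_errors = standard_errors(x, result, model)
    return result


def standard_errors(data, fit: FitResult, model) -> dict:
    """SEs from the inverse observed information (numeric Hessian at the MLE).

    A non-positive-definite information matrix yields NaN entries and a
    warning rather than an exception.
    """
    model = get_model(model)
    theta = fit.theta
    x = np.asarray(data, dtype=float)
    nan_out = {name: float("nan") for name in model.param_names}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess(theta, lambda th: log_likelihood(x, th, model))
        info = -np.asarray(hess)
        # Positive definiteness via Cholesky; failure -> flagged NaNs.
        np.linalg.cholesky(info)
        cov = np.linalg.inv(info)
        ses = np.sqrt(np.diag(cov))
    except (np.linalg.LinAlgError, ValueError, FloatingPointError):
        warnings.warn(
            f"observed information for model {model.name!r} is not positive "
            "definite; standard errors unavailable",
            stacklevel=2,
        )
        return nan_out
    if not np.all(np.isfinite(ses)):
        warnings.warn(
            f"non-finite standard errors for model {model.name!r}", stacklevel=2
        )
        return nan_out
    return dict(zip(model.param_names, (float(s) for s in ses)))
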