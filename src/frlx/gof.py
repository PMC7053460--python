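"""Goodness of fit: Anderson-Darling, Cramér-von Mises, Kolmogorov-Smirnov,
empirical TTT coordinates, and ranked multi-model comparisons.

All three statistics act on the probability-integral transform
``z_i = G(x_(i))`` of the sorted sample only, so feeding ``(z, uniform)``
gives identical values to feeding ``(data, model)``.  ``z`` is clamped to
``[1e-12, 1 - 1e-12]`` to keep the Anderson-Darling statistic finite when a
fitted cdf value rounds to 0 or 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import special

from .estimation import FitConfig, fit_mle
from .models import get_model

__all__ = [
    "GofReport",
    "ad_statistic",
    "cm_statistic",
    "ks_statistic",
    "ks_pvalue",
    "ks_pvalue_bootstrap",
    "gof_report",
    "ttt_coordinates",
    "compare_models",
]

_Z_CLAMP = 1e-12


def _pit(data, model, theta) -> np.ndarray:
    """Sorted, clamped probability-integral transform of the sample."""
    if model is None:  # data are already probabilities
        z = np.sort(np.asarray(data, dtype=float))
    else:
        model = get_model(model)
        z = np.sort(np.asarray(model.cdf(np.asarray(data, dtype=float), theta)))
    return np.clip(z, _Z_CLAMP, 1.0 - _Z_CLAMP)


@dataclass(frozen=True)
class GofReport:
    """Distance statistics for one fitted model on one sample."""

    model: str
    n: int
    cm: float
    ad: float
    ks: float
    ks_pvalue: float

    def to_dict(self) -> dict:
        return asdict(self)


def ad_statistic(data, model=None, theta=None) -> float:
    """Anderson-Darling statistic
    ``-n - (1/n) sum_i (2i-1)[log z_i + log(1 - z_(n-i+1))]``.

    ``model=None`` treats ``data`` as cdf values directly.
    """
    z = _pit(data, model, theta)
    n = z.size
    if n < 2:
        raise ValueError("Anderson-Darling needs at least 2 observations")
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(z) + np.log1p(-z[::-1]))))


def cm_statistic(data, model=None, theta=None) -> float:
    """Cramér-von Mises statistic ``1/(12n) + sum_i [z_i - (2i-1)/(2n)]**2``."""
    z = _pit(data, model, theta)
    n = z.size
    if n < 1:
        raise ValueError("empty sample")
    i = np.arange(1, n + 1)
    return float(1.0 / (12 * n) + np.sum((z - (2 * i - 1) / (2 * n)) ** 2))


def ks_statistic(data, model=None, theta=None) -> float:
    """Two-sided Kolmogorov-Smirnov distance
    ``max_i max(i/n - z_i, z_i - (i-1)/n)``."""
    z = _pit(data, model, theta)
    n = z.size
    if n < 1:
        raise ValueError("empty sample")
    i = np.arange(1, n + 1)
    return float(np.max(np.maximum(i / n - z, z - (i - 1) / n)))


def ks_pvalue(ks: float, n: int) -> float:
    """Asymptotic Kolmogorov p-value ``P(sup |B(t)| > sqrt(n) * D)``."""
    return float(special.kolmogorov(math.sqrt(n) * ks))


def ks_pvalue_bootstrap(data, model, theta, n_boot: int = 200, seed: int = 0,
                        config: FitConfig | None = None) -> float:
    """Parametric-bootstrap KS p-value accounting for parameter estimation.

    Simulates ``n_boot`` samples from the fitted model, refits each, and
    returns the fraction of bootstrap KS statistics at least as large as the
    observed one.
    """
    model = get_model(model)
    x = np.asarray(data, dtype=float)
    observed = ks_statistic(x, model, theta)
    config = config or FitConfig(start=tuple(theta), multistart=1, compute_se=False)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        sim = model.rvs(x.size, theta, rng)
        fit = fit_mle(sim, model, config)
        if ks_statistic(sim, model, fit.theta) >= observed:
            exceed += 1
    return (exceed + 1) / (n_boot + 1)


def gof_report(data, model, theta) -> GofReport:
    """All three statistics plus the asymptotic KS p-value for one model."""
    model = get_model(model)
    x = np.asarray(data, dtype=float)
    ks = ks_statistic(x, model, theta)
    return GofReport(
        model=model.name,
        n=int(x.size),
        cm=cm_statistic(x, model, theta),
        ad=ad_statistic(x, model, theta),
        ks=ks,
        ks_pvalue=ks_pvalue(ks, x.size),
    )


def ttt_coordinates(data) -> np.ndarray:
    """Scaled total-time-on-test coordinates ``(i/n, T_i)`` for i = 1..n.

    ``T_i = [sum_{j<=i} x_(j) + (n-i) x_(i)] / sum_j x_(j)``; the final point
    is exactly (1, 1).  Concave curves indicate increasing hazard; an S shape
    indicates a unimodal hazard.
    """
    x = np.sort(np.asarray(data, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("TTT transform needs at least 2 observations")
    if np.any(x <= 0):
        raise ValueError("TTT transform requires strictly positive observations")
    csum = np.cumsum(x)
    total = csum[-1]
    i = np.arange(1, n + 1)
    t = (csum + (n - i) * x) / total
    return np.column_stack([i / n, t])


def compare_models(data, models, config: FitConfig | None = None) -> pd.DataFrame:
    """Fit each model by MLE and rank by (KS, AD, CM) ascending.

    Models that fail to converge stay in the table flagged ``converged=False``
    (ranked after converged ones).  Deterministic given data and config.
    """
    models = [get_model(m) for m in models]
    if len(models) < 1:
        raise ValueError("need at least one model to compare")
    rows = []
    for model in models:
        fit = fit_mle(data, model, config)
        report = gof_report(data, model, fit.theta)
        row = {
            "model": model.name,
            "params": fit.estimates,
            "loglik": fit.loglik,
            "converged": fit.converged,
            "cm": report.cm,
            "ad": report.ad,
            "ks": report.ks,
            "ks_pvalue": report.ks_pvalue,
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["converged", "ks", "ad", "cm"], ascending=[False, True, True, True],
        kind="stable",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
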