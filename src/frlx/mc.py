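"""Monte Carlo evaluation of the maximum-likelihood estimators.

For each sample size n the harness draws R independent samples from the true
model by inverse-transform sampling, fits each by MLE, and summarizes each
parameter w by

    Bias(w) = (1/R) sum_i (w_hat_i - w),    MSE(w) = (1/R) sum_i (w_hat_i - w)^2.

Seeding uses ``numpy.random.SeedSequence`` spawning: the master seed derives
one independent substream per (sample size, replicate), so every cell is
reproducible in isolation and results do not depend on execution order.
Replicates whose fit fails to converge are excluded from the averages, with
the count reported per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimation import FitConfig, fit_mle
from .models import get_model

__all__ = ["McConfig", "McSummary", "run_mc_study", "mc_table"]


@dataclass(frozen=True)
class McConfig:
    """Configuration of one generate-fit-summarize study."""

    model: str
    true_params: tuple
    sample_sizes: tuple
    replications: int = 1000
    seed: int = 0
    fit_config: FitConfig | None = None

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        k = get_model(self.model).n_params
        if len(self.true_params) != k:
            raise ValueError(f"model {self.model!r} takes {k} parameters")
        if any(n < k for n in self.sample_sizes):
            raise ValueError("every sample size must be >= number of parameters")


@dataclass
class McSummary:
    """Per-(n, parameter) mean estimate, bias and MSE, plus raw replicates.

    ``table`` has one row per (n, parameter) with columns
    n, parameter, true, mle, mse, bias, n_fail.  ``estimates`` maps each
    sample size to the (R_ok, k) array of converged replicate estimates.
    """

    model: str
    true_params: dict
    replications: int
    seed: int
    table: pd.DataFrame
    estimates: dict = field(default_factory=dict)

    def cell(self, n: int, parameter: str) -> pd.Series:
        t = self.table
        row = t[(t["n"] == n) & (t["parameter"] == parameter)]
        if row.empty:
            raise KeyError(f"no cell (n={n}, parameter={parameter!r})")
        return row.iloc[0]


def run_mc_study(config: McConfig, fitter=None) -> McSummary:
    """Run the full study described by ``config``.

    ``fitter(sample, model, fit_config) -> FitResult`` may be overridden
    (e.g. stubbed in tests); default is :func:`frlx.estimation.fit_mle`.
    Raises if every replication in some cell fails.
    """
    model = get_model(config.model)
    truth = np.asarray(config.true_params, dtype=float)
    fit_config = config.fit_config or FitConfig(
        start=tuple(truth), multistart=1, compute_se=False
    )
    fitter = fitter or fit_mle
    master = np.random.SeedSequence(config.seed)
    per_n_seeds = master.spawn(len(config.sample_sizes))

    rows = []
    estimates: dict = {}
    for n, n_seed in zip(config.sample_sizes, per_n_seeds):
        rep_seeds = n_seed.spawn(config.replications)
        kept = []
        n_fail = 0
        for rep_seed in rep_seeds:
            rng = np.random.default_rng(rep_seed)
            sample = model.rvs(int(n), truth, rng)
            fit = fitter(sample, model, fit_config)
            if fit.converged and np.all(np.isfinite(fit.theta)):
                kept.append(fit.theta)
            else:
                n_fail += 1
        if not kept:
            raise RuntimeError(
                f"all {config.replications} replications failed to converge "
                f"for model {model.name!r} at n={n}"
            )
        est = np.vstack(kept)
        estimates[int(n)] = est
        dev = est - truth
        for j, name in enumerate(model.param_names):
            rows.append({
                "n": int(n),
                "parameter": name,
                "true": float(truth[j]),
                "mle": float(np.mean(est[:, j])),
                "mse": float(np.mean(dev[:, j] ** 2)),
                "bias": float(np.mean(dev[:, j])),
                "n_fail": n_fail,
            })
    return McSummary(
        model=model.name,
        true_params=model.theta_dict(truth),
        replications=config.replications,
        seed=config.seed,
        table=pd.DataFrame(rows),
        estimates=estimates,
    )


def mc_table(summary: McSummary) -> pd.DataFrame:
    """Rows (n, parameter, MLE mean, MSE, bias) in the conventional order."""
    cols = ["n", "parameter", "mle", "mse", "bias"]
    return summary.table[cols].copy()
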