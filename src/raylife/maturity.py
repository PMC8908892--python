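"""Logistic maturity ogive and median size-at-maturity (DW50).

The probability that an individual of disc width ``x`` is mature is modelled
as a logistic in size,

    P(mature | x) = 1 / (1 + exp(-(a + b * x))),

so the median size-at-maturity is DW50 = -a / b, the width at which half the
population is mature.  Coefficients are estimated by Bayesian MCMC with a
Bernoulli likelihood and weakly-informative normal(10, 5) priors on both
``a`` and ``b``; the DW50 posterior is formed draw-wise (``-a/b`` per retained
draw) so its credible interval carries the posterior correlation of (a, b).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import growth as _growth
from .inference import (
    MCMCConfig,
    PosteriorDraws,
    Prior,
    PriorSpec,
    sample_posterior,
    summarize,
)

__all__ = [
    "MaturityObservation",
    "MaturityCoefs",
    "MaturityFit",
    "maturity_prob",
    "dw50",
    "default_maturity_priors",
    "fit_maturity",
    "fit_maturity_by_sex",
    "age_at_maturity",
]


@dataclass(frozen=True)
class MaturityObservation:
    """One staged specimen: disc width (cm), sex and binary maturity."""

    specimen_id: str
    dw: float
    sex: str
    mature: int

    def __post_init__(self) -> None:
        if not self.dw > 0:
            raise ValueError(f"disc width must be > 0, got {self.dw}")
        if self.mature not in (0, 1):
            raise ValueError("mature must be 0 (immature) or 1 (mature)")


@dataclass(frozen=True)
class MaturityCoefs:
    """Logistic coefficients: intercept ``a`` (dimensionless), slope ``b`` (cm^-1)."""

    a: float
    b: float

    @property
    def dw50(self) -> float:
        return dw50(self.a, self.b)


def maturity_prob(coefs: MaturityCoefs | tuple[float, float], dw) -> float | np.ndarray:
    """Probability of being mature at disc width ``dw`` (cm)."""
    a, b = (coefs.a, coefs.b) if isinstance(coefs, MaturityCoefs) else coefs
    out = expit(a + b * np.asarray(dw, dtype=float))
    return out if out.ndim else float(out)


def dw50(a: float, b: float) -> float:
    """Median size-at-maturity, ``-a / b`` (cm); undefined for a flat ogive."""
    if b == 0:
        raise ValueError("dw50 is undefined when the logistic slope b is 0")
    return -a / b


def default_maturity_priors() -> PriorSpec:
    """Uninformative normal(10, 5) on both the intercept and the slope."""
    return PriorSpec({"a": Prior("normal", 10.0, 5.0), "b": Prior("normal", 10.0, 5.0)})


@dataclass
class MaturityFit:
    """Posterior maturity-ogive fit for one stratum."""

    draws: PosteriorDraws  # parameters a, b
    summary: "object"  # FitSummary over a, b
    dw50_draws: np.ndarray  # flattened draw-wise -a/b
    dw50_median: float
    dw50_ci: tuple[float, float]
    n_obs: int

    @property
    def coefs(self) -> MaturityCoefs:
        """Posterior-median coefficients (point summary only)."""
        med = self.summary.table["median"]
        return MaturityCoefs(a=med["a"], b=med["b"])

    @property
    def dw50_from_medians(self) -> float:
        """The alternative point estimate -median(a)/median(b); may differ from
        the draw-wise median and is reported alongside it."""
        return dw50(self.coefs.a, self.coefs.b)


def fit_maturity(
    data: Sequence[MaturityObservation],
    config: MCMCConfig | None = None,
    priors: PriorSpec | None = None,
) -> MaturityFit:
    """Fit the maturity ogive by MCMC.

    Requires both immature and mature individuals in ``data``.  DW50 is
    computed per retained draw; the reported point estimate is the posterior
    median of those draw-wise values.
    """
    if config is None:
        config = MCMCConfig()
    if priors is None:
        priors = default_maturity_priors()
    y = np.array([o.mature for o in data], dtype=float)
    x = np.array([o.dw for o in data], dtype=float)
    if len(data) == 0 or y.min() == y.max():
        raise ValueError(
            "fit_maturity needs both immature and mature individuals"
        )
    pa, pb = priors["a"], priors["b"]

    def log_post(theta: np.ndarray) -> float:
        a, b = theta
        eta = a + b * x
        # log P(y=1) = -log1p(exp(-eta)); log P(y=0) = -log1p(exp(eta))
        ll = -np.sum(np.logaddexp(0.0, np.where(y == 1, -eta, eta)))
        return pa.logpdf(a) + pb.logpdf(b) + ll

    draws = sample_posterior(
        log_post,
        np.array([0.0, 0.5]),
        config,
        names=["a", "b"],
        init_scales=[3.0, 0.15],
    )
    summary = summarize(draws)
    a_d = draws.flat("a")
    b_d = draws.flat("b")
    with np.errstate(divide="ignore"):
        dw50_d = -a_d / b_d
    lo, med, hi = np.quantile(dw50_d, [0.025, 0.5, 0.975])
    return MaturityFit(
        draws=draws,
        summary=summary,
        dw50_draws=dw50_d,
        dw50_median=float(med),
        dw50_ci=(float(lo), float(hi)),
        n_obs=len(data),
    )


def fit_maturity_by_sex(
    data: Sequence[MaturityObservation],
    config: MCMCConfig | None = None,
    priors: PriorSpec | None = None,
) -> pd.DataFrame:
    """Independent male, female and combined fits, one summary row each.

    Mirrors the conventional reporting: coefficients with 95% credible
    intervals and DW50 with its interval.  Strata with fewer than two classes
    are skipped.
    """
    if config is None:
        config = MCMCConfig()
    strata = {
        "male": [o for o in data if o.sex == "M"],
        "female": [o for o in data if o.sex == "F"],
        "combined": list(data),
    }
    rows = {}
    for i, (name, obs) in enumerate(strata.items()):
        classes = {o.mature for o in obs}
        if len(classes) < 2:
            continue
        # distinct, reproducible seed per stratum
        cfg = MCMCConfig(
            n_chains=config.n_chains,
            n_iter=config.n_iter,
            n_warmup=config.n_warmup,
            seed=config.seed + i,
            target_accept=config.target_accept,
            adapt_window=config.adapt_window,
        )
        fit = fit_maturity(obs, cfg, priors)
        t = fit.summary.table
        rows[name] = {
            "n": fit.n_obs,
            "a": t.loc["a", "median"],
            "a_ci_low": t.loc["a", "ci_low"],
            "a_ci_high": t.loc["a", "ci_high"],
            "b": t.loc["b", "median"],
            "b_ci_low": t.loc["b", "ci_low"],
            "b_ci_high": t.loc["b", "ci_high"],
            "dw50": fit.dw50_median,
            "dw50_ci_low": fit.dw50_ci[0],
            "dw50_ci_high": fit.dw50_ci[1],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def age_at_maturity(growth_params: "_growth.GrowthParams", dw50_cm: float) -> float:
    """Age (years) at which the growth curve reaches the median maturity size."""
    return _growth.age_at_size(growth_params, dw50_cm)
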