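"""Size-at-age growth functions for batoids.

Three standard families relate vertebral age (annual band counts, years) to
disc width (DW, cm): logistic, Gompertz and von Bertalanffy.  All three share
the parameterisation (``dw_inf``, ``dw_birth``, ``k``) so that every curve
passes through ``dw_birth`` at age 0 and approaches the asymptote ``dw_inf``
as age grows.  The von Bertalanffy curve is used in its size-at-birth form

    DW(age) = DW_birth + (DW_inf - DW_birth) * (1 - exp(-k * age)),

i.e. the increment ``(DW_inf - DW_birth)`` enters with a positive sign so the
curve increases toward the asymptote.

Observed disc widths are modelled as Gaussian around the curve with a common
observation standard deviation ``sigma`` (cm); the pointwise log-likelihood is
retained for leave-one-out cross-validation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GrowthFamily",
    "GrowthParams",
    "SizeAtAgeObservation",
    "SizeOutOfRangeError",
    "predict_dw",
    "age_at_size",
    "fraction_of_max_at_age",
    "log_likelihood",
    "fit_growth",
]


class GrowthFamily(str, enum.Enum):
    """Growth-function family."""

    LOGISTIC = "logistic"
    GOMPERTZ = "gompertz"
    VON_BERTALANFFY = "von_bertalanffy"


class SizeOutOfRangeError(ValueError):
    """Requested disc width lies outside [dw_birth, dw_inf) for this curve."""


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of one growth-function family.

    Attributes
    ----------
    family : GrowthFamily
        Curve family.
    dw_inf : float
        Asymptotic disc width (cm).
    dw_birth : float
        Disc width at birth, i.e. at age 0 (cm).
    k : float
        Growth coefficient (year^-1), rate of approach to the asymptote.
    sigma : float
        Observation standard deviation of disc width around the curve (cm).
    """

    family: GrowthFamily
    dw_inf: float
    dw_birth: float
    k: float
    sigma: float = 1.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", GrowthFamily(self.family))
        if not (self.dw_inf > self.dw_birth > 0):
            raise ValueError(
                f"require dw_inf > dw_birth > 0, got dw_inf={self.dw_inf}, "
                f"dw_birth={self.dw_birth}"
            )
        if not self.k > 0:
            raise ValueError(f"growth coefficient k must be > 0, got {self.k}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    def with_sigma(self, sigma: float) -> "GrowthParams":
        return replace(self, sigma=sigma)


@dataclass(frozen=True)
class SizeAtAgeObservation:
    """One aged specimen: vertebral band-count age (years) and disc width (cm)."""

    specimen_id: str
    age: float
    dw: float

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if not self.dw > 0:
            raise ValueError(f"disc width must be > 0, got {self.dw}")


def _check_ages(age) -> np.ndarray:
    age = np.asarray(age, dtype=float)
    if np.any(age < 0) or np.any(~np.isfinite(age)):
        raise ValueError("ages must be finite and >= 0")
    return age


def predict_dw(params: GrowthParams, age):
    """Predicted disc width (cm) at ``age`` (years) under ``params``.

    Accepts a scalar or array of ages; returns the matching shape.
    """
    age = _check_ages(age)
    winf, wb, k = params.dw_inf, params.dw_birth, params.k
    if params.family is GrowthFamily.LOGISTIC:
        out = winf / (1.0 + ((winf - wb) / wb) * np.exp(-k * age))
    elif params.family is GrowthFamily.GOMPERTZ:
        out = wb * np.exp(np.log(winf / wb) * (1.0 - np.exp(-k * age)))
    else:  # von Bertalanffy, size-at-birth form
        out = wb + (winf - wb) * (1.0 - np.exp(-k * age))
    return out if out.ndim else float(out)


def age_at_size(params: GrowthParams, dw):
    """Closed-form inverse of :func:`predict_dw`: age (years) at disc width ``dw``.

    Valid for ``dw_birth <= dw < dw_inf``; raises
    :class:`SizeOutOfRangeError` outside that range.
    """
    dw = np.asarray(dw, dtype=float)
    winf, wb, k = params.dw_inf, params.dw_birth, params.k
    if np.any(dw < wb) or np.any(dw >= winf):
        raise SizeOutOfRangeError(
            f"disc width must lie in [{wb}, {winf}) cm for family "
            f"{params.family.value}; got {dw}"
        )
    if params.family is GrowthFamily.LOGISTIC:
        # dw = winf / (1 + c e^{-ka}), c = (winf - wb)/wb
        c = (winf - wb) / wb
        out = -np.log((winf / dw - 1.0) / c) / k
    elif params.family is GrowthFamily.GOMPERTZ:
        ell = np.log(winf / wb)
        out = -np.log(1.0 - np.log(dw / wb) / ell) / k
    else:
        out = -np.log(1.0 - (dw - wb) / (winf - wb)) / k
    # dw == dw_birth maps to exactly 0; clip away -0.0 from rounding
    out = np.maximum(out, 0.0)
    return out if out.ndim else float(out)


def fraction_of_max_at_age(dw_at_age: float, dw_max: float) -> float:
    """Fraction of the maximum disc width attained, ``dw_at_age / dw_max``."""
    if not (0 < dw_at_age <= dw_max):
        raise ValueError(
            f"require 0 < dw_at_age <= dw_max, got {dw_at_age} vs {dw_max}"
        )
    return dw_at_age / dw_max


def _as_arrays(data: Sequence[SizeAtAgeObservation]) -> tuple[np.ndarray, np.ndarray]:
    ages = np.array([o.age for o in data], dtype=float)
    dws = np.array([o.dw for o in data], dtype=float)
    return ages, dws


def log_likelihood(
    params: GrowthParams, data: Sequence[SizeAtAgeObservation]
) -> tuple[float, np.ndarray]:
    """Gaussian log-likelihood of observed disc widths around the growth curve.

    Returns ``(total, pointwise)`` where ``pointwise[i]`` is the log-density of
    observation ``i`` and ``total`` is their sum.  The pointwise vector is what
    leave-one-out cross-validation consumes.
    """
    if len(data) == 0:
        raise ValueError("log_likelihood requires at least one observation")
    ages, dws = _as_arrays(data)
    mu = predict_dw(params, ages)
    pointwise = stats.norm.logpdf(dws, loc=mu, scale=params.sigma)
    return float(pointwise.sum()), pointwise


# ---------------------------------------------------------------------------
# Bayesian fit of one family


def default_growth_priors():
    """Weakly-informative priors centred on the literature sizes for the species.

    DW_birth ~ lognormal(log 10, 1); DW_inf ~ lognormal(log 34, 1);
    k ~ lognormal(-1, 1) (a normal(-1, 1) prior on log k, keeping k positive);
    sigma ~ half-normal(0, 5 cm).
    """
    from .inference import Prior, PriorSpec

    return PriorSpec(
        {
            "dw_inf": Prior("lognormal", np.log(34.0), 1.0),
            "dw_birth": Prior("lognormal", np.log(10.0), 1.0),
            "k": Prior("lognormal", -1.0, 1.0),
            "sigma": Prior("half_normal", 0.0, 5.0),
        }
    )


@dataclass
class GrowthFit:
    """Posterior fit of one growth family."""

    family: GrowthFamily
    draws: "object"  # inference.PosteriorDraws
    summary: "object"  # inference.FitSummary (DataFrame-backed)
    pointwise_loglik: np.ndarray  # (chains, draws, n_obs)
    n_obs: int

    @property
    def median_params(self) -> GrowthParams:
        med = self.summary.table["median"]
        return GrowthParams(
            family=self.family,
            dw_inf=med["dw_inf"],
            dw_birth=med["dw_birth"],
            k=med["k"],
            sigma=med["sigma"],
        )


def fit_growth(
    data: Sequence[SizeAtAgeObservation],
    family: GrowthFamily | str,
    config=None,
    priors=None,
) -> GrowthFit:
    """Fit one growth family by MCMC.

    All four parameters are positive and are sampled on the log scale with the
    Jacobian correction; draws with ``dw_inf <= dw_birth`` are excluded by the
    posterior (log-density ``-inf``).
    """
    from .inference import MCMCConfig, sample_posterior, summarize

    family = GrowthFamily(family)
    if config is None:
        config = MCMCConfig()
    if priors is None:
        priors = default_growth_priors()
    if len(data) == 0:
        raise ValueError("fit_growth requires data")

    ages, dws = _as_arrays(data)
    names = ["dw_inf", "dw_birth", "k", "sigma"]
    prior_list = [priors[n] for n in names]

    def log_post(theta: np.ndarray) -> float:
        # theta holds log-parameters
        winf, wb, k, sigma = np.exp(theta)
        if not winf > wb:
            return -np.inf
        lp = sum(p.logpdf(v) for p, v in zip(prior_list, (winf, wb, k, sigma)))
        lp += theta.sum()  # Jacobian of the log transform
        if not np.isfinite(lp):
            return -np.inf
        if family is GrowthFamily.LOGISTIC:
            mu = winf / (1.0 + ((winf - wb) / wb) * np.exp(-k * ages))
        elif family is GrowthFamily.GOMPERTZ:
            mu = wb * np.exp(np.log(winf / wb) * (1.0 - np.exp(-k * ages)))
        else:
            mu = wb + (winf - wb) * (1.0 - np.exp(-k * ages))
        resid = dws - mu
        ll = -0.5 * np.sum(resid * resid) / (sigma * sigma)
        ll -= len(dws) * (np.log(sigma) + 0.5 * np.log(2.0 * np.pi))
        return lp + ll

    init = np.log([34.0, 12.0, 0.3, 2.0])
    draws = sample_posterior(
        log_post,
        init,
        config,
        names=[f"log_{n}" for n in names],
        init_scales=[0.2, 0.05, 0.3, 0.2],
    )
    # back-transform to the natural scale for reporting
    natural = draws.transformed(np.exp, names=names)
    summary = summarize(natural)

    arr = natural.array  # (chains, draws, 4)
    winf, wb, k, sigma = (arr[..., i] for i in range(4))
    if family is GrowthFamily.LOGISTIC:
        mu = winf[..., None] / (
            1.0
            + ((winf - wb) / wb)[..., None] * np.exp(-k[..., None] * ages[None, None, :])
        )
    elif family is GrowthFamily.GOMPERTZ:
        mu = wb[..., None] * np.exp(
            np.log(winf / wb)[..., None] * (1.0 - np.exp(-k[..., None] * ages[None, None, :]))
        )
    else:
        mu = wb[..., None] + (winf - wb)[..., None] * (
            1.0 - np.exp(-k[..., None] * ages[None, None, :])
        )
    s = sigma[..., None]
    pw = -0.5 * ((dws[None, None, :] - mu) / s) ** 2 - np.log(s) - 0.5 * np.log(2 * np.pi)

    return GrowthFit(
        family=family,
        draws=natural,
        summary=summary,
        pointwise_loglik=pw,
        n_obs=len(data),
    )
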