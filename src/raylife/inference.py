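"""Seeded adaptive random-walk Metropolis sampler and MCMC diagnostics.

The sampler runs independent chains of Gaussian random-walk Metropolis with a
covariance proposal adapted during warm-up only: the global step scale chases
an acceptance rate of ~0.3 and the proposal covariance is refreshed from the
accumulated warm-up draws (Haario-style adaptive Metropolis).  After warm-up
the proposal is frozen, so the retained chain is a genuine Markov chain.
Everything is deterministic given the seed.

Convergence diagnostics (split R-hat, autocorrelation-based effective sample
size) are delegated to ArviZ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Prior",
    "PriorSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "FitSummary",
    "SamplerError",
    "sample_posterior",
    "rhat",
    "ess",
    "summarize",
]

_PRIOR_FAMILIES = ("lognormal", "normal", "half_normal")
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class SamplerError(RuntimeError):
    """The sampler failed in a way that makes its output unusable."""


@dataclass(frozen=True)
class Prior:
    """One univariate prior: family, location and scale.

    ``lognormal(location, scale)`` places a normal(location, scale) on the log
    of the parameter; ``half_normal(location, scale)`` is a normal folded at
    ``location`` (support ``x >= location``).
    """

    family: str
    location: float
    scale: float

    def __post_init__(self) -> None:
        if self.family not in _PRIOR_FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}")
        if not self.scale > 0:
            raise ValueError(f"prior scale must be > 0, got {self.scale}")

    def _dist(self):
        if self.family == "lognormal":
            return stats.lognorm(s=self.scale, scale=np.exp(self.location))
        if self.family == "normal":
            return stats.norm(loc=self.location, scale=self.scale)
        return stats.halfnorm(loc=self.location, scale=self.scale)

    def logpdf(self, x: float) -> float:
        # closed forms: scipy frozen distributions are too slow inside MCMC
        mu, s = self.location, self.scale
        if self.family == "lognormal":
            if x <= 0:
                return -np.inf
            lx = np.log(x)
            return -lx - np.log(s) - _LOG_SQRT_2PI - 0.5 * ((lx - mu) / s) ** 2
        if self.family == "normal":
            return -np.log(s) - _LOG_SQRT_2PI - 0.5 * ((x - mu) / s) ** 2
        if x < mu:
            return -np.inf
        return np.log(2.0) - np.log(s) - _LOG_SQRT_2PI - 0.5 * ((x - mu) / s) ** 2

    def ppf(self, q: float) -> float:
        return float(self._dist().ppf(q))

    def rvs(self, size, rng):
        return self._dist().rvs(size=size, random_state=rng)


class PriorSpec(Mapping):
    """Named collection of :class:`Prior` entries (mapping parameter -> prior)."""

    def __init__(self, priors: Mapping[str, Prior]):
        self._priors = dict(priors)

    def __getitem__(self, name: str) -> Prior:
        return self._priors[name]

    def __iter__(self):
        return iter(self._priors)

    def __len__(self) -> int:
        return len(self._priors)

    def logpdf(self, values: Mapping[str, float]) -> float:
        return sum(self._priors[n].logpdf(v) for n, v in values.items())


@dataclass(frozen=True)
class MCMCConfig:
    """Chain protocol: 4 chains of 3,500 iterations, the first 1,000 warm-up.

    With the defaults each chain retains 2,500 draws, 10,000 in total.
    """

    n_chains: int = 4
    n_iter: int = 3500
    n_warmup: int = 1000
    seed: int = 0
    target_accept: float = 0.3
    adapt_window: int = 50

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains")
        if not 0 < self.n_warmup < self.n_iter:
            raise ValueError("require 0 < n_warmup < n_iter")

    @property
    def n_retained(self) -> int:
        return self.n_iter - self.n_warmup


@dataclass
class PosteriorDraws:
    """Retained draws: array of shape (chains, draws, parameters)."""

    array: np.ndarray
    names: list[str]
    config: MCMCConfig

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=float)
        if self.array.ndim != 3:
            raise ValueError("draws array must be (chains, draws, parameters)")
        if self.array.shape[2] != len(self.names):
            raise ValueError("parameter-name count mismatch")

    @property
    def n_chains(self) -> int:
        return self.array.shape[0]

    @property
    def n_draws(self) -> int:
        return self.array.shape[1]

    def parameter(self, name: str) -> np.ndarray:
        """Draws for one parameter, shape (chains, draws)."""
        return self.array[..., self.names.index(name)]

    def flat(self, name: str) -> np.ndarray:
        return self.parameter(name).reshape(-1)

    def transformed(self, fn, names: list[str] | None = None) -> "PosteriorDraws":
        return PosteriorDraws(fn(self.array), names or self.names, self.config)

    def to_dataset(self):
        return az.convert_to_dataset(
            {n: self.parameter(n) for n in self.names}
        )

    def to_dataframe(self) -> pd.DataFrame:
        """One row per retained draw with a chain column (CSV-friendly)."""
        chains, draws, _ = self.array.shape
        df = pd.DataFrame(
            self.array.reshape(chains * draws, -1), columns=self.names
        )
        df.insert(0, "draw", np.tile(np.arange(draws), chains))
        df.insert(0, "chain", np.repeat(np.arange(chains), draws))
        return df


@dataclass
class FitSummary:
    """Per-parameter posterior medians, 95% credible intervals and diagnostics."""

    table: pd.DataFrame  # index: parameter; columns: median, ci_low, ci_high, rhat, ess

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _run_chain(
    log_posterior: Callable[[np.ndarray], float],
    init: np.ndarray,
    config: MCMCConfig,
    rng: np.random.Generator,
    init_chol: np.ndarray | None = None,
) -> np.ndarray:
    d = init.size
    x = init.astype(float).copy()
    lp = float(log_posterior(x))
    if not np.isfinite(lp):
        raise SamplerError("log_posterior is not finite at the initial point")

    scale = 2.38 / np.sqrt(d)
    chol = np.eye(d) if init_chol is None else init_chol.copy()
    warm = np.empty((config.n_warmup, d))
    out = np.empty((config.n_retained, d))
    accepted_warmup = 0
    window_acc = 0
    # covariance adaptation starts once the transient has likely decayed
    cov_start = config.n_warmup // 2
    discard = config.n_warmup // 4

    for i in range(config.n_iter):
        warmup = i < config.n_warmup
        z = rng.standard_normal(d)
        prop = x + scale * (chol @ z)
        lp_prop = float(log_posterior(prop))
        if np.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            window_acc += 1
            if warmup:
                accepted_warmup += 1
        if warmup:
            warm[i] = x
            if (i + 1) % config.adapt_window == 0:
                rate = window_acc / config.adapt_window
                scale *= np.exp(rate - config.target_accept)
                window_acc = 0
                if d > 1 and i + 1 >= cov_start:
                    hist = warm[discard : i + 1]
                    cov = np.cov(hist.T) + 1e-10 * np.eye(d)
                    try:
                        new_chol = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        new_chol = None
                    if new_chol is not None:
                        if i + 1 == ((cov_start // config.adapt_window) + 1) * config.adapt_window:
                            scale = 2.38 / np.sqrt(d)  # re-baseline for the new shape
                        chol = new_chol
            if i == config.n_warmup - 1:
                if accepted_warmup == 0:
                    raise SamplerError(
                        "no proposal accepted during warm-up; "
                        "check the posterior or the initial point"
                    )
                window_acc = 0
        else:
            out[i - config.n_warmup] = x
    return out


def sample_posterior(
    log_posterior: Callable[[np.ndarray], float],
    init: Sequence[float],
    config: MCMCConfig,
    names: list[str] | None = None,
    init_scales: Sequence[float] | None = None,
) -> PosteriorDraws:
    """Run ``config.n_chains`` adaptive random-walk Metropolis chains.

    ``log_posterior`` maps a parameter vector to a log-density (``-inf``
    allowed outside the support, NaN rejected at the start).  ``init_scales``
    optionally sets the starting per-parameter proposal scales (before
    covariance adaptation takes over).  Warm-up draws are discarded; draws are
    bit-reproducible for a given config (chain seeds are spawned from
    ``config.seed``).
    """
    init = np.atleast_1d(np.asarray(init, dtype=float))
    lp0 = float(log_posterior(init))
    if np.isnan(lp0):
        raise SamplerError("log_posterior returned NaN at the initial point")
    if not np.isfinite(lp0):
        raise SamplerError("log_posterior is not finite at the initial point")
    names = names or [f"theta_{i}" for i in range(init.size)]
    init_chol = None
    if init_scales is not None:
        init_chol = np.diag(np.asarray(init_scales, dtype=float))

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [
        _run_chain(log_posterior, init, config, np.random.default_rng(s), init_chol)
        for s in seeds
    ]
    return PosteriorDraws(np.stack(chains), list(names), config)


def _chain_matrix(draws: PosteriorDraws | np.ndarray, parameter=None) -> np.ndarray:
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required")
        return draws.parameter(parameter)
    return np.asarray(draws, dtype=float)


def rhat(draws: PosteriorDraws | np.ndarray, parameter: str | None = None) -> float:
    """Split-chain Gelman–Rubin R-hat (each chain halved before comparison).

    Values near 1 indicate the chains agree; > 1.01 is conventionally taken as
    lack of convergence.  Constant chains yield NaN with a warning.
    """
    m = _chain_matrix(draws, parameter)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 4:
        raise ValueError("rhat needs >= 2 chains and >= 4 draws per chain")
    if np.allclose(m, m.flat[0]):
        warnings.warn("constant chains: R-hat is undefined", RuntimeWarning)
        return float("nan")
    return float(az.rhat(az.convert_to_dataset({"x": m}), method="split")["x"].item())


def ess(draws: PosteriorDraws | np.ndarray, parameter: str | None = None) -> float:
    """Autocorrelation-based effective sample size, pooled over chains."""
    m = _chain_matrix(draws, parameter)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 4:
        raise ValueError("ess needs >= 2 chains and >= 4 draws per chain")
    if np.allclose(m, m.flat[0]):
        warnings.warn("constant chains: ESS is minimal", RuntimeWarning)
        return 1.0
    val = float(az.ess(az.convert_to_dataset({"x": m}), method="mean")["x"].item())
    return min(val, float(m.size))  # capped: ESS cannot exceed the draw count


def summarize(draws: PosteriorDraws) -> FitSummary:
    """Posterior medians, equal-tailed 95% credible intervals, R-hat and ESS."""
    rows = {}
    for name in draws.names:
        m = draws.parameter(name)
        flat = m.reshape(-1)
        lo, med, hi = np.quantile(flat, [0.025, 0.5, 0.975])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows[name] = {
                "median": med,
                "ci_low": lo,
                "ci_high": hi,
                "rhat": rhat(m),
                "ess": ess(m),
            }
    return FitSummary(pd.DataFrame.from_dict(rows, orient="index"))
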