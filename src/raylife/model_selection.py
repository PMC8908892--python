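"""PSIS-LOO cross-validation and LOOIC-based comparison of growth fits.

Predictive performance is estimated by Pareto-smoothed importance-sampling
leave-one-out cross-validation (PSIS-LOO) on the pointwise log-likelihood
matrix retained from the fit, reported on the LOOIC (deviance) scale,
``LOOIC = -2 * elpd_loo``.  Fits whose LOOIC values differ by less than two
are treated as indistinguishable in predictive ability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

__all__ = ["LooResult", "ComparisonResult", "psis_loo", "psis_log_weights", "compare"]

#: |ΔLOOIC| below which two models are considered indistinguishable.
LOOIC_EQUIVALENCE = 2.0


@dataclass
class LooResult:
    """PSIS-LOO estimate for one model.

    ``se`` is the standard error of LOOIC (twice the elpd standard error,
    ``2 * sqrt(n * var(pointwise elpd))``).  ``pareto_k`` holds the per-
    observation generalized-Pareto shape diagnostics; values above 0.7 mark
    unreliable importance weights.
    """

    elpd_loo: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    n_obs: int

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd_loo

    @property
    def n_high_k(self) -> int:
        return int(np.sum(self.pareto_k > 0.7))

    @classmethod
    def from_looic(cls, looic: float, n_obs: int, se: float = np.nan) -> "LooResult":
        """Wrap an externally reported LOOIC value (no pointwise detail)."""
        return cls(
            elpd_loo=-0.5 * looic,
            se=se,
            pointwise=np.full(n_obs, np.nan),
            pareto_k=np.full(n_obs, np.nan),
            n_obs=n_obs,
        )


def psis_loo(pointwise_loglik: np.ndarray) -> LooResult:
    """PSIS-LOO from a pointwise log-likelihood array.

    Parameters
    ----------
    pointwise_loglik : ndarray
        ``(chains, draws, observations)`` or ``(draws, observations)`` array of
        per-draw, per-observation log-likelihoods.

    Raises on non-finite entries; warns below 100 total draws, where the
    Pareto smoothing of the importance weights is unreliable.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 2:
        ll = ll[None, ...]
    if ll.ndim != 3:
        raise ValueError("expected (chains, draws, observations) log-likelihoods")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihoods must be finite")
    n_chains, n_draws, n_obs = ll.shape
    if n_chains * n_draws < 100:
        warnings.warn(
            f"only {n_chains * n_draws} draws: PSIS-LOO is unreliable below 100",
            RuntimeWarning,
        )
    idata = az.from_dict(
        posterior={"_dummy": np.zeros((n_chains, n_draws))},
        log_likelihood={"y": ll},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = az.loo(idata, pointwise=True)
    pointwise = np.asarray(res.loo_i.values, dtype=float)
    return LooResult(
        elpd_loo=float(res.elpd_loo),
        se=2.0 * float(res.se),
        pointwise=pointwise,
        pareto_k=np.asarray(res.pareto_k.values, dtype=float),
        n_obs=n_obs,
    )


def psis_log_weights(log_ratios: np.ndarray) -> tuple[np.ndarray, float]:
    """Pareto-smoothed, self-normalized log importance weights for one observation.

    Returns ``(log_weights, pareto_k)``; ``exp(log_weights)`` sums to 1.
    """
    lw, k = az.psislw(np.asarray(log_ratios, dtype=float))
    return np.asarray(lw), float(k)


@dataclass
class ComparisonResult:
    """LOOIC ranking of several models fitted to the same observations."""

    table: pd.DataFrame  # sorted ascending by looic; columns looic, se, delta_looic
    indistinguishable: bool

    @property
    def best(self) -> str:
        return str(self.table.index[0])

    def pairwise_deltas(self) -> pd.DataFrame:
        looic = self.table["looic"]
        return pd.DataFrame(
            np.abs(looic.values[:, None] - looic.values[None, :]),
            index=looic.index,
            columns=looic.index,
        )


def compare(results: dict[str, LooResult]) -> ComparisonResult:
    """Rank models by LOOIC (ascending) and flag practical equivalence.

    All results must come from the same observation set; the flag is set when
    every pairwise |ΔLOOIC| is below 2.
    """
    if len(results) < 2:
        raise ValueError("compare needs at least two models")
    ns = {r.n_obs for r in results.values()}
    if len(ns) != 1:
        raise ValueError(f"models were fitted to different observation counts: {ns}")
    tab = pd.DataFrame(
        {
            "n": [r.n_obs for r in results.values()],
            "looic": [r.looic for r in results.values()],
            "se": [r.se for r in results.values()],
        },
        index=list(results),
    ).sort_values("looic", kind="stable")
    tab["delta_looic"] = tab["looic"] - tab["looic"].iloc[0]
    max_delta = float(tab["looic"].max() - tab["looic"].min())
    return ComparisonResult(table=tab, indistinguishable=max_delta < LOOIC_EQUIVALENCE)
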