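"""Stomach-content analysis: life stages, Index of Importance, PERMANOVA.

Diet is quantified over six fixed prey groups.  For each prey group ``a``
within a life stage,

    %W_a = (100 * W_a) / W_body       per stomach, then averaged over the
                                      stomachs with food (configurable to a
                                      pooled mass ratio),
    %F_a = (100 * S_a) / S            with S the stomachs containing food,
    HI_a = %F_a + %W_a,
    IOI_a = 100 * HI_a / sum(HI),

so the Index of Importance is a percentage that sums to 100 over prey groups
within a stratum.  Composition differences among life stages are tested with
PERMANOVA on Bray–Curtis dissimilarities of per-stomach mass proportions,
with seeded label permutations, plus pairwise tests with Holm adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PREY_GROUPS",
    "LIFE_STAGES",
    "StomachSample",
    "PermanovaResult",
    "classify_life_stage",
    "pct_weight",
    "pct_freq",
    "ioi",
    "composition_matrix",
    "bray_curtis",
    "permanova",
    "pairwise_permanova",
]

PREY_GROUPS = (
    "crustaceans",
    "polychaetes",
    "bivalves",
    "other_molluscs",
    "teleosts",
    "unidentified",
)
LIFE_STAGES = ("YOY", "juvenile", "adult")


@dataclass(frozen=True)
class StomachSample:
    """Stomach contents of one specimen over the six fixed prey groups."""

    specimen_id: str
    life_stage: str
    body_mass: float  # g
    masses: Mapping[str, float]  # g per prey group
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.life_stage not in LIFE_STAGES:
            raise ValueError(f"unknown life stage {self.life_stage!r}")
        if not self.body_mass > 0:
            raise ValueError("body mass must be > 0")
        unknown = set(self.masses) - set(PREY_GROUPS)
        unknown |= set(self.counts) - set(PREY_GROUPS)
        if unknown:
            raise ValueError(f"unknown prey groups: {sorted(unknown)}")
        for g, m in self.masses.items():
            if m < 0:
                raise ValueError(f"negative mass for {g}")
        for g, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"count for {g} must be a non-negative integer")

    def mass(self, group: str) -> float:
        return float(self.masses.get(group, 0.0))

    @property
    def total_mass(self) -> float:
        return float(sum(self.masses.get(g, 0.0) for g in PREY_GROUPS))

    @property
    def has_food(self) -> bool:
        return self.total_mass > 0


def classify_life_stage(age, dw: float, mature: int, dw50: float) -> str:
    """Life stage from age, size and maturity.

    Young-of-the-year are individuals aged under one year (band count 0);
    adults are mature individuals at or above the median size-at-maturity;
    everything else is juvenile.  A missing age is treated as >= 1 year (an
    unaged specimen cannot be assigned to the YOY class).
    """
    if age is not None and not (isinstance(age, float) and np.isnan(age)):
        if age < 0:
            raise ValueError("age must be >= 0")
        if age < 1:
            return "YOY"
    if mature and dw >= dw50:
        return "adult"
    return "juvenile"


def pct_weight(mass_of_group: float, body_mass: float) -> float:
    """Prey-group mass as a percentage of the predator's body mass."""
    if not body_mass > 0:
        raise ValueError("body mass must be > 0")
    if mass_of_group < 0:
        raise ValueError("prey mass must be >= 0")
    return 100.0 * mass_of_group / body_mass


def pct_freq(n_stomachs_with_group: int, n_stomachs_with_food: int) -> float:
    """Frequency of occurrence (%): stomachs containing the group over stomachs with food."""
    if n_stomachs_with_food <= 0:
        raise ValueError("need at least one stomach containing food")
    if not 0 <= n_stomachs_with_group <= n_stomachs_with_food:
        raise ValueError("occurrence count out of range")
    return 100.0 * n_stomachs_with_group / n_stomachs_with_food


def _ioi_one_stratum(stomachs: Sequence[StomachSample], weight_method: str) -> pd.DataFrame:
    fed = [s for s in stomachs if s.has_food]
    s_total = len(fed)
    rows = {}
    for g in PREY_GROUPS:
        occurrences = sum(1 for s in fed if s.mass(g) > 0)
        fa = pct_freq(occurrences, s_total)
        if weight_method == "mean_individual":
            wa = float(np.mean([pct_weight(s.mass(g), s.body_mass) for s in fed]))
        elif weight_method == "pooled":
            wa = pct_weight(sum(s.mass(g) for s in fed), sum(s.body_mass for s in fed))
        else:
            raise ValueError(f"unknown %W aggregation {weight_method!r}")
        rows[g] = {"pct_weight": wa, "pct_freq": fa, "hi": wa + fa}
    tab = pd.DataFrame.from_dict(rows, orient="index")
    hi_sum = tab["hi"].sum()
    tab["ioi"] = 0.0 if hi_sum == 0 else 100.0 * tab["hi"] / hi_sum
    return tab


def ioi(
    stomachs: Sequence[StomachSample],
    stratify_by_life_stage: bool = True,
    weight_method: str = "mean_individual",
) -> pd.DataFrame:
    """Index of Importance per prey group, optionally per life stage.

    Returns a DataFrame indexed by (life_stage, prey_group) when stratified,
    else by prey_group, with columns ``pct_weight``, ``pct_freq``, ``hi`` and
    ``ioi``.  ``ioi`` sums to 100 within each stratum.  A stratum whose
    stomachs are all empty is skipped with a warning.
    """
    if not stratify_by_life_stage:
        if not any(s.has_food for s in stomachs):
            raise ValueError("no stomach contains food")
        return _ioi_one_stratum(stomachs, weight_method)
    pieces = {}
    for stage in LIFE_STAGES:
        sub = [s for s in stomachs if s.life_stage == stage]
        if not sub:
            continue
        if not any(s.has_food for s in sub):
            warnings.warn(
                f"all {stage} stomachs are empty; stratum skipped", RuntimeWarning
            )
            continue
        pieces[stage] = _ioi_one_stratum(sub, weight_method)
    if not pieces:
        raise ValueError("no stratum contains food")
    out = pd.concat(pieces, names=["life_stage", "prey_group"])
    return out


def composition_matrix(
    stomachs: Sequence[StomachSample], response: str = "mass"
) -> pd.DataFrame:
    """Per-stomach prey composition: rows are specimens, columns prey groups.

    ``response`` is ``"mass"`` (proportions of content mass, rows sum to 1),
    ``"count"`` (proportions of item counts) or ``"presence"`` (0/1).  Empty
    stomachs are excluded.
    """
    rows = {}
    for s in stomachs:
        if response == "mass":
            v = np.array([s.mass(g) for g in PREY_GROUPS])
        elif response == "count":
            v = np.array([float(s.counts.get(g, 0)) for g in PREY_GROUPS])
        elif response == "presence":
            v = np.array([float(s.mass(g) > 0) for g in PREY_GROUPS])
        else:
            raise ValueError(f"unknown response {response!r}")
        tot = v.sum()
        if tot == 0:
            continue
        rows[s.specimen_id] = v / tot if response != "presence" else v
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(PREY_GROUPS))


def bray_curtis(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Bray–Curtis dissimilarity, ``1 - 2*sum(min)/sum(total)``."""
    x = np.asarray(matrix, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    return squareform(pdist(x, metric="braycurtis"))


@dataclass
class PermanovaResult:
    """One permutational multivariate ANOVA on a distance matrix."""

    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ss_total: float
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int


def _permanova_stats(
    d2: np.ndarray, codes: np.ndarray, n_groups: int, ss_total: float
) -> tuple[float, float, float]:
    """(SS_between, SS_within, F) from squared distances and group codes.

    SS_total = sum of squared distances over pairs / n; SS_within sums, per
    group, the within-group squared distances over the group size.
    """
    n = d2.shape[0]
    onehot = np.zeros((n, n_groups))
    onehot[np.arange(n), codes] = 1.0
    counts = onehot.sum(axis=0)
    within_pairs = np.einsum("ig,ij,jg->g", onehot, d2, onehot) / 2.0
    ss_within = float((within_pairs / counts).sum())
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return ss_between, ss_within, f


def permanova(
    dist: np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """PERMANOVA pseudo-F with a seeded permutation p-value.

    The total sum of squared distances is partitioned into within- and
    between-group components (one-way design); significance comes from
    ``n_perm`` random label permutations,
    ``p = (#{F_perm >= F_obs} + 1) / (n_perm + 1)``, so the smallest
    attainable p-value is ``1 / (n_perm + 1)``.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(groups)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("dist must be a symmetric square matrix")
    if len(labels) != n:
        raise ValueError("group labels must match the distance matrix")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every group needs at least two members")

    d2 = d * d
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ssb, ssw, f_obs = _permanova_stats(d2, codes, len(uniq), ss_total)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        _, _, f_perm = _permanova_stats(d2, perm, len(uniq), ss_total)
        if f_perm >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermanovaResult(
        df_between=len(uniq) - 1,
        df_within=n - len(uniq),
        ss_between=ssb,
        ss_within=ssw,
        ss_total=ss_total,
        pseudo_f=f_obs,
        r_squared=ssb / ss_total,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
    )


def pairwise_permanova(
    dist: np.ndarray,
    groups: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """PERMANOVA on every group pair, with raw and Holm-adjusted p-values.

    Pairs are ordered lexicographically; each pair's test runs on the
    sub-matrix of its members with its own derived seed.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(groups)
    uniq = sorted(np.unique(labels).tolist())
    rows = []
    for i, (g1, g2) in enumerate(itertools.combinations(uniq, 2)):
        idx = np.flatnonzero((labels == g1) | (labels == g2))
        res = permanova(d[np.ix_(idx, idx)], labels[idx], n_perm=n_perm, seed=seed + i)
        rows.append(
            {
                "group_1": g1,
                "group_2": g2,
                "pseudo_f": res.pseudo_f,
                "r_squared": res.r_squared,
                "p_value": res.p_value,
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
    return out
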