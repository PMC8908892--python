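"""CSV readers, analysis configuration and the end-to-end pipeline.

The interchange format is plain CSV (UTF-8, header row, decimal point): a
specimen table (one row per fish) and a long-format stomach table (one row per
specimen × prey group).  ``run_pipeline`` chains the full analysis — growth
fits for the three families, LOOIC comparison, maturity ogives per stratum,
age-at-maturity, life-stage classification, Index of Importance and PERMANOVA
— and writes one CSV per stage plus a JSON run log carrying the seed, the
config hash and convergence diagnostics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diet import (
    PREY_GROUPS,
    StomachSample,
    bray_curtis,
    classify_life_stage,
    composition_matrix,
    ioi,
    pairwise_permanova,
    permanova,
)
from .growth import GrowthFamily, GrowthParams, SizeAtAgeObservation, fit_growth
from .inference import MCMCConfig
from .maturity import MaturityObservation, age_at_maturity, fit_maturity_by_sex
from .model_selection import LooResult, compare, psis_loo

logger = logging.getLogger("raylife")

__all__ = [
    "SpecimenRecord",
    "SpecimenValidationError",
    "AnalysisConfig",
    "read_specimens",
    "read_stomachs",
    "run_pipeline",
]

_SEXES = {"M", "F", "U"}
_MATURITY = {"immature", "mature", "unknown"}
_SPECIMEN_COLUMNS = [
    "specimen_id",
    "sex",
    "dw_cm",
    "tl_cm",
    "mass_g",
    "age_years",
    "maturity",
    "location",
]


@dataclass(frozen=True)
class SpecimenRecord:
    """One fish as read from the specimen table."""

    specimen_id: str
    sex: str
    dw_cm: float
    tl_cm: float | None
    mass_g: float
    age_years: int | None  # None when the vertebral readings disagreed
    maturity: str  # immature / mature / unknown
    location: str


class SpecimenValidationError(ValueError):
    """Row-level validation failures, each tagged with its CSV line number."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid specimen rows:\n" + "\n".join(errors))


def read_specimens(path) -> list[SpecimenRecord]:
    """Read and validate the specimen CSV.

    Records with a missing age are kept (they are excluded from the growth fit
    downstream); records failing validation are collected and reported
    together with their line numbers.
    """
    df = pd.read_csv(path)
    if "maturity" not in df.columns:
        warnings.warn(
            "specimen CSV has no maturity column; all records treated as unknown "
            "(maturity and diet stages will be skipped)",
            RuntimeWarning,
        )
        df["maturity"] = "unknown"
    missing = [c for c in _SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise SpecimenValidationError([f"missing columns: {missing}"])
    errors: list[str] = []
    records: list[SpecimenRecord] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        problems = []
        if not row["dw_cm"] > 0:
            problems.append(f"dw_cm must be > 0 (got {row['dw_cm']})")
        if not row["mass_g"] > 0:
            problems.append(f"mass_g must be > 0 (got {row['mass_g']})")
        if row["sex"] not in _SEXES:
            problems.append(f"sex must be one of {sorted(_SEXES)} (got {row['sex']!r})")
        if row["maturity"] not in _MATURITY:
            problems.append(
                f"maturity must be one of {sorted(_MATURITY)} (got {row['maturity']!r})"
            )
        age = row["age_years"]
        if pd.isna(age):
            age = None
        elif float(age) < 0 or float(age) != int(age):
            problems.append(f"age_years must be a non-negative integer (got {age})")
        else:
            age = int(age)
        if problems:
            errors.extend(f"line {line}: {p}" for p in problems)
            continue
        records.append(
            SpecimenRecord(
                specimen_id=str(row["specimen_id"]),
                sex=str(row["sex"]),
                dw_cm=float(row["dw_cm"]),
                tl_cm=None if pd.isna(row["tl_cm"]) else float(row["tl_cm"]),
                mass_g=float(row["mass_g"]),
                age_years=age,
                maturity=str(row["maturity"]),
                location=str(row["location"]),
            )
        )
    if errors:
        raise SpecimenValidationError(errors)
    return records


def read_stomachs(path, specimens: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Read the long-format stomach CSV and pivot to one row per specimen.

    Unknown prey-group names are an error; specimens without stomach rows are
    omitted.  Returns a wide DataFrame with ``mass_<group>`` and
    ``count_<group>`` columns, indexed by specimen_id.
    """
    df = pd.read_csv(path)
    needed = {"specimen_id", "prey_group", "mass_g", "count"}
    if not needed <= set(df.columns):
        raise ValueError(f"stomach CSV needs columns {sorted(needed)}")
    unknown = set(df["prey_group"]) - set(PREY_GROUPS)
    if unknown:
        raise ValueError(f"unknown prey groups in stomach CSV: {sorted(unknown)}")
    df["specimen_id"] = df["specimen_id"].astype(str)
    known_ids = {s.specimen_id for s in specimens}
    df = df[df["specimen_id"].isin(known_ids)]
    mass = df.pivot_table(
        index="specimen_id", columns="prey_group", values="mass_g", aggfunc="sum", fill_value=0.0
    ).reindex(columns=list(PREY_GROUPS), fill_value=0.0)
    count = df.pivot_table(
        index="specimen_id", columns="prey_group", values="count", aggfunc="sum", fill_value=0
    ).reindex(columns=list(PREY_GROUPS), fill_value=0)
    wide = pd.concat(
        {"mass": mass, "count": count}, axis=1
    )
    wide.columns = [f"{a}_{g}" for a, g in wide.columns]
    return wide


@dataclass
class AnalysisConfig:
    """Everything one pipeline run needs; the seed is mandatory."""

    specimens_csv: str
    stomachs_csv: str | None = None
    output_dir: str = "raylife_out"
    seed: int = 0
    n_chains: int = 4
    n_iter: int = 3500
    n_warmup: int = 1000
    diet_response: str = "mass"
    diet_distance: str = "bray_curtis"
    n_perm: int = 999
    pct_weight_method: str = "mean_individual"

    _KNOWN = None  # filled below

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cls(**raw)

    def mcmc(self, seed_offset: int = 0) -> MCMCConfig:
        return MCMCConfig(
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            n_warmup=self.n_warmup,
            seed=self.seed + seed_offset,
        )

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")  # where results land does not alter them
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _growth_observations(specimens: Sequence[SpecimenRecord]) -> list[SizeAtAgeObservation]:
    return [
        SizeAtAgeObservation(s.specimen_id, float(s.age_years), s.dw_cm)
        for s in specimens
        if s.age_years is not None
    ]


def _maturity_observations(specimens: Sequence[SpecimenRecord]) -> list[MaturityObservation]:
    return [
        MaturityObservation(s.specimen_id, s.dw_cm, s.sex, 1 if s.maturity == "mature" else 0)
        for s in specimens
        if s.maturity in ("immature", "mature")
    ]


def _stomach_samples(
    specimens: Sequence[SpecimenRecord], wide: pd.DataFrame, dw50_by_sex: dict[str, float]
) -> list[StomachSample]:
    by_id = {s.specimen_id: s for s in specimens}
    out = []
    for sid, row in wide.iterrows():
        s = by_id[sid]
        stage = classify_life_stage(
            s.age_years,
            s.dw_cm,
            1 if s.maturity == "mature" else 0,
            dw50_by_sex.get(s.sex, dw50_by_sex["combined"]),
        )
        out.append(
            StomachSample(
                specimen_id=sid,
                life_stage=stage,
                body_mass=s.mass_g,
                masses={g: float(row[f"mass_{g}"]) for g in PREY_GROUPS},
                counts={g: int(row[f"count_{g}"]) for g in PREY_GROUPS},
            )
        )
    return out


def _stage_tag(df: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.digest()
    df["seed"] = config.seed
    return df


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis and write per-stage CSVs plus a run log.

    Stages that cannot run (no stomach table, single-class maturity data) are
    skipped with a warning; growth always runs.  Reruns with the same config
    produce identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    specimens = read_specimens(config.specimens_csv)
    results: dict = {"config_hash": config.digest(), "seed": config.seed}
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": dataclasses.asdict(config),
        "n_specimens": len(specimens),
        "stages": {},
    }

    # --- growth: three families + LOOIC comparison -------------------------
    obs = _growth_observations(specimens)
    if not obs:
        raise ValueError("growth stage: no aged specimens")
    fits = {}
    loos = {}
    rows = {}
    for j, fam in enumerate(GrowthFamily):
        fit = fit_growth(obs, fam, config=config.mcmc(seed_offset=j))
        fits[fam.value] = fit
        loos[fam.value] = psis_loo(fit.pointwise_loglik)
        t = fit.summary.table
        rows[fam.value] = {
            "n": fit.n_obs,
            "looic": loos[fam.value].looic,
            "looic_se": loos[fam.value].se,
            **{
                f"{p}{suffix}": t.loc[p, col]
                for p in ("dw_inf", "dw_birth", "k", "sigma")
                for suffix, col in (("", "median"), ("_ci_low", "ci_low"), ("_ci_high", "ci_high"))
            },
            "min_ess": t["ess"].min(),
            "max_rhat": t["rhat"].max(),
        }
    growth_table = pd.DataFrame.from_dict(rows, orient="index").sort_values("looic")
    comparison = compare(loos)
    growth_table["delta_looic"] = comparison.table["delta_looic"]
    _stage_tag(growth_table, config).to_csv(out / "growth_fits.csv", index_label="model")
    results["growth"] = fits
    results["comparison"] = comparison
    log["stages"]["growth"] = {
        "n": len(obs),
        "indistinguishable": comparison.indistinguishable,
        "best": comparison.best,
        "max_rhat": float(growth_table["max_rhat"].max()),
        "min_ess": float(growth_table["min_ess"].min()),
    }

    # --- maturity ----------------------------------------------------------
    mat_obs = _maturity_observations(specimens)
    dw50_by_sex: dict[str, float] = {}
    classes = {o.mature for o in mat_obs}
    if len(classes) < 2:
        warnings.warn("maturity stage skipped: need both classes", RuntimeWarning)
        log["stages"]["maturity"] = {"skipped": True}
    else:
        mat_table = fit_maturity_by_sex(mat_obs, config.mcmc(seed_offset=10))
        # age-at-maturity from the selected (lowest-LOOIC) growth fit
        best_fit = fits[comparison.best].median_params
        ages_at_mat = {}
        for stratum, row in mat_table.iterrows():
            try:
                ages_at_mat[stratum] = age_at_maturity(best_fit, row["dw50"])
            except ValueError:
                ages_at_mat[stratum] = np.nan
        mat_table["age_at_maturity"] = pd.Series(ages_at_mat)
        _stage_tag(mat_table, config).to_csv(out / "maturity.csv", index_label="stratum")
        results["maturity"] = mat_table
        dw50_by_sex = {
            "M": mat_table.loc["male", "dw50"] if "male" in mat_table.index else np.nan,
            "F": mat_table.loc["female", "dw50"] if "female" in mat_table.index else np.nan,
            "combined": mat_table.loc["combined", "dw50"],
        }
        for k in ("M", "F"):
            if np.isnan(dw50_by_sex[k]):
                dw50_by_sex[k] = dw50_by_sex["combined"]
        log["stages"]["maturity"] = {
            "n": len(mat_obs),
            "dw50": {k: float(v) for k, v in dw50_by_sex.items()},
        }

    # --- diet --------------------------------------------------------------
    if config.stomachs_csv is None or not dw50_by_sex:
        warnings.warn("diet stage skipped", RuntimeWarning)
        log["stages"]["diet"] = {"skipped": True}
    else:
        wide = read_stomachs(config.stomachs_csv, specimens)
        stomachs = _stomach_samples(specimens, wide, dw50_by_sex)
        ioi_table = ioi(stomachs, weight_method=config.pct_weight_method)
        _stage_tag(ioi_table.reset_index(), config).to_csv(out / "ioi.csv", index=False)
        results["ioi"] = ioi_table

        comp = composition_matrix(stomachs, response=config.diet_response)
        if config.diet_distance == "bray_curtis":
            dist = bray_curtis(comp.values)
        elif config.diet_distance == "euclidean":
            from scipy.spatial.distance import pdist, squareform

            dist = squareform(pdist(comp.values))
        else:
            raise ValueError(f"unknown distance {config.diet_distance!r}")
        stage_of = {s.specimen_id: s.life_stage for s in stomachs}
        labels = np.array([stage_of[sid] for sid in comp.index])
        perm = permanova(dist, labels, n_perm=config.n_perm, seed=config.seed)
        pw = pairwise_permanova(dist, labels, n_perm=config.n_perm, seed=config.seed)
        perm_table = pd.DataFrame(
            [
                {
                    "df_between": perm.df_between,
                    "df_within": perm.df_within,
                    "ss_between": perm.ss_between,
                    "pseudo_f": perm.pseudo_f,
                    "r_squared": perm.r_squared,
                    "p_value": perm.p_value,
                    "n_permutations": perm.n_permutations,
                }
            ]
        )
        _stage_tag(perm_table, config).to_csv(out / "permanova.csv", index=False)
        _stage_tag(pw, config).to_csv(out / "permanova_pairwise.csv", index=False)
        results["permanova"] = perm
        results["pairwise"] = pw
        log["stages"]["diet"] = {
            "n_stomachs": len(stomachs),
            "permanova_p": perm.p_value,
            "pseudo_f": perm.pseudo_f,
        }

    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=float)
    results["log"] = log
    return results
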