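"""Mixed-model frames and the term-dropping fitting procedure.

Three model frames correspond to the study's regression analyses:

* yearling body mass (Gaussian) on the inbreeding coefficient F, age at
  measurement, maternal age, group size, litter size and rainfall, with
  social group, breeding attempt, maternal, paternal and individual
  identities as random intercepts;
* survival to one year (binomial-logit) on the same covariates minus age;
* mate-guard paternity success (binomial-logit) on guard-female
  relatedness, male age rank, female age, group sex ratio and guarding
  days, with group, attempt, guard and female random intercepts.

Fitting follows the classical backward-elimination protocol: terms are
sequentially dropped (least significant first, likelihood-ratio chi-square
on ML fits, 1 df) until all remaining terms are significant at P < 0.05;
every eliminated term is then put back into the minimal model individually
to obtain its reported chi-square, P and effect size.

The numerical engine is lme4, driven through an Rscript subprocess; frames
and results cross the boundary as CSV/JSON.
"""

from __future__ import annotations

import json
import logging
import subprocess
import tempfile
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .filters import classify_guard_success, _natal_attempts
from .pedigree import RelatednessMatrix
from .records import StudyDataset

__all__ = [
    "TermResult",
    "ModelFitResult",
    "build_mass_frame",
    "build_survival_frame",
    "build_guard_success_frame",
    "fit_and_simplify",
    "MASS_FIXED_TERMS",
    "SURVIVAL_FIXED_TERMS",
    "GUARD_SUCCESS_FIXED_TERMS",
]

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44
YEARLING_WINDOW = (350, 370)

MASS_FIXED_TERMS = [
    "inbreeding_f",
    "age_days",
    "maternal_age_months",
    "group_size",
    "n_pups",
    "rainfall",
]
MASS_RANDOM = [
    "social_group",
    "breeding_attempt",
    "maternal_id",
    "paternal_id",
    "individual_id",
]
SURVIVAL_FIXED_TERMS = [
    "inbreeding_f",
    "maternal_age_months",
    "group_size",
    "n_pups",
    "rainfall",
]
SURVIVAL_RANDOM = ["social_group", "breeding_attempt", "maternal_id", "paternal_id"]
GUARD_SUCCESS_FIXED_TERMS = [
    "guard_female_r",
    "male_age_rank",
    "female_age_months",
    "sex_ratio_male",
    "n_days_guarding",
]
GUARD_SUCCESS_RANDOM = ["social_group", "breeding_attempt", "guard_id", "female_id"]


@dataclass
class TermResult:
    estimate: float
    se: float
    chisq: float
    p: float
    in_minimal: bool


@dataclass
class ModelFitResult:
    family: str
    terms: dict[str, TermResult]
    minimal_terms: list[str]
    intercept: float
    intercept_se: float
    random_effect_names: list[str]
    n_observations: int
    converged: bool
    singular: bool = False
    replicate: object = None
    error: str | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "family": self.family,
            "n_observations": self.n_observations,
            "converged": self.converged,
            "singular": self.singular,
            "random_effects": self.random_effect_names,
            "minimal_terms": self.minimal_terms,
            "intercept": {"estimate": self.intercept, "se": self.intercept_se},
            "terms": {k: vars(v) for k, v in self.terms.items()},
        }
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


# ---------------------------------------------------------------------- #
# frame builders
# ---------------------------------------------------------------------- #


def _covariate_base(
    ds: StudyDataset,
    inbreeding: pd.DataFrame,
    maternal_age_unit: str = "months",
) -> pd.DataFrame:
    """Per-offspring covariates shared by the mass and survival frames.

    Individuals without confidently assigned parents have no defined F and
    are excluded. Maternal age is at the offspring's birth, in months by
    default (``maternal_age_unit="years"`` switches the scale).
    """
    if maternal_age_unit not in ("months", "years"):
        raise ValueError(f"unknown maternal_age_unit {maternal_age_unit!r}")
    age_div = DAYS_PER_MONTH if maternal_age_unit == "months" else 365.25
    if ds.pedigree is None:
        raise ValueError("dataset has no pedigree")
    ped = ds.pedigree
    birth = {r.individual_id: r.birth_date for r in ped.records}
    f_map = inbreeding.set_index("individual_id")
    p = ds.parentage[ds.parentage["dam_id"].notna() & ds.parentage["sire_id"].notna()]
    att = ds.attempts.set_index("attempt_id")
    rows = []
    for r in p.itertuples(index=False):
        iid = r.offspring_id
        if iid not in f_map.index or not bool(f_map.loc[iid, "parents_known"]):
            continue
        if r.attempt_id not in att.index:
            continue
        a = att.loc[r.attempt_id]
        b_off, b_dam = birth.get(iid), birth.get(r.dam_id)
        maternal_age = (
            (b_off - b_dam).days / age_div
            if (b_off is not None and b_dam is not None)
            else np.nan
        )
        rows.append(
            {
                "individual_id": iid,
                "inbreeding_f": float(f_map.loc[iid, "F"]),
                "maternal_age_months": maternal_age,
                "group_size": a["group_size_adults"],
                "n_pups": a["n_pups_born"],
                "rainfall": a["rainfall_30d"],
                "social_group": a["group_id"],
                "breeding_attempt": r.attempt_id,
                "maternal_id": r.dam_id,
                "paternal_id": r.sire_id,
            }
        )
    return pd.DataFrame(rows)


def _drop_incomplete(frame: pd.DataFrame, name: str) -> pd.DataFrame:
    n0 = len(frame)
    out = frame.dropna().reset_index(drop=True)
    if len(out) < n0:
        logger.info("%s frame: dropped %d incomplete row(s)", name, n0 - len(out))
    out.attrs["n_dropped_incomplete"] = n0 - len(out)
    return out


def build_mass_frame(
    ds: StudyDataset,
    inbreeding: pd.DataFrame,
    maternal_age_unit: str = "months",
) -> pd.DataFrame:
    """Yearling body-mass model frame (one row per mass record, age 350-370 d)."""
    lo, hi = YEARLING_WINDOW
    base = _covariate_base(ds, inbreeding, maternal_age_unit)
    mass = ds.outcomes[
        ds.outcomes["body_mass_g"].notna()
        & ds.outcomes["age_days"].notna()
        & ds.outcomes["age_days"].between(lo, hi)
    ][["individual_id", "age_days", "body_mass_g"]]
    frame = mass.merge(base, on="individual_id", how="inner")
    frame = frame.rename(columns={"body_mass_g": "body_mass"})
    frame["age_days"] = frame["age_days"].astype(float)
    return _drop_incomplete(frame, "mass")


def build_survival_frame(
    ds: StudyDataset,
    inbreeding: pd.DataFrame,
    maternal_age_unit: str = "months",
) -> pd.DataFrame:
    """Survival-to-one-year model frame (one row per individual)."""
    base = _covariate_base(ds, inbreeding, maternal_age_unit)
    surv = (
        ds.outcomes[ds.outcomes["survived_to_1yr"].notna()]
        .groupby("individual_id", as_index=False)["survived_to_1yr"]
        .first()
        .rename(columns={"survived_to_1yr": "survived"})
    )
    frame = surv.merge(base, on="individual_id", how="inner")
    frame["survived"] = frame["survived"].astype(int)
    return _drop_incomplete(frame, "survival")


def build_guard_success_frame(
    ds: StudyDataset,
    relmat: RelatednessMatrix,
    natal_only: bool = False,
) -> pd.DataFrame:
    """Mate-guard paternity-success model frame.

    Restricted to guard-female pairs where both have confidently assigned
    parents and the guard's age rank and female's age are known (stated
    exclusions). Sex ratio is the proportion of the attempt's adults that
    are male.
    """
    classified = classify_guard_success(ds)
    if classified.empty:
        return pd.DataFrame(
            columns=["success", *GUARD_SUCCESS_FIXED_TERMS, *GUARD_SUCCESS_RANDOM]
        )
    if natal_only:
        keep = _natal_attempts(ds, ("M",))
        classified = classified[classified["attempt_id"].isin(keep)]
    parented = ds.confidently_parented()
    m = ds.membership.set_index(["attempt_id", "individual_id"])

    adults = ds.membership[
        ds.membership["age_days"].notna() & (ds.membership["age_days"] > 365)
    ]
    sex_ratio = adults.groupby("attempt_id")["sex"].agg(
        lambda s: float((s == "M").mean())
    )

    rows = []
    for r in classified.itertuples(index=False):
        if r.guard_id not in parented or r.female_id not in parented:
            continue
        try:
            g_row = m.loc[(r.attempt_id, r.guard_id)]
            f_row = m.loc[(r.attempt_id, r.female_id)]
        except KeyError:
            continue
        if pd.isna(g_row["age_rank"]) or pd.isna(f_row["age_days"]):
            continue
        rows.append(
            {
                "success": int(r.success),
                "guard_female_r": relmat.relatedness(r.guard_id, r.female_id),
                "male_age_rank": float(g_row["age_rank"]),
                "female_age_months": float(f_row["age_days"]) / DAYS_PER_MONTH,
                "sex_ratio_male": float(sex_ratio.get(r.attempt_id, np.nan)),
                "n_days_guarding": float(r.n_days_guarding),
                "social_group": r.group_id,
                "breeding_attempt": r.attempt_id,
                "guard_id": r.guard_id,
                "female_id": r.female_id,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["success", *GUARD_SUCCESS_FIXED_TERMS, *GUARD_SUCCESS_RANDOM]
    )
    return _drop_incomplete(frame, "guard_success")


# ---------------------------------------------------------------------- #
# fitting
# ---------------------------------------------------------------------- #


def _backend_script() -> Path:
    return Path(resources.files("mungokin") / "lme4_backend.R")


def _run_backend(
    frame: pd.DataFrame,
    response: str,
    fixed: list[str],
    random: list[str],
    family: str,
    alpha: float,
    simplify: bool,
    replicate_col: str | None,
    estimates_only: bool = False,
) -> list[dict]:
    with tempfile.TemporaryDirectory(prefix="mungokin_lmm_") as tmp:
        tmp = Path(tmp)
        data_path = tmp / "frame.csv"
        out_path = tmp / "result.json"
        cols = [response, *fixed, *random]
        if replicate_col:
            cols.append(replicate_col)
        frame[cols].to_csv(data_path, index=False)
        cfg = {
            "data": str(data_path),
            "out": str(out_path),
            "response": response,
            "fixed": fixed,
            "random": random,
            "family": family,
            "alpha": alpha,
            "simplify": simplify,
            "replicate_col": replicate_col,
            "estimates_only": estimates_only,
        }
        cfg_path = tmp / "config.json"
        cfg_path.write_text(json.dumps(cfg))
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(_backend_script()), str(cfg_path)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0 or not out_path.exists():
            raise RuntimeError(
                f"lme4 backend failed (exit {proc.returncode}):\n{proc.stderr[-2000:]}"
            )
        return json.loads(out_path.read_text())


def _parse_result(raw: dict, family: str, random: list[str]) -> ModelFitResult:
    if "error" in raw:
        return ModelFitResult(
            family=family,
            terms={},
            minimal_terms=[],
            intercept=np.nan,
            intercept_se=np.nan,
            random_effect_names=random,
            n_observations=0,
            converged=False,
            error=raw["error"],
            replicate=raw.get("replicate"),
        )
    terms = {
        name: TermResult(
            estimate=t["estimate"],
            se=t["se"],
            chisq=np.nan if t["chisq"] is None else t["chisq"],
            p=np.nan if t["p"] is None else t["p"],
            in_minimal=bool(t["in_minimal"]),
        )
        for name, t in raw["terms"].items()
    }
    return ModelFitResult(
        family=family,
        terms=terms,
        minimal_terms=list(raw["minimal_terms"]),
        intercept=raw["intercept"],
        intercept_se=raw["intercept_se"],
        random_effect_names=random,
        n_observations=int(raw["n_obs"]),
        converged=bool(raw["converged"]),
        singular=bool(raw["singular"]),
        replicate=raw.get("replicate"),
    )


def fit_and_simplify(
    frame: pd.DataFrame,
    response: str,
    fixed: list[str],
    random: list[str],
    family: str = "gaussian",
    alpha: float = 0.05,
    simplify: bool = True,
) -> ModelFitResult:
    """Fit a mixed model and apply the backward-elimination protocol.

    All model comparisons use maximum-likelihood (not REML) fits, the
    standard requirement for fixed-effect likelihood-ratio tests. With
    ``simplify=False`` the full model is kept and each term's chi-square
    comes from dropping it from the full model. Singular random-effect
    fits are reported with ``singular=True`` rather than refitted.
    """
    if family not in ("gaussian", "binomial"):
        raise ValueError(f"unsupported family {family!r}")
    if frame.empty:
        raise ValueError("empty model frame")
    raw = _run_backend(frame, response, fixed, random, family, alpha, simplify, None)
    return _parse_result(raw[0], family, random)


def fit_replicates(
    frame: pd.DataFrame,
    response: str,
    fixed: list[str],
    random: list[str],
    family: str = "gaussian",
    alpha: float = 0.05,
    simplify: bool = True,
    replicate_col: str = "replicate",
    estimates_only: bool = False,
) -> list[ModelFitResult]:
    """Fit one model per replicate in a stacked frame (single R session).

    ``estimates_only`` skips the per-term likelihood-ratio tests and reports
    effect sizes and SEs straight from the (full or simplified) fit — much
    cheaper for parameter-recovery sweeps.
    """
    raw = _run_backend(
        frame, response, fixed, random, family, alpha, simplify, replicate_col,
        estimates_only=estimates_only,
    )
    return [_parse_result(r, family, random) for r in raw]
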