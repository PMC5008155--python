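"""Forward-time generator of a plural-breeding, bi-philopatric population.

The generator emulates the study design of a cooperatively breeding
mongoose-like society: several stable social groups in which both sexes are
philopatric, multiple females per group enter oestrus synchronously, each
oestrous female is mate-guarded by one or more adult males, paternity is
promiscuous (guards get a baseline share, other males sneak matings, and a
small fraction of sires are extra-group), litters average three pups, and
offspring mature at one year. Because both sexes breed in their natal
group, pairwise relatedness among potential mates accumulates over
generations and spans the full range from 0 to 0.5+ — the structure the
analysis pipeline is designed to interrogate.

Kin avoidance enters through two exponential-decay choice kernels:

* guard choice: a male guards female f with weight exp(-beta_guard * r(m, f));
* paternity:   a non-guard or extra-group sire is drawn with weight
  exp(-beta_paternity * r(m, f)).

With both strengths at 0 the process is exactly random mating (uniform
choice), which makes the generator a valid null for type-I-error checks of
the permutation machinery. Offspring fitness carries inbreeding depression:
body mass declines by ``gamma_mass`` grams per unit F and survival by
``gamma_survival`` on the logit scale.

The output is a :class:`~mungokin.records.StudyDataset` in the canonical
schema (plus the full pedigree), byte-identical under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeRecord
from .records import StudyDataset

__all__ = ["SimulationParams", "simulate", "truth_report"]


@dataclass
class SimulationParams:
    """Generative parameters; defaults describe the emulated study system."""

    n_groups: int = 6
    founders_per_group: int = 6          # per sex
    n_attempts_per_group: int = 12
    attempt_interval_days: int = 90
    p_female_in_oestrus: float = 0.6
    max_oestrous_females: int = 10
    guard_count_rate: float = 0.35       # n_guards = 1 + Poisson(rate)
    guard_days_rate: float = 1.0         # n_days = 1 + Poisson(rate)
    litter_extra_rate: float = 2.0       # litter = 1 + Poisson(rate), mean 3
    beta_guard: float = 0.0              # guard-choice kin-avoidance strength
    beta_paternity: float = 0.0          # sire-choice kin-avoidance strength
    p_guard_paternity_base: float = 0.4  # baseline chance a pup's sire is a guard
    p_extra_group_sire: float = 0.10
    maturity_days: int = 365
    gestation_days: int = 60             # birth inside the 40-80 d window
    # offspring fitness
    gamma_mass: float = -347.9           # g per unit F
    gamma_survival: float = 0.0          # logit per unit F
    mass_intercept: float = 807.5
    mass_age_slope: float = 1.15         # g per day of age at weighing
    survival_intercept: float = 0.0
    survival_rainfall_slope: float = 0.20
    rainfall_mean: float = 2.0           # mm/day over 30 d pre-birth
    rainfall_sd: float = 1.0
    # random-effect SDs (mass scale in grams; survival on logit)
    re_sd_group: float = 10.0
    re_sd_attempt: float = 15.0
    re_sd_mother: float = 15.0
    re_sd_father: float = 10.0
    re_sd_individual: float = 25.0
    residual_sd: float = 40.0
    surv_re_sd: float = 0.3              # shared SD for all survival REs
    n_mass_records_per_yearling: int = 2
    assignment_confidence: float = 1.0
    founder_min_age_days: int = 400
    founder_age_spread_days: int = 800
    adult_lifespan_days: int = 1825      # ~5 y; drives generational turnover

    def validate(self) -> None:
        probs = [
            self.p_female_in_oestrus,
            self.p_guard_paternity_base,
            self.p_extra_group_sire,
            self.assignment_confidence,
        ]
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not (math.isfinite(self.beta_guard) and math.isfinite(self.beta_paternity)):
            raise ValueError("avoidance strengths must be finite")
        if self.beta_guard < 0 or self.beta_paternity < 0:
            raise ValueError("avoidance strengths must be >= 0")
        if min(self.n_groups, self.founders_per_group, self.n_attempts_per_group) < 1:
            raise ValueError("population dimensions must be >= 1")


class _Population:
    """Growing individual registry with an incrementally maintained kinship
    matrix (same recursion as :meth:`Pedigree.kinship_matrix`)."""

    def __init__(self, capacity: int = 256, lifespan_days: int = 10**6):
        self.lifespan_days = lifespan_days
        self.n = 0
        self.K = np.zeros((capacity, capacity))
        self.ids: list[str] = []
        self.sex: list[str] = []
        self.birth: list[date] = []
        self.dam: list[int | None] = []
        self.sire: list[int | None] = []
        self.group: list[int] = []
        self.natal: list[int | None] = []
        self.survived: list[bool] = []

    def _grow(self):
        cap = self.K.shape[0]
        newK = np.zeros((2 * cap, 2 * cap))
        newK[:cap, :cap] = self.K
        self.K = newK

    def add(
        self,
        iid: str,
        sex: str,
        birth: date,
        dam: int | None,
        sire: int | None,
        group: int,
        natal: int | None,
        survived: bool = True,
    ) -> int:
        i = self.n
        if i >= self.K.shape[0]:
            self._grow()
        if dam is None and sire is None:
            self.K[i, i] = 0.5
        else:
            row = np.zeros(i)
            if dam is not None:
                row += 0.5 * self.K[dam, :i]
            if sire is not None:
                row += 0.5 * self.K[sire, :i]
            self.K[i, :i] = row
            self.K[:i, i] = row
            f_ds = self.K[dam, sire] if (dam is not None and sire is not None) else 0.0
            self.K[i, i] = 0.5 * (1.0 + f_ds)
        self.ids.append(iid)
        self.sex.append(sex)
        self.birth.append(birth)
        self.dam.append(dam)
        self.sire.append(sire)
        self.group.append(group)
        self.natal.append(natal)
        self.survived.append(survived)
        self.n += 1
        return i

    def kinship(self, i: int, j: int) -> float:
        return float(self.K[i, j])

    def inbreeding(self, i: int) -> float:
        d, s = self.dam[i], self.sire[i]
        return self.kinship(d, s) if (d is not None and s is not None) else 0.0

    def age_days(self, i: int, on: date) -> int:
        return (on - self.birth[i]).days

    def present(self, i: int, on: date) -> bool:
        """Alive-and-in-population: non-survivors die before maturity and
        everyone dies at the adult lifespan."""
        a = self.age_days(i, on)
        if a < 0 or a > self.lifespan_days:
            return False
        return self.survived[i] or a < 180

    def members(self, group: int, on: date) -> list[int]:
        return [
            i
            for i in range(self.n)
            if self.group[i] == group and self.present(i, on)
        ]


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Top-k Gumbel trick: successive weighted draws without replacement."""
    if k >= weights.size:
        return np.arange(weights.size)
    keys = np.log(weights) + rng.gumbel(size=weights.size)
    return np.argpartition(-keys, k - 1)[:k]


def simulate(params: SimulationParams, seed: int) -> tuple[StudyDataset, dict]:
    """Run the generator; returns the dataset and a true-parameter record."""
    params.validate()
    rng = np.random.default_rng(seed)
    pop = _Population(lifespan_days=params.adult_lifespan_days)
    t0 = date(2000, 1, 1)

    # founders: unrelated within and across groups, staggered adult ages
    for g in range(params.n_groups):
        for sex in ("F", "M"):
            for j in range(params.founders_per_group):
                age = params.founder_min_age_days + int(
                    rng.integers(0, params.founder_age_spread_days + 1)
                )
                pop.add(
                    f"G{g}{sex}{j:02d}",
                    sex,
                    t0 - timedelta(days=age),
                    None,
                    None,
                    g,
                    natal=None,
                )

    u_group = rng.normal(0.0, params.re_sd_group, size=params.n_groups)
    su_group = rng.normal(0.0, params.surv_re_sd, size=params.n_groups)
    u_parent: dict[tuple[str, int], float] = {}

    def parent_effect(kind: str, idx: int, sd: float) -> float:
        key = (kind, idx)
        if key not in u_parent:
            u_parent[key] = float(rng.normal(0.0, sd))
        return u_parent[key]

    membership_rows, attempt_rows, parentage_rows = [], [], []
    guard_rows, outcome_rows = [], []
    skipped_attempts: list[str] = []
    pup_counter = 0
    attempt_counter = 0

    for j in range(params.n_attempts_per_group):
        for g in range(params.n_groups):
            t = t0 + timedelta(
                days=j * params.attempt_interval_days + g * 3 + 30
            )
            attempt_id = f"A{attempt_counter:04d}"
            attempt_counter += 1
            members = pop.members(g, t)
            adults = [
                i for i in members if pop.age_days(i, t) > params.maturity_days
            ]
            adult_f = [i for i in adults if pop.sex[i] == "F"]
            adult_m = [i for i in adults if pop.sex[i] == "M"]

            in_oestrus = [
                f for f in adult_f if rng.random() < params.p_female_in_oestrus
            ][: params.max_oestrous_females]
            if not in_oestrus or not adult_m:
                skipped_attempts.append(attempt_id)
                continue

            eg_males = [
                i
                for i in range(pop.n)
                if pop.group[i] != g
                and pop.sex[i] == "M"
                and pop.present(i, t)
                and pop.age_days(i, t) > params.maturity_days
            ]

            # --- mate guarding -------------------------------------- #
            guards_of: dict[int, list[int]] = {}
            for f in in_oestrus:
                n_g = min(
                    1 + int(rng.poisson(params.guard_count_rate)), len(adult_m)
                )
                r = np.array([2.0 * pop.kinship(m, f) for m in adult_m])
                w = np.exp(-params.beta_guard * r)
                pick = _weighted_sample_without_replacement(w, n_g, rng)
                guards_of[f] = [adult_m[int(i)] for i in pick]
                for m in guards_of[f]:
                    guard_rows.append(
                        {
                            "attempt_id": attempt_id,
                            "guard_id": pop.ids[m],
                            "female_id": pop.ids[f],
                            "n_days_guarding": 1
                            + int(rng.poisson(params.guard_days_rate)),
                        }
                    )

            # --- conception and birth ------------------------------- #
            birth_date = t + timedelta(days=params.gestation_days)
            rainfall = max(0.0, float(rng.normal(params.rainfall_mean, params.rainfall_sd)))
            u_attempt = float(rng.normal(0.0, params.re_sd_attempt))
            su_attempt = float(rng.normal(0.0, params.surv_re_sd))
            pups: list[int] = []
            for f in in_oestrus:
                litter = 1 + int(rng.poisson(params.litter_extra_rate))
                fguards = guards_of[f]
                non_guards = [m for m in adult_m if m not in fguards]
                # sire-choice weights are fixed within a female's litter
                if non_guards:
                    r_ng = np.array(
                        [2.0 * pop.kinship(m, f) for m in non_guards]
                    )
                    w_ng = np.exp(-params.beta_paternity * r_ng)
                    w_ng /= w_ng.sum()
                w_eg = None
                if eg_males:
                    r_eg = np.array(
                        [2.0 * pop.kinship(m, f) for m in eg_males]
                    )
                    w_eg = np.exp(-params.beta_paternity * r_eg)
                    w_eg /= w_eg.sum()
                for _ in range(litter):
                    u = rng.random()
                    if u < params.p_extra_group_sire and eg_males:
                        sire = eg_males[int(rng.choice(len(eg_males), p=w_eg))]
                    elif (
                        rng.random() < params.p_guard_paternity_base
                        or not non_guards
                    ):
                        sire = fguards[int(rng.integers(0, len(fguards)))]
                    else:
                        sire = non_guards[
                            int(rng.choice(len(non_guards), p=w_ng))
                        ]
                    pup_id = f"P{pup_counter:05d}"
                    pup_counter += 1
                    sex = "F" if rng.random() < 0.5 else "M"
                    idx = pop.add(
                        pup_id, sex, birth_date, f, sire, g, natal=g,
                        survived=True,
                    )
                    F = pop.inbreeding(idx)
                    logit = (
                        params.survival_intercept
                        + params.gamma_survival * F
                        + params.survival_rainfall_slope * rainfall
                        + su_group[g]
                        + su_attempt
                        + parent_effect("sm", f, params.surv_re_sd)
                        + parent_effect("sp", sire, params.surv_re_sd)
                    )
                    survived = rng.random() < 1.0 / (1.0 + math.exp(-logit))
                    pop.survived[idx] = survived
                    pups.append(idx)
                    parentage_rows.append(
                        {
                            "offspring_id": pup_id,
                            "attempt_id": attempt_id,
                            "dam_id": pop.ids[f],
                            "sire_id": pop.ids[sire],
                            "dam_confidence": params.assignment_confidence,
                            "sire_confidence": params.assignment_confidence,
                        }
                    )
                    if survived:
                        for _ in range(params.n_mass_records_per_yearling):
                            age = int(rng.integers(350, 371))
                            mass = (
                                params.mass_intercept
                                + params.mass_age_slope * age
                                + params.gamma_mass * F
                                + u_group[g]
                                + u_attempt
                                + parent_effect("m", f, params.re_sd_mother)
                                + parent_effect("p", sire, params.re_sd_father)
                                + parent_effect(
                                    "i", idx, params.re_sd_individual
                                )
                                + float(rng.normal(0.0, params.residual_sd))
                            )
                            outcome_rows.append(
                                {
                                    "individual_id": pup_id,
                                    "age_days": age,
                                    "body_mass_g": round(mass, 3),
                                    "survived_to_1yr": 1,
                                }
                            )
                    else:
                        outcome_rows.append(
                            {
                                "individual_id": pup_id,
                                "age_days": pd.NA,
                                "body_mass_g": np.nan,
                                "survived_to_1yr": 0,
                            }
                        )

            # --- tables for this attempt ---------------------------- #
            ranks: dict[int, int] = {}
            for sex in ("F", "M"):
                sex_adults = sorted(
                    (i for i in adults if pop.sex[i] == sex),
                    key=lambda i: (pop.birth[i], pop.ids[i]),
                )
                for rank, i in enumerate(sex_adults, start=1):
                    ranks[i] = rank
            for i in members:
                membership_rows.append(
                    {
                        "group_id": f"G{g}",
                        "attempt_id": attempt_id,
                        "individual_id": pop.ids[i],
                        "age_days": pop.age_days(i, t),
                        "sex": pop.sex[i],
                        "is_natal": pop.natal[i] == g,
                        "age_rank": ranks.get(i, pd.NA),
                    }
                )
            attempt_rows.append(
                {
                    "attempt_id": attempt_id,
                    "group_id": f"G{g}",
                    "oestrus_start_date": t,
                    "birth_date": birth_date,
                    "rainfall_30d": round(rainfall, 4),
                    "group_size_adults": len(adults),
                    "n_pups_born": len(pups),
                }
            )

    pedigree = Pedigree.from_records(
        PedigreeRecord(
            individual_id=pop.ids[i],
            dam_id=pop.ids[pop.dam[i]] if pop.dam[i] is not None else None,
            sire_id=pop.ids[pop.sire[i]] if pop.sire[i] is not None else None,
            sex=pop.sex[i],
            birth_date=pop.birth[i],
            natal_group_id=(
                f"G{pop.natal[i]}" if pop.natal[i] is not None else None
            ),
        )
        for i in range(pop.n)
    )

    from .records import CANONICAL_COLUMNS

    def _frame(rows, name):
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS[name])

    ds = StudyDataset(
        membership=_frame(membership_rows, "membership").astype(
            {"age_days": "Int64", "age_rank": "Int64"}
        ),
        attempts=_frame(attempt_rows, "attempts"),
        parentage=_frame(parentage_rows, "parentage"),
        guards=_frame(guard_rows, "guards").astype(
            {"n_days_guarding": "Int64"}
        ),
        outcomes=_frame(outcome_rows, "outcomes").astype(
            {"age_days": "Int64", "survived_to_1yr": "Int64"}
        ),
        pedigree=pedigree,
    )
    # hand over the incrementally built relatedness matrix (2 * kinship),
    # reordered to the validated pedigree's topological id order
    from .pedigree import RelatednessMatrix

    idx_of = {iid: k for k, iid in enumerate(pop.ids)}
    perm = np.array([idx_of[i] for i in pedigree.ids])
    ds.relatedness = RelatednessMatrix(
        pedigree.ids, 2.0 * pop.K[np.ix_(perm, perm)]
    )

    inb = [pop.inbreeding(i) for i in range(pop.n) if pop.dam[i] is not None]
    truth = {
        "params": asdict(params),
        "seed": seed,
        "n_individuals": pop.n,
        "n_offspring": pup_counter,
        "n_attempts_run": attempt_counter - len(skipped_attempts),
        "skipped_attempts": skipped_attempts,
        "mean_offspring_F": float(np.mean(inb)) if inb else 0.0,
        "max_offspring_F": float(np.max(inb)) if inb else 0.0,
    }
    return ds, truth


def truth_report(ds: StudyDataset) -> dict:
    """Realized bookkeeping computed from the dataset itself.

    Used by parameter-recovery tests to cross-check the generator's output
    against the canonical tables (row counts, realized mean relatedness of
    breeding and guard dyads, offspring F distribution).
    """
    relmat = ds.pedigree.relatedness_matrix() if ds.pedigree else None
    out = {
        "n_membership_rows": len(ds.membership),
        "n_attempts": len(ds.attempts),
        "n_parentage_rows": len(ds.parentage),
        "n_guard_rows": len(ds.guards),
        "n_outcome_rows": len(ds.outcomes),
        "n_pups_born_total": int(ds.attempts["n_pups_born"].sum()),
    }
    if relmat is not None:
        dyads = ds.parentage[
            ds.parentage["dam_id"].notna() & ds.parentage["sire_id"].notna()
        ][["attempt_id", "dam_id", "sire_id"]].drop_duplicates()
        if len(dyads):
            out["mean_breeding_pair_r"] = float(
                np.mean(
                    [
                        relmat.relatedness(d, s)
                        for d, s in zip(dyads["dam_id"], dyads["sire_id"])
                    ]
                )
            )
        if len(ds.guards):
            out["mean_guard_female_r"] = float(
                np.mean(
                    [
                        relmat.relatedness(g, f)
                        for g, f in zip(
                            ds.guards["guard_id"], ds.guards["female_id"]
                        )
                    ]
                )
            )
        inb = ds.pedigree.inbreeding_table()
        known = inb[inb["parents_known"]]
        out["n_offspring_with_F"] = int(len(known))
        out["mean_offspring_F"] = float(known["F"].mean()) if len(known) else 0.0
    return out
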