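"""Inclusion/exclusion rules applied before each analysis, with accounting.

Each filter returns both the retained rows and a :class:`FilterReport`
recording how many input rows passed each criterion individually and how
many survived the conjunction. Retention is always the conjunction of all
criteria; the per-row "dropped_by" attribution uses a fixed precedence
(first criterion in the stated order that the row fails) so the counts
reconcile exactly: ``n_input = n_retained + sum(dropped_by counts)``.

The criteria mirror a mate-choice study design in a plural breeder:
pedigree-derived relatedness is only trusted for individuals whose own
parents are confidently assigned, and randomization pools are only trusted
when most of their members have assigned parents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import timedelta

import pandas as pd

from .pedigree import RelatednessMatrix
from .records import StudyDataset

__all__ = [
    "FilterReport",
    "breeding_pair_filter",
    "guard_pair_filter",
    "classify_guard_success",
    "identify_epp",
    "CONFIDENCE_THRESHOLD",
    "PATERNITY_WINDOW_DAYS",
]

#: parentage assignments are "confident" at probability >= 0.8
CONFIDENCE_THRESHOLD = 0.8
#: offspring born 40-80 days after an observed oestrus are attributed to it
PATERNITY_WINDOW_DAYS = (40, 80)


@dataclass
class FilterReport:
    analysis_name: str
    n_input: int
    per_criterion_pass_counts: dict[str, int]
    n_retained: int
    retained_keys: list[tuple]
    dropped_by: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        assert self.n_retained <= min(
            self.per_criterion_pass_counts.values(), default=self.n_input
        )
        assert self.n_input == self.n_retained + sum(self.dropped_by.values())

    def to_json(self, path=None) -> str:
        payload = {
            "analysis_name": self.analysis_name,
            "n_input": self.n_input,
            "per_criterion_pass_counts": self.per_criterion_pass_counts,
            "n_retained": self.n_retained,
            "dropped_by": self.dropped_by,
        }
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _apply_criteria(name: str, keys: list[tuple], crit: dict[str, list[bool]]):
    """Conjoin per-criterion boolean columns into retained keys + report."""
    n = len(keys)
    pass_counts = {c: int(sum(v)) for c, v in crit.items()}
    retained, dropped = [], {c: 0 for c in crit}
    for i, key in enumerate(keys):
        failing = [c for c in crit if not crit[c][i]]
        if failing:
            dropped[failing[0]] += 1
        else:
            retained.append(key)
    report = FilterReport(
        analysis_name=name,
        n_input=n,
        per_criterion_pass_counts=pass_counts,
        n_retained=len(retained),
        retained_keys=retained,
        dropped_by={c: k for c, k in dropped.items() if k},
    )
    return retained, report


def _natal_attempts(ds: StudyDataset, sexes: tuple[str, ...]) -> set[str]:
    """Attempts where every adult of the given sex(es) was born in the group.

    A member with unknown natal status counts as non-natal (the conservative
    reading); members of unknown age are not adults for this purpose.
    """
    m = ds.membership
    adults = m[
        m["age_days"].notna()
        & (m["age_days"] > 365)
        & m["sex"].isin(list(sexes))
    ]
    ok = adults.groupby("attempt_id")["is_natal"].agg(
        lambda s: bool(s.notna().all() and s.all())
    )
    return set(ok.index[ok])


def _candidate_parented_fraction(
    ds: StudyDataset, attempt_id: str, sex: str, parented: frozenset[str]
) -> float:
    pool = ds.candidate_adults(attempt_id, sex)
    if not pool:
        return 0.0
    return sum(1 for i in pool if i in parented) / len(pool)


# ---------------------------------------------------------------------- #
# breeding pairs
# ---------------------------------------------------------------------- #


def breeding_pair_filter(
    ds: StudyDataset,
    natal_only: bool = False,
    threshold: float = CONFIDENCE_THRESHOLD,
    candidate_scope: str = "within_group",
):
    """Retained mother-sire dyads for the mate-choice randomization.

    One dyad per unique (attempt, mother, sire) triple — several pups by the
    same male in one attempt are a single breeding pair. Criteria:

    1. the mother has both parents confidently assigned;
    2. at least 80% of candidate fathers (adult males in the group at the
       attempt, the randomization pool) have confidently assigned parents;
    3. the sire was a member of the mother's group at the attempt
       (within-group mating).

    ``natal_only`` restricts input to attempts where every adult of both
    sexes is natal to the group. ``candidate_scope`` is fixed at
    ``"within_group"``; the population-wide alternative would need a
    population register the tables do not carry.
    """
    if candidate_scope != "within_group":
        raise NotImplementedError("only within_group candidate fathers supported")
    p = ds.parentage
    ok = (
        p["dam_id"].notna()
        & p["sire_id"].notna()
        & (p["dam_confidence"] >= threshold)
        & (p["sire_confidence"] >= threshold)
    )
    dyads = (
        p.loc[ok, ["attempt_id", "dam_id", "sire_id"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    name = "breeding_pairs"
    if natal_only:
        keep = _natal_attempts(ds, ("F", "M"))
        dyads = dyads[dyads["attempt_id"].isin(keep)].reset_index(drop=True)
        name += "_natal_only"

    parented = ds.confidently_parented(threshold)
    frac_cache = {
        a: _candidate_parented_fraction(ds, a, "M", parented)
        for a in dyads["attempt_id"].unique()
    }
    roster = ds.membership.groupby("attempt_id")["individual_id"].agg(set)

    keys = list(dyads.itertuples(index=False, name=None))
    crit = {
        "1_mother_parents_assigned": [d in parented for _, d, _s in keys],
        "2_candidate_fathers_80pct": [frac_cache[a] >= 0.8 for a, _, _ in keys],
        "3_within_group_sire": [
            s in roster.get(a, set()) for a, _, s in keys
        ],
    }
    retained, report = _apply_criteria(name, keys, crit)
    out = pd.DataFrame(retained, columns=["attempt_id", "mother_id", "sire_id"])
    return out, report


# ---------------------------------------------------------------------- #
# guard-female pairs
# ---------------------------------------------------------------------- #


def guard_pair_filter(
    ds: StudyDataset,
    natal_only: bool = False,
    threshold: float = CONFIDENCE_THRESHOLD,
):
    """Retained guard-female dyads for the guarding randomization.

    Criteria: (1) the guard has confidently assigned parents; (2) at least
    80% of candidate females — the females observed guarded within the same
    oestrus event, i.e. the reshuffling pool — have confidently assigned
    parents. ``natal_only`` restricts to attempts where all adult females
    are natal.
    """
    g = ds.guards[["attempt_id", "guard_id", "female_id"]].drop_duplicates()
    name = "guard_pairs"
    if natal_only:
        keep = _natal_attempts(ds, ("F",))
        g = g[g["attempt_id"].isin(keep)]
        name += "_natal_only"
    g = g.reset_index(drop=True)

    parented = ds.confidently_parented(threshold)
    pool = ds.guards.groupby("attempt_id")["female_id"].agg(lambda s: set(s))
    frac = {
        a: (sum(1 for f in fs if f in parented) / len(fs)) if fs else 0.0
        for a, fs in pool.items()
    }

    keys = list(g.itertuples(index=False, name=None))
    crit = {
        "1_guard_parents_assigned": [gd in parented for _, gd, _f in keys],
        "2_candidate_females_80pct": [frac[a] >= 0.8 for a, _, _ in keys],
    }
    retained, report = _apply_criteria(name, keys, crit)
    out = pd.DataFrame(retained, columns=["attempt_id", "guard_id", "female_id"])
    return out, report


# ---------------------------------------------------------------------- #
# guard success and extra-pair paternity
# ---------------------------------------------------------------------- #


def _window_offspring(ds: StudyDataset, threshold: float) -> pd.DataFrame:
    """Confidently-mothered offspring with birth dates (via their attempt)."""
    p = ds.parentage
    p = p[p["dam_id"].notna() & (p["dam_confidence"] >= threshold)]
    births = ds.attempts.set_index("attempt_id")["birth_date"]
    p = p.assign(birth_date=p["attempt_id"].map(births))
    return p[p["birth_date"].notna()]


def classify_guard_success(
    ds: StudyDataset, threshold: float = CONFIDENCE_THRESHOLD
) -> pd.DataFrame:
    """Label each guard-female-attempt row successful or unsuccessful.

    A guard is *successful* if the guarded female has at least one
    confidently-assigned offspring born 40-80 days after the observed
    oestrus whose sire is the guard. Rows whose female has no
    confidently-assigned offspring in that window are excluded entirely
    (the oestrus produced nothing attributable).
    """
    lo, hi = PATERNITY_WINDOW_DAYS
    offs = _window_offspring(ds, threshold)
    oestrus = ds.attempts.set_index("attempt_id")["oestrus_start_date"]
    groups = ds.attempts.set_index("attempt_id")["group_id"]
    rows = []
    for r in ds.guards.drop_duplicates(
        subset=["attempt_id", "guard_id", "female_id"]
    ).itertuples(index=False):
        t0 = oestrus.get(r.attempt_id)
        if t0 is None or pd.isna(t0):
            continue
        w = offs[
            (offs["dam_id"] == r.female_id)
            & (offs["birth_date"] >= t0 + timedelta(days=lo))
            & (offs["birth_date"] <= t0 + timedelta(days=hi))
        ]
        if w.empty:
            continue  # not classifiable
        sired = w[
            (w["sire_id"] == r.guard_id) & (w["sire_confidence"] >= threshold)
        ]
        rows.append(
            {
                "attempt_id": r.attempt_id,
                "group_id": groups.get(r.attempt_id),
                "guard_id": r.guard_id,
                "female_id": r.female_id,
                "n_days_guarding": r.n_days_guarding,
                "success": not sired.empty,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "attempt_id",
            "group_id",
            "guard_id",
            "female_id",
            "n_days_guarding",
            "success",
        ],
    )


def identify_epp(
    ds: StudyDataset,
    relmat: RelatednessMatrix,
    classified: pd.DataFrame | None = None,
    threshold: float = CONFIDENCE_THRESHOLD,
    natal_only: bool = False,
):
    """Paired guard-vs-EPP relatedness rows from unsuccessful guards.

    For each unsuccessful guard-female pair, the extra-pair (EPP) male is
    the single confidently-assigned non-guard sire of the female's window
    offspring. Cases with two or more distinct EPP identities are excluded
    (no unambiguous pairwise comparison), as are rows where the guard,
    female or EPP male lacks assigned parents. The EPP male is
    ``within_group`` if he was on the attempt's group roster, else
    ``extra_group``. ``natal_only`` restricts to attempts where every
    adult male was born in the group (no familiarity cue to relatedness).
    """
    if classified is None:
        classified = classify_guard_success(ds, threshold)
    if natal_only:
        classified = classified[
            classified["attempt_id"].isin(_natal_attempts(ds, ("M",)))
        ]
    lo, hi = PATERNITY_WINDOW_DAYS
    offs = _window_offspring(ds, threshold)
    oestrus = ds.attempts.set_index("attempt_id")["oestrus_start_date"]
    roster = ds.membership.groupby("attempt_id")["individual_id"].agg(set)
    parented = ds.confidently_parented(threshold)

    unsuccessful = classified[~classified["success"]].reset_index(drop=True)
    keys, crit_rows = [], []
    details = []
    for r in unsuccessful.itertuples(index=False):
        t0 = oestrus[r.attempt_id]
        w = offs[
            (offs["dam_id"] == r.female_id)
            & (offs["birth_date"] >= t0 + timedelta(days=lo))
            & (offs["birth_date"] <= t0 + timedelta(days=hi))
            & offs["sire_id"].notna()
            & (offs["sire_confidence"] >= threshold)
        ]
        epp_males = sorted(set(w["sire_id"]) - {r.guard_id})
        keys.append((r.attempt_id, r.guard_id, r.female_id))
        crit_rows.append(
            {
                "1_guard_parents_assigned": r.guard_id in parented,
                "2_female_parents_assigned": r.female_id in parented,
                "3_epp_male_parents_assigned": len(epp_males) >= 1
                and all(m in parented for m in epp_males),
                "4_single_epp_identity": len(epp_males) == 1,
            }
        )
        details.append(epp_males[0] if len(epp_males) == 1 else None)

    crit = {
        c: [row[c] for row in crit_rows]
        for c in (
            "1_guard_parents_assigned",
            "2_female_parents_assigned",
            "3_epp_male_parents_assigned",
            "4_single_epp_identity",
        )
    }
    retained, report = _apply_criteria("epp_pairs", keys, crit)
    retained_set = set(retained)
    out_rows = []
    for key, epp_male in zip(keys, details):
        if key not in retained_set:
            continue
        attempt_id, guard_id, female_id = key
        out_rows.append(
            {
                "attempt_id": attempt_id,
                "guard_id": guard_id,
                "female_id": female_id,
                "epp_male_id": epp_male,
                "guard_r": relmat.relatedness(guard_id, female_id),
                "epp_r": relmat.relatedness(epp_male, female_id),
                "epp_scope": (
                    "within_group"
                    if epp_male in roster.get(attempt_id, set())
                    else "extra_group"
                ),
            }
        )
    out = pd.DataFrame(
        out_rows,
        columns=[
            "attempt_id",
            "guard_id",
            "female_id",
            "epp_male_id",
            "guard_r",
            "epp_r",
            "epp_scope",
        ],
    )
    return out, report
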