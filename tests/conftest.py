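"""Shared fixture builders: tiny hand-constructed study datasets and random
pedigrees, all generated programmatically at test time."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from mungokin.pedigree import Pedigree, PedigreeRecord
from mungokin.records import CANONICAL_COLUMNS, StudyDataset

_DTYPES = {
    "membership": {"age_days": "Int64", "age_rank": "Int64", "is_natal": "boolean"},
    "attempts": {
        "rainfall_30d": "float64",
        "group_size_adults": "Int64",
        "n_pups_born": "Int64",
    },
    "parentage": {"dam_confidence": "float64", "sire_confidence": "float64"},
    "guards": {"n_days_guarding": "Int64"},
    "outcomes": {
        "age_days": "Int64",
        "body_mass_g": "float64",
        "survived_to_1yr": "Int64",
    },
}


def rec(iid, dam=None, sire=None, sex=None, born=None, natal=None):
    return PedigreeRecord(
        individual_id=iid,
        dam_id=dam,
        sire_id=sire,
        sex=sex,
        birth_date=born,
        natal_group_id=natal,
    )


def make_dataset(pedigree_records=None, **tables) -> StudyDataset:
    """Assemble a StudyDataset from lists of row dicts (missing fields -> NA)."""
    frames = {}
    for name, cols in CANONICAL_COLUMNS.items():
        rows = list(tables.get(name, ()))
        df = pd.DataFrame(rows, columns=cols)
        for col, dt in _DTYPES[name].items():
            df[col] = df[col].astype(dt)
        frames[name] = df
    ped = (
        Pedigree.from_records(pedigree_records)
        if pedigree_records is not None
        else None
    )
    return StudyDataset(pedigree=ped, **frames)


def member(group, attempt, iid, age_days, sex, natal, rank=None):
    return {
        "group_id": group,
        "attempt_id": attempt,
        "individual_id": iid,
        "age_days": age_days,
        "sex": sex,
        "is_natal": natal,
        "age_rank": rank,
    }


def attempt(aid, group, oestrus, birth=None, rainfall=2.0, n_adults=0, n_pups=0):
    return {
        "attempt_id": aid,
        "group_id": group,
        "oestrus_start_date": oestrus,
        "birth_date": birth,
        "rainfall_30d": rainfall,
        "group_size_adults": n_adults,
        "n_pups_born": n_pups,
    }


def parentage(off, aid, dam, sire, conf=1.0):
    return {
        "offspring_id": off,
        "attempt_id": aid,
        "dam_id": dam,
        "sire_id": sire,
        "dam_confidence": conf if dam else None,
        "sire_confidence": conf if sire else None,
    }


def guard(aid, g, f, days=1):
    return {
        "attempt_id": aid,
        "guard_id": g,
        "female_id": f,
        "n_days_guarding": days,
    }


@pytest.fixture
def two_group_study() -> StudyDataset:
    """Hand-built two-group fixture exercising every filter criterion.

    Group G1: founders FA, MA, FB, MB, MC breed at A1 producing full-sib
    pairs (W, X) = FA x MA and (Y, Z) = FB x MB. At A2 only the four
    offspring remain; X guards Y and sires her pup P1 (successful), Z
    guards W but X sires both of W's pups (unsuccessful guard, single
    within-group EPP male X).

    Group G2: founders FC, FD, MD, ME breed at A1b producing V = FC x MD.
    At A3 the founders are still present, so criterion 2 (80% of candidate
    fathers with assigned parents) fails; MD guards and sires with V, ME
    guards V unsuccessfully (EPP male MD has no assigned parents), and MD
    also guards FD, who produces nothing (unclassifiable row).
    """
    f95, f00, f02 = date(1995, 1, 1), date(2000, 3, 1), date(2002, 3, 2)
    peds = [
        rec("FA", sex="F", born=f95),
        rec("MA", sex="M", born=f95),
        rec("FB", sex="F", born=date(1995, 2, 1)),
        rec("MB", sex="M", born=date(1995, 2, 1)),
        rec("MC", sex="M", born=date(1995, 3, 1)),
        rec("FC", sex="F", born=f95),
        rec("FD", sex="F", born=date(1995, 2, 1)),
        rec("MD", sex="M", born=f95),
        rec("ME", sex="M", born=date(1995, 2, 1)),
        rec("W", "FA", "MA", "F", f00, "G1"),
        rec("X", "FA", "MA", "M", f00, "G1"),
        rec("Y", "FB", "MB", "F", f00, "G1"),
        rec("Z", "FB", "MB", "M", f00, "G1"),
        rec("V", "FC", "MD", "F", f00, "G2"),
        rec("P1", "Y", "X", "F", f02, "G1"),
        rec("P2", "W", "X", "M", f02, "G1"),
        rec("P3", "W", "X", "F", f02, "G1"),
        rec("P4", "V", "MD", "M", f02, "G2"),
    ]
    o00, o02 = date(2000, 1, 1), date(2002, 1, 1)
    attempts_ = [
        attempt("A1", "G1", o00, f00, n_adults=5, n_pups=4),
        attempt("A1b", "G2", o00, f00, n_adults=4, n_pups=1),
        attempt("A2", "G1", o02, f02, n_adults=4, n_pups=3),
        attempt("A3", "G2", o02, f02, n_adults=5, n_pups=1),
    ]
    a1_age, a2_founder_age, a2_age = 1826, 2557, 671
    membership_ = [
        member("G1", "A1", "FA", a1_age, "F", False, 1),
        member("G1", "A1", "MA", a1_age, "M", False, 1),
        member("G1", "A1", "FB", a1_age - 31, "F", False, 2),
        member("G1", "A1", "MB", a1_age - 31, "M", False, 2),
        member("G1", "A1", "MC", a1_age - 59, "M", False, 3),
        member("G2", "A1b", "FC", a1_age, "F", False, 1),
        member("G2", "A1b", "FD", a1_age - 31, "F", False, 2),
        member("G2", "A1b", "MD", a1_age, "M", False, 1),
        member("G2", "A1b", "ME", a1_age - 31, "M", False, 2),
        member("G1", "A2", "W", a2_age, "F", True, 1),
        member("G1", "A2", "X", a2_age, "M", True, 1),
        member("G1", "A2", "Y", a2_age, "F", True, 2),
        member("G1", "A2", "Z", a2_age, "M", True, 2),
        member("G2", "A3", "V", a2_age, "F", True, 3),
        member("G2", "A3", "FC", a2_founder_age, "F", False, 1),
        member("G2", "A3", "FD", a2_founder_age - 31, "F", False, 2),
        member("G2", "A3", "MD", a2_founder_age, "M", False, 1),
        member("G2", "A3", "ME", a2_founder_age - 31, "M", False, 2),
    ]
    parentage_ = [
        parentage("W", "A1", "FA", "MA"),
        parentage("X", "A1", "FA", "MA"),
        parentage("Y", "A1", "FB", "MB"),
        parentage("Z", "A1", "FB", "MB"),
        parentage("V", "A1b", "FC", "MD"),
        parentage("P1", "A2", "Y", "X"),
        parentage("P2", "A2", "W", "X"),
        parentage("P3", "A2", "W", "X"),
        parentage("P4", "A3", "V", "MD"),
    ]
    guards_ = [
        guard("A1", "MC", "FB", 1),
        guard("A2", "X", "Y", 3),
        guard("A2", "Z", "W", 2),
        guard("A3", "MD", "V", 2),
        guard("A3", "ME", "V", 1),
        guard("A3", "MD", "FD", 1),
    ]
    outcomes_ = [
        {"individual_id": "P1", "age_days": 360, "body_mass_g": 1200.0,
         "survived_to_1yr": 1},
        {"individual_id": "P2", "age_days": None, "body_mass_g": None,
         "survived_to_1yr": 0},
    ]
    return make_dataset(
        pedigree_records=peds,
        membership=membership_,
        attempts=attempts_,
        parentage=parentage_,
        guards=guards_,
        outcomes=outcomes_,
    )


def random_pedigree(rng: np.random.Generator, n_founders=12, n_per_gen=9,
                    n_gens=4) -> Pedigree:
    """Random multi-generation pedigree (parents drawn from any earlier
    generation, so inbreeding loops arise naturally)."""
    records = []
    females, males = [], []
    for i in range(n_founders):
        sex = "F" if i % 2 == 0 else "M"
        iid = f"F{i:02d}"
        records.append(rec(iid, sex=sex, born=date(2000, 1, 1)))
        (females if sex == "F" else males).append(iid)
    for g in range(1, n_gens + 1):
        born = date(2000 + g, 1, 1)
        new_f, new_m = [], []
        for j in range(n_per_gen):
            sex = "F" if rng.random() < 0.5 else "M"
            iid = f"G{g}I{j:02d}"
            dam = females[int(rng.integers(0, len(females)))]
            sire = males[int(rng.integers(0, len(males)))]
            records.append(rec(iid, dam, sire, sex, born))
            (new_f if sex == "F" else new_m).append(iid)
        females, males = females + new_f, males + new_m
    return Pedigree.from_records(records)
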