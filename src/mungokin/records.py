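"""Data model and CSV I/O for the behavioural study tables.

Five canonical tables describe a plural-breeding study population:

* ``membership``  — group roster at each breeding attempt
  (``group_id, attempt_id, individual_id, age_days, sex, is_natal, age_rank``)
* ``attempts``    — one row per group oestrus event
  (``attempt_id, group_id, oestrus_start_date, birth_date, rainfall_30d,
  group_size_adults, n_pups_born``)
* ``parentage``   — per-offspring dam/sire assignments with confidences
  (``offspring_id, attempt_id, dam_id, sire_id, dam_confidence,
  sire_confidence``)
* ``guards``      — observed mate-guarding links
  (``attempt_id, guard_id, female_id, n_days_guarding``)
* ``outcomes``    — body-mass records and survival to one year
  (``individual_id, age_days, body_mass_g, survived_to_1yr``)

plus the pedigree itself (see :mod:`mungokin.pedigree`). Externally
deposited data with different headers is adapted through a declarative
column map. Readers tolerate a UTF-8 BOM and sniff comma vs tab delimiters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree

__all__ = ["StudyDataset", "read_tables", "CANONICAL_COLUMNS", "ADULT_AGE_DAYS"]

logger = logging.getLogger(__name__)

#: "adult" means aged strictly more than one year at the event date
ADULT_AGE_DAYS = 365

CANONICAL_COLUMNS: dict[str, list[str]] = {
    "membership": [
        "group_id",
        "attempt_id",
        "individual_id",
        "age_days",
        "sex",
        "is_natal",
        "age_rank",
    ],
    "attempts": [
        "attempt_id",
        "group_id",
        "oestrus_start_date",
        "birth_date",
        "rainfall_30d",
        "group_size_adults",
        "n_pups_born",
    ],
    "parentage": [
        "offspring_id",
        "attempt_id",
        "dam_id",
        "sire_id",
        "dam_confidence",
        "sire_confidence",
    ],
    "guards": ["attempt_id", "guard_id", "female_id", "n_days_guarding"],
    "outcomes": ["individual_id", "age_days", "body_mass_g", "survived_to_1yr"],
}

_NUMERIC = {
    "age_days": "Int64",
    "age_rank": "Int64",
    "rainfall_30d": "float64",
    "group_size_adults": "Int64",
    "n_pups_born": "Int64",
    "dam_confidence": "float64",
    "sire_confidence": "float64",
    "n_days_guarding": "Int64",
    "body_mass_g": "float64",
    "survived_to_1yr": "Int64",
}
_DATES = {"oestrus_start_date", "birth_date"}
_BOOLS = {"is_natal"}


@dataclass
class StudyDataset:
    """All study tables plus the pedigree, cross-validated on load.

    ``relatedness`` is an optional cached additive-relatedness matrix; the
    generator attaches the one it maintained while simulating (identical to
    ``pedigree.relatedness_matrix()``, which remains the source of truth
    when loading from disk).
    """

    membership: pd.DataFrame
    attempts: pd.DataFrame
    parentage: pd.DataFrame
    guards: pd.DataFrame
    outcomes: pd.DataFrame
    pedigree: Pedigree | None = None
    relatedness: object = None
    validation_warnings: list[str] = field(default_factory=list)

    def relatedness_matrix(self):
        if self.relatedness is None:
            if self.pedigree is None:
                raise ValueError("dataset has neither relatedness nor pedigree")
            self.relatedness = self.pedigree.relatedness_matrix()
        return self.relatedness

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    # -------------------------------------------------------------- #

    def attempt_row(self, attempt_id: str) -> pd.Series:
        rows = self.attempts[self.attempts["attempt_id"] == attempt_id]
        if rows.empty:
            raise KeyError(f"unknown attempt_id {attempt_id!r}")
        return rows.iloc[0]

    def candidate_adults(self, attempt_id: str, sex: str) -> frozenset[str]:
        """Group members of ``sex`` aged > 1 year at the attempt.

        Members with unknown age are excluded (their adulthood cannot be
        established). Deterministic and invariant to table row order.
        """
        self.attempt_row(attempt_id)  # existence check
        m = self.membership
        sel = (
            (m["attempt_id"] == attempt_id)
            & (m["sex"] == sex)
            & m["age_days"].notna()
            & (m["age_days"] > ADULT_AGE_DAYS)
        )
        return frozenset(m.loc[sel, "individual_id"])

    def confidently_parented(self, threshold: float = 0.8) -> frozenset[str]:
        """Ids whose dam AND sire are assigned with confidence >= threshold."""
        p = self.parentage
        ok = (
            p["dam_id"].notna()
            & p["sire_id"].notna()
            & (p["dam_confidence"] >= threshold)
            & (p["sire_confidence"] >= threshold)
        )
        return frozenset(p.loc[ok, "offspring_id"])

    def write(self, directory) -> dict[str, Path]:
        """Write the five canonical CSVs (plus ``pedigree.csv`` if present)."""
        from .pedigree import write_pedigree_csv

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in CANONICAL_COLUMNS:
            df = self.table(name).copy()
            for c in set(df.columns) & _DATES:
                df[c] = df[c].map(lambda d: d.isoformat() if pd.notna(d) else "")
            if "is_natal" in df.columns:
                df["is_natal"] = df["is_natal"].map(
                    lambda v: "" if pd.isna(v) else ("1" if v else "0")
                )
            paths[name] = directory / f"{name}.csv"
            df.to_csv(paths[name], index=False)
        if self.pedigree is not None:
            paths["pedigree"] = directory / "pedigree.csv"
            write_pedigree_csv(self.pedigree, paths["pedigree"])
        return paths


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8-sig") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def _read_one(path, name: str, column_map: dict[str, str] | None) -> pd.DataFrame:
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, encoding="utf-8-sig")
    if column_map:
        df = df.rename(columns=column_map)
    required = CANONICAL_COLUMNS[name]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"table {name!r}: missing required column(s) {missing}")
    df = df[required].copy()
    for c in df.columns:
        df[c] = df[c].replace("", np.nan)
        if c in _NUMERIC:
            df[c] = pd.to_numeric(df[c]).astype(_NUMERIC[c])
        elif c in _DATES:
            df[c] = pd.to_datetime(df[c], format="%Y-%m-%d").dt.date
        elif c in _BOOLS:
            df[c] = df[c].map(
                {"1": True, "0": False, "True": True, "False": False, np.nan: pd.NA}
            )
    return df


def read_tables(
    paths: dict[str, str | Path],
    column_map: dict[str, dict[str, str]] | None = None,
    pedigree: Pedigree | None = None,
) -> StudyDataset:
    """Load the canonical tables, adapt foreign headers and cross-validate.

    Parameters
    ----------
    paths
        Mapping of table name -> CSV path; must contain the five canonical
        table names and may contain ``"pedigree"``.
    column_map
        Optional per-table mapping of source header -> canonical field, for
        externally deposited data.
    pedigree
        Pre-loaded pedigree; overrides any ``"pedigree"`` path entry.

    Referential-integrity problems (ids in observation tables absent from
    the pedigree or attempt register) are collected as warnings on the
    returned dataset, never hard errors.
    """
    from .pedigree import read_pedigree_csv

    column_map = column_map or {}
    tables = {
        name: _read_one(paths[name], name, column_map.get(name))
        for name in CANONICAL_COLUMNS
    }
    for name, df in tables.items():
        logger.info("loaded %-10s %6d rows from %s", name, len(df), paths[name])
    if pedigree is None and "pedigree" in paths:
        pedigree = read_pedigree_csv(paths["pedigree"])

    ds = StudyDataset(pedigree=pedigree, **tables)

    known_attempts = set(ds.attempts["attempt_id"].dropna())
    for name in ("membership", "parentage", "guards"):
        bad = sorted(
            set(ds.table(name)["attempt_id"].dropna()) - known_attempts
        )
        if bad:
            ds.validation_warnings.append(
                f"{name}: {len(bad)} attempt_id(s) not in attempts table "
                f"(e.g. {bad[:3]})"
            )
    if pedigree is not None:
        known_ids = set(pedigree.ids)
        checks = [
            ("membership", "individual_id"),
            ("parentage", "offspring_id"),
            ("parentage", "dam_id"),
            ("parentage", "sire_id"),
            ("guards", "guard_id"),
            ("guards", "female_id"),
            ("outcomes", "individual_id"),
        ]
        for name, col in checks:
            bad = sorted(set(ds.table(name)[col].dropna()) - known_ids)
            if bad:
                ds.validation_warnings.append(
                    f"{name}.{col}: {len(bad)} id(s) not in pedigree "
                    f"(e.g. {bad[:3]})"
                )
    return ds


def read_dataset_dir(directory, **kwargs) -> StudyDataset:
    """Convenience: load a directory produced by :meth:`StudyDataset.write`."""
    directory = Path(directory)
    paths = {name: directory / f"{name}.csv" for name in CANONICAL_COLUMNS}
    ped = directory / "pedigree.csv"
    if ped.exists():
        paths["pedigree"] = ped
    return read_tables(paths, **kwargs)
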