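"""Pedigree representation and identity-by-descent machinery.

A pedigree is a directed acyclic graph of dam/sire links. From it we compute
the classical quantities of quantitative genetics:

* kinship (coancestry) ``f(i, j)``: the probability that one allele drawn at
  random from *i* and one from *j* are identical by descent (IBD);
* additive (numerator) relatedness ``r = a_ij = 2 f(i, j)``, the quantity
  field studies report as "pairwise relatedness" (0.5 for outbred
  parent-offspring or full sibs);
* the inbreeding coefficient ``F_i = f(dam_i, sire_i)``, the probability
  that an individual's two alleles are IBD.

Founders (individuals with no known parents) are taken to be non-inbred and
mutually unrelated; an individual with exactly one known parent is treated
as if the missing side were a unique phantom founder. These are the
universal conventions of pedigree analysis.

A Monte Carlo gene-dropping routine provides an independent estimate of the
same quantities by literally transmitting founder alleles down the pedigree,
and serves as the validation oracle for the exact recursion.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeRecord",
    "Pedigree",
    "PedigreeError",
    "GeneDropResult",
    "gene_drop",
    "read_pedigree_csv",
    "write_relatedness_long",
    "write_inbreeding_table",
]

FEMALE = "F"
MALE = "M"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, ...)."""


@dataclass(frozen=True)
class PedigreeRecord:
    """One individual: identity, parent links and basic metadata.

    ``None`` encodes "unknown" for every optional field. ``sex`` is ``"F"``,
    ``"M"`` or ``None``.
    """

    individual_id: str
    dam_id: str | None = None
    sire_id: str | None = None
    sex: str | None = None
    birth_date: date | None = None
    natal_group_id: str | None = None


def _parse_date(value) -> date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, date):
        return value
    s = str(value).strip()
    if not s:
        return None
    return datetime.strptime(s, "%Y-%m-%d").date()


class Pedigree:
    """A validated pedigree in topological order (parents before offspring).

    Construct with :meth:`from_records`; the constructor itself assumes the
    caller has already produced a valid topological ordering.
    """

    def __init__(self, records: Sequence[PedigreeRecord]):
        self.records: tuple[PedigreeRecord, ...] = tuple(records)
        self.ids: tuple[str, ...] = tuple(r.individual_id for r in records)
        self.index: dict[str, int] = {iid: k for k, iid in enumerate(self.ids)}
        n = len(self.ids)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        for k, r in enumerate(self.records):
            if r.dam_id is not None and r.dam_id in self.index:
                self.dam_idx[k] = self.index[r.dam_id]
            if r.sire_id is not None and r.sire_id in self.index:
                self.sire_idx[k] = self.index[r.sire_id]
        self._kinship: np.ndarray | None = None

    # ------------------------------------------------------------------ #
    # construction / validation
    # ------------------------------------------------------------------ #

    @classmethod
    def from_records(cls, records: Iterable[PedigreeRecord]) -> "Pedigree":
        """Validate and topologically sort ``records``.

        Dangling parent references (a parent id that has no record of its
        own) are reported with a warning and the parent treated as unknown,
        i.e. a founder on that side. Cycles and duplicate ids are hard
        errors, as are sex-inconsistent parent links and a parent born
        after its offspring (when both dates are known).
        """
        records = list(records)
        by_id: dict[str, PedigreeRecord] = {}
        for r in records:
            if r.individual_id in by_id:
                raise PedigreeError(f"duplicate individual_id {r.individual_id!r}")
            by_id[r.individual_id] = r

        dangling = sorted(
            {
                p
                for r in records
                for p in (r.dam_id, r.sire_id)
                if p is not None and p not in by_id
            }
        )
        if dangling:
            warnings.warn(
                f"{len(dangling)} dangling parent reference(s) treated as "
                f"founders: {dangling[:5]}{'...' if len(dangling) > 5 else ''}",
                stacklevel=2,
            )

        for r in records:
            for pid, expected, label in (
                (r.dam_id, FEMALE, "dam"),
                (r.sire_id, MALE, "sire"),
            ):
                if pid is None or pid not in by_id:
                    continue
                parent = by_id[pid]
                if parent.sex is not None and parent.sex != expected:
                    raise PedigreeError(
                        f"{label} {pid!r} of {r.individual_id!r} has sex "
                        f"{parent.sex!r}"
                    )
                if (
                    parent.birth_date is not None
                    and r.birth_date is not None
                    and parent.birth_date >= r.birth_date
                ):
                    raise PedigreeError(
                        f"{label} {pid!r} born {parent.birth_date} not before "
                        f"offspring {r.individual_id!r} born {r.birth_date}"
                    )

        # Kahn's algorithm over known parent->offspring edges.
        children: dict[str, list[str]] = {i: [] for i in by_id}
        n_parents: dict[str, int] = {}
        for r in records:
            k = 0
            for pid in (r.dam_id, r.sire_id):
                if pid is not None and pid in by_id:
                    children[pid].append(r.individual_id)
                    k += 1
            n_parents[r.individual_id] = k
        ready = [r.individual_id for r in records if n_parents[r.individual_id] == 0]
        order: list[str] = []
        while ready:
            iid = ready.pop()
            order.append(iid)
            for c in children[iid]:
                n_parents[c] -= 1
                if n_parents[c] == 0:
                    ready.append(c)
        if len(order) < len(records):
            member = sorted(i for i in by_id if n_parents[i] > 0)[0]
            raise PedigreeError(f"ancestry cycle involving {member!r}")
        return cls([by_id[i] for i in order])

    # ------------------------------------------------------------------ #
    # exact IBD quantities
    # ------------------------------------------------------------------ #

    def __len__(self) -> int:
        return len(self.ids)

    def kinship_matrix(self) -> np.ndarray:
        """Dense kinship matrix ``f`` over all individuals (topological order).

        Standard tabular recursion: for individual *i* with parents *d*, *s*
        (kinship with an unknown parent is 0),

            f(i, i) = (1 + f(d, s)) / 2
            f(i, j) = (f(d, j) + f(s, j)) / 2   for earlier j.

        Cached after the first call.
        """
        if self._kinship is not None:
            return self._kinship
        n = len(self)
        f = np.zeros((n, n))
        for i in range(n):
            d, s = self.dam_idx[i], self.sire_idx[i]
            row = np.zeros(i)
            if d >= 0:
                row += 0.5 * f[d, :i]
            if s >= 0:
                row += 0.5 * f[s, :i]
            f[i, :i] = row
            f[:i, i] = row
            f_ds = f[d, s] if (d >= 0 and s >= 0) else 0.0
            f[i, i] = 0.5 * (1.0 + f_ds)
        self._kinship = f
        return f

    def relatedness_matrix(self) -> "RelatednessMatrix":
        """Additive relatedness ``a = 2 f`` with diagonal ``1 + F``."""
        return RelatednessMatrix(self.ids, 2.0 * self.kinship_matrix())

    def inbreeding_table(self) -> pd.DataFrame:
        """Per-individual ``F`` with a ``parents_known`` flag.

        ``F = f(dam, sire)`` when both parents are known and 0 otherwise
        (a missing parent is an unrelated phantom founder).
        """
        f = self.kinship_matrix()
        rows = []
        for i, iid in enumerate(self.ids):
            d, s = self.dam_idx[i], self.sire_idx[i]
            known = bool(d >= 0 and s >= 0)
            rows.append(
                {
                    "individual_id": iid,
                    "F": float(f[d, s]) if known else 0.0,
                    "parents_known": known,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class RelatednessMatrix:
    """Symmetric additive-relatedness matrix ``a_ij = 2 f(i, j)``."""

    ids: Sequence[str]
    a: np.ndarray
    index: Mapping[str, int] = field(init=False)

    def __post_init__(self):
        self.ids = tuple(self.ids)
        self.index = {iid: k for k, iid in enumerate(self.ids)}

    def relatedness(self, i: str, j: str) -> float:
        """Pairwise relatedness ``r`` for a pair of ids (diagonal = 1 + F)."""
        try:
            return float(self.a[self.index[i], self.index[j]])
        except KeyError as exc:
            raise KeyError(f"unknown individual {exc.args[0]!r}") from None


# ---------------------------------------------------------------------- #
# gene dropping
# ---------------------------------------------------------------------- #


@dataclass
class GeneDropResult:
    """Replicate-level allele draws plus summary estimators.

    ``alleles`` has shape ``(n_replicates, n_individuals, 2)``; each founder
    (and each missing parent side) contributes globally unique allele labels,
    so label equality is exactly identity by descent.
    """

    pedigree: Pedigree
    alleles: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.alleles.shape[0]

    def inbreeding(self, individual_id: str) -> tuple[float, float]:
        """(estimate, Monte Carlo SE) of F: fraction of replicates with an
        IBD allele pair."""
        k = self.pedigree.index[individual_id]
        hit = self.alleles[:, k, 0] == self.alleles[:, k, 1]
        p = float(hit.mean())
        se = float(np.sqrt(p * (1.0 - p) / self.n_replicates))
        return p, se

    def relatedness(self, i: str, j: str) -> tuple[float, float]:
        """(estimate, MC SE) of additive relatedness ``r = 2 f(i, j)``.

        The per-replicate statistic is the fraction of the four cross-allele
        comparisons that are IBD; its mean estimates f.
        """
        ki, kj = self.pedigree.index[i], self.pedigree.index[j]
        ai = self.alleles[:, ki, :]
        aj = self.alleles[:, kj, :]
        s = (
            (ai[:, 0] == aj[:, 0]).astype(np.float64)
            + (ai[:, 0] == aj[:, 1])
            + (ai[:, 1] == aj[:, 0])
            + (ai[:, 1] == aj[:, 1])
        ) / 4.0
        est = 2.0 * float(s.mean())
        se = 2.0 * float(s.std(ddof=1) / np.sqrt(self.n_replicates))
        return est, se


    def relatedness_all(self) -> tuple[np.ndarray, np.ndarray]:
        """Estimates and MC SEs of additive relatedness for every pair.

        Returns ``(est, se)`` as symmetric (N, N) arrays; the diagonal holds
        ``1 + F`` estimates. Row-blocked so the whole computation streams
        through numpy instead of a per-pair Python loop.
        """
        R, n, _ = self.alleles.shape
        est = np.empty((n, n))
        se = np.empty((n, n))
        a0 = self.alleles[:, :, 0]
        a1 = self.alleles[:, :, 1]
        for i in range(n):
            ai0 = a0[:, i : i + 1]
            ai1 = a1[:, i : i + 1]
            s = (
                (a0 == ai0).astype(np.float32)
                + (a0 == ai1)
                + (a1 == ai0)
                + (a1 == ai1)
            ) * np.float32(0.25)
            m = s.mean(axis=0, dtype=np.float64)
            v = (s.astype(np.float64) ** 2).mean(axis=0) - m**2
            est[i] = 2.0 * m
            se[i] = 2.0 * np.sqrt(np.maximum(v, 0.0) * (R / (R - 1)) / R)
        # self-comparison counts the identical pair twice: s_ii = (2 + 2*1{IBD})/4,
        # so est_ii = 1 + F_hat as documented
        return est, se


def gene_drop(pedigree: Pedigree, n_replicates: int, seed) -> GeneDropResult:
    """Monte Carlo transmission of founder alleles through the pedigree.

    Every founder carries two unique alleles; every missing parent side of a
    non-founder contributes one unique allele (a draw from a phantom founder
    no one else descends from). Each non-founder inherits one uniformly
    chosen allele per known parent, independently per replicate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    alleles = np.empty((n_replicates, n, 2), dtype=np.int32)
    next_label = 0
    for i in range(n):
        for side, parent in ((0, pedigree.dam_idx[i]), (1, pedigree.sire_idx[i])):
            if parent < 0:
                alleles[:, i, side] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, size=n_replicates)
                alleles[:, i, side] = alleles[
                    np.arange(n_replicates), parent, pick
                ]
    return GeneDropResult(pedigree, alleles)


# ---------------------------------------------------------------------- #
# CSV I/O
# ---------------------------------------------------------------------- #

PEDIGREE_COLUMNS = ["id", "dam", "sire", "sex", "birth_date", "natal_group"]


def read_pedigree_csv(path) -> Pedigree:
    """Read the canonical pedigree CSV (``id,dam,sire,sex,birth_date,
    natal_group``; empty field = unknown) and validate it."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8-sig")
    missing = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree file missing column(s): {missing}")
    records = [
        PedigreeRecord(
            individual_id=row["id"],
            dam_id=row["dam"] or None,
            sire_id=row["sire"] or None,
            sex=row["sex"] or None,
            birth_date=_parse_date(row["birth_date"]),
            natal_group_id=row["natal_group"] or None,
        )
        for row in df.to_dict("records")
    ]
    return Pedigree.from_records(records)


def write_pedigree_csv(pedigree: Pedigree, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PEDIGREE_COLUMNS)
        for r in pedigree.records:
            w.writerow(
                [
                    r.individual_id,
                    r.dam_id or "",
                    r.sire_id or "",
                    r.sex or "",
                    r.birth_date.isoformat() if r.birth_date else "",
                    r.natal_group_id or "",
                ]
            )


def write_relatedness_long(matrix: RelatednessMatrix, path) -> None:
    """Emit the relatedness matrix in long format ``id1,id2,r`` (upper
    triangle including the diagonal)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id1", "id2", "r"])
        for i, idi in enumerate(matrix.ids):
            for j in range(i, len(matrix.ids)):
                w.writerow([idi, matrix.ids[j], repr(float(matrix.a[i, j]))])


def write_inbreeding_table(table: pd.DataFrame, path) -> None:
    table[["individual_id", "F"]].rename(columns={"individual_id": "id"}).to_csv(
        path, index=False
    )
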