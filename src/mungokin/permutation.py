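"""Constrained randomization nulls and one-tailed Monte Carlo tests.

Two null models, both preserving the observed mating structure:

* **Breeding pairs** — each mother keeps her attempt and her number of
  distinct sires *k*, but her mates are redrawn as *k* distinct males
  sampled uniformly from the adult males of her group at that attempt.
  Males may be reused across females.

* **Guard-female pairs** — within each oestrus event, the observed
  guard-female edges are reshuffled preserving every male's number of
  guarded females and every female's number of guards, with no duplicate
  edge, uniformly over valid configurations (configuration-model endpoint
  permutation with rejection of multi-edges; exact enumeration for small
  events that exhaust the retry budget).

The test statistic is the mean pairwise relatedness of the dyads; the
one-tailed Monte Carlo P-value for "lower relatedness than expected under
random pairing" uses the add-one convention

    p = (1 + #{null mean <= observed mean}) / (n_perms + 1)

so p is never zero and ties count against rejection.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import RelatednessMatrix
from .records import StudyDataset

__all__ = [
    "PermutationResult",
    "BreedingRandomization",
    "GuardRandomization",
    "permutation_test",
]

_ENUM_MAX_EDGES = 8  # exact enumeration bound for small events
_RETRY_CAP = 10_000


@dataclass
class PermutationResult:
    analysis_name: str
    observed_mean: float
    null_means: np.ndarray
    p_one_tailed: float
    n_perms: int
    seed: int | None
    n_dyads: int

    def to_json(self, path=None, include_null: bool = False) -> str:
        payload = {
            "analysis_name": self.analysis_name,
            "observed_mean": self.observed_mean,
            "null_mean_of_means": float(np.mean(self.null_means)),
            "p_one_tailed": self.p_one_tailed,
            "n_perms": self.n_perms,
            "seed": self.seed,
            "n_dyads": self.n_dyads,
        }
        if include_null:
            payload["null_means"] = [float(x) for x in self.null_means]
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


class BreedingRandomization:
    """Null model for mother-sire dyads under within-group random mating.

    Mothers whose candidate pool is smaller than their number of distinct
    sires cannot be randomized and are excluded from both the observed and
    the null sets (listed in :attr:`excluded`).
    """

    def __init__(
        self,
        dyads: pd.DataFrame,
        ds: StudyDataset,
        relmat: RelatednessMatrix,
    ):
        self.relmat = relmat
        self.excluded: list[tuple] = []
        self._slots: list[dict] = []
        observed: list[float] = []
        grouped = dyads.groupby(["attempt_id", "mother_id"], sort=True)
        pool_cache: dict[str, tuple[str, ...]] = {}
        for (attempt_id, mother_id), sub in grouped:
            if attempt_id not in pool_cache:
                pool_cache[attempt_id] = tuple(
                    sorted(ds.candidate_adults(attempt_id, "M"))
                )
            pool = pool_cache[attempt_id]
            sires = sorted(sub["sire_id"])
            k = len(sires)
            if len(pool) < k:
                self.excluded.append((attempt_id, mother_id, k, len(pool)))
                continue
            r_row = np.array(
                [relmat.relatedness(mother_id, m) for m in pool]
            )
            self._slots.append(
                {
                    "attempt_id": attempt_id,
                    "mother_id": mother_id,
                    "pool": pool,
                    "k": k,
                    "r_row": r_row,
                }
            )
            observed.extend(relmat.relatedness(mother_id, s) for s in sires)
        self.observed_values = np.asarray(observed)

    @property
    def n_dyads(self) -> int:
        return int(self.observed_values.size)

    @property
    def observed_mean(self) -> float:
        if self.n_dyads == 0:
            raise ValueError("no dyads to test")
        return float(self.observed_values.mean())

    def sample(self, rng: np.random.Generator) -> list[tuple[str, str, str]]:
        """One permuted dyad set as (attempt, mother, male) triples."""
        out = []
        for s in self._slots:
            pick = rng.choice(len(s["pool"]), size=s["k"], replace=False)
            out.extend(
                (s["attempt_id"], s["mother_id"], s["pool"][int(i)])
                for i in pick
            )
        return out

    def null_means(self, n_perms: int, rng: np.random.Generator) -> np.ndarray:
        """Vectorized null distribution of the mean dyad relatedness."""
        if self.n_dyads == 0:
            raise ValueError("no dyads to test")
        sums = np.zeros(n_perms)
        for s in self._slots:
            m, k, r_row = len(s["pool"]), s["k"], s["r_row"]
            if k == m:
                sums += r_row.sum()
            elif k == 1:
                idx = rng.integers(0, m, size=n_perms)
                sums += r_row[idx]
            else:
                keys = rng.random((n_perms, m))
                idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
                sums += r_row[idx].sum(axis=1)
        return sums / self.n_dyads


class GuardRandomization:
    """Degree-preserving reshuffle of guard-female edges within events."""

    def __init__(
        self,
        dyads: pd.DataFrame,
        relmat: RelatednessMatrix,
    ):
        self.relmat = relmat
        self.degenerate: list[str] = []
        self._events: list[dict] = []
        observed: list[float] = []
        for attempt_id, sub in dyads.groupby("attempt_id", sort=True):
            guards = list(sub["guard_id"])
            females = list(sub["female_id"])
            r_lookup = {
                (g, f): relmat.relatedness(g, f)
                for g in set(guards)
                for f in set(females)
            }
            event = {
                "attempt_id": attempt_id,
                "guards": guards,
                "females": females,
                "r": r_lookup,
                "configs": None,
            }
            if len(set(females)) == 1 or len(set(guards)) == 1:
                # only the observed configuration exists
                self.degenerate.append(attempt_id)
                event["fixed"] = True
            else:
                event["fixed"] = False
            self._events.append(event)
            observed.extend(r_lookup[(g, f)] for g, f in zip(guards, females))
        self.observed_values = np.asarray(observed)

    @property
    def n_dyads(self) -> int:
        return int(self.observed_values.size)

    @property
    def observed_mean(self) -> float:
        if self.n_dyads == 0:
            raise ValueError("no dyads to test")
        return float(self.observed_values.mean())

    @staticmethod
    def _valid(guards: list[str], females: list[str]) -> bool:
        return len(set(zip(guards, females))) == len(guards)

    def _enumerate(self, event: dict) -> list[tuple[str, ...]]:
        """All distinct valid female-endpoint sequences for a small event.

        Each simple configuration corresponds to the same number of
        sequences, so uniform sampling over this list is uniform over
        configurations.
        """
        if event["configs"] is None:
            seqs = {
                perm
                for perm in itertools.permutations(event["females"])
                if self._valid(event["guards"], list(perm))
            }
            event["configs"] = sorted(seqs)
        return event["configs"]

    def _shuffle_event(
        self, event: dict, rng: np.random.Generator
    ) -> list[str]:
        guards, females = event["guards"], event["females"]
        if event["fixed"]:
            return females
        n = len(females)
        for _ in range(_RETRY_CAP):
            perm = [females[i] for i in rng.permutation(n)]
            if self._valid(guards, perm):
                return perm
        configs = self._enumerate(event)  # small events only in practice
        return list(configs[rng.integers(0, len(configs))])

    def sample(self, rng: np.random.Generator) -> list[tuple[str, str, str]]:
        out = []
        for ev in self._events:
            perm = self._shuffle_event(ev, rng)
            out.extend(
                (ev["attempt_id"], g, f) for g, f in zip(ev["guards"], perm)
            )
        return out

    def null_means(self, n_perms: int, rng: np.random.Generator) -> np.ndarray:
        if self.n_dyads == 0:
            raise ValueError("no dyads to test")
        means = np.empty(n_perms)
        for p in range(n_perms):
            total = 0.0
            for ev in self._events:
                perm = self._shuffle_event(ev, rng)
                r = ev["r"]
                total += sum(r[(g, f)] for g, f in zip(ev["guards"], perm))
            means[p] = total / self.n_dyads
        return means


def permutation_test(
    randomization,
    n_perms: int = 10_000,
    seed: int | None = None,
    analysis_name: str = "permutation_test",
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """One-tailed Monte Carlo test for lower-than-random dyad relatedness."""
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    observed = randomization.observed_mean
    null = randomization.null_means(n_perms, rng)
    p = (1.0 + int(np.sum(null <= observed))) / (n_perms + 1.0)
    return PermutationResult(
        analysis_name=analysis_name,
        observed_mean=observed,
        null_means=null,
        p_one_tailed=float(p),
        n_perms=n_perms,
        seed=seed,
        n_dyads=randomization.n_dyads,
    )
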