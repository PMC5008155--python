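"""Constrained randomization engines and the Monte Carlo P-value."""

import itertools
from datetime import date

import numpy as np
import pandas as pd
import pytest

from mungokin.filters import breeding_pair_filter, guard_pair_filter
from mungokin.permutation import (
    BreedingRandomization,
    GuardRandomization,
    permutation_test,
)

from conftest import attempt, guard, make_dataset, member, parentage, rec


class _StubRandomization:
    """Fixed observed/null pair for exercising the P-value convention."""

    def __init__(self, observed, nulls):
        self._obs = observed
        self._nulls = np.asarray(nulls, dtype=float)
        self.n_dyads = 1

    @property
    def observed_mean(self):
        return self._obs

    def null_means(self, n_perms, rng):
        assert n_perms == len(self._nulls)
        return self._nulls


def _breeding_fixture():
    """Two females, three candidate males, graded relatedness.

    F1 and M1 are full sibs (r=0.5), M2 is their maternal half sib
    (r=0.25); symmetrically F2/M3 are full sibs and M2 is F2's half sib.
    Observed pairs: F1 x M2 (r=0.25) and F2 x M1 (r=0).
    """
    f95, f00, f02 = date(1995, 1, 1), date(2000, 3, 1), date(2002, 3, 2)
    peds = [
        rec("P", sex="F", born=f95),
        rec("Q", sex="M", born=f95),
        rec("R", sex="F", born=f95),
        rec("S", sex="M", born=f95),
        rec("F1", "P", "Q", "F", f00, "G1"),
        rec("M1", "P", "Q", "M", f00, "G1"),
        rec("M2", "R", "Q", "M", f00, "G1"),
        rec("F2", "R", "S", "F", f00, "G1"),
        rec("M3", "R", "S", "M", f00, "G1"),
        rec("K1", "F1", "M2", "F", f02, "G1"),
        rec("K2", "F2", "M1", "M", f02, "G1"),
    ]
    membership_ = [
        member("G1", "B1", i, 671, "M" if i.startswith("M") else "F", True, k)
        for k, i in enumerate(["F1", "F2", "M1", "M2", "M3"], start=1)
    ]
    attempts_ = [
        attempt("B0", "G1", date(2000, 1, 1), f00),
        attempt("B1", "G1", date(2002, 1, 1), f02),
    ]
    parentage_ = [
        parentage("F1", "B0", "P", "Q"),
        parentage("M1", "B0", "P", "Q"),
        parentage("M2", "B0", "R", "Q"),
        parentage("F2", "B0", "R", "S"),
        parentage("M3", "B0", "R", "S"),
        parentage("K1", "B1", "F1", "M2"),
        parentage("K2", "B1", "F2", "M1"),
    ]
    return make_dataset(
        pedigree_records=peds,
        membership=membership_,
        attempts=attempts_,
        parentage=parentage_,
    )


def _exact_breeding_null(ds, dyads, relmat):
    """Brute-force enumeration over all equally likely assignments."""
    slots = []
    for (a, mother), sub in dyads.groupby(["attempt_id", "mother_id"]):
        pool = sorted(ds.candidate_adults(a, "M"))
        k = len(sub)
        slots.append((mother, list(itertools.combinations(pool, k))))
    n_dyads = len(dyads)
    means = []
    for combo in itertools.product(*[c for _, c in slots]):
        total = sum(
            relmat.relatedness(mother, m)
            for (mother, _), chosen in zip(slots, combo)
            for m in chosen
        )
        means.append(total / n_dyads)
    return np.array(means)


class TestBreedingRandomization:
    def test_forced_assignment_returns_observed(self):
        ds = _breeding_fixture()
        m = ds.membership
        ds.membership = m[m.individual_id.isin(["F1", "M2"])]
        dyads = pd.DataFrame(
            [("B1", "F1", "M2")], columns=["attempt_id", "mother_id", "sire_id"]
        )
        relmat = ds.pedigree.relatedness_matrix()
        rand = BreedingRandomization(dyads, ds, relmat)
        out = rand.sample(np.random.default_rng(0))
        assert out == [("B1", "F1", "M2")]
        res = permutation_test(rand, n_perms=50, seed=1)
        assert res.p_one_tailed == 1.0  # degenerate null: ties count as <=

    def test_pool_smaller_than_multiplicity_excluded(self):
        ds = _breeding_fixture()
        m = ds.membership
        ds.membership = m[m.individual_id.isin(["F1", "M2"])]
        dyads = pd.DataFrame(
            [("B1", "F1", "M2"), ("B1", "F1", "M3")],
            columns=["attempt_id", "mother_id", "sire_id"],
        )
        relmat = ds.pedigree.relatedness_matrix()
        rand = BreedingRandomization(dyads, ds, relmat)
        assert rand.n_dyads == 0
        assert rand.excluded == [("B1", "F1", 2, 1)]
        with pytest.raises(ValueError, match="no dyads"):
            permutation_test(rand, n_perms=10, seed=0)

    def test_two_sires_uniform_over_pairs(self):
        """A female with two distinct sires among three candidates: each
        unordered candidate pair must appear with probability 1/3."""
        ds = _breeding_fixture()
        dyads = pd.DataFrame(
            [("B1", "F1", "M1"), ("B1", "F1", "M2")],
            columns=["attempt_id", "mother_id", "sire_id"],
        )
        relmat = ds.pedigree.relatedness_matrix()
        rand = BreedingRandomization(dyads, ds, relmat)
        rng = np.random.default_rng(42)
        counts = {}
        n = 30_000
        for _ in range(n):
            males = frozenset(m for _, _, m in rand.sample(rng))
            counts[males] = counts.get(males, 0) + 1
        assert len(counts) == 3
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 3) <= 4 * se

    def test_independent_assignments_across_females(self):
        ds = _breeding_fixture()
        dyads = pd.DataFrame(
            [("B1", "F1", "M2"), ("B1", "F2", "M1")],
            columns=["attempt_id", "mother_id", "sire_id"],
        )
        relmat = ds.pedigree.relatedness_matrix()
        rand = BreedingRandomization(dyads, ds, relmat)
        rng = np.random.default_rng(7)
        n = 20_000
        joint = np.zeros((3, 3))
        males = ["M1", "M2", "M3"]
        for _ in range(n):
            s = dict((f, m) for _, f, m in rand.sample(rng))
            joint[males.index(s["F1"]), males.index(s["F2"])] += 1
        joint /= n
        # independence: joint ~ outer product of uniform marginals
        assert np.abs(joint - 1 / 9).max() <= 5 * np.sqrt((1 / 9) * (8 / 9) / n)

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        ds = _breeding_fixture()
        relmat = ds.pedigree.relatedness_matrix()
        dyads, _ = breeding_pair_filter(ds)
        assert len(dyads) == 2
        exact = _exact_breeding_null(ds, dyads, relmat)
        rand = BreedingRandomization(dyads, ds, relmat)
        obs = rand.observed_mean
        p_exact = np.mean(exact <= obs)
        res = permutation_test(rand, n_perms=20_000, seed=5)
        se = np.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(res.p_one_tailed - p_exact) <= 3 * se

    def test_null_mean_matches_analytic_expectation(self):
        ds = _breeding_fixture()
        relmat = ds.pedigree.relatedness_matrix()
        dyads, _ = breeding_pair_filter(ds)
        rand = BreedingRandomization(dyads, ds, relmat)
        # each female contributes the mean relatedness to her pool
        expected = np.mean(
            [np.mean(s["r_row"]) for s in rand._slots for _ in range(s["k"])]
        )
        nulls = rand.null_means(20_000, np.random.default_rng(3))
        assert np.mean(nulls) == pytest.approx(expected, abs=4 * nulls.std()
                                               / np.sqrt(len(nulls)))


class TestGuardRandomization:
    def _guard_ds(self):
        ds = _breeding_fixture()
        return ds, ds.pedigree.relatedness_matrix()

    def test_single_edge_event_unchanged(self):
        ds, relmat = self._guard_ds()
        dyads = pd.DataFrame(
            [("B1", "M1", "F2")], columns=["attempt_id", "guard_id", "female_id"]
        )
        rand = GuardRandomization(dyads, relmat)
        assert rand.degenerate == ["B1"]
        assert rand.sample(np.random.default_rng(0)) == [("B1", "M1", "F2")]

    def test_two_by_two_matchings_equally_likely(self):
        ds, relmat = self._guard_ds()
        dyads = pd.DataFrame(
            [("B1", "M1", "F1"), ("B1", "M3", "F2")],
            columns=["attempt_id", "guard_id", "female_id"],
        )
        rand = GuardRandomization(dyads, relmat)
        rng = np.random.default_rng(9)
        n = 20_000
        hits = 0
        for _ in range(n):
            s = rand.sample(rng)
            if ("B1", "M1", "F1") in s:
                hits += 1
        assert abs(hits / n - 0.5) <= 4 * np.sqrt(0.25 / n)

    def test_no_duplicate_edges_when_guard_has_two_females(self):
        ds, relmat = self._guard_ds()
        dyads = pd.DataFrame(
            [
                ("B1", "M1", "F1"),
                ("B1", "M1", "F2"),
                ("B1", "M2", "F1"),
            ],
            columns=["attempt_id", "guard_id", "female_id"],
        )
        rand = GuardRandomization(dyads, relmat)
        rng = np.random.default_rng(1)
        for _ in range(2_000):
            s = rand.sample(rng)
            assert len(set(s)) == 3  # never the same (guard, female) twice
            degs = pd.DataFrame(s, columns=["a", "g", "f"])
            assert degs.groupby("g").size().to_dict() == {"M1": 2, "M2": 1}
            assert degs.groupby("f").size().to_dict() == {"F1": 2, "F2": 1}

    def test_exact_enumeration_agrees_with_sampling(self):
        ds, relmat = self._guard_ds()
        dyads = pd.DataFrame(
            [
                ("B1", "M1", "F1"),
                ("B1", "M1", "F2"),
                ("B1", "M2", "F1"),
            ],
            columns=["attempt_id", "guard_id", "female_id"],
        )
        rand = GuardRandomization(dyads, relmat)
        ev = rand._events[0]
        configs = rand._enumerate(ev)
        # M1 must take both females; M2 takes either: 2 configurations
        assert len(configs) == 2


class TestPValueConvention:
    def test_add_one_never_zero(self):
        stub = _StubRandomization(0.0, np.linspace(0.1, 1.0, 9_999))
        res = permutation_test(stub, n_perms=9_999, seed=0)
        assert res.p_one_tailed == pytest.approx(1 / 10_000)

    def test_degenerate_null_gives_p_one(self):
        stub = _StubRandomization(0.3, np.full(99, 0.3))
        res = permutation_test(stub, n_perms=99, seed=0)
        assert res.p_one_tailed == 1.0

    def test_result_fields(self):
        stub = _StubRandomization(0.5, np.array([0.4, 0.6, 0.5, 0.7]))
        res = permutation_test(stub, n_perms=4, seed=12, analysis_name="x")
        assert res.n_perms == 4 and res.seed == 12
        assert len(res.null_means) == 4
        assert 0 < res.p_one_tailed <= 1
        assert res.p_one_tailed == pytest.approx((1 + 2) / 5)

    def test_invalid_n_perms(self):
        with pytest.raises(ValueError):
            permutation_test(_StubRandomization(0, [0]), n_perms=0, seed=0)
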