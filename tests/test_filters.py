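"""Inclusion/exclusion rules, hand-enumerated on the two-group fixture."""

from datetime import date

import pytest

from mungokin.filters import (
    breeding_pair_filter,
    classify_guard_success,
    guard_pair_filter,
    identify_epp,
)
from mungokin.synth import SimulationParams, simulate

from conftest import attempt, guard, make_dataset, member, parentage, rec


class TestBreedingPairFilter:
    def test_hand_enumerated_counts(self, two_group_study):
        """Six distinct mother-sire dyads: the three founder-mother dyads
        fail criterion 1, the G2 dyad fails criterion 2 (0/2 candidate
        fathers parented), the two A2 dyads survive everything."""
        dyads, rep = breeding_pair_filter(two_group_study)
        assert rep.n_input == 6
        assert rep.per_criterion_pass_counts == {
            "1_mother_parents_assigned": 3,
            "2_candidate_fathers_80pct": 2,
            "3_within_group_sire": 6,
        }
        assert rep.n_retained == 2
        assert rep.dropped_by == {
            "1_mother_parents_assigned": 3,
            "2_candidate_fathers_80pct": 1,
        }
        assert set(map(tuple, dyads.to_numpy())) == {
            ("A2", "Y", "X"),
            ("A2", "W", "X"),
        }

    def test_multiple_pups_same_sire_is_one_dyad(self, two_group_study):
        # W has two pups by X in A2 but contributes a single (W, X) dyad
        dyads, _ = breeding_pair_filter(two_group_study)
        assert len(dyads[(dyads.mother_id == "W")]) == 1

    def test_natal_only_restricts_to_all_natal_attempts(self, two_group_study):
        dyads, rep = breeding_pair_filter(two_group_study, natal_only=True)
        assert rep.analysis_name.endswith("natal_only")
        assert rep.n_input == 2 and rep.n_retained == 2
        assert set(dyads.attempt_id) == {"A2"}

    def test_low_confidence_mother_dropped(self, two_group_study):
        ds = two_group_study
        p = ds.parentage.copy()
        # degrade Y's own parentage assignment below the 0.8 threshold
        p.loc[p.offspring_id == "Y", "dam_confidence"] = 0.5
        old = ds.parentage
        try:
            ds.parentage = p
            dyads, rep = breeding_pair_filter(ds)
            assert ("A2", "Y", "X") not in set(map(tuple, dyads.to_numpy()))
        finally:
            ds.parentage = old

    def test_eighty_percent_boundary(self):
        """10 candidate fathers with 7 parented (70%) fails criterion 2;
        raising it to 8 (80%) passes."""

        def build(n_parented):
            f00, f02 = date(2000, 3, 1), date(2002, 3, 2)
            peds = [rec("FF", sex="F", born=date(1995, 1, 1)),
                    rec("MF", sex="M", born=date(1995, 1, 1)),
                    rec("MOM", "FF", "MF", "F", f00, "G1")]
            membership_ = [member("G1", "B1", "MOM", 671, "F", True, 1)]
            parentage_ = [parentage("MOM", "B0", "FF", "MF")]
            for k in range(10):
                mid = f"M{k}"
                if k < n_parented:
                    peds.append(rec(mid, "FF", "MF", "M", f00, "G1"))
                    parentage_.append(parentage(mid, "B0", "FF", "MF"))
                else:
                    peds.append(rec(mid, sex="M", born=f00))
                membership_.append(member("G1", "B1", mid, 671, "M", True, k + 1))
            parentage_.append(parentage("KID", "B1", "MOM", "M9"))
            peds.append(rec("KID", "MOM", "M9", "F", f02, "G1"))
            attempts_ = [
                attempt("B0", "G1", date(2000, 1, 1), f00),
                attempt("B1", "G1", date(2002, 1, 1), f02),
            ]
            return make_dataset(
                pedigree_records=peds,
                membership=membership_,
                attempts=attempts_,
                parentage=parentage_,
            )

        _, rep70 = breeding_pair_filter(build(7))
        assert rep70.per_criterion_pass_counts["2_candidate_fathers_80pct"] == 0
        _, rep80 = breeding_pair_filter(build(8))
        assert rep80.per_criterion_pass_counts["2_candidate_fathers_80pct"] > 0

    def test_idempotent_and_order_independent(self, two_group_study):
        d1, r1 = breeding_pair_filter(two_group_study)
        ds = two_group_study
        old = ds.parentage
        try:
            ds.parentage = old.sample(frac=1, random_state=3)
            d2, r2 = breeding_pair_filter(ds)
        finally:
            ds.parentage = old
        assert set(map(tuple, d1.to_numpy())) == set(map(tuple, d2.to_numpy()))
        assert r1.per_criterion_pass_counts == r2.per_criterion_pass_counts

    def test_report_reconciles(self, two_group_study):
        _, rep = breeding_pair_filter(two_group_study)
        assert rep.n_input == rep.n_retained + sum(rep.dropped_by.values())


class TestGuardPairFilter:
    def test_hand_enumerated_counts(self, two_group_study):
        dyads, rep = guard_pair_filter(two_group_study)
        assert rep.n_input == 6
        assert rep.per_criterion_pass_counts == {
            "1_guard_parents_assigned": 2,
            "2_candidate_females_80pct": 2,
        }
        assert set(map(tuple, dyads.to_numpy())) == {
            ("A2", "X", "Y"),
            ("A2", "Z", "W"),
        }

    def test_natal_only(self, two_group_study):
        dyads, rep = guard_pair_filter(two_group_study, natal_only=True)
        assert rep.n_input == 2 and rep.n_retained == 2

    def test_unparented_guard_dropped(self, two_group_study):
        dyads, _ = guard_pair_filter(two_group_study)
        assert "MC" not in set(dyads.guard_id)


class TestGuardSuccess:
    def test_classification(self, two_group_study):
        rows = classify_guard_success(two_group_study)
        got = {
            (r.attempt_id, r.guard_id, r.female_id): r.success
            for r in rows.itertuples()
        }
        assert got == {
            ("A1", "MC", "FB"): False,
            ("A2", "X", "Y"): True,
            ("A2", "Z", "W"): False,
            ("A3", "MD", "V"): True,
            ("A3", "ME", "V"): False,
        }

    def test_female_without_window_offspring_excluded(self, two_group_study):
        rows = classify_guard_success(two_group_study)
        assert not ((rows.guard_id == "MD") & (rows.female_id == "FD")).any()

    def test_birth_outside_window_not_attributed(self, two_group_study):
        """Shifting the A2 births to 90 days post-oestrus removes them from
        the 40-80 day attribution window entirely."""
        ds = two_group_study
        old = ds.attempts
        try:
            a = old.copy()
            a.loc[a.attempt_id == "A2", "birth_date"] = date(2002, 4, 1)
            ds.attempts = a
            rows = classify_guard_success(ds)
            assert not (rows.attempt_id == "A2").any()
        finally:
            ds.attempts = old


class TestIdentifyEpp:
    def test_single_within_group_epp(self, two_group_study):
        relmat = two_group_study.pedigree.relatedness_matrix()
        rows, rep = identify_epp(two_group_study, relmat)
        assert rep.n_input == 3  # the three unsuccessful guard rows
        assert len(rows) == 1
        r = rows.iloc[0]
        assert (r.guard_id, r.female_id, r.epp_male_id) == ("Z", "W", "X")
        assert r.epp_scope == "within_group"
        assert r.guard_r == 0.0  # Z and W descend from unrelated founders
        assert r.epp_r == 0.5  # X and W are full sibs

    def test_natal_only_restricts_to_all_natal_male_attempts(self, two_group_study):
        relmat = two_group_study.pedigree.relatedness_matrix()
        rows, rep = identify_epp(two_group_study, relmat, natal_only=True)
        # only A2 has an all-natal adult male roster
        assert rep.n_input == 1
        assert set(rows.attempt_id) == {"A2"}

    def test_two_epp_identities_excluded(self, two_group_study):
        ds = two_group_study
        old = ds.parentage
        try:
            p = old.copy()
            # give W's second pup a different non-guard sire
            p.loc[p.offspring_id == "P3", "sire_id"] = "MC"
            ds.parentage = p
            relmat = ds.pedigree.relatedness_matrix()
            rows, rep = identify_epp(ds, relmat)
            assert len(rows) == 0
            assert rep.per_criterion_pass_counts["4_single_epp_identity"] == 2
        finally:
            ds.parentage = old

    def test_extra_group_scope(self, two_group_study):
        """A sire absent from the attempt roster is an extra-group EPP male."""
        ds = two_group_study
        old_p, old_m = ds.parentage, ds.membership
        try:
            p = old_p.copy()
            # Z (parented, in G1) sires W's pups but is removed from the
            # A2 roster, making him extra-group for that attempt
            m = old_m[~((old_m.attempt_id == "A2") &
                        (old_m.individual_id == "Z"))]
            ds.parentage, ds.membership = p, m
            # guard becomes X on W (unsuccessful: pups sired by Z)
            g = ds.guards.copy()
            g.loc[(g.attempt_id == "A2") & (g.female_id == "W"),
                  "guard_id"] = "X"
            p.loc[p.offspring_id.isin(["P2", "P3"]), "sire_id"] = "Z"
            old_g = ds.guards
            ds.guards = g
            try:
                relmat = ds.pedigree.relatedness_matrix()
                rows, _ = identify_epp(ds, relmat)
                w_row = rows[rows.female_id == "W"].iloc[0]
                assert w_row.epp_male_id == "Z"
                assert w_row.epp_scope == "extra_group"
            finally:
                ds.guards = old_g
        finally:
            ds.parentage, ds.membership = old_p, old_m


class TestOnGeneratorOutput:
    def test_full_confidence_rows_with_parented_mothers_pass(self):
        """With assignment confidence 1 every dyad whose mother is
        pedigree-born passes criterion 1, and nothing passes when the
        confidence is degraded below the threshold."""
        ds, _ = simulate(SimulationParams(n_groups=3, n_attempts_per_group=8),
                         seed=11)
        parented = ds.confidently_parented()
        _, rep = breeding_pair_filter(ds)
        n_parented_mothers = (
            ds.parentage[["attempt_id", "dam_id", "sire_id"]]
            .drop_duplicates()["dam_id"]
            .isin(parented)
            .sum()
        )
        assert rep.per_criterion_pass_counts["1_mother_parents_assigned"] == (
            n_parented_mothers
        )
        low = ds
        old = low.parentage
        try:
            p = old.copy()
            p["dam_confidence"] = 0.5
            low.parentage = p
            _, rep_low = breeding_pair_filter(low)
            assert rep_low.n_input == 0 or rep_low.per_criterion_pass_counts[
                "1_mother_parents_assigned"
            ] == 0
        finally:
            low.parentage = old
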