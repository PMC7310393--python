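"""Connectedness coefficients: tallies, GS, BOD/AN_POP, harmonic means."""

import itertools

import numpy as np
import pytest

from amaci import (
    Pedigree,
    SireOffspringCounts,
    an_pop,
    bod,
    build_report,
    genetic_similarity,
    harmonic_mean_sire,
    herd_genetic_similarity,
    herd_harmonic_mean,
    tally_mgs_grandoffspring,
    tally_sire_offspring,
)
from conftest import make_phenotypes


@pytest.fixture
def toy():
    """Two populations; s1 is a common bull, s2/s3 national; g is the
    maternal grand-sire of the B-records via dam dm."""
    ped = Pedigree.from_records(
        [("g", "", ""), ("s1", "", ""), ("s2", "", ""), ("s3", "", ""),
         ("dm", "g", "")]
        + [(f"x{i}", "s1", "", 1990, "") for i in range(5)]
        + [(f"y{i}", "s2", "", 1990, "") for i in range(5)]
        + [(f"z{i}", "s3", "dm", 1990, "") for i in range(4)]
    )
    rows = (
        [(f"x{i}", "A", "M", "hA", "c1", "", 100.0) for i in range(3)]
        + [(f"x{i}", "B", "M", "hB", "c2", "", 100.0) for i in range(3, 5)]
        + [(f"y{i}", "A", "F", "hA", "c1", "", 100.0) for i in range(5)]
        + [(f"z{i}", "B", "F", "hB", "c2", "dm", 100.0) for i in range(4)]
    )
    return ped, make_phenotypes(rows)


class TestTallies:
    def test_sire_counts_by_population(self, toy):
        ped, phen = toy
        counts = {c.sire_id: c for c in tally_sire_offspring(phen, ped)}
        assert counts["s1"].counts == {"A": 3, "B": 2}
        assert counts["s2"].counts == {"A": 5}
        assert counts["s3"].counts == {"B": 4}
        assert counts["s1"].populations() == {"A", "B"}

    def test_unknown_sire_contributes_nothing(self):
        ped = Pedigree.from_records([("w", "", "")])
        phen = make_phenotypes([("w", "A", "M", "h", "c", "", 1.0)])
        assert tally_sire_offspring(phen, ped) == []

    def test_phenotyped_animal_missing_from_pedigree_errors(self, toy):
        ped, phen = toy
        bad = phen.copy()
        bad.loc[0, "animal"] = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            tally_sire_offspring(bad, ped)

    def test_mgs_credit_through_dam(self, toy):
        ped, phen = toy
        counts = {c.sire_id: c for c in tally_mgs_grandoffspring(phen, ped)}
        assert counts["g"].counts == {"B": 4}

    def test_record_with_unknown_dam_gives_no_mgs(self, toy):
        ped, phen = toy
        counts = tally_mgs_grandoffspring(phen, ped)
        ids = {c.sire_id for c in counts}
        assert ids == {"g"}  # only the z-records have a pedigree dam


class TestGeneticSimilarity:
    def test_hand_worked_ratio(self, toy):
        ped, phen = toy
        counts = tally_sire_offspring(phen, ped)
        assert genetic_similarity(counts, "A", "B") == pytest.approx(5 / 14)

    def test_no_common_bulls_gives_zero(self):
        counts = [SireOffspringCounts("s2", {"A": 5}),
                  SireOffspringCounts("s3", {"B": 4})]
        assert genetic_similarity(counts, "A", "B") == 0.0

    def test_every_bull_common_gives_one(self):
        counts = [SireOffspringCounts("s", {"A": 2, "B": 3})]
        assert genetic_similarity(counts, "A", "B") == 1.0

    def test_empty_pair_is_missing_not_zero(self):
        counts = [SireOffspringCounts("s", {"C": 2})]
        assert genetic_similarity(counts, "A", "B") is None

    def test_symmetry(self, toy):
        ped, phen = toy
        counts = tally_sire_offspring(phen, ped)
        assert genetic_similarity(counts, "A", "B") == (
            genetic_similarity(counts, "B", "A")
        )


class TestHerdGS:
    def test_hand_worked_herd_ratio(self):
        counts = [
            SireOffspringCounts("s1", {"A": 4, "B": 6},
                                {("h", "A"): 4, ("hb", "B"): 6}),
            SireOffspringCounts("s2", {"A": 2}, {("h", "A"): 2}),
            SireOffspringCounts("s4", {"B": 10}, {("hb", "B"): 10}),
        ]
        assert herd_genetic_similarity(counts, "h", "B") == pytest.approx(10 / 22)

    def test_home_bred_only_herd_is_zero(self):
        counts = [SireOffspringCounts("s", {"A": 3}, {("h", "A"): 3}),
                  SireOffspringCounts("t", {"B": 5})]
        assert herd_genetic_similarity(counts, "h", "B") == 0.0

    def test_tot_is_mean_of_cb_and_cmgs(self):
        assert (0.4 + 0.2) / 2 == pytest.approx(0.3)  # definitionally trivial


class TestBOD:
    @pytest.mark.parametrize(
        "n_pops_used,expected",
        [(2, 0.25), (3, 0.375), (5, 0.625)],
    )
    def test_balanced_over_k_of_8(self, n_pops_used, expected):
        counts = SireOffspringCounts(
            "s", {f"P{j}": 10 for j in range(n_pops_used)}
        )
        assert bod(counts, 8) == pytest.approx(expected)
        assert an_pop(bod(counts, 8), 8) == pytest.approx(n_pops_used)

    def test_fully_balanced_is_one(self):
        counts = SireOffspringCounts("s", {f"P{j}": 7 for j in range(8)})
        assert bod(counts, 8) == pytest.approx(1.0)

    def test_single_population_floor(self):
        counts = SireOffspringCounts("s", {"P0": 40})
        assert bod(counts, 8) == pytest.approx(0.125)
        assert an_pop(0.125, 8) == pytest.approx(1.0)

    def test_zero_offspring_errors(self):
        with pytest.raises(ValueError):
            bod(SireOffspringCounts("s", {}), 8)

    def test_scale_invariance(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 9))
            counts = {f"P{j}": int(rng.integers(1, 50)) for j in range(k)}
            c1 = SireOffspringCounts("s", counts)
            c2 = SireOffspringCounts("s", {p: 7 * n for p, n in counts.items()})
            assert bod(c1, 8) == pytest.approx(bod(c2, 8))


class TestHarmonicMean:
    def test_equal_sizes(self):
        assert harmonic_mean_sire(10, 10) == pytest.approx(10.0)

    def test_unequal(self):
        assert harmonic_mean_sire(2, 6) == pytest.approx(3.0)

    def test_dominated_by_smaller(self):
        assert harmonic_mean_sire(1, 1000) == pytest.approx(2000 / 1001)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            harmonic_mean_sire(0, 5)

    def test_herd_sum_hand_worked(self):
        counts = [
            SireOffspringCounts("s1", {"A": 4, "B": 6},
                                {("h", "A"): 4, ("b1", "B"): 6}),
            SireOffspringCounts("s2", {"A": 2, "C": 2},
                                {("h", "A"): 2, ("c1", "C"): 2}),
        ]
        assert herd_harmonic_mean(counts, "h") == pytest.approx(4.8 + 2.0)

    def test_herd_without_common_bulls_is_zero(self):
        counts = [SireOffspringCounts("s", {"A": 3}, {("h", "A"): 3})]
        assert herd_harmonic_mean(counts, "h") == 0.0

    def test_homogeneous_degree_one(self):
        counts = [
            SireOffspringCounts("s1", {"A": 4, "B": 6},
                                {("h", "A"): 4, ("b1", "B"): 6}),
        ]
        doubled = [
            SireOffspringCounts("s1", {"A": 8, "B": 12},
                                {("h", "A"): 8, ("b1", "B"): 12}),
        ]
        assert herd_harmonic_mean(doubled, "h") == pytest.approx(
            2 * herd_harmonic_mean(counts, "h")
        )


class TestReport:
    def test_single_link_counts(self, toy):
        ped, phen = toy
        report = build_report(phen, ped, populations=["A", "B", "C"])
        assert report.n_unique_cb == 1
        pair = report.cb_pairs.set_index(["pop_a", "pop_b"])
        assert pair.loc[("A", "B"), "n_common"] == 1
        assert pair.loc[("A", "C"), "n_common"] == 0

    def test_no_exchange_means_no_cb(self):
        ped = Pedigree.from_records(
            [("sA", "", ""), ("sB", "", ""), ("u", "sA", ""), ("v", "sB", "")]
        )
        phen = make_phenotypes(
            [("u", "A", "M", "hA", "c", "", 1.0), ("v", "B", "M", "hB", "c", "", 1.0)]
        )
        report = build_report(phen, ped)
        assert report.n_unique_cb == 0
        assert report.cb_pairs["gs"].iloc[0] == 0.0

    def test_cmgs_also_cb_crosstab(self):
        # sire g has own offspring in A and B, and grand-offspring in A and B
        ped = Pedigree.from_records(
            [("g", "", ""), ("d1", "g", ""), ("d2", "g", ""),
             ("o1", "g", ""), ("o2", "g", ""),
             ("w1", "", "d1"), ("w2", "", "d2")]
        )
        phen = make_phenotypes(
            [("o1", "A", "M", "hA", "c", "", 1.0),
             ("o2", "B", "M", "hB", "c", "", 1.0),
             ("w1", "A", "F", "hA", "c", "d1", 1.0),
             ("w2", "B", "F", "hB", "c", "d2", 1.0)]
        )
        report = build_report(phen, ped)
        assert report.n_unique_cb == 1
        assert report.cmgs_also_cb.loc[2, "yes"] == 1
        assert report.sire_table["is_cb"].sum() == 1

    def test_brute_force_matches_on_random_fixture(self, rng):
        # random records; recompute GS and BOD by raw enumeration
        pops = ["A", "B", "C"]
        sires = [f"s{i}" for i in range(8)]
        ped_rows = [(s, "", "") for s in sires]
        rows = []
        for i in range(300):
            s = sires[rng.integers(len(sires))]
            ped_rows.append((f"k{i}", s, ""))
            p = pops[rng.integers(3)]
            rows.append((f"k{i}", p, "M", f"h{p}{rng.integers(3)}", "c", "", 1.0))
        ped = Pedigree.from_records(ped_rows)
        phen = make_phenotypes(rows)
        report = build_report(phen, ped, populations=pops)

        sire_of = {f"k{i}": ped.parents_of(f"k{i}")[0] for i in range(300)}
        for a, b in itertools.combinations(pops, 2):
            num = den = 0
            for s in sires:
                na = sum(1 for r in rows if sire_of[r[0]] == s and r[1] == a)
                nb = sum(1 for r in rows if sire_of[r[0]] == s and r[1] == b)
                if na + nb:
                    den += na + nb
                    if na and nb:
                        num += na + nb
            expected = num / den if den else None
            got = report.cb_pairs.set_index(["pop_a", "pop_b"]).loc[(a, b), "gs"]
            assert got == pytest.approx(expected)

        for s in sires:
            n = {p: sum(1 for r in rows if sire_of[r[0]] == s and r[1] == p)
                 for p in pops}
            tot = sum(n.values())
            nbar = tot / 3
            expected_bod = 1 - sum(abs(v - nbar) for v in n.values()) / (2 * tot)
            got = report.sire_table.set_index("sire").loc[s, "bod"]
            assert got == pytest.approx(expected_bod)

    def test_an_pop_above_one_for_common_bulls(self, toy):
        ped, phen = toy
        report = build_report(phen, ped)
        cb = report.sire_table[report.sire_table["is_cb"]]
        assert (cb["an_pop"] > 1).all()
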