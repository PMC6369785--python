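"""Contingency recoding, the elimination statistic, and coding sensitivity."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from cyclophylo.contingency import (
    DependencyError,
    DependencyGraph,
    coding_sensitivity,
    elimination_statistic,
    recode_contingent,
    recode_flat,
)
from cyclophylo.matrix import CellValue
from cyclophylo.parsimony import SearchSettings

from conftest import make_matrix


def chain_graph():
    return DependencyGraph([("c1", frozenset("1"), "c2"), ("c2", frozenset("1"), "c3")])


class TestRecodeContingent:
    def test_unlicensed_controller_makes_dependent_inapplicable(self):
        m = make_matrix({"A": "01"})
        g = DependencyGraph([("c1", frozenset("1"), "c2")])
        out = recode_contingent(m, g)
        assert out.cells[0][1].is_inapplicable

    def test_licensed_controller_leaves_dependent_unchanged(self):
        m = make_matrix({"A": "11"})
        g = DependencyGraph([("c1", frozenset("1"), "c2")])
        out = recode_contingent(m, g)
        assert out.cells[0][1].states == frozenset("1")

    def test_missing_controller_propagates_missing(self):
        m = make_matrix({"A": "?1"})
        g = DependencyGraph([("c1", frozenset("1"), "c2")])
        out = recode_contingent(m, g)
        assert out.cells[0][1].is_missing

    def test_chain_cascades_inapplicable(self):
        m = make_matrix({"A": "011"})
        out = recode_contingent(m, chain_graph())
        assert out.cells[0][1].is_inapplicable
        assert out.cells[0][2].is_inapplicable

    def test_chain_recode_count_matches_enumeration(self, rng):
        # brute-force oracle: walk each taxon's controller chain upward and
        # count (taxon, dependent) pairs with an unlicensed ancestor
        g = chain_graph()
        for _ in range(30):
            rows = {
                f"T{i}": "".join(rng.choice("01") for _ in range(3))
                for i in range(6)
            }
            m = make_matrix(rows)
            out = recode_contingent(m, g)

            def unlicensed_ancestor(ti, ch):
                dep = g.controller_of(ch)
                while dep is not None:
                    ctrl, lic = dep
                    cv = m.cell(f"T{ti}", ctrl)
                    if cv.is_states and not (cv.states & lic):
                        return True
                    dep = g.controller_of(ctrl)
                return False

            expected = sum(
                unlicensed_ancestor(i, ch)
                for i in range(6)
                for ch in ("c2", "c3")
            )
            observed = sum(
                cv.is_inapplicable for row in out.cells for cv in row
            )
            assert observed == expected

    def test_graph_referencing_absent_characters_rejected(self):
        m = make_matrix({"A": "01"})
        g = DependencyGraph([("c1", frozenset("1"), "c9")])
        with pytest.raises(DependencyError):
            recode_contingent(m, g)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_idempotent(self, seed):
        rng = random.Random(seed)
        rows = {
            f"T{i}": "".join(rng.choice("01?") for _ in range(4)) for i in range(5)
        }
        m = make_matrix(rows)
        g = DependencyGraph(
            [("c1", frozenset("1"), "c2"), ("c2", frozenset("1"), "c3"),
             ("c1", frozenset("1"), "c4")]
        )
        once = recode_contingent(m, g)
        twice = recode_contingent(once, g)
        assert once.equal_cells(twice)


class TestRecodeFlat:
    def test_round_trip_restores_flat_original(self, rng):
        # a flat-coded matrix (absences scored '0') with no missing cells is
        # a fixed point of contingency recoding followed by flat recoding
        g = chain_graph()
        for _ in range(20):
            rows = {
                f"T{i}": "".join(rng.choice("01") for _ in range(3))
                for i in range(5)
            }
            flat0 = recode_flat(recode_contingent(make_matrix(rows), g), g)
            round_trip = recode_flat(recode_contingent(flat0, g), g)
            assert round_trip.equal_cells(flat0)
            # and every cell touched by the round trip is the fill state
            cont = recode_contingent(flat0, g)
            for i in range(5):
                for j in range(3):
                    if cont.cells[i][j].is_inapplicable:
                        assert round_trip.cells[i][j].states == frozenset("0")
                    else:
                        assert round_trip.cells[i][j] == cont.cells[i][j]

    def test_no_inapplicable_cells_returned_unchanged(self):
        m = make_matrix({"A": "011", "B": "111"})
        out = recode_flat(m, chain_graph())
        assert out.equal_cells(m)

    def test_cells_changed_equals_inapplicable_dependent_count(self, rng):
        g = chain_graph()
        rows = {
            f"T{i}": "".join(rng.choice("01") for _ in range(3)) for i in range(8)
        }
        cont = recode_contingent(make_matrix(rows), g)
        flat = recode_flat(cont, g)
        n_inapp = sum(cv.is_inapplicable for row in cont.cells for cv in row)
        n_changed = sum(
            a != b
            for ra, rb in zip(cont.cells, flat.cells)
            for a, b in zip(ra, rb)
        )
        assert n_changed == n_inapp

    def test_orphan_inapplicable_reported(self):
        m = make_matrix({"A": "-1"})
        g = DependencyGraph([("c1", frozenset("1"), "c2")])
        out = recode_flat(m, g)  # c1 has no controller: left unchanged
        assert out.cells[0][0].is_inapplicable
        with pytest.raises(DependencyError):
            recode_flat(m, g, on_orphan="error")


class TestEliminationStatistic:
    def test_seventy_percent_taxon(self):
        # 10 flat-codable characters, 7 recoded inapplicable -> 0.70
        flat = make_matrix({"A": "1111111111"})
        cont = make_matrix({"A": "-------111"})
        report = elimination_statistic(flat, cont)
        assert report.per_taxon["A"] == (10, 7, 0.70)

    def test_empty_dependency_graph_all_zero(self):
        m = make_matrix({"A": "0101", "B": "1010"})
        cont = recode_contingent(m, DependencyGraph([]))
        report = elimination_statistic(m, cont)
        assert all(v[2] == 0.0 for v in report.per_taxon.values())

    def test_group_mean_is_unweighted_mean_and_percent_rounds(self):
        flat = make_matrix({"A": "1111", "B": "1111"})
        cont = make_matrix({"A": "--11", "B": "---1"})
        report = elimination_statistic(
            flat, cont, groups={"grp": ["A", "B"]}
        )
        assert report.group_means["grp"] == pytest.approx((0.5 + 0.75) / 2)
        assert report.percent("grp") == 62
        lo = min(report.fraction("A"), report.fraction("B"))
        hi = max(report.fraction("A"), report.fraction("B"))
        assert lo <= report.group_means["grp"] <= hi

    def test_unknown_group_member_rejected(self):
        m = make_matrix({"A": "11"})
        with pytest.raises(ValueError, match="unknown"):
            elimination_statistic(m, m, groups={"g": ["Z"]})

    def test_invariant_to_reordering(self, rng):
        g = chain_graph()
        rows = {
            f"T{i}": "".join(rng.choice("01?") for _ in range(3))
            for i in range(6)
        }
        m = make_matrix(rows)
        cont = recode_contingent(m, g)
        base = elimination_statistic(m, cont)
        taxa = list(m.taxa)
        chars = list(m.characters)
        rng.shuffle(taxa)
        rng.shuffle(chars)
        m2 = m.reorder(taxa, chars)
        cont2 = cont.reorder(taxa, chars)
        perm = elimination_statistic(m2, cont2)
        assert base.per_taxon == perm.per_taxon

    def test_informative_cells_never_increase_under_contingency(self, rng):
        g = chain_graph()
        for _ in range(10):
            rows = {
                f"T{i}": "".join(rng.choice("01") for _ in range(3))
                for i in range(6)
            }
            m = make_matrix(rows)
            cont = recode_contingent(m, g)
            assert cont.n_state_cells() <= m.n_state_cells()
            assert cont.n_informative() <= m.n_informative()


class TestCodingSensitivity:
    def test_no_dependents_identical_tree_sets(self, rng):
        rows = {t: "".join(rng.choice("01") for _ in range(8)) for t in "ABCDEF"}
        m = make_matrix(rows)
        rep = coding_sensitivity(
            m, DependencyGraph([]),
            SearchSettings(n_replicates=3, swap="SPR", seed=1),
            clade=["A", "B"], clade_name="AB",
        )
        assert rep.score_contingency == rep.score_flat
        assert rep.contingency_only_splits == frozenset()
        assert rep.flat_only_splits == frozenset()

    def test_report_fields_always_populated(self, rng):
        rows = {t: "".join(rng.choice("01") for _ in range(6)) for t in "ABCDE"}
        m = make_matrix(rows)
        rep = coding_sensitivity(
            m, DependencyGraph([("c1", frozenset("1"), "c2")]),
            SearchSettings(n_replicates=2, swap="NNI", seed=0),
            clade=["A", "B"], clade_name="crown",
        )
        assert rep.clade_name == "crown"
        assert isinstance(rep.monophyletic_contingency, bool)
        assert isinstance(rep.monophyletic_flat, bool)

    def test_engineered_case_flips_monophyly_verdict(self):
        # Soft-bodied crown taxon H shares structural absences with the
        # soft-bodied outgroups O1, O2: a skeletal controller c1 (present in
        # L and the armoured clade G1-G4) licenses six skeletal detail
        # characters c2-c7.  Scoring those details "absent" (flat coding)
        # stacks six pseudo-characters uniting {H, O1, O2} against the two
        # genuine crown synapomorphies (c8, c9 uniting H with L); coding
        # them inapplicable removes that additive weight.
        block = "111111"
        rows = {
            "O1": "0" + "------" + "00" + "0" + "00",
            "O2": "0" + "------" + "00" + "0" + "00",
            "H":  "0" + "------" + "11" + "1" + "00",
            "L":  "1" + block + "11" + "1" + "00",
            "G1": "1" + block + "00" + "1" + "11",
            "G2": "1" + block + "00" + "1" + "11",
            "G3": "1" + block + "00" + "1" + "11",
            "G4": "1" + block + "00" + "1" + "11",
        }
        m = make_matrix(rows)
        g = DependencyGraph(
            [("c1", frozenset("1"), f"c{j}") for j in range(2, 8)]
        )
        rep = coding_sensitivity(
            m, g, SearchSettings(n_replicates=6, swap="SPR", seed=3),
            clade=["H", "L"], clade_name="crown pair",
        )
        assert rep.monophyletic_contingency
        assert not rep.monophyletic_flat
        # verdicts recomputed independently by bipartition membership
        clade = frozenset(["H", "L"])
        assert clade in rep.consensus_contingency.bipartitions()
        assert clade not in rep.consensus_flat.bipartitions()
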