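"""Feature grouping, candidate assignment, MS2 annotation, network export."""

import numpy as np
import pytest

from dissmet.annotate import (
    Ms1Feature,
    Ms2Peak,
    annotate_fragments,
    assign_candidates,
    build_network,
    group_features,
    identify,
    sequential_losses,
    validate_printed_fragments,
)
from dissmet.chem import Formula

from conftest import PARENT


def _group_key(groups):
    return {frozenset(f.feature_id for f in g.features) for g in groups}


class TestGrouping:
    def test_fixture_groups_into_twenty_metabolites(self, table1):
        groups = group_features(table1.features)
        assert len(groups) == 20

    def test_grouping_is_a_partition(self, table1):
        groups = group_features(table1.features)
        seen = [f.feature_id for g in groups for f in g.features]
        assert sorted(seen) == sorted(f.feature_id for f in table1.features)
        assert len(seen) == len(set(seen))

    def test_grouping_is_order_independent(self, table1):
        baseline = _group_key(group_features(table1.features))
        rng = np.random.default_rng(42)
        for _ in range(3):
            shuffled = list(table1.features)
            rng.shuffle(shuffled)
            assert _group_key(group_features(shuffled)) == baseline

    def test_dual_polarity_rows_merge(self, table1):
        groups = group_features(table1.features)
        key = _group_key(groups)
        for pair in (
            {"M0p", "M0n"}, {"M1p", "M1n"}, {"M5p", "M5n"},
            {"M10p", "M10n"}, {"M13p", "M13n"}, {"M16p", "M16n"}, {"M17p", "M17n"},
        ):
            assert frozenset(pair) in key

    def test_positional_isomers_stay_separate(self, table1):
        # same composition (C11H14O5) but 1.85 min apart in retention time
        isomers = [f for f in table1.features if f.feature_id in ("M2", "M6")]
        assert len(_group_key(group_features(isomers))) == 2

    def test_single_feature_forms_one_group(self, table1):
        one = [table1.features[0]]
        groups = group_features(one)
        assert len(groups) == 1 and len(groups[0].features) == 1


class TestAssignCandidates:
    def _group_of(self, table1, fid):
        groups = group_features(table1.features)
        return next(g for g in groups if fid in {f.feature_id for f in g.features})

    def test_parent_group_identified_at_depth_zero(self, table1, closure_index):
        group = self._group_of(table1, "M0p")
        top = assign_candidates(group, closure_index)[0]
        assert top.formula == PARENT and top.path.depth == 0

    def test_ester_cleavage_product_at_depth_one(self, table1, closure_index):
        group = self._group_of(table1, "M1p")
        top = assign_candidates(group, closure_index)[0]
        assert top.formula == Formula.parse("C23H32O15")
        assert top.path.rules == ("sinapoyl ester cleavage",)

    def test_decoy_mass_goes_unidentified(self, closure_index):
        decoy = Ms1Feature("D0", 9.0, "+", "[M+H]+", 500.00000)
        groups = group_features([decoy])
        assert assign_candidates(groups[0], closure_index) == []

    def test_fixture_recovery_rates(self, table1, closure_index):
        groups = group_features(table1.features)
        hits5 = hits7 = 0
        for g in groups:
            truth = table1.neutral_formulas[g.features[0].feature_id]
            c5 = assign_candidates(g, closure_index, 5.0)
            c7 = assign_candidates(g, closure_index, 7.0)
            hits5 += bool(c5) and c5[0].formula == truth
            hits7 += bool(c7) and c7[0].formula == truth
        assert hits5 >= 19
        assert hits7 == 20

    def test_candidate_ppms_respect_gate(self, table1, closure_index):
        for g in group_features(table1.features):
            for cand in assign_candidates(g, closure_index, 5.0):
                assert all(abs(p) <= 5.0 for p in cand.ppms)


class TestFragmentAnnotation:
    def test_base_peak_of_deprotonated_parent(self):
        out = annotate_fragments(PARENT, "[M-H]-", [Ms2Peak(205.05049, 100.0)])
        (a,) = out
        assert a.formula == Formula.parse("C11H9O4")
        assert a.ppm == pytest.approx(-0.7, abs=0.05)
        assert a.status == "sub-formula-valid"

    def test_precursor_peak_has_empty_loss(self):
        mz = 753.22528
        (a,) = annotate_fragments(PARENT, "[M-H]-", [Ms2Peak(mz, 50.0)])
        assert a.formula == Formula.parse("C34H41O19")
        assert a.neutral_loss.is_empty()

    def test_sequential_water_loss_labeled(self):
        peaks = [Ms2Peak(223.06189, 7.23), Ms2Peak(205.05049, 100.0)]
        steps = sequential_losses(annotate_fragments(PARENT, "[M-H]-", peaks))
        assert len(steps) == 1
        _, _, step, label = steps[0]
        assert step == Formula.parse("H2O") and label == "water"

    def test_unassignable_peak_flagged(self):
        (a,) = annotate_fragments(PARENT, "[M-H]-", [Ms2Peak(205.50000, 10.0)])
        assert a.status == "unassigned" and a.formula is None

    def test_assignments_are_contained_subformulas(self, table1):
        feat = next(f for f in table1.features if f.feature_id == "M0n")
        precursor_ion = Formula.parse("C34H41O19")
        for a in annotate_fragments(PARENT, "[M-H]-", feat.ms2, frag_tol_ppm=10.0):
            if a.formula is not None:
                assert precursor_ion.contains(a.formula)
                assert abs(a.ppm) <= 10.0

    def test_radical_methyl_loss_permitted(self):
        # the 205 -> 190 transition of the sinapoyl fragment chain
        out = annotate_fragments(PARENT, "[M-H]-", [Ms2Peak(190.02710, 88.4)])
        assert out[0].formula == Formula.parse("C10H6O4")

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            annotate_fragments(PARENT, "[M-H]-", [], frag_tol_ppm=0.0)


class TestPrintedFragmentValidation:
    def test_impossible_subformulas_flagged(self, table1):
        report = validate_printed_fragments(table1.features, table1.neutral_formulas)
        flagged = {
            (r["feature_id"], r["printed_formula"]) for r in report if not r["subformula_ok"]
        }
        assert ("M9", "C19H15O5") in flagged  # C19 exceeds the C16 precursor
        assert ("M4", "C11H15O12") in flagged  # O12 exceeds the O8 precursor

    def test_consistent_assignment_passes(self, table1):
        report = validate_printed_fragments(table1.features, table1.neutral_formulas)
        row = next(
            r for r in report if r["feature_id"] == "M0n" and r["fragment_mz"] == 205.05049
        )
        assert row["subformula_ok"] and row["mass_ok"]
        assert row["ppm"] == pytest.approx(-0.7, abs=0.05)

    def test_empty_fragment_list_gives_empty_report(self):
        feat = Ms1Feature("X", 1.0, "+", "[M+H]+", 225.07570)
        assert validate_printed_fragments([feat], {"X": Formula.parse("C11H12O5")}) == []


class TestNetwork:
    def test_single_identified_parent_is_isolated_node(self, table1, closure_index, rules):
        parent_rows = [f for f in table1.features if f.metabolite == "M0"]
        records = identify(group_features(parent_rows), closure_index)
        g = build_network(records, rules, PARENT)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_ester_cleavage_edge(self, table1, closure_index, rules):
        rows = [f for f in table1.features if f.metabolite in ("M0", "M1")]
        records = identify(group_features(rows), closure_index)
        g = build_network(records, rules, PARENT)
        by_formula = {g.nodes[n]["formula"]: n for n in g.nodes}
        src, dst = by_formula["C34H42O19"], by_formula["C23H32O15"]
        assert g.edges[src, dst]["rule"] == "sinapoyl ester cleavage"

    def test_demethylation_chain_has_virtual_intermediates(self, table1, closure_index, rules):
        rows = [f for f in table1.features if f.metabolite in ("M0", "M5")]
        records = identify(group_features(rows), closure_index)
        g = build_network(records, rules, PARENT)
        virtual = [n for n, d in g.nodes(data=True) if not d["observed"]]
        assert len(virtual) == 2  # two unobserved demethylation intermediates
        assert g.number_of_edges() == 3
        assert all(d["rule"] == "demethylation" for _, _, d in g.edges(data=True))

    def test_edges_replay_parent_to_children(self, table1, closure_index, rules):
        records = identify(group_features(table1.features), closure_index)
        g = build_network([r for r in records if r.identified], rules, PARENT)
        by_name = {r.name: r for r in rules}
        for u, v, data in g.edges(data=True):
            src = Formula.parse(g.nodes[u]["formula"])
            dst = Formula.parse(g.nodes[v]["formula"])
            assert by_name[data["rule"]].apply(src) == dst


class TestIdentify:
    def test_isomers_labeled_by_rt_rank(self, table1, closure_index):
        records = identify(group_features(table1.features), closure_index)
        c11 = [r for r in records if r.formula == Formula.parse("C11H14O5")]
        assert len(c11) == 2
        first, second = sorted(c11, key=lambda r: r.rt_min)
        assert "[isomer 1]" in first.reaction_label
        assert "[isomer 2]" in second.reaction_label

    def test_unidentified_groups_retained(self, table1, closure_index):
        records = identify(group_features(table1.features), closure_index, tol_ppm=5.0)
        unidentified = [r for r in records if not r.identified]
        # the one 5-ppm failure keeps its row with an empty formula
        assert len(unidentified) == 1
        assert unidentified[0].source_labels == ("M14",)
        assert unidentified[0].reaction_label == "unidentified"
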