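"""GPR logic, model container invariants, I/O round trips, and media rules."""

import itertools

import numpy as np
import pytest

from metapersona import (GprParseError, apply_media, evaluate_gpr_bool,
                         gene_states_to_reaction_state, parse_gpr, solve_fba)
from metapersona.io import model_from_dict, model_to_dict, read_model, write_model


class TestGprParsing:
    @pytest.mark.parametrize("text,serialized", [
        ("g1", "g1"),
        ("g1 and (g2 or g3)", "g1 and (g2 or g3)"),
        ("(g1 or g2) and g3", "(g1 or g2) and g3"),
        ("g1 AND g2 OR g3", "g1 and g2 or g3"),  # and binds tighter
        ("((g1))", "g1"),
    ])
    def test_round_trip_serialization(self, text, serialized):
        assert parse_gpr(text).to_string() == serialized

    def test_precedence_and_binds_tighter(self):
        e = parse_gpr("g1 and g2 or g3")
        assert e.op == "or"
        assert e.children[0].op == "and"

    @pytest.mark.parametrize("bad", ["", "  ", "g1 and", "(g1 or g2", "and g1",
                                     "g1 g2", "g1 or or g2"])
    def test_malformed_raises_with_position(self, bad):
        with pytest.raises(GprParseError):
            parse_gpr(bad)

    def test_reparse_is_identity(self):
        for text in ["g1 and (g2 or g3) and g4", "(a or b) and (c or d)"]:
            e = parse_gpr(text)
            assert parse_gpr(e.to_string()).to_string() == e.to_string()


class TestGprEvaluation:
    @pytest.mark.parametrize("text,present,expected", [
        ("g1 or g2", {"g2"}, True),
        ("g1 and g2", {"g1"}, False),
        ("g1 and (g2 or g3)", {"g1", "g3"}, True),
        ("(g1 or g2) and g3", {"g1", "g3"}, True),
        ("(g1 or g2) and g3", {"g2"}, False),
    ])
    def test_boolean_evaluation(self, text, present, expected):
        assert evaluate_gpr_bool(parse_gpr(text), present) is expected

    @pytest.mark.parametrize("text,states,expected", [
        ("g1 and g2", {"g1": 1, "g2": -1}, -1),
        ("g1 or g2", {"g1": 1, "g2": -1}, 1),
        ("g1 and (g2 or g3)", {"g1": 0, "g2": 1, "g3": -1}, 0),
        ("g1", {}, 0),  # unmapped genes default to 0
    ])
    def test_ternary_min_max_rule(self, text, states, expected):
        assert gene_states_to_reaction_state(parse_gpr(text), states) == expected

    @pytest.mark.parametrize("text", [
        "g1", "g1 and g2", "g1 or g2", "g1 and (g2 or g3)",
        "(g1 or g2) and (g3 or g4)", "g1 or g2 and g3 or g4",
    ])
    def test_binary_restriction_agrees_with_boolean(self, text):
        """On states {0,+1} the min/max rule is exactly boolean evaluation."""
        expr = parse_gpr(text)
        genes = sorted(expr.genes())
        for bits in itertools.product([0, 1], repeat=len(genes)):
            states = dict(zip(genes, bits))
            present = {g for g, b in states.items() if b}
            assert (gene_states_to_reaction_state(expr, states) == 1) \
                == evaluate_gpr_bool(expr, present)

    def test_monotone_in_gene_states(self):
        """Raising any single gene state never lowers the reaction state."""
        expr = parse_gpr("(g1 or g2) and (g3 or g4)")
        genes = sorted(expr.genes())
        for states in itertools.product([-1, 0, 1], repeat=len(genes)):
            base = dict(zip(genes, states))
            v0 = gene_states_to_reaction_state(expr, base)
            for g in genes:
                if base[g] < 1:
                    raised = dict(base, **{g: base[g] + 1})
                    assert gene_states_to_reaction_state(expr, raised) >= v0


class TestModelContainer:
    def test_exchange_detection_one_sided(self, toy1):
        # EX_A and BIOMASS touch one side only; R1 converts
        assert list(toy1.exchange_flags) == [True, False, True]

    def test_bound_violation_rejected(self, toy1):
        with pytest.raises(ValueError, match="lower bound"):
            toy1.with_bounds(toy1.upper_bound + 1, toy1.upper_bound)

    def test_gpr_gene_must_be_declared(self):
        doc = model_to_dict(pytest.importorskip("metapersona").make_toy1())
        doc["reactions"][1]["gpr"] = "ghost"
        doc["genes"] = []
        with pytest.raises(ValueError, match="ghost"):
            model_from_dict(doc)

    def test_unknown_metabolite_rejected(self, toy1):
        doc = model_to_dict(toy1)
        doc["reactions"][0]["mets"] = {"nosuch": -1}
        with pytest.raises(ValueError, match="unknown metabolite"):
            model_from_dict(doc)

    def test_missing_objective_warns(self, toy1):
        doc = model_to_dict(toy1)
        for r in doc["reactions"]:
            r["objective"] = 0
        with pytest.warns(UserWarning, match="no objective"):
            model_from_dict(doc)


class TestModelIO:
    def test_json_round_trip_is_identity(self, toy1_and, tmp_path):
        path = tmp_path / "m.json"
        write_model(toy1_and, path)
        again = read_model(path)
        assert model_to_dict(again) == model_to_dict(toy1_and)

    def test_sbml_round_trip_preserves_semantics(self, toy1_and, tmp_path):
        path = tmp_path / "m.xml"
        write_model(toy1_and, path, format="sbml")
        again = read_model(path)
        assert again.reaction_ids == toy1_and.reaction_ids
        assert np.allclose(again.lower_bound, toy1_and.lower_bound)
        assert np.allclose(again.upper_bound, toy1_and.upper_bound)
        gprs = [g.to_string() if g else None for g in again.gpr]
        assert gprs == [g.to_string() if g else None for g in toy1_and.gpr]
        assert list(again.core_flags) == list(toy1_and.core_flags)
        assert solve_fba(again).objective_value == pytest.approx(
            solve_fba(toy1_and).objective_value)

    def test_sbml_matches_cobra_fba(self, toy1_and, tmp_path):
        """Independent cross-check: cobrapy solves the exported SBML to the
        same optimum."""
        cobra = pytest.importorskip("cobra")
        path = tmp_path / "m.xml"
        write_model(toy1_and, path, format="sbml")
        cm = cobra.io.read_sbml_model(str(path))
        assert cm.slim_optimize() == pytest.approx(10.0, abs=1e-6)


class TestMedia:
    def test_listed_exchange_bounds_replaced(self, toy1):
        out = apply_media(toy1, {"EX_A": (-10, 1000)})
        j = out.reaction_index("EX_A")
        assert (out.lower_bound[j], out.upper_bound[j]) == (-10, 1000)

    def test_empty_media_closes_all_uptake(self, toy1):
        out = apply_media(toy1, {})
        assert np.all(out.lower_bound[out.exchange_flags] >= 0)

    def test_non_exchange_key_rejected(self, toy1):
        with pytest.raises(ValueError, match="not an exchange"):
            apply_media(toy1, {"R1": (0, 10)})

    def test_absent_key_warns_and_skips(self, toy1):
        with pytest.warns(UserWarning, match="not in model"):
            out = apply_media(toy1, {"EX_missing": (-5, 5)})
        assert np.all(out.lower_bound[out.exchange_flags] >= 0)

    def test_starved_model_cannot_grow(self, toy1):
        # closing the only carbon uptake forces a zero optimum
        out = apply_media(toy1, {})
        assert solve_fba(out).objective_value == pytest.approx(0.0, abs=1e-9)
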