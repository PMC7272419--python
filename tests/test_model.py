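"""Model container, structural invariants, curation, and I/O round-trips."""

from fractions import Fraction

import pytest

from gemreduce.model import (BOUNDARY, ENZYMATIC, TRANSPORT, CurationRule, Gem,
                             FormatError, MediumDefinition, Metabolite,
                             Reaction, ValidationError, apply_medium_curation,
                             default_curation_rules, gem_from_dict,
                             gem_to_dict, read_json, read_sbml, write_json,
                             write_sbml)


def _tiny_gem():
    return Gem("tiny",
               [Metabolite("a_c", compartment="c"),
                Metabolite("b_c", compartment="c")],
               [Reaction("R1", {"a_c": -1, "b_c": 1}, 0, 10)])


class TestInvariants:
    def test_minimal_model_is_valid_and_enzymatic(self):
        gem = _tiny_gem()
        gem.validate()
        assert gem.reaction_kind("R1") == ENZYMATIC

    def test_undeclared_metabolite_is_rejected(self):
        gem = _tiny_gem()
        gem.add_reaction(Reaction("BAD", {"ghost_c": -1, "b_c": 1}))
        with pytest.raises(ValidationError, match="ghost_c"):
            gem.validate()

    def test_all_violations_reported_at_once(self):
        gem = _tiny_gem()
        gem.add_reaction(Reaction("BAD1", {"ghost_c": -1, "b_c": 1}))
        gem.add_reaction(Reaction("BAD2", {"a_c": -1, "b_c": 1}, 5, -5))
        with pytest.raises(ValidationError) as err:
            gem.validate()
        assert len(err.value.violations) == 2

    def test_kind_inference_structural_and_overridable(self):
        gem = Gem("kinds",
                  [Metabolite("x_e", compartment="e"),
                   Metabolite("x_c", compartment="c")],
                  [Reaction("EX_x", {"x_e": -1}),
                   Reaction("T_x", {"x_e": -1, "x_c": 1}),
                   Reaction("ANNOT", {"x_c": -1, "x_e": 1}, kind=ENZYMATIC)])
        assert gem.reaction_kind("EX_x") == BOUNDARY
        assert gem.reaction_kind("T_x") == TRANSPORT
        assert gem.reaction_kind("ANNOT") == ENZYMATIC  # explicit wins

    def test_fraction_coefficients_from_decimals(self):
        rxn = Reaction("R", {"a_c": 0.5, "b_c": "2/3"})
        assert rxn.stoichiometry["a_c"] == Fraction(1, 2)
        assert rxn.stoichiometry["b_c"] == Fraction(2, 3)


class TestJsonRoundTrip:
    def test_planted_fixture_roundtrips_exactly(self, planted, tmp_path):
        gem, _, _ = planted
        path = tmp_path / "toy.json"
        write_json(gem, path)
        back = read_json(path)
        assert set(back.reactions) == set(gem.reactions)
        for rid, rxn in gem.reactions.items():
            assert back.reactions[rid].stoichiometry == rxn.stoichiometry
            assert back.reactions[rid].subsystem == rxn.subsystem
            assert back.reactions[rid].gene_rule == rxn.gene_rule
            assert abs(back.reactions[rid].lower_bound - rxn.lower_bound) < 1e-9
            assert abs(back.reactions[rid].upper_bound - rxn.upper_bound) < 1e-9
        assert back.biomass_id == gem.biomass_id

    def test_malformed_json_names_the_problem(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(FormatError):
            read_json(path)

    def test_missing_record_field_is_a_format_error(self):
        with pytest.raises(FormatError):
            gem_from_dict({"metabolites": [], "reactions": [{"id": "R"}]})


class TestSbmlRoundTrip:
    def test_stoichiometry_bounds_rules_subsystems_preserved(self, planted,
                                                             tmp_path):
        gem, _, _ = planted
        path = tmp_path / "toy.xml"
        write_sbml(gem, path)
        back = read_sbml(path)
        assert set(back.reactions) == set(gem.reactions)
        for rid, rxn in gem.reactions.items():
            assert back.reactions[rid].stoichiometry == rxn.stoichiometry
            assert back.reactions[rid].subsystem == rxn.subsystem
            assert back.reactions[rid].gene_rule == rxn.gene_rule
            assert abs(back.reactions[rid].lower_bound - rxn.lower_bound) < 1e-9


class TestCuration:
    def test_empty_rules_and_full_medium_change_nothing(self):
        gem = Gem("m",
                  [Metabolite("x_e", compartment="e"),
                   Metabolite("x_c", compartment="c")],
                  [Reaction("EX_x", {"x_e": -1}, -10, 10),
                   Reaction("T_x", {"x_e": -1, "x_c": 1}, -10, 10),
                   Reaction("SINK", {"x_c": -1}, 0, 10, kind=ENZYMATIC)])
        curated, report = apply_medium_curation(
            gem, MediumDefinition({"x_e": 10.0}), rules=[])
        for rid in gem.reactions:
            assert curated.reactions[rid].lower_bound == gem.reactions[rid].lower_bound
            assert curated.reactions[rid].upper_bound == gem.reactions[rid].upper_bound
        assert not report.entries

    def test_orphan_exchange_closed_for_uptake(self):
        # x_e has an exchange but no transporter: uptake must be closed
        gem = Gem("m",
                  [Metabolite("x_e", compartment="e"),
                   Metabolite("y_e", compartment="e"),
                   Metabolite("y_c", compartment="c")],
                  [Reaction("EX_x", {"x_e": -1}, -10, 10),
                   Reaction("EX_y", {"y_e": -1}, -10, 10),
                   Reaction("T_y", {"y_e": -1, "y_c": 1}, -10, 10),
                   Reaction("SINK", {"y_c": -1}, 0, 10, kind=ENZYMATIC)])
        curated, report = apply_medium_curation(
            gem, MediumDefinition({"x_e": 10.0, "y_e": 10.0}),
            default_curation_rules())
        assert curated.reactions["EX_x"].lower_bound == 0.0
        assert curated.reactions["EX_y"].lower_bound == -10.0
        assert any(e.rule == "orphan-exchange" for e in report.entries)

    def test_coa_carrying_transporter_blocked_others_untouched(self, planted):
        gem, _, truth = planted
        gem = gem.copy()
        gem.add_metabolite(Metabolite("paccoa_c", "palmitoyl-CoA",
                                      "C37H62N7O17P3S", 0, "c"))
        gem.add_metabolite(Metabolite("paccoa_e", "palmitoyl-CoA",
                                      "C37H62N7O17P3S", 0, "e"))
        gem.add_reaction(Reaction("T_COA", {"paccoa_e": -1, "paccoa_c": 1},
                                  -10, 10))
        before = {r: (x.lower_bound, x.upper_bound)
                  for r, x in gem.reactions.items()}
        curated, report = apply_medium_curation(gem, truth.medium,
                                                default_curation_rules())
        assert (curated.reactions["T_COA"].lower_bound,
                curated.reactions["T_COA"].upper_bound) == (0.0, 0.0)
        diff = [r for r in before
                if (curated.reactions[r].lower_bound,
                    curated.reactions[r].upper_bound) != before[r]]
        # only the forbidden transporter and the non-medium uptakes changed
        assert "T_COA" in diff
        assert all(gem.reaction_kind(r) == BOUNDARY for r in diff
                   if r != "T_COA")

    def test_phosphate_cargo_matched_by_formula(self):
        rule = CurationRule("no-P", "forbid_transport_cargo", element="P")
        assert rule.matches_metabolite(
            Metabolite("g6p_c", "glucose 6-phosphate", "C6H13O9P"))
        assert not rule.matches_metabolite(
            Metabolite("glc_c", "glucose", "C6H12O6"))

    def test_curation_only_tightens_bounds(self, planted):
        gem, _, truth = planted
        curated, _ = apply_medium_curation(gem, truth.medium,
                                           default_curation_rules())
        for rid, rxn in gem.reactions.items():
            new = curated.reactions[rid]
            assert new.lower_bound >= rxn.lower_bound - 1e-12
            assert new.upper_bound <= rxn.upper_bound + 1e-12
        assert set(curated.reactions) == set(gem.reactions)

    def test_medium_metabolite_without_exchange_warns(self):
        gem = Gem("m",
                  [Metabolite("x_e", compartment="e"),
                   Metabolite("x_c", compartment="c")],
                  [Reaction("T_x", {"x_e": -1, "x_c": 1}, -10, 10),
                   Reaction("SINK", {"x_c": -1}, 0, 10, kind=ENZYMATIC)])
        _, report = apply_medium_curation(gem, MediumDefinition({"x_e": 5.0}), [])
        assert any("x_e" in w for w in report.warnings)

    def test_medium_referencing_intracellular_metabolite_is_invalid(self):
        gem = _tiny_gem()
        with pytest.raises(ValidationError):
            MediumDefinition({"a_c": 1.0}).validate_against(gem)


def test_serialization_is_deterministic(planted):
    gem, _, _ = planted
    assert gem_to_dict(gem) == gem_to_dict(gem.copy())
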