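"""Gibbs-energy evaluation, directionality intervals, coverage."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemreduce.model import Gem, Metabolite, Reaction
from gemreduce.thermo import (BIDIRECTIONAL, FORWARD_ONLY, REVERSE_ONLY, RT,
                              CompartmentData, GibbsDomainError,
                              MetaboliteThermo, ThermoTable, coverage_report,
                              gibbs_bounds, reaction_gibbs)


def _iso_gem():
    """a_c -> b_c isomerization plus an exchange."""
    return Gem("iso",
               [Metabolite("a_c", formula="C2", compartment="c"),
                Metabolite("b_c", formula="C2", compartment="c")],
               [Reaction("R", {"a_c": -1, "b_c": 1}, -10, 10),
                Reaction("EX_a", {"a_c": -1}, -10, 10)])


def _table(dfg_a, dfg_b, err=0.0):
    return ThermoTable({"a_c": MetaboliteThermo(dfg_a, err),
                        "b_c": MetaboliteThermo(dfg_b, err)},
                       {"c": CompartmentData()})


def test_rt_constant_matches_gas_constant_times_temperature():
    assert RT == pytest.approx(2.47638, abs=5e-6)


class TestReactionGibbs:
    def test_symmetric_isomerization_is_zero(self):
        gem = _iso_gem()
        ln = math.log(1e-3)
        val = reaction_gibbs(gem, gem.reactions["R"], _table(-100, -100),
                             {"a_c": ln, "b_c": ln})
        assert val == pytest.approx(0.0, abs=1e-9)

    def test_worked_example_with_concentration_term(self):
        # DrG'0 = -2; x_a = 1 mM, x_b = 0.1 mM -> -2 + RT ln(0.1)
        gem = _iso_gem()
        val = reaction_gibbs(gem, gem.reactions["R"], _table(-10, -12),
                             {"a_c": math.log(1e-3), "b_c": math.log(1e-4)})
        assert val == pytest.approx(-2 + RT * math.log(0.1), abs=1e-6)

    def test_tenfold_ratio_gives_rt_ln_ten(self):
        gem = _iso_gem()
        val = reaction_gibbs(gem, gem.reactions["R"], _table(-50, -50),
                             {"a_c": math.log(1e-4), "b_c": math.log(1e-3)})
        assert val == pytest.approx(RT * math.log(10), abs=1e-6)

    def test_unknown_participant_is_undetermined(self):
        gem = _iso_gem()
        table = ThermoTable({"a_c": MetaboliteThermo(-10),
                             "b_c": MetaboliteThermo(None, reason="no-structure")},
                            {"c": CompartmentData()})
        ln = math.log(1e-3)
        assert reaction_gibbs(gem, gem.reactions["R"], table,
                              {"a_c": ln, "b_c": ln}) is None

    def test_concentration_outside_box_is_a_domain_error(self):
        gem = _iso_gem()
        with pytest.raises(GibbsDomainError):
            reaction_gibbs(gem, gem.reactions["R"], _table(0, 0),
                           {"a_c": math.log(1.0), "b_c": math.log(1e-3)})

    def test_boundary_reactions_have_no_gibbs_energy(self):
        gem = _iso_gem()
        with pytest.raises(ValueError, match="not applicable"):
            reaction_gibbs(gem, gem.reactions["EX_a"], _table(0, 0), {})

    def test_protons_and_water_excluded_from_concentration_product(self):
        gem = Gem("p",
                  [Metabolite("a_c", formula="C2", compartment="c"),
                   Metabolite("b_c", formula="C2", compartment="c"),
                   Metabolite("h_c", formula="H", compartment="c"),
                   Metabolite("h2o_c", formula="H2O", compartment="c")],
                  [Reaction("R", {"a_c": -1, "h2o_c": -1, "b_c": 1, "h_c": 1})])
        table = ThermoTable({"a_c": MetaboliteThermo(-5.0),
                             "b_c": MetaboliteThermo(-5.0)},
                            {"c": CompartmentData()})
        ln = math.log(1e-3)
        # no ln-concentration needed (or used) for h/h2o
        val = reaction_gibbs(gem, gem.reactions["R"], table,
                             {"a_c": ln, "b_c": ln})
        assert val == pytest.approx(0.0, abs=1e-9)


class TestGibbsBounds:
    def test_moderately_negative_reaction_stays_bidirectional(self):
        # DrG'0 = -50 is overwhelmed by the 10 pM..0.1 M concentration box
        gem = _iso_gem()
        gb = gibbs_bounds(gem, gem.reactions["R"], _table(0, -50))
        assert gb.maximum == pytest.approx(-50 + RT * math.log(1e10), abs=1e-6)
        assert gb.direction == BIDIRECTIONAL

    def test_strongly_negative_reaction_is_forward_only(self):
        gem = _iso_gem()
        gb = gibbs_bounds(gem, gem.reactions["R"], _table(0, -100))
        assert gb.maximum < 0
        assert gb.maximum == pytest.approx(-100 + RT * math.log(1e10), abs=1e-6)
        assert gb.direction == FORWARD_ONLY

    def test_strongly_positive_reaction_is_reverse_only(self):
        gem = _iso_gem()
        gb = gibbs_bounds(gem, gem.reactions["R"], _table(0, 100))
        assert gb.minimum > 0
        assert gb.direction == REVERSE_ONLY

    def test_estimation_error_widens_the_interval(self):
        gem = _iso_gem()
        tight = gibbs_bounds(gem, gem.reactions["R"], _table(0, -100, err=0.0))
        wide = gibbs_bounds(gem, gem.reactions["R"], _table(0, -100, err=30.0))
        assert wide.minimum == pytest.approx(tight.minimum - 60, abs=1e-9)
        assert wide.maximum == pytest.approx(tight.maximum + 60, abs=1e-9)
        assert wide.direction == BIDIRECTIONAL

    def test_unknown_participant_leaves_direction_undetermined(self):
        gem = _iso_gem()
        table = ThermoTable({"a_c": MetaboliteThermo(None, reason="missing-group"),
                             "b_c": MetaboliteThermo(0.0)},
                            {"c": CompartmentData()})
        assert not gibbs_bounds(gem, gem.reactions["R"], table).determined

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(dfg_b=st.floats(-120, 120),
           ln_a=st.floats(math.log(1e-11), math.log(0.1)),
           ln_b=st.floats(math.log(1e-11), math.log(0.1)))
    def test_interval_contains_every_interior_evaluation(self, dfg_b, ln_a, ln_b):
        gem = _iso_gem()
        table = _table(0.0, dfg_b)
        gb = gibbs_bounds(gem, gem.reactions["R"], table)
        val = reaction_gibbs(gem, gem.reactions["R"], table,
                             {"a_c": ln_a, "b_c": ln_b})
        assert gb.minimum - 1e-9 <= val <= gb.maximum + 1e-9

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(shift=st.floats(-5, 5), ln_a=st.floats(-20, -6))
    def test_uniform_concentration_shift_cancels_for_isomerization(self, shift,
                                                                   ln_a):
        # sum of coefficients is zero, so scaling all concentrations by a
        # common factor leaves DrG' unchanged
        gem = _iso_gem()
        table = ThermoTable({"a_c": MetaboliteThermo(-7.0),
                             "b_c": MetaboliteThermo(-3.0)},
                            {"c": CompartmentData(conc_lb=1e-12, conc_ub=1.0)})
        base = reaction_gibbs(gem, gem.reactions["R"], table,
                              {"a_c": ln_a, "b_c": ln_a - 1.0})
        moved = reaction_gibbs(gem, gem.reactions["R"], table,
                               {"a_c": ln_a + shift, "b_c": ln_a - 1.0 + shift})
        assert moved == pytest.approx(base, abs=1e-8)


class TestCoverage:
    def test_full_annotation_gives_full_coverage(self, planted):
        gem, thermo, _ = planted
        report = coverage_report(gem, thermo)
        assert report.metabolite_pct == 100.0

    def test_partial_coverage_hand_count(self):
        gem = Gem("cov",
                  [Metabolite(m, formula="C", compartment="c")
                   for m in ("a_c", "b_c", "c_c", "d_c")],
                  [Reaction("R1", {"a_c": -1, "b_c": 1}),
                   Reaction("R2", {"c_c": -1, "d_c": 1})])
        table = ThermoTable({"a_c": MetaboliteThermo(0.0),
                             "b_c": MetaboliteThermo(0.0),
                             "c_c": MetaboliteThermo(0.0),
                             "d_c": MetaboliteThermo(None,
                                                     reason="incomplete-formula")},
                            {"c": CompartmentData()})
        report = coverage_report(gem, table)
        assert report.metabolite_pct == pytest.approx(75.0)
        assert report.reaction_pct == pytest.approx(50.0)
        assert report.unknown_by_reason["incomplete-formula"] == 1


def test_thermo_table_tsv_roundtrip():
    table = ThermoTable({"a_c": MetaboliteThermo(-12.5, 1.25),
                         "b_c": MetaboliteThermo(None, reason="missing-group")})
    back = ThermoTable.from_tsv(table.to_tsv())
    assert back.metabolites["a_c"].dfg0 == -12.5
    assert back.metabolites["a_c"].error == 1.25
    assert not back.metabolites["b_c"].known
    assert back.metabolites["b_c"].reason == "missing-group"
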