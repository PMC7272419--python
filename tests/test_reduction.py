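"""Reduced-model assembly and the validation battery."""

import numpy as np
import pytest

from gemreduce.lumpgem import lumps_for_model
from gemreduce.model import BOUNDARY, Gem, Metabolite, Reaction
from gemreduce.oracles import brute_force_essential_genes
from gemreduce.reduction import (AssemblyError, PhysiologyConstraints,
                                 TaskDefinition, apply_physiology, assemble,
                                 check_tasks, compare_essentiality,
                                 gene_essentiality, load_tasks_yaml,
                                 min_active_reactions_for_target, tva_compare)
from gemreduce.tfa import TfaProblem


class TestAssembly:
    def test_statistics_are_internally_consistent(self, planted_reduction):
        stats = planted_reduction.reduced.statistics
        assert stats.n_total == (stats.n_enzymatic + stats.n_boundary
                                 + stats.n_transport + stats.n_lumped)
        assert stats.n_lumped == len(planted_reduction.lumps)
        reduced = planted_reduction.reduced.gem
        assert stats.n_metabolites == len(reduced.metabolites)

    def test_non_lumped_reactions_exist_verbatim_in_parent(
            self, planted, planted_reduction):
        gem, _, _ = planted
        reduced = planted_reduction.reduced
        for rid, rxn in reduced.gem.reactions.items():
            if rid in reduced.lump_ids:
                continue
            assert rid in gem.reactions
            assert rxn.stoichiometry == gem.reactions[rid].stoichiometry

    def test_growth_feasible_with_lumps_infeasible_without(
            self, planted, planted_reduction):
        _, thermo, _ = planted
        reduced = planted_reduction.reduced.gem
        sol = TfaProblem(reduced, thermo).max_growth()
        assert sol.ok and sol.objective > 0.1
        crippled = reduced.copy()
        for lump_id in planted_reduction.reduced.lump_ids:
            crippled.reactions[lump_id].upper_bound = 0.0
        sol2 = TfaProblem(crippled, thermo).max_growth()
        assert (not sol2.ok) or sol2.objective < 1e-9

    def test_missing_lump_for_needed_bbb_is_an_assembly_error(
            self, planted, planted_reduction):
        gem, thermo, truth = planted
        out = planted_reduction
        with pytest.raises(AssemblyError, match="p_c"):
            assemble(out.curated, out.core, out.connection.merged_reactions,
                     [], out.bbb_classification)

    def test_smin_flavor_contains_one_per_bbb_flavor(self, suite_reductions):
        for gem, thermo, truth, out in suite_reductions[:3]:
            ctx = set(out.core.reaction_ids) | out.connection.merged_reactions
            _, lumps_one, cls = lumps_for_model(gem, thermo, ctx,
                                                flavor="one-per-BBB")
            red_one = assemble(out.curated, out.core,
                               out.connection.merged_reactions, lumps_one, cls)
            assert set(red_one.gem.reactions) - red_one.lump_ids \
                <= set(out.reduced.gem.reactions)

    def test_lump_expansion_is_mass_balanced_in_the_parent(
            self, planted, planted_reduction):
        """Any reduced-model flux solution, with each lump replaced by its
        witness recipe, satisfies the parent's mass balance."""
        gem, thermo, _ = planted
        reduced = planted_reduction.reduced.gem
        sol = TfaProblem(reduced, thermo).max_growth()
        assert sol.ok
        parent_flux = {rid: 0.0 for rid in gem.reactions}
        for rid in reduced.reactions:
            if rid in gem.reactions:
                parent_flux[rid] += sol.flux(rid)
        for lumped in planted_reduction.lumps:
            v = sol.flux(lumped.id)
            for rid, w in lumped.weights.items():
                parent_flux[rid] += v * float(w)
        s, met_ids, rxn_ids = gem.stoichiometric_matrix()
        residual = s @ np.array([parent_flux[r] for r in rxn_ids])
        # the lumped BBB itself is drained by biomass in both views; all
        # other species must balance exactly
        for met, r in zip(met_ids, residual):
            assert abs(r) < 1e-6, f"imbalance at {met}: {r}"


class TestTasks:
    def test_feasible_infeasible_and_missing_entity_categories(
            self, planted, planted_reduction):
        _, thermo, _ = planted
        reduced = planted_reduction.reduced.gem
        tasks = [
            TaskDefinition("produce-bbb", inputs=[("u1_e", 10.0)],
                           outputs=[("p_c", 1e-3)]),
            TaskDefinition("hidden-intermediate", inputs=[("u1_e", 10.0)],
                           outputs=[("q1_c", 1e-3)]),
            TaskDefinition("starved", outputs=[("p_c", 1e-3)]),
        ]
        results = {r.task_id: r for r in check_tasks(reduced, tasks, thermo)}
        assert results["produce-bbb"].passed
        assert not results["hidden-intermediate"].passed
        assert results["hidden-intermediate"].category == "missing-entity"
        assert not results["starved"].passed
        assert results["starved"].category == "infeasible"

    def test_empty_task_list_gives_empty_report(self, planted):
        gem, thermo, _ = planted
        assert check_tasks(gem, [], thermo) == []

    def test_example_task_file_loads_and_runs_on_the_parent(self, planted):
        from pathlib import Path
        gem, thermo, _ = planted
        text = (Path(__file__).parent.parent / "examples" /
                "tasks_toy.yaml").read_text()
        tasks = load_tasks_yaml(text)
        assert len(tasks) == 10
        results = {r.task_id: r for r in check_tasks(gem, tasks, thermo)}
        assert results["growth"].passed
        assert results["biosynthetic-intermediate"].passed  # parent has q1_c
        assert not results["secretion-only-check"].passed


class TestEssentiality:
    def test_exhaustive_knockout_oracle_agreement(self, planted):
        gem, thermo, truth = planted
        ess = gene_essentiality(gem, thermo)
        assert {g for g, e in ess.items() if e} == truth.essential_genes \
            == brute_force_essential_genes(gem)

    def test_isozymes_not_essential_complex_members_essential(self, planted):
        gem, thermo, _ = planted
        ess = gene_essentiality(gem, thermo)
        assert not ess["gU2a"] and not ess["gU2b"]   # isozymes
        assert ess["gL1a"] and ess["gL1b"]           # obligate complex

    def test_parent_essentiality_preserved_in_reduction(
            self, planted, planted_reduction):
        gem, thermo, _ = planted
        reduced = planted_reduction.reduced.gem
        comp = compare_essentiality(gene_essentiality(gem, thermo),
                                    gene_essentiality(reduced, thermo))
        assert comp.preserved, f"violations: {comp.parent_only}"

    def test_reduction_may_create_new_essentiality(
            self, planted, planted_reduction):
        # dropping the parallel degree-2 bridge makes its degree-1 twin
        # essential in the reduction only
        gem, thermo, _ = planted
        reduced = planted_reduction.reduced.gem
        comp = compare_essentiality(gene_essentiality(gem, thermo),
                                    gene_essentiality(reduced, thermo))
        assert "gB1" in comp.reduced_only


class TestTvaCompare:
    def test_removed_parallel_route_shrinks_reduced_ranges(
            self, planted, planted_reduction):
        gem, thermo, _ = planted
        rows = tva_compare(gem, planted_reduction.reduced.gem, thermo)
        by_id = {r.reaction: r for r in rows}
        # reactions absent from the reduction are excluded
        assert "R_B2a" not in by_id
        # every reduced range is contained in the parent range
        for r in rows:
            if r.parent.status == "ok" and r.reduced.status == "ok":
                assert r.reduced.minimum >= r.parent.minimum - 1e-7
                assert r.reduced.maximum <= r.parent.maximum + 1e-7

    def test_untouched_chain_reaction_keeps_identical_range(self):
        # a reaction whose whole neighborhood survives reduction keeps its
        # flux range; emulated by comparing a model with itself
        from gemreduce.fixtures import make_thermo_toy
        gem, thermo = make_thermo_toy()
        rows = tva_compare(gem, gem.copy(), thermo)
        for r in rows:
            assert r.absolute_change == pytest.approx(0.0, abs=1e-7)
            assert r.relative_change == pytest.approx(0.0, abs=1e-7)


class TestMinActive:
    def test_linear_chain_counts_every_step_and_the_exchange(self):
        from gemreduce.fixtures import make_min_active_toy
        gem, expected = make_min_active_toy(chain_len=4, with_shortcut=False)
        result = min_active_reactions_for_target(gem, None, "a4_c")
        assert result.status == "ok"
        assert result.count == expected == 6

    def test_shortcut_route_is_preferred(self):
        from gemreduce.fixtures import make_min_active_toy
        gem, expected = make_min_active_toy(chain_len=4, with_shortcut=True)
        result = min_active_reactions_for_target(gem, None, "a4_c")
        assert result.count == expected == 4
        assert {"S1", "S2"} <= set(result.reactions)

    def test_unreachable_target_reports_infeasible(self):
        from gemreduce.fixtures import make_min_active_toy
        gem, _ = make_min_active_toy(chain_len=3, with_shortcut=False)
        work = gem.copy()
        work.reactions["R2"].upper_bound = 0.0
        assert min_active_reactions_for_target(work, None, "a3_c").status \
            == "infeasible"


class TestPhysiology:
    def test_constraints_are_clamped_onto_the_right_reactions(
            self, leukemia_toy):
        gem, _ = leukemia_toy
        phys = PhysiologyConstraints(growth_cap=0.035, oxygen_uptake_cap=2.0,
                                     atp_maintenance_floor=1.07,
                                     exchange_bounds={"EX_glc_e": (-5.0, 0.0)})
        out = apply_physiology(gem, phys)
        assert out.reactions["BIOMASS"].upper_bound == 0.035
        assert out.reactions["EX_o2_e"].lower_bound == -2.0
        assert out.reactions["ATPM"].lower_bound == 1.07
        assert out.reactions["EX_glc_e"].lower_bound == -5.0
        # original untouched
        assert gem.reactions["BIOMASS"].upper_bound == 1000.0
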