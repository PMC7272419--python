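"""Reduced-model assembly and the consistency-validation battery.

A reduced model is the core network plus the medium-connection reactions,
the (deduplicated) lumped biosynthesis reactions, the biomass reaction,
and the boundary reactions of whatever metabolites remain.  Validation
covers: metabolic-task feasibility, preservation of gene essentiality
relative to the parent model, thermodynamic flux-variability comparison,
and minimal-active-network queries under a measured physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lumpgem import BbbClassification, LumpedReaction
from .model import BOUNDARY, ENZYMATIC, TRANSPORT, Gem, Reaction
from .redgem import CoreNetwork
from .solver import INF, Status
from .tfa import TfaConfig, TfaProblem, VariabilityRange, tva
from .thermo import ThermoTable, coverage_report


class AssemblyError(ValueError):
    pass


@dataclass
class PhysiologyConstraints:
    """Experimentally measured rates clamped onto a model.

    All rates in mmol/gDW/h except growth (1/h).  ``exchange_bounds`` maps
    a boundary reaction id to (lb, ub) from exometabolomics.
    """
    growth_cap: float | None = None
    oxygen_uptake_cap: float | None = None
    atp_maintenance_floor: float | None = None
    oxygen_exchange: str = "EX_o2_e"
    atp_maintenance_rxn: str = "ATPM"
    exchange_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)


def apply_physiology(gem: Gem, phys: PhysiologyConstraints) -> Gem:
    out = gem.copy()
    if phys.growth_cap is not None and out.biomass_id in out.reactions:
        out.reactions[out.biomass_id].upper_bound = phys.growth_cap
    if phys.oxygen_uptake_cap is not None and phys.oxygen_exchange in out.reactions:
        rxn = out.reactions[phys.oxygen_exchange]
        coef = next(iter(rxn.stoichiometry.values()))
        if coef < 0:
            rxn.lower_bound = max(rxn.lower_bound, -phys.oxygen_uptake_cap)
        else:
            rxn.upper_bound = min(rxn.upper_bound, phys.oxygen_uptake_cap)
    if phys.atp_maintenance_floor is not None and phys.atp_maintenance_rxn in out.reactions:
        out.reactions[phys.atp_maintenance_rxn].lower_bound = phys.atp_maintenance_floor
    for rid, (lb, ub) in phys.exchange_bounds.items():
        if rid in out.reactions:
            out.reactions[rid].lower_bound = lb
            out.reactions[rid].upper_bound = ub
    return out


@dataclass
class ModelStatistics:
    n_metabolites: int
    n_enzymatic: int
    n_boundary: int
    n_transport: int
    n_lumped: int
    n_genes: int
    pct_metabolites_thermo: float | None = None
    pct_reactions_thermo: float | None = None

    @property
    def n_total(self) -> int:
        return self.n_enzymatic + self.n_boundary + self.n_transport + self.n_lumped

    def to_tsv(self) -> str:
        rows = [("metabolites", self.n_metabolites),
                ("enzymatic_reactions", self.n_enzymatic),
                ("boundary_reactions", self.n_boundary),
                ("transport_reactions", self.n_transport),
                ("lumped_reactions", self.n_lumped),
                ("total_reactions", self.n_total),
                ("genes", self.n_genes)]
        if self.pct_metabolites_thermo is not None:
            rows.append(("pct_metabolites_with_gibbs",
                         round(self.pct_metabolites_thermo, 1)))
            rows.append(("pct_reactions_with_gibbs",
                         round(self.pct_reactions_thermo, 1)))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


@dataclass
class ReducedModel:
    gem: Gem
    parent_id: str
    lumps: list[LumpedReaction]
    provenance: dict[str, str]       # reduced reaction id -> origin tag
    statistics: ModelStatistics

    @property
    def lump_ids(self) -> set[str]:
        return {lm.id for lm in self.lumps}


def assemble(parent: Gem, core: CoreNetwork, medium_reactions: set[str],
             lumps: list[LumpedReaction],
             bbb_classification: BbbClassification | None = None,
             thermo: ThermoTable | None = None,
             model_id: str | None = None) -> ReducedModel:
    """Compose the reduced model and compute its statistics block.

    Raises AssemblyError when a BBB classified as needing a lump has none
    (the resulting model could never grow).
    """
    if bbb_classification is not None:
        lumped_bbbs = {lm.bbb for lm in lumps}
        missing = [b for b in bbb_classification.needs_lump
                   if b not in lumped_bbbs]
        if missing:
            raise AssemblyError(
                f"BBBs need a lumped reaction but have none: {missing}")

    keep: dict[str, str] = {}
    for rid, prov in core.reactions.items():
        keep[rid] = prov
    for rid in sorted(medium_reactions):
        keep.setdefault(rid, "medium-connection")
    if parent.biomass_id:
        keep.setdefault(parent.biomass_id, "biomass")

    met_ids: set[str] = set()
    for rid in keep:
        met_ids.update(parent.reactions[rid].stoichiometry)
    for lm in lumps:
        met_ids.update(lm.stoichiometry)
    # boundaries of retained metabolites, with their (curated) bounds
    for rid in parent.boundary_reactions():
        if set(parent.reactions[rid].stoichiometry) <= met_ids:
            keep.setdefault(rid, "retained-boundary")

    reduced = Gem(model_id or f"{parent.id}_reduced",
                  [parent.metabolites[m] for m in sorted(met_ids)],
                  [parent.reactions[rid] for rid in sorted(keep)],
                  biomass_id=parent.biomass_id,
                  extracellular=parent.extracellular).copy()
    provenance = dict(keep)
    for lm in lumps:
        reduced.add_reaction(lm.to_reaction())
        provenance[lm.id] = f"lumped:{','.join(sorted(lm.subnetwork_reactions))}"
    reduced.compartments = sorted({m.compartment
                                   for m in reduced.metabolites.values()})
    reduced.validate()

    kinds = {rid: reduced.reaction_kind(rid) for rid in reduced.reactions}
    lump_ids = {lm.id for lm in lumps}
    stats = ModelStatistics(
        n_metabolites=len(reduced.metabolites),
        n_enzymatic=sum(1 for r, k in kinds.items()
                        if k == ENZYMATIC and r not in lump_ids),
        n_boundary=sum(1 for k in kinds.values() if k == BOUNDARY),
        n_transport=sum(1 for k in kinds.values() if k == TRANSPORT),
        n_lumped=len(lump_ids),
        n_genes=len(reduced.genes()),
    )
    if thermo is not None:
        cov = coverage_report(reduced, thermo)
        stats.pct_metabolites_thermo = cov.metabolite_pct
        stats.pct_reactions_thermo = cov.reaction_pct
    return ReducedModel(reduced, parent.id, list(lumps), provenance, stats)


# ---------------------------------------------------------------------------
# Metabolic tasks
# ---------------------------------------------------------------------------

@dataclass
class TaskDefinition:
    id: str
    inputs: list[tuple[str, float]] = field(default_factory=list)    # (met, max uptake)
    outputs: list[tuple[str, float]] = field(default_factory=list)   # (met, min production)
    overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    description: str = ""


@dataclass
class TaskResult:
    task_id: str
    passed: bool
    category: str | None = None   # "missing-entity" (reduction hid it) | "infeasible"
    detail: str = ""


def load_tasks_yaml(text: str) -> list[TaskDefinition]:
    import yaml
    raw = yaml.safe_load(text)
    tasks = []
    for t in raw:
        tasks.append(TaskDefinition(
            t["id"],
            [(d["metabolite"], float(d.get("max_rate", 1000.0)))
             for d in t.get("inputs", [])],
            [(d["metabolite"], float(d.get("min_rate", 1e-3)))
             for d in t.get("outputs", [])],
            {k: (float(v[0]), float(v[1]))
             for k, v in (t.get("overrides") or {}).items()},
            t.get("description", "")))
    return tasks


def check_tasks(model: Gem, tasks: list[TaskDefinition],
                thermo: ThermoTable | None = None,
                config: TfaConfig | None = None) -> list[TaskResult]:
    """Feasibility of each task under its boundary overrides.

    Every uptake is closed, the task's inputs are opened at their caps,
    each required output gets a demand at its floor, then the TFA problem
    is checked for feasibility.  A task referencing a metabolite or
    reaction absent from the model fails with category ``missing-entity``
    — for reduced models the usual cause is a species hidden inside a
    lumped reaction.
    """
    results = []
    for task in tasks:
        missing = [m for m, _ in task.inputs + task.outputs
                   if m not in model.metabolites]
        missing += [r for r in task.overrides if r not in model.reactions]
        if missing:
            results.append(TaskResult(task.id, False, "missing-entity",
                                      ",".join(sorted(set(missing)))))
            continue
        work = model.copy()
        for rid in work.boundary_reactions():
            rxn = work.reactions[rid]
            coef = next(iter(rxn.stoichiometry.values()))
            if coef < 0:
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
            else:
                rxn.upper_bound = min(rxn.upper_bound, 0.0)
        for met, cap in task.inputs:
            rid = f"TIN_{met}"
            work.add_reaction(Reaction(rid, {met: 1}, 0.0, cap, kind=BOUNDARY))
        for met, floor in task.outputs:
            rid = f"TOUT_{met}"
            work.add_reaction(Reaction(rid, {met: -1}, floor, 1000.0,
                                       kind=BOUNDARY))
        for rid, (lb, ub) in task.overrides.items():
            work.reactions[rid].lower_bound = lb
            work.reactions[rid].upper_bound = ub
        problem = TfaProblem(work, thermo, config or TfaConfig())
        sol = problem.solve({}, "max")
        if sol.ok:
            results.append(TaskResult(task.id, True))
        else:
            results.append(TaskResult(task.id, False, "infeasible"))
    return results


# ---------------------------------------------------------------------------
# Gene essentiality
# ---------------------------------------------------------------------------

GROWTH_FLOOR = 1e-6  # 1/h; "no growth" cutoff, well above solver tolerance


def _disabled_reactions(model: Gem, gene: str) -> list[str]:
    from cobra.core.gene import GPR
    out = []
    for rid, rxn in model.reactions.items():
        if not rxn.gene_rule or gene not in rxn.genes():
            continue
        if not GPR.from_string(rxn.gene_rule).eval(knockouts={gene}):
            out.append(rid)
    return out


def gene_essentiality(model: Gem, thermo: ThermoTable | None = None,
                      growth_floor: float = GROWTH_FLOOR,
                      config: TfaConfig | None = None) -> dict[str, bool]:
    """Single-gene knockouts: a gene is essential when maximal growth
    falls below ``growth_floor`` with every reaction whose gene rule
    evaluates false disabled.  Reactions without a rule are never
    disabled."""
    out: dict[str, bool] = {}
    for gene in sorted(model.genes()):
        disabled = _disabled_reactions(model, gene)
        if not disabled:
            out[gene] = False
            continue
        work = model.copy()
        for rid in disabled:
            work.reactions[rid].lower_bound = 0.0
            work.reactions[rid].upper_bound = 0.0
        problem = TfaProblem(work, thermo, config or TfaConfig())
        sol = problem.max_growth()
        out[gene] = not (sol.ok and sol.objective >= growth_floor)
    return out


@dataclass
class EssentialityComparison:
    essential_both: list[str]
    reduced_only: list[str]
    parent_only: list[str]          # shared genes essential only in the parent

    @property
    def preserved(self) -> bool:
        """The consistency property: every shared gene essential in the
        parent is also essential in the reduction."""
        return not self.parent_only


def compare_essentiality(parent_ess: dict[str, bool],
                         reduced_ess: dict[str, bool]) -> EssentialityComparison:
    shared = sorted(set(parent_ess) & set(reduced_ess))
    both = [g for g in shared if parent_ess[g] and reduced_ess[g]]
    red_only = [g for g in shared if reduced_ess[g] and not parent_ess[g]]
    par_only = [g for g in shared if parent_ess[g] and not reduced_ess[g]]
    return EssentialityComparison(both, red_only, par_only)


# ---------------------------------------------------------------------------
# TVA comparison
# ---------------------------------------------------------------------------

EPS_WIDTH = 1e-9


@dataclass
class TvaComparison:
    reaction: str
    parent: VariabilityRange
    reduced: VariabilityRange

    @property
    def absolute_change(self) -> float:
        return self.parent.width - self.reduced.width

    @property
    def relative_change(self) -> float:
        return self.absolute_change / max(self.parent.width, EPS_WIDTH)


def tva_compare(parent: Gem, reduced: Gem, thermo: ThermoTable | None = None,
                physiology: PhysiologyConstraints | None = None,
                reactions: list[str] | None = None,
                config: TfaConfig | None = None) -> list[TvaComparison]:
    """TVA ranges of the common reactions in parent and reduced model,
    sorted by decreasing absolute range change."""
    common = sorted(set(parent.reactions) & set(reduced.reactions))
    if reactions is not None:
        common = [r for r in common if r in set(reactions)]
    gems = [parent, reduced]
    if physiology is not None:
        gems = [apply_physiology(g, physiology) for g in gems]
    ranges = [tva(TfaProblem(g, thermo, config or TfaConfig()), common)
              for g in gems]
    out = [TvaComparison(r, ranges[0][r], ranges[1][r]) for r in common]
    resolved = [x for x in out if x.parent.status == "ok" and x.reduced.status == "ok"]
    unresolved = [x for x in out if x not in resolved]
    resolved.sort(key=lambda x: -abs(x.absolute_change))
    return resolved + unresolved


def tva_compare_tsv(rows: list[TvaComparison]) -> str:
    lines = ["reaction\tparent_lb\tparent_ub\treduced_lb\treduced_ub\t"
             "absolute_change\trelative_change"]
    for x in rows:
        if x.parent.status == "ok" and x.reduced.status == "ok":
            lines.append(
                f"{x.reaction}\t{x.parent.minimum:.6g}\t{x.parent.maximum:.6g}"
                f"\t{x.reduced.minimum:.6g}\t{x.reduced.maximum:.6g}"
                f"\t{x.absolute_change:.6g}\t{x.relative_change:.6g}")
        else:
            lines.append(f"{x.reaction}\t-\t-\t-\t-\tunresolved\tunresolved")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Minimal active network for a target metabolite
# ---------------------------------------------------------------------------

@dataclass
class MinActiveResult:
    status: str
    count: int | None = None
    reactions: frozenset[str] = frozenset()


def min_active_reactions_for_target(model: Gem, thermo: ThermoTable | None,
                                    target: str, demand: float = 1e-3,
                                    config: TfaConfig | None = None,
                                    ) -> MinActiveResult:
    """Fewest reactions (boundaries included) that must be active to
    sustain a demand on ``target``: minimize sum(bF + bR) subject to the
    demand floor."""
    if target not in model.metabolites:
        return MinActiveResult("missing-entity")
    work = model.copy()
    dm = f"DM_{target}"
    if dm not in work.reactions:
        work.add_reaction(Reaction(dm, {target: -1}, 0.0, 1000.0, kind=BOUNDARY))
    problem = TfaProblem(work, thermo, config or TfaConfig())
    objective = {}
    for rid in work.reactions:
        if rid == dm:
            continue
        objective[problem.bf(rid)] = 1.0
        objective[problem.br(rid)] = 1.0
    sol = problem.lp.solve(objective, "min",
                           extra_constraints=[(problem.net(dm), demand, INF)])
    if not sol.ok:
        return MinActiveResult("infeasible")
    active = frozenset(
        rid for rid in work.reactions if rid != dm and
        sol[problem.bf(rid)] + sol[problem.br(rid)] > 0.5)
    return MinActiveResult("ok", int(round(sol.objective)), active)
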