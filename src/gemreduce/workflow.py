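"""End-to-end reduction pipeline: curation -> core network -> medium
connection -> biosynthetic lumping -> assembly -> consistency checks."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .lumpgem import BbbClassification, LumpedReaction, lump_report_tsv, lumps_for_model
from .model import (CurationReport, Gem, MediumDefinition, apply_medium_curation,
                    default_curation_rules, write_json)
from .redgem import CoreConfig, CoreNetwork, pairwise_connect
from .redgemx import MediumConnection, connect_all
from .reduction import ReducedModel, assemble
from .tfa import TfaConfig, TfaProblem
from .thermo import ThermoTable, coverage_report


@dataclass
class ReductionOutcome:
    curated: Gem
    curation_report: CurationReport
    core: CoreNetwork
    connection: MediumConnection
    bbb_classification: BbbClassification
    lumps: list[LumpedReaction]
    reduced: ReducedModel
    timings: dict[str, float] = field(default_factory=dict)


def reduce_model(gem: Gem, thermo: ThermoTable | None,
                 medium: MediumDefinition, core_config: CoreConfig,
                 c: float = 1e-3, flavor: str = "Smin",
                 exclude_targets: set[str] = frozenset(),
                 curation_rules=None, use_thermo: bool = True,
                 max_alternatives: int = 32,
                 tfa_config: TfaConfig | None = None) -> ReductionOutcome:
    """Run the whole reduction on an in-memory model.

    ``use_thermo=False`` runs the subnetwork searches without the
    thermodynamic constraints (pure stoichiometric feasibility).
    """
    timings = {}
    t0 = time.perf_counter()
    curated, report = apply_medium_curation(
        gem, medium,
        curation_rules if curation_rules is not None else default_curation_rules())
    timings["curation"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    core = pairwise_connect(curated, core_config)
    timings["core"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    connection = connect_all(curated, thermo, core, medium, c=c,
                             exclude=set(exclude_targets),
                             max_alternatives=max_alternatives,
                             use_thermo=use_thermo, config=tfa_config)
    timings["medium-connection"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    context = set(core.reaction_ids) | connection.merged_reactions
    results, lumps, bbb_cls = lumps_for_model(
        curated, thermo, context, c=c, flavor=flavor,
        max_alternatives=max_alternatives, use_thermo=use_thermo,
        config=tfa_config)
    timings["lumping"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    reduced = assemble(curated, core, connection.merged_reactions, lumps,
                       bbb_cls, thermo)
    timings["assembly"] = time.perf_counter() - t0
    return ReductionOutcome(curated, report, core, connection, bbb_cls,
                            lumps, reduced, timings)


def write_outcome(outcome: ReductionOutcome, out_dir, thermo=None,
                  extra_log: dict | None = None) -> None:
    """Persist the per-step artifacts and a machine-readable run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_json(outcome.reduced.gem, out / "reduced_model.json")
    (out / "curation_report.tsv").write_text(outcome.curation_report.to_tsv())
    (out / "core_reactions.tsv").write_text(outcome.core.to_tsv())
    (out / "core_connectivity.tsv").write_text(outcome.core.connectivity_tsv())
    (out / "medium_connection.tsv").write_text(outcome.connection.to_tsv())
    (out / "lumped_reactions.tsv").write_text(
        lump_report_tsv(outcome.curated, outcome.lumps))
    (out / "statistics.tsv").write_text(outcome.reduced.statistics.to_tsv())
    log = {"version": __version__, "timings_s": outcome.timings}
    if thermo is not None:
        cov = coverage_report(outcome.reduced.gem, thermo)
        log["thermo_coverage_pct"] = {
            "metabolites": round(cov.metabolite_pct, 1),
            "reactions": round(cov.reaction_pct, 1)}
    if extra_log:
        log.update(extra_log)
    (out / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True)
                                      + "\n")


def max_growth_tfa(gem: Gem, thermo: ThermoTable | None = None,
                   config: TfaConfig | None = None) -> float | None:
    """Convenience: maximal growth rate under TFA constraints."""
    sol = TfaProblem(gem, thermo, config or TfaConfig()).max_growth()
    return sol.objective if sol.ok else None
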