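"""Connect each extracellular medium metabolite to the core network with
the fewest non-core reactions, enumerating all minimal alternatives.

The search classifies extracellular metabolites into medium (1a),
already-in-core (1b) and other (1c), and reactions into core (2a) and
non-core (2b).  Non-core reactions among extracellular metabolites only,
and the boundary/transport reactions of class-1c metabolites, are blocked:
this guarantees a found subnetwork actually reaches the core instead of
wandering through the periplasm of unrelated exchanges.  Then, for one
medium metabolite at a time, its uptake is forced (>= c) and the MILP of
:mod:`gemreduce.minnet` minimizes the number of active non-core reactions;
the subnetworks it returns include every reaction needed to balance
cofactors and by-products, not just the textbook pathway.

Boundary reactions are exempt from the count: a subnetwork is measured in
network (enzymatic/transport) reactions, with exchanges treated as the
environment's side of the problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import BOUNDARY, TRANSPORT, Gem, MediumDefinition, Reaction, ValidationError
from .minnet import MinNetResult, minimal_subnetworks
from .redgem import CoreNetwork
from .solver import INF
from .tfa import TfaConfig
from .thermo import ThermoTable

DEFAULT_UPTAKE_FLOOR = 1e-3  # mmol/gDW/h; >= 1e3 * solver feasibility tol


@dataclass
class RedgemxClassification:
    medium_mets: set[str]          # class 1a
    in_core_mets: set[str]         # class 1b
    other_mets: set[str]           # class 1c
    core_rxns: set[str]            # class 2a
    noncore_rxns: set[str]         # class 2b
    blocked_rxns: set[str]

    def counted(self, gem: Gem) -> set[str]:
        """Non-core reactions that carry a z variable in the search."""
        return {r for r in self.noncore_rxns
                if r not in self.blocked_rxns
                and gem.reaction_kind(r) != BOUNDARY}


def classify(gem: Gem, core: CoreNetwork,
             medium: MediumDefinition) -> RedgemxClassification:
    """Deterministic partition of metabolites and reactions (steps 1-4)."""
    medium.validate_against(gem)
    extracellular = set(gem.extracellular_metabolites())
    medium_mets = set(medium.uptakes)
    bad = medium_mets - extracellular
    if bad:
        raise ValidationError(
            [f"medium metabolite {m} is not extracellular" for m in sorted(bad)])
    in_core = (extracellular & core.metabolites) - medium_mets
    other = extracellular - medium_mets - in_core

    core_rxns = set(core.reaction_ids)
    if gem.biomass_id:
        core_rxns.add(gem.biomass_id)
    noncore = set(gem.reactions) - core_rxns

    blocked: set[str] = set()
    for rid in sorted(noncore):
        rxn = gem.reactions[rid]
        kind = gem.reaction_kind(rid)
        if kind != BOUNDARY and set(rxn.stoichiometry) <= extracellular:
            blocked.add(rid)  # step 3: purely extracellular conversions
        elif kind in (BOUNDARY, TRANSPORT) and set(rxn.stoichiometry) & other:
            blocked.add(rid)  # step 4: exchanges/transports of class-1c species
    return RedgemxClassification(medium_mets, in_core, other,
                                 core_rxns, noncore, blocked)


@dataclass
class ConnectResult:
    target: str
    status: str            # "ok" | "unconnectable"
    result: MinNetResult | None = None

    @property
    def smin(self) -> int | None:
        return self.result.smin if self.result else None

    @property
    def subnetworks(self):
        return self.result.subnetworks if self.result else []


def _uptake_forcing(gem: Gem, met_id: str, c: float,
                    ) -> tuple[Gem, list[tuple[str, float, float]], str]:
    """Forcing constraints for uptake >= c of an extracellular metabolite,
    adding a temporary exchange when the model lacks one."""
    boundaries = gem.boundary_of(met_id)
    work = gem
    if not boundaries:
        work = gem.copy()
        rid = f"EXT_{met_id}"
        work.add_reaction(Reaction(rid, {met_id: -1}, -1000.0, 1000.0,
                                   kind=BOUNDARY))
        boundaries = [rid]
    rid = sorted(boundaries)[0]
    coef = next(iter(gem.reactions[rid].stoichiometry.values())) if rid in gem.reactions \
        else -1
    # uptake = flux direction that injects the metabolite into the system
    if coef < 0:
        forcing = [(rid, -INF, -c)]
        work = work if work is not gem else gem.copy()
        rxn = work.reactions[rid]
        rxn.lower_bound = min(rxn.lower_bound, -c)
    else:
        forcing = [(rid, c, INF)]
        work = work if work is not gem else gem.copy()
        rxn = work.reactions[rid]
        rxn.upper_bound = max(rxn.upper_bound, c)
    return work, forcing, rid


def connect_medium_metabolite(gem: Gem, thermo: ThermoTable | None,
                              classification: RedgemxClassification,
                              target: str, c: float = DEFAULT_UPTAKE_FLOOR,
                              max_alternatives: int = 32,
                              use_thermo: bool = True,
                              config: TfaConfig | None = None) -> ConnectResult:
    """All minimal subnetworks connecting one medium metabolite (class 1a)
    to the core.  ``c`` is the forced uptake floor."""
    if target not in classification.medium_mets:
        raise ValidationError([f"{target} is not a class-1a medium metabolite"])
    if c <= 0:
        raise ValueError("uptake floor c must be > 0")
    work, forcing, _ = _uptake_forcing(gem, target, c)
    counted = classification.counted(gem)
    res = minimal_subnetworks(work, thermo, counted, forcing, target,
                              blocked=classification.blocked_rxns,
                              max_alternatives=max_alternatives,
                              use_thermo=use_thermo, config=config)
    if res.status != "ok":
        return ConnectResult(target, "unconnectable")
    return ConnectResult(target, "ok", res)


@dataclass
class MediumConnection:
    per_target: dict[str, ConnectResult] = field(default_factory=dict)

    @property
    def merged_reactions(self) -> set[str]:
        """Union of all minimal-subnetwork reactions, to append to the core."""
        out: set[str] = set()
        for cr in self.per_target.values():
            for sub in cr.subnetworks:
                out |= sub.reactions
        return out

    @property
    def unconnectable(self) -> list[str]:
        return sorted(t for t, cr in self.per_target.items()
                      if cr.status != "ok")

    def to_tsv(self) -> str:
        lines = ["target\talternative\tsize\treactions"]
        for t in sorted(self.per_target):
            cr = self.per_target[t]
            if cr.status != "ok":
                lines.append(f"{t}\t-\t-\tunconnectable")
                continue
            for i, sub in enumerate(cr.subnetworks):
                lines.append(f"{t}\t{i}\t{sub.size}\t"
                             + ",".join(sorted(sub.reactions)))
        return "\n".join(lines) + "\n"


def connect_all(gem: Gem, thermo: ThermoTable | None, core: CoreNetwork,
                medium: MediumDefinition, c: float = DEFAULT_UPTAKE_FLOOR,
                exclude: set[str] = frozenset(),
                max_alternatives: int = 32, use_thermo: bool = True,
                config: TfaConfig | None = None) -> MediumConnection:
    """Run the connection for every medium metabolite not in ``exclude``
    (the caller may exclude e.g. inorganics it does not wish to connect)."""
    classification = classify(gem, core, medium)
    out = MediumConnection()
    for target in sorted(classification.medium_mets - set(exclude)):
        if target in classification.in_core_mets:
            continue
        out.per_target[target] = connect_medium_metabolite(
            gem, thermo, classification, target, c, max_alternatives,
            use_thermo, config)
    return out
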