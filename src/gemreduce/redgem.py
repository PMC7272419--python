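"""Core-network construction: intra-subsystem expansion and degree-D
pairwise connection of the chosen subsystems.

Starting from a list of subsystems (families of reactions sharing a
label), the core grows in two moves:

* **intra-expansion** — any model reaction, whatever its own label, whose
  non-cofactor participants all belong to one starting subsystem's
  metabolite set is pulled in (subsystem labels in genome-scale models
  often misplace such reactions);
* **degree-D connection** — a directed search over the metabolite-reaction
  graph adds every path of at most D reactions between two subsystem
  metabolites.  A k-reaction path has k-1 intermediate metabolites, all of
  which join the core.  Cofactor pairs (ATP/ADP, NAD(P)(H), CoA, protons,
  water, Pi/PPi, CO2, O2 by default) are not allowed to act as connecting
  carriers — they stay in the stoichiometry of included reactions but a
  path may not run through them.  Paths may not traverse the extracellular
  compartment; connecting the medium is the medium-connection algorithm's
  job.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import BOUNDARY, Gem

#: base names treated as cofactor/small carrier species by default
DEFAULT_COFACTOR_BASES = (
    "atp", "adp", "amp", "nad", "nadh", "nadp", "nadph", "coa",
    "h", "h2o", "pi", "ppi", "co2", "o2",
)


def default_cofactors(gem: Gem) -> set[str]:
    """Metabolite ids whose base name (id minus compartment suffix) is a
    known cofactor/carrier."""
    out = set()
    for mid in gem.metabolites:
        base = re.sub(r"_[a-z][a-z0-9]?$", "", mid).lower()
        if base in DEFAULT_COFACTOR_BASES:
            out.add(mid)
    return out


@dataclass
class CoreConfig:
    subsystems: list[str]
    degree: int = 1
    cofactors: set[str] | None = None      # None -> default_cofactors(gem)
    extracellular: str | None = None       # None -> gem.extracellular

    def __post_init__(self):
        if self.degree < 1:
            raise ValueError("degree must be an integer >= 1")

    def resolve(self, gem: Gem) -> tuple[set[str], str]:
        missing = [s for s in self.subsystems
                   if not any(r.subsystem == s for r in gem.reactions.values())]
        if missing:
            raise ValueError(f"subsystems not present in the model: {missing}")
        cof = self.cofactors if self.cofactors is not None else default_cofactors(gem)
        return set(cof), self.extracellular or gem.extracellular


PROV_INITIAL = "initial-subsystem"
PROV_INTRA = "intra-expansion"


def prov_degree(k: int) -> str:
    return f"degree-{k}"


@dataclass
class CoreNetwork:
    """The explicitly represented core: reactions with provenance, their
    metabolites, and the pairwise subsystem connectivity counts."""
    reactions: dict[str, str]                      # rxn id -> provenance
    metabolites: set[str]
    connectivity: dict[tuple[str, str], set[str]]  # sorted pair -> rxn ids
    subsystems: list[str] = field(default_factory=list)
    unconnected_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def reaction_ids(self) -> set[str]:
        return set(self.reactions)

    def connectivity_counts(self) -> dict[tuple[str, str], int]:
        return {pair: len(rxns) for pair, rxns in self.connectivity.items()}

    def to_tsv(self) -> str:
        lines = ["reaction\tprovenance"]
        for rid in sorted(self.reactions):
            lines.append(f"{rid}\t{self.reactions[rid]}")
        return "\n".join(lines) + "\n"

    def connectivity_tsv(self) -> str:
        lines = ["subsystem_a\tsubsystem_b\tn_connecting_reactions"]
        for (a, b), rxns in sorted(self.connectivity.items()):
            lines.append(f"{a}\t{b}\t{len(rxns)}")
        return "\n".join(lines) + "\n"


def _subsystem_metabolites(gem: Gem, subsystems: list[str],
                           cofactors: set[str], extracellular: str,
                           ) -> dict[str, set[str]]:
    """Non-cofactor, intracellular metabolite set per starting subsystem."""
    out: dict[str, set[str]] = {s: set() for s in subsystems}
    for rxn in gem.reactions.values():
        if rxn.subsystem in out:
            for m in rxn.stoichiometry:
                met = gem.metabolites[m]
                if m not in cofactors and met.compartment != extracellular:
                    out[rxn.subsystem].add(m)
    return out


def initial_reactions(gem: Gem, config: CoreConfig) -> set[str]:
    return {r.id for r in gem.reactions.values()
            if r.subsystem in config.subsystems}


def intra_expand(gem: Gem, config: CoreConfig) -> set[str]:
    """Reactions outside the starting subsystems whose non-cofactor
    participants all sit inside a single starting subsystem."""
    cofactors, extracellular = config.resolve(gem)
    sub_mets = _subsystem_metabolites(gem, config.subsystems, cofactors,
                                      extracellular)
    initial = initial_reactions(gem, config)
    added: set[str] = set()
    for rxn in gem.reactions.values():
        if rxn.id in initial or gem.reaction_kind(rxn.id) == BOUNDARY:
            continue
        carried = [m for m in rxn.stoichiometry if m not in cofactors]
        if not carried:
            continue
        # extracellular participants never belong to a subsystem metabolite
        # set, so transports are excluded here automatically
        if any(set(carried) <= mets for mets in sub_mets.values()):
            added.add(rxn.id)
    return added


def _adjacency(gem: Gem, cofactors: set[str], extracellular: str,
               ) -> dict[str, list[tuple[str, str]]]:
    """met -> [(reaction, next_met)] honoring reaction directionality.

    An edge u -r-> v exists when r can convert u into v in an allowed
    direction; cofactors and extracellular species carry no edges.
    """
    adj: dict[str, list[tuple[str, str]]] = {}

    def allowed(m: str) -> bool:
        return m not in cofactors and gem.metabolites[m].compartment != extracellular

    for rxn in gem.reactions.values():
        if gem.reaction_kind(rxn.id) == BOUNDARY:
            continue
        subs = [m for m in rxn.reactants() if allowed(m)]
        prods = [m for m in rxn.products() if allowed(m)]
        pairs = []
        if rxn.upper_bound > 0:
            pairs += [(u, v) for u in subs for v in prods]
        if rxn.lower_bound < 0:
            pairs += [(v, u) for u in subs for v in prods]
        for u, v in pairs:
            adj.setdefault(u, []).append((rxn.id, v))
    return adj


def pairwise_connect(gem: Gem, config: CoreConfig) -> CoreNetwork:
    """Build the full core: initial subsystems, intra-expansion, and all
    <=D-reaction connecting paths, with per-pair connectivity counts."""
    cofactors, extracellular = config.resolve(gem)
    sub_mets = _subsystem_metabolites(gem, config.subsystems, cofactors,
                                      extracellular)
    core_mets = set().union(*sub_mets.values()) if sub_mets else set()
    membership: dict[str, list[str]] = {}
    for s, mets in sub_mets.items():
        for m in mets:
            membership.setdefault(m, []).append(s)

    initial = initial_reactions(gem, config)
    intra = intra_expand(gem, config)
    provenance: dict[str, str] = {}
    for rid in sorted(initial):
        provenance[rid] = PROV_INITIAL
    for rid in sorted(intra):
        provenance[rid] = PROV_INTRA

    adj = _adjacency(gem, cofactors, extracellular)
    connectivity: dict[tuple[str, str], set[str]] = {}
    path_mets: set[str] = set()

    def record(src: str, dst: str, rxns: list[str], k: int) -> None:
        for a in membership[src]:
            for b in membership[dst]:
                pair = tuple(sorted((a, b)))
                connectivity.setdefault(pair, set()).update(rxns)
        for rid in rxns:
            if rid not in provenance:
                provenance[rid] = prov_degree(k)

    def dfs(start: str, current: str, rxns: list[str], mets: list[str]) -> None:
        depth = len(rxns)
        if depth >= config.degree:
            return
        for rid, nxt in adj.get(current, []):
            if rid in rxns or nxt in mets or nxt == start:
                continue
            if nxt in core_mets:
                record(start, nxt, rxns + [rid], depth + 1)
                path_mets.update(mets[1:])
            else:
                dfs(start, nxt, rxns + [rid], mets + [nxt])

    for start in sorted(core_mets):
        dfs(start, start, [], [start])

    # intermediates of recorded paths join the core
    metabolites = set(core_mets) | path_mets
    for rid in provenance:
        metabolites.update(gem.reactions[rid].stoichiometry)

    unconnected = []
    names = sorted(config.subsystems)
    for i, a in enumerate(names):
        for b in names[i:]:
            if not connectivity.get((a, b)):
                unconnected.append((a, b))
    return CoreNetwork(provenance, metabolites, connectivity,
                       list(config.subsystems), unconnected)
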