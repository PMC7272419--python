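"""Exhaustive brute-force oracles for small models.

These deliberately avoid the package's MILP machinery: feasibility is
checked with plain scipy LPs on the stoichiometric matrix, and path
search uses networkx.  They exist to certify, by enumeration, the results
of the minimal-subnetwork, minimal-medium, core-connection and gene
essentiality algorithms on fixtures small enough to enumerate
(<= 2**cap subsets).
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from scipy.optimize import linprog

from .model import BOUNDARY, Gem

DEFAULT_CAP = 14


class OracleCapExceeded(ValueError):
    pass


def _lp_feasible(gem: Gem, zero_rxns: set[str],
                 forcing: list[tuple[str, float, float]]) -> bool:
    """LP feasibility of S v = 0 with ``zero_rxns`` clamped and per-reaction
    net-flux forcings applied as bound intersections."""
    s, _, rxn_ids = gem.stoichiometric_matrix()
    lb = np.array([gem.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([gem.reactions[r].upper_bound for r in rxn_ids])
    for rid in zero_rxns:
        j = rxn_ids.index(rid)
        lb[j] = ub[j] = 0.0
    for rid, lo, hi in forcing:
        j = rxn_ids.index(rid)
        lb[j] = max(lb[j], lo)
        ub[j] = min(ub[j], hi)
        if lb[j] > ub[j]:
            return False
    res = linprog(np.zeros(len(rxn_ids)), A_eq=s, b_eq=np.zeros(s.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    return res.status == 0


def brute_force_min_subnetworks(gem: Gem, counted: set[str],
                                forcing: list[tuple[str, float, float]],
                                blocked: set[str] = frozenset(),
                                cap: int = DEFAULT_CAP,
                                ) -> tuple[int | None, list[frozenset]]:
    """Enumerate subsets of ``counted`` in increasing cardinality; a subset
    is feasible iff the LP with only that subset active (all other counted
    reactions blocked) satisfies the forcing.  Returns the minimum
    cardinality and every feasible set of that size, or (None, []) when no
    subset works."""
    counted_sorted = sorted(counted)
    if len(counted_sorted) > cap:
        raise OracleCapExceeded(
            f"{len(counted_sorted)} candidate reactions exceed the oracle cap {cap}")
    # feasibility is monotone in the open set: if everything open fails,
    # every subset fails
    if not _lp_feasible(gem, set(blocked), forcing):
        return None, []
    for size in range(len(counted_sorted) + 1):
        hits = []
        for subset in itertools.combinations(counted_sorted, size):
            zero = (set(counted_sorted) - set(subset)) | set(blocked)
            if _lp_feasible(gem, zero, forcing):
                hits.append(frozenset(subset))
        if hits:
            return size, hits
    return None, []


def brute_force_minimal_media(gem: Gem, growth_lb: float,
                              cap: int = DEFAULT_CAP,
                              ) -> tuple[int | None, list[frozenset]]:
    """Minimum number of open boundary reactions supporting growth, and all
    boundary subsets of that size, by exhaustive enumeration."""
    if gem.biomass_id is None:
        raise ValueError("needs a biomass reaction")
    boundaries = sorted(r for r in gem.boundary_reactions()
                        if r != gem.biomass_id)
    if len(boundaries) > cap:
        raise OracleCapExceeded(
            f"{len(boundaries)} boundary reactions exceed the oracle cap {cap}")
    forcing = [(gem.biomass_id, growth_lb, float("inf"))]
    for size in range(len(boundaries) + 1):
        hits = []
        for subset in itertools.combinations(boundaries, size):
            zero = set(boundaries) - set(subset)
            if _lp_feasible(gem, zero, forcing):
                hits.append(frozenset(subset))
        if hits:
            return size, hits
    return None, []


def brute_force_essential_genes(gem: Gem, growth_floor: float = 1e-6,
                                ) -> set[str]:
    """Exhaustive single-gene knockouts under plain FBA (LP)."""
    from cobra.core.gene import GPR

    essential = set()
    for gene in sorted(gem.genes()):
        work = gem.copy()
        for rid, rxn in work.reactions.items():
            if rxn.gene_rule and gene in rxn.genes():
                if not GPR.from_string(rxn.gene_rule).eval(knockouts={gene}):
                    rxn.lower_bound = rxn.upper_bound = 0.0
        s, _, rxn_ids = work.stoichiometric_matrix()
        c = np.zeros(len(rxn_ids))
        c[rxn_ids.index(work.biomass_id)] = -1.0
        bounds = [(work.reactions[r].lower_bound, work.reactions[r].upper_bound)
                  for r in rxn_ids]
        res = linprog(c, A_eq=s, b_eq=np.zeros(s.shape[0]), bounds=bounds,
                      method="highs")
        growth = -res.fun if res.status == 0 else 0.0
        if growth < growth_floor:
            essential.add(gene)
    return essential


def path_connection_reactions(gem: Gem, subsystems: list[str], degree: int,
                              cofactors: set[str], extracellular: str,
                              ) -> dict[int, set[str]]:
    """networkx-based oracle for the degree-D connection: all simple edge
    paths of length <= degree between subsystem metabolites, intermediates
    outside every subsystem, cofactors and the extracellular compartment
    excluded as carriers.  Returns reactions grouped by path length."""
    sub_mets: dict[str, set[str]] = {s: set() for s in subsystems}
    for rxn in gem.reactions.values():
        if rxn.subsystem in sub_mets:
            for m in rxn.stoichiometry:
                met = gem.metabolites[m]
                if m not in cofactors and met.compartment != extracellular:
                    sub_mets[rxn.subsystem].add(m)
    core_mets = set().union(*sub_mets.values()) if sub_mets else set()

    graph = nx.MultiDiGraph()

    def allowed(m: str) -> bool:
        return (m not in cofactors
                and gem.metabolites[m].compartment != extracellular)

    for rxn in gem.reactions.values():
        if gem.reaction_kind(rxn.id) == BOUNDARY:
            continue
        subs = [m for m in rxn.reactants() if allowed(m)]
        prods = [m for m in rxn.products() if allowed(m)]
        if rxn.upper_bound > 0:
            for u in subs:
                for v in prods:
                    graph.add_edge(u, v, key=rxn.id)
        if rxn.lower_bound < 0:
            for u in prods:
                for v in subs:
                    graph.add_edge(u, v, key=rxn.id)

    found: dict[int, set[str]] = {k: set() for k in range(1, degree + 1)}
    for src in sorted(core_mets & set(graph.nodes)):
        for dst in sorted(core_mets & set(graph.nodes)):
            if dst == src:
                continue
            for path in nx.all_simple_edge_paths(graph, src, dst,
                                                 cutoff=degree):
                mets_between = [e[1] for e in path[:-1]]
                if any(m in core_mets for m in mets_between):
                    continue
                rxns = [e[2] for e in path]
                if len(set(rxns)) < len(rxns):
                    continue
                found[len(path)].update(rxns)
    return found
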