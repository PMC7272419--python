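"""Minimal biosynthetic subnetworks per biomass building block (BBB) and
their lumped reactions.

A BBB that a demand flux can already pull out of the core network (plus
the medium-connection reactions and open exchanges) needs no lump.  For
each remaining BBB the same MILP as the medium-connection search finds the
smallest set of non-core reactions whose activity lets a demand of c on
the BBB be met — cofactor regeneration and by-product disposal included —
and enumerates all alternatives of that minimal size.

Each subnetwork is then collapsed into one lumped reaction: the
constituent reactions are summed with the witness fluxes of an LP re-solve
(active set fixed, BBB demand = 1) as weights.  Weights are reconstructed
as exact rationals so subnetwork-internal intermediates cancel to exactly
zero and elemental balance is preserved exactly; if reconstruction fails
the float weights are kept and the lump is flagged.  Distinct subnetworks
can collapse to the same net reaction, so lumps are deduplicated by exact
net stoichiometry before entering a reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog

from .minnet import MinNetResult, Subnetwork, minimal_subnetworks
from .model import BOUNDARY, Gem, Reaction
from .solver import INF
from .tfa import TfaConfig
from .thermo import ThermoTable

DEFAULT_DEMAND = 1e-3       # mmol/gDW/h demand floor used in classification
_WEIGHT_DENOM_CAP = 10 ** 4


def demand_reaction_id(bbb: str) -> str:
    return f"DM_{bbb}"


def _with_demand(gem: Gem, bbb: str) -> tuple[Gem, str]:
    work = gem.copy()
    rid = demand_reaction_id(bbb)
    if rid not in work.reactions:
        work.add_reaction(Reaction(rid, {bbb: -1}, 0.0, 1000.0, kind=BOUNDARY,
                                   name=f"demand for {bbb}"))
    return work, rid


def _lp_feasible_demand(gem: Gem, allowed: set[str], bbb: str,
                        c: float) -> bool:
    """Plain LP: can a demand of >= c on ``bbb`` be met using only the
    ``allowed`` reactions?  (No thermodynamics — classification is
    structural.)"""
    work, dm = _with_demand(gem, bbb)
    for rid, rxn in work.reactions.items():
        if rid != dm and rid not in allowed:
            rxn.lower_bound = rxn.upper_bound = 0.0
    work.reactions[dm].lower_bound = c
    s, _, rxn_ids = work.stoichiometric_matrix()
    bounds = [(work.reactions[r].lower_bound, work.reactions[r].upper_bound)
              for r in rxn_ids]
    res = linprog(np.zeros(len(rxn_ids)), A_eq=s, b_eq=np.zeros(s.shape[0]),
                  bounds=bounds, method="highs")
    return res.status == 0


@dataclass
class BbbClassification:
    producible: list[str]    # core-producible or medium-supplied
    needs_lump: list[str]


def classify_bbbs(gem: Gem, context_rxns: set[str],
                  c: float = DEFAULT_DEMAND) -> BbbClassification:
    """Partition the BBBs by whether the core + medium-connection context
    (plus open boundaries) can already supply them."""
    allowed = set(context_rxns) | set(gem.boundary_reactions())
    producible, needs = [], []
    for bbb in sorted(gem.bbbs()):
        if _lp_feasible_demand(gem, allowed, bbb, c):
            producible.append(bbb)
        else:
            needs.append(bbb)
    return BbbClassification(producible, needs)


def min_subnetwork_for_bbb(gem: Gem, thermo: ThermoTable | None,
                           context_rxns: set[str], bbb: str,
                           c: float = DEFAULT_DEMAND,
                           max_alternatives: int = 32,
                           size_slack: int = 0,
                           use_thermo: bool = True,
                           config: TfaConfig | None = None) -> MinNetResult:
    """All minimal subnetworks (of size Smin, or up to Smin + size_slack)
    producing ``bbb`` from the core context.

    Context reactions, boundary reactions and the demand itself are usable
    but not counted; every other reaction carries a z variable.
    """
    work, dm = _with_demand(gem, bbb)
    counted = {rid for rid in work.reactions
               if rid not in context_rxns
               and rid != dm
               and rid != gem.biomass_id
               and work.reaction_kind(rid) != BOUNDARY}
    return minimal_subnetworks(work, thermo, counted, [(dm, c, INF)], bbb,
                               max_alternatives=max_alternatives,
                               size_slack=size_slack,
                               use_thermo=use_thermo, config=config)


# ---------------------------------------------------------------------------
# Lumping
# ---------------------------------------------------------------------------

@dataclass
class LumpedReaction:
    id: str
    bbb: str
    stoichiometry: dict[str, Fraction]
    subnetwork_reactions: frozenset[str]
    gene_rule: str
    exact: bool = True   # False when rational weight reconstruction failed
    weights: dict[str, Fraction] = field(default_factory=dict)

    def equation(self) -> str:
        rxn = self.to_reaction()
        return rxn.equation()

    def to_reaction(self) -> Reaction:
        return Reaction(self.id, dict(self.stoichiometry), 0.0, 1000.0,
                        subsystem="lumped", gene_rule=self.gene_rule,
                        kind="enzymatic", name=f"lumped synthesis of {self.bbb}")

    def dedupe_key(self) -> frozenset:
        return frozenset(self.stoichiometry.items())


def _witness_weights(gem: Gem, context_rxns: set[str],
                     subnetwork: Subnetwork, bbb: str) -> dict[str, float]:
    """LP witness with the active set fixed and BBB demand = 1, minimizing
    total absolute flux for a parsimonious, reproducible weight vector."""
    work, dm = _with_demand(gem, bbb)
    allowed = set(context_rxns) | set(subnetwork.reactions) | \
        set(work.boundary_reactions()) | {dm}
    for rid, rxn in work.reactions.items():
        if rid not in allowed or rid == gem.biomass_id:
            rxn.lower_bound = rxn.upper_bound = 0.0
    work.reactions[dm].lower_bound = 1.0
    work.reactions[dm].upper_bound = 1.0

    s, _, rxn_ids = work.stoichiometric_matrix()
    n = len(rxn_ids)
    # v = vf - vr, minimize sum(vf + vr)
    a_eq = np.hstack([s, -s])
    c_vec = np.ones(2 * n)
    bounds = []
    for r in rxn_ids:
        rxn = work.reactions[r]
        bounds.append((0.0, max(0.0, rxn.upper_bound)))
    for r in rxn_ids:
        rxn = work.reactions[r]
        bounds.append((0.0, max(0.0, -rxn.lower_bound)))
    # demand fixed at 1 (both bounds 1 on forward part)
    j = rxn_ids.index(dm)
    bounds[j] = (1.0, 1.0)
    bounds[n + j] = (0.0, 0.0)
    res = linprog(c_vec, A_eq=a_eq, b_eq=np.zeros(s.shape[0]), bounds=bounds,
                  method="highs")
    if res.status != 0:
        raise RuntimeError(f"witness LP for {bbb} failed (status {res.status})")
    v = res.x[:n] - res.x[n:]
    return {rid: float(v[i]) for i, rid in enumerate(rxn_ids)
            if rid in subnetwork.reactions}


def lump(gem: Gem, context_rxns: set[str], subnetwork: Subnetwork,
         index: int = 0) -> LumpedReaction:
    """Collapse one subnetwork into its flux-weighted net reaction.

    The net stoichiometry sums only the subnetwork's reactions; metabolites
    exchanged with the core appear as net reactants/products, internal
    intermediates cancel exactly, and the BBB nets to +1 per flux unit of
    demand.
    """
    bbb = subnetwork.target
    weights_f = _witness_weights(gem, context_rxns, subnetwork, bbb)
    if all(abs(w) < 1e-9 for w in weights_f.values()) and weights_f:
        raise ValueError(f"witness produces no {bbb}: zero flux on subnetwork")

    exact = True
    weights: dict[str, Fraction] = {}
    for rid, w in weights_f.items():
        frac = Fraction(w).limit_denominator(_WEIGHT_DENOM_CAP)
        if abs(float(frac) - w) > 1e-6 * max(1.0, abs(w)):
            exact = False
        weights[rid] = frac

    net: dict[str, Fraction] = {}
    for rid, w in weights.items():
        if w == 0:
            continue
        for m, coef in gem.reactions[rid].stoichiometry.items():
            net[m] = net.get(m, Fraction(0)) + w * coef
    net = {m: c for m, c in net.items() if c != 0}

    if exact:
        # verify the witness balances: metabolites touched only by the
        # subnetwork must have cancelled
        sub_only = {m for rid in subnetwork.reactions
                    for m in gem.reactions[rid].stoichiometry}
        for rid in gem.reactions:
            if rid in subnetwork.reactions:
                continue
            if rid in context_rxns or gem.reaction_kind(rid) == BOUNDARY:
                sub_only -= set(gem.reactions[rid].stoichiometry)
        if any(m in net for m in sub_only if m != bbb):
            exact = False

    if bbb not in net or net[bbb] <= 0:
        raise ValueError(f"lump for {bbb} has non-positive BBB coefficient")
    scale = net[bbb]
    if scale != 1:
        net = {m: c / scale for m, c in net.items()}
        weights = {r: w / scale for r, w in weights.items()}

    rules = sorted({gem.reactions[r].gene_rule
                    for r in subnetwork.reactions if gem.reactions[r].gene_rule})
    gene_rule = " and ".join(f"({r})" for r in rules) if rules else ""
    return LumpedReaction(f"LMP_{bbb}_{index}", bbb, net,
                          frozenset(subnetwork.reactions), gene_rule,
                          exact, weights)


def elemental_imbalance(gem: Gem, lumped: LumpedReaction) -> dict[str, Fraction]:
    """Per-element net atom count of the lump, exactly zero whenever every
    constituent reaction is balanced (the net reaction is a weighted sum of
    balanced columns of S)."""
    totals: dict[str, Fraction] = {}
    for m, coef in lumped.stoichiometry.items():
        for elem, count in gem.metabolites[m].element_counts().items():
            totals[elem] = totals.get(elem, Fraction(0)) + coef * count
    return {e: c for e, c in totals.items() if c != 0}


def dedupe(lumps: list[LumpedReaction]) -> list[LumpedReaction]:
    """Unique lumps by exact net stoichiometry (order-independent,
    idempotent); the first representative of each net reaction is kept,
    in sorted id order."""
    seen: dict[frozenset, LumpedReaction] = {}
    for lumped in sorted(lumps, key=lambda x: x.id):
        seen.setdefault(lumped.dedupe_key(), lumped)
    return sorted(seen.values(), key=lambda x: x.id)


def lumps_for_model(gem: Gem, thermo: ThermoTable | None,
                    context_rxns: set[str],
                    c: float = DEFAULT_DEMAND,
                    flavor: str = "Smin",
                    max_alternatives: int = 32,
                    use_thermo: bool = True,
                    config: TfaConfig | None = None,
                    ) -> tuple[dict[str, MinNetResult], list[LumpedReaction], BbbClassification]:
    """Run the whole lumping stage: classify BBBs, search subnetworks for
    the ones that need them, lump, and deduplicate.

    ``flavor``: ``"one-per-BBB"`` keeps the first minimal subnetwork per
    BBB; ``"Smin"`` keeps all unique lumps of minimal size.
    """
    if flavor not in ("one-per-BBB", "Smin"):
        raise ValueError(f"unknown reduction flavor {flavor!r}")
    classification = classify_bbbs(gem, context_rxns, c)
    results: dict[str, MinNetResult] = {}
    lumps: list[LumpedReaction] = []
    for bbb in classification.needs_lump:
        cap = 1 if flavor == "one-per-BBB" else max_alternatives
        res = min_subnetwork_for_bbb(gem, thermo, context_rxns, bbb, c,
                                     max_alternatives=cap,
                                     use_thermo=use_thermo, config=config)
        results[bbb] = res
        for i, sub in enumerate(res.subnetworks):
            lumps.append(lump(gem, context_rxns, sub, i))
    return results, dedupe(lumps), classification


def lump_report_tsv(gem: Gem, lumps: list[LumpedReaction]) -> str:
    lines = ["bbb\tlump\tsize\treactions\tequation"]
    for lm in lumps:
        lines.append(f"{lm.bbb}\t{lm.id}\t{len(lm.subnetwork_reactions)}\t"
                     + ",".join(sorted(lm.subnetwork_reactions)) + "\t"
                     + lm.equation())
    return "\n".join(lines) + "\n"
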