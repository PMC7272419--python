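"""Thermodynamics-based flux analysis (TFA) as a mixed-integer program.

Every reaction's net flux is split into non-negative forward and reverse
parts, v_i = vF_i - vR_i, each coupled to a direction binary through a
big-M constraint (vF_i <= M*bF_i, vR_i <= M*bR_i, bF_i + bR_i <= 1).
Thermodynamically covered, non-boundary reactions additionally carry a
Gibbs-energy variable tied to the metabolite log-concentration variables,

    DrG'_i = DrG'0_i + RT * sum_j n_ij * ln x_j   (within estimation error)

and the binaries enforce sign consistency:

    DrG'_i - M + M*bF_i <= 0      (forward use requires DrG'_i <= 0)
   -DrG'_i - M + M*bR_i <= 0      (reverse use requires DrG'_i >= 0)

Binaries are created for every reaction — also the ones without Gibbs
variables — because the minimal-medium and minimal-subnetwork searches
reuse them as activity indicators.

Thermodynamic flux variability analysis (TVA) minimizes and maximizes each
net flux under the full constraint set; plain FVA (the LP relaxation
without any thermodynamics) is provided as the independent comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import BOUNDARY, Gem
from .solver import INF, LinearProblem, Solution, Status
from .thermo import RT, ThermoTable, gibbs_bounds, standard_reaction_gibbs
import math


class ConfigurationError(ValueError):
    """Big-M constant does not dominate the quantities it must bound."""


@dataclass
class TfaConfig:
    m_flux: float = 1000.0    # mmol/gDW/h; must exceed every flux bound
    m_gibbs: float = 1000.0   # kJ/mol; must exceed every reachable |DrG'|
    use_thermo: bool = True   # switch off for a plain (binary-indicator) FBA


class TfaProblem:
    """The TFA MILP for a model, with named variables per reaction.

    Variable naming: ``VF_<rxn>``/``VR_<rxn>`` split fluxes, ``BF_<rxn>``/
    ``BR_<rxn>`` direction binaries, ``DG_<rxn>`` Gibbs energies,
    ``LC_<met>`` log-concentrations.  Reactions are processed in sorted-id
    order so the MILP is identical across runs.
    """

    def __init__(self, gem: Gem, thermo: ThermoTable | None = None,
                 config: TfaConfig | None = None):
        self.gem = gem
        self.thermo = thermo
        self.config = config or TfaConfig()
        self.lp = LinearProblem()
        self.covered: set[str] = set()
        self._build()

    # -- variable names -------------------------------------------------
    @staticmethod
    def vf(rid: str) -> str:
        return f"VF_{rid}"

    @staticmethod
    def vr(rid: str) -> str:
        return f"VR_{rid}"

    @staticmethod
    def bf(rid: str) -> str:
        return f"BF_{rid}"

    @staticmethod
    def br(rid: str) -> str:
        return f"BR_{rid}"

    @staticmethod
    def dg(rid: str) -> str:
        return f"DG_{rid}"

    @staticmethod
    def lc(mid: str) -> str:
        return f"LC_{mid}"

    def net(self, rid: str, coef: float = 1.0) -> dict[str, float]:
        """Objective/constraint coefficients for the net flux of ``rid``."""
        return {self.vf(rid): coef, self.vr(rid): -coef}

    # -- build ----------------------------------------------------------
    def _build(self) -> None:
        gem, thermo, cfg = self.gem, self.thermo, self.config
        m_flux, m_gibbs = cfg.m_flux, cfg.m_gibbs
        rxn_ids = sorted(gem.reactions)

        worst = max((max(abs(r.lower_bound), abs(r.upper_bound))
                     for r in gem.reactions.values()), default=0.0)
        if worst > m_flux:
            raise ConfigurationError(
                f"big-M for fluxes ({m_flux}) is below a model bound ({worst})")

        use_thermo = cfg.use_thermo and thermo is not None
        if use_thermo:
            for rid in rxn_ids:
                rxn = gem.reactions[rid]
                if gem.reaction_kind(rid) == BOUNDARY or rid == gem.biomass_id:
                    continue
                # one-sided pseudo-reactions (demands, sinks, biomass-like
                # drains) are not chemical conversions: no Gibbs energy
                if not rxn.reactants() or not rxn.products():
                    continue
                if thermo.covers_reaction(gem, rxn):
                    self.covered.add(rid)

        # log-concentration variables for participants of covered reactions
        lc_mets: set[str] = set()
        for rid in sorted(self.covered):
            for m in gem.reactions[rid].stoichiometry:
                if not thermo.excluded(gem, m):
                    lc_mets.add(m)
        for mid in sorted(lc_mets):
            comp = thermo.compartment(gem.metabolites[mid].compartment)
            self.lp.add_var(self.lc(mid), math.log(comp.conc_lb),
                            math.log(comp.conc_ub))

        for rid in rxn_ids:
            rxn = gem.reactions[rid]
            lb, ub = rxn.lower_bound, rxn.upper_bound
            self.lp.add_var(self.vf(rid), 0.0, max(0.0, ub))
            self.lp.add_var(self.vr(rid), 0.0, max(0.0, -lb))
            self.lp.add_binary(self.bf(rid))
            self.lp.add_binary(self.br(rid))
            self.lp.add_constr(f"net_{rid}", self.net(rid), lb, ub)
            self.lp.add_constr(f"useF_{rid}",
                               {self.vf(rid): 1.0, self.bf(rid): -m_flux}, -INF, 0.0)
            self.lp.add_constr(f"useR_{rid}",
                               {self.vr(rid): 1.0, self.br(rid): -m_flux}, -INF, 0.0)
            self.lp.add_constr(f"dir_{rid}",
                               {self.bf(rid): 1.0, self.br(rid): 1.0}, -INF, 1.0)

            if rid in self.covered:
                gb = gibbs_bounds(gem, rxn, thermo)
                reach = max(abs(gb.minimum), abs(gb.maximum))
                if reach > m_gibbs:
                    raise ConfigurationError(
                        f"big-M for Gibbs energies ({m_gibbs}) is below the "
                        f"reachable |DrG'| of {rid} ({reach:.1f})")
                self.lp.add_var(self.dg(rid), gb.minimum, gb.maximum)
                drg0, err = standard_reaction_gibbs(gem, rxn, thermo)
                tie = {self.dg(rid): 1.0}
                for m, c in rxn.stoichiometry.items():
                    if thermo.excluded(gem, m):
                        continue
                    tie[self.lc(m)] = tie.get(self.lc(m), 0.0) - RT * float(c)
                self.lp.add_constr(f"gibbs_{rid}", tie, drg0 - err, drg0 + err)
                self.lp.add_constr(f"sgnF_{rid}",
                                   {self.dg(rid): 1.0, self.bf(rid): m_gibbs},
                                   -INF, m_gibbs)
                self.lp.add_constr(f"sgnR_{rid}",
                                   {self.dg(rid): -1.0, self.br(rid): m_gibbs},
                                   -INF, m_gibbs)

        # mass balance S v = 0
        balance: dict[str, dict[str, float]] = {m: {} for m in gem.metabolites}
        for rid in rxn_ids:
            for m, c in gem.reactions[rid].stoichiometry.items():
                row = balance[m]
                row[self.vf(rid)] = row.get(self.vf(rid), 0.0) + float(c)
                row[self.vr(rid)] = row.get(self.vr(rid), 0.0) - float(c)
        for mid in sorted(balance):
            if balance[mid]:
                self.lp.add_constr(f"mass_{mid}", balance[mid], 0.0, 0.0)

    # -- solving --------------------------------------------------------
    def solve(self, objective: dict[str, float] | None = None, sense: str = "max",
              extra_constraints=None, var_bound_overrides=None) -> "TfaSolution":
        """Optimize a linear expression over *net fluxes* ``{rxn_id: coef}``."""
        obj: dict[str, float] = {}
        for rid, coef in (objective or {}).items():
            obj[self.vf(rid)] = obj.get(self.vf(rid), 0.0) + coef
            obj[self.vr(rid)] = obj.get(self.vr(rid), 0.0) - coef
        sol = self.lp.solve(obj, sense, extra_constraints=extra_constraints,
                            var_bound_overrides=var_bound_overrides)
        return TfaSolution(sol, self)

    def max_growth(self) -> "TfaSolution":
        if self.gem.biomass_id is None:
            raise ValueError("model has no biomass reaction")
        return self.solve({self.gem.biomass_id: 1.0}, "max")


@dataclass
class TfaSolution:
    raw: Solution
    problem: TfaProblem = field(repr=False)

    @property
    def status(self) -> Status:
        return self.raw.status

    @property
    def ok(self) -> bool:
        return self.raw.ok

    @property
    def objective(self) -> float | None:
        return self.raw.objective

    def flux(self, rid: str) -> float:
        return self.raw[TfaProblem.vf(rid)] - self.raw[TfaProblem.vr(rid)]

    def fluxes(self) -> dict[str, float]:
        return {rid: self.flux(rid) for rid in self.problem.gem.reactions}

    def gibbs(self, rid: str) -> float | None:
        name = TfaProblem.dg(rid)
        return self.raw[name] if self.problem.lp.has_var(name) else None


@dataclass
class VariabilityRange:
    minimum: float | None
    maximum: float | None
    status: str = "ok"  # or "unresolved"

    @property
    def width(self) -> float:
        return (self.maximum - self.minimum) if self.status == "ok" else float("nan")


def tva(problem: TfaProblem, reaction_ids: list[str] | None = None,
        ) -> dict[str, VariabilityRange]:
    """Per-reaction net-flux range under the full TFA constraint set.

    Two MILP solves per reaction.  A failed solve marks the range
    unresolved and the scan continues.
    """
    rids = sorted(reaction_ids if reaction_ids is not None else problem.gem.reactions)
    out: dict[str, VariabilityRange] = {}
    for rid in rids:
        lo = problem.solve({rid: 1.0}, "min")
        hi = problem.solve({rid: 1.0}, "max")
        if lo.ok and hi.ok:
            out[rid] = VariabilityRange(lo.objective, hi.objective)
        else:
            out[rid] = VariabilityRange(None, None, "unresolved")
    return out


def fva(gem: Gem, reaction_ids: list[str] | None = None,
        extra_bounds: dict[str, tuple[float, float]] | None = None,
        ) -> dict[str, VariabilityRange]:
    """Plain flux variability analysis: the LP with only S v = 0 and bounds.

    Implemented directly on scipy.linprog, independently of the MILP layer,
    so it can serve as the relaxation oracle for TVA containment checks.
    """
    s, met_ids, rxn_ids = gem.stoichiometric_matrix()
    lb = np.array([gem.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([gem.reactions[r].upper_bound for r in rxn_ids])
    if extra_bounds:
        for rid, (lo, hi) in extra_bounds.items():
            j = rxn_ids.index(rid)
            lb[j], ub[j] = lo, hi
    targets = sorted(reaction_ids if reaction_ids is not None else rxn_ids)
    out: dict[str, VariabilityRange] = {}
    for rid in targets:
        j = rxn_ids.index(rid)
        c = np.zeros(len(rxn_ids))
        vals = []
        for sign in (1.0, -1.0):
            c[j] = sign
            res = linprog(c, A_eq=s, b_eq=np.zeros(s.shape[0]),
                          bounds=list(zip(lb, ub)), method="highs")
            vals.append(res.fun * sign if res.status == 0 else None)
            c[j] = 0.0
        if vals[0] is None or vals[1] is None:
            out[rid] = VariabilityRange(None, None, "unresolved")
        else:
            out[rid] = VariabilityRange(vals[0], vals[1])
    return out


def fba_max(gem: Gem, objective_rxn: str) -> float | None:
    """Plain FBA optimum (LP, no thermodynamics); None if not optimal."""
    s, met_ids, rxn_ids = gem.stoichiometric_matrix()
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_rxn)] = -1.0
    bounds = [(gem.reactions[r].lower_bound, gem.reactions[r].upper_bound)
              for r in rxn_ids]
    res = linprog(c, A_eq=s, b_eq=np.zeros(s.shape[0]), bounds=bounds,
                  method="highs")
    return -res.fun if res.status == 0 else None
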