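"""Thermodynamic properties of metabolites and reactions.

The transformed Gibbs free energy of a reaction i at metabolite
concentrations x is

    DrG'_i = sum_j n_ij * DfG'0_j  +  RT * sum_j n_ij * ln x_j

with n_ij the stoichiometric coefficient of metabolite j, DfG'0_j its
standard transformed Gibbs free energy of formation (already at the
compartment pH / ionic strength — estimating it from structure is outside
this package; it arrives as an input table), R = 8.31e-3 kJ/K/mol and
T = 298 K.  Protons and water are excluded from the concentration term:
their activity is absorbed into the transformed formation energies.

Extremizing DrG' over the compartment concentration boxes, widened by the
summed formation-energy estimation errors sum_j |n_ij|*err_j, yields a
directionality interval per reaction: DrG'_max < 0 means the reaction can
only run forward, DrG'_min > 0 only in reverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import BOUNDARY, Gem, Reaction

R_GAS = 8.31e-3   # kJ / (K mol)
T_KELVIN = 298.0  # K
RT = R_GAS * T_KELVIN  # 2.47638 kJ/mol

#: formulas excluded from the RT*ln(x) concentration product
EXCLUDED_FORMULAS = frozenset({"H", "H2O"})

UNKNOWN_REASONS = ("no-structure", "incomplete-formula", "missing-group")


@dataclass
class CompartmentData:
    """Physico-chemical properties of one compartment."""
    pH: float = 7.0
    ionic_strength: float = 0.15      # M
    membrane_potential: float = 0.0   # mV, vs reference compartment
    conc_lb: float = 1e-11            # M (10 pM)
    conc_ub: float = 0.1              # M

    def __post_init__(self):
        if not (0 < self.conc_lb <= self.conc_ub):
            raise ValueError("need 0 < conc_lb <= conc_ub")


@dataclass
class MetaboliteThermo:
    dfg0: float | None          # kJ/mol, None if unknown
    error: float = 0.0          # kJ/mol, >= 0
    reason: str | None = None   # why unknown, one of UNKNOWN_REASONS

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("estimation error must be >= 0")
        if self.dfg0 is None and self.reason is None:
            self.reason = "no-structure"

    @property
    def known(self) -> bool:
        return self.dfg0 is not None


@dataclass
class ThermoTable:
    """Formation energies per metabolite plus compartment properties."""
    metabolites: dict[str, MetaboliteThermo] = field(default_factory=dict)
    compartments: dict[str, CompartmentData] = field(default_factory=dict)

    def compartment(self, comp: str) -> CompartmentData:
        return self.compartments.get(comp, CompartmentData())

    def excluded(self, gem: Gem, met_id: str) -> bool:
        """Protons and water do not enter the concentration product."""
        return gem.metabolites[met_id].formula in EXCLUDED_FORMULAS

    def covers_reaction(self, gem: Gem, rxn: Reaction) -> bool:
        """True iff every participant (excluded species aside) has a DfG'0."""
        for m in rxn.stoichiometry:
            if self.excluded(gem, m):
                continue
            t = self.metabolites.get(m)
            if t is None or not t.known:
                return False
        return True

    # -- TSV / config I/O ----------------------------------------------
    def to_tsv(self) -> str:
        lines = ["metabolite\tdfg0_kJ_mol\terror_kJ_mol\tstatus\treason"]
        for m, t in self.metabolites.items():
            if t.known:
                lines.append(f"{m}\t{t.dfg0}\t{t.error}\tok\t")
            else:
                lines.append(f"{m}\t\t\tunknown\t{t.reason}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str,
                 compartments: dict[str, CompartmentData] | None = None) -> "ThermoTable":
        mets = {}
        for line in text.strip().splitlines()[1:]:
            parts = line.rstrip("\n").split("\t")
            mid, dfg0, err, status = parts[0], parts[1], parts[2], parts[3]
            reason = parts[4] if len(parts) > 4 else ""
            if status == "ok":
                mets[mid] = MetaboliteThermo(float(dfg0), float(err or 0.0))
            else:
                mets[mid] = MetaboliteThermo(None, 0.0, reason or "no-structure")
        return cls(mets, compartments or {})


class GibbsDomainError(ValueError):
    """A supplied concentration lies outside its compartment bounds."""


def _ln_bounds(gem: Gem, thermo: ThermoTable, met_id: str) -> tuple[float, float]:
    comp = thermo.compartment(gem.metabolites[met_id].compartment)
    return math.log(comp.conc_lb), math.log(comp.conc_ub)


def standard_reaction_gibbs(gem: Gem, rxn: Reaction,
                            thermo: ThermoTable) -> tuple[float, float] | None:
    """(DrG'0, summed |n|*error) for a covered reaction, else None."""
    if not thermo.covers_reaction(gem, rxn):
        return None
    drg0 = 0.0
    err = 0.0
    for m, c in rxn.stoichiometry.items():
        if thermo.excluded(gem, m):
            continue
        t = thermo.metabolites[m]
        drg0 += float(c) * t.dfg0
        err += abs(float(c)) * t.error
    return drg0, err


def reaction_gibbs(gem: Gem, rxn: Reaction, thermo: ThermoTable,
                   log_concentrations: dict[str, float]) -> float | None:
    """Evaluate DrG' at given ln-concentrations; None if undetermined.

    Boundary reactions have no Gibbs energy (they are exchanges with the
    environment, not chemical conversions) and raise ValueError.
    """
    if gem.reaction_kind(rxn.id) == BOUNDARY:
        raise ValueError(f"{rxn.id} is a boundary reaction: DrG' is not applicable")
    std = standard_reaction_gibbs(gem, rxn, thermo)
    if std is None:
        return None
    drg0, _ = std
    total = drg0
    for m, c in rxn.stoichiometry.items():
        if thermo.excluded(gem, m):
            continue
        ln_x = log_concentrations[m]
        lo, hi = _ln_bounds(gem, thermo, m)
        if not (lo - 1e-9 <= ln_x <= hi + 1e-9):
            raise GibbsDomainError(
                f"ln x for {m} = {ln_x:.3f} outside [{lo:.3f}, {hi:.3f}]")
        total += float(c) * RT * ln_x
    return total


FORWARD_ONLY = "forward-only"
REVERSE_ONLY = "reverse-only"
BIDIRECTIONAL = "bidirectional"
UNDETERMINED = "undetermined"


@dataclass
class GibbsBounds:
    minimum: float | None
    maximum: float | None
    direction: str

    @property
    def determined(self) -> bool:
        return self.direction != UNDETERMINED


def gibbs_bounds(gem: Gem, rxn: Reaction, thermo: ThermoTable) -> GibbsBounds:
    """Extremize DrG' over the concentration box, widened by estimation error."""
    std = standard_reaction_gibbs(gem, rxn, thermo)
    if std is None:
        return GibbsBounds(None, None, UNDETERMINED)
    drg0, err = std
    lo_sum = hi_sum = 0.0
    for m, c in rxn.stoichiometry.items():
        if thermo.excluded(gem, m):
            continue
        lo, hi = _ln_bounds(gem, thermo, m)
        cf = float(c)
        if cf > 0:
            lo_sum += cf * lo
            hi_sum += cf * hi
        else:
            lo_sum += cf * hi
            hi_sum += cf * lo
    g_min = drg0 - err + RT * lo_sum
    g_max = drg0 + err + RT * hi_sum
    if g_max < 0:
        direction = FORWARD_ONLY
    elif g_min > 0:
        direction = REVERSE_ONLY
    else:
        direction = BIDIRECTIONAL
    return GibbsBounds(g_min, g_max, direction)


@dataclass
class CoverageReport:
    n_metabolites: int
    n_metabolites_known: int
    n_reactions: int
    n_reactions_covered: int
    unknown_by_reason: dict[str, int]

    @property
    def metabolite_pct(self) -> float:
        return 100.0 * self.n_metabolites_known / self.n_metabolites if self.n_metabolites else 0.0

    @property
    def reaction_pct(self) -> float:
        return 100.0 * self.n_reactions_covered / self.n_reactions if self.n_reactions else 0.0


def coverage_report(gem: Gem, thermo: ThermoTable) -> CoverageReport:
    """How much of the model carries thermodynamic information.

    Metabolite coverage is over unique metabolites (one base species may
    appear in several compartments with distinct ids; each id counts once).
    Reaction coverage counts non-boundary reactions whose participants all
    have formation energies.
    """
    reasons = {r: 0 for r in UNKNOWN_REASONS}
    known = 0
    for m in gem.metabolites:
        t = thermo.metabolites.get(m)
        if t is not None and t.known:
            known += 1
        else:
            reason = t.reason if t is not None else "no-structure"
            reasons[reason] = reasons.get(reason, 0) + 1
    rxns = [r for r in gem.reactions.values()]
    covered = sum(1 for r in rxns
                  if gem.reaction_kind(r.id) != BOUNDARY
                  and thermo.covers_reaction(gem, r))
    return CoverageReport(len(gem.metabolites), known, len(rxns), covered, reasons)
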