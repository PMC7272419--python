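"""Genome-scale metabolic model (GEM) container, I/O, and medium curation.

The in-memory container keeps stoichiometric coefficients as exact
:class:`fractions.Fraction` objects so that downstream summation of
reactions into lumped reactions cancels intermediates exactly instead of
accumulating floating-point residue.  SBML (Level 3 + FBC) import/export
is delegated to COBRApy; a small JSON dialect is the native round-trip
format for toy models and reduced models.

Metabolite ids follow the compartment-suffix convention ``<base>_<comp>``
(e.g. ``glc_c`` for cytosolic glucose, ``glc_e`` for extracellular).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction

DEFAULT_BOUND = 1000.0

# Reaction kinds (structural; can be overridden by explicit annotation)
ENZYMATIC = "enzymatic"
TRANSPORT = "transport"
BOUNDARY = "boundary"

_DENOM_CAP = 10 ** 6  # decimal inputs are snapped to rationals below this cap


def as_fraction(x) -> Fraction:
    """Coerce a stoichiometric coefficient to an exact rational.

    Strings like ``"2/3"`` are parsed exactly; floats are reconstructed with
    a denominator cap of 10**6 (metabolic models rarely need more than a few
    decimal places, but biomass coefficients are long decimals).
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, str):
        return Fraction(x)
    return Fraction(x).limit_denominator(_DENOM_CAP)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str = ""
    charge: int = 0
    compartment: str = "c"
    annotation: dict = field(default_factory=dict)

    def element_counts(self) -> dict[str, int]:
        """Parse a Hill-style formula (``C6H12O6``) into element counts."""
        counts: dict[str, int] = {}
        for elem, num in re.findall(r"([A-Z][a-z]?)(\d*)", self.formula or ""):
            counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        return counts


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    subsystem: str = ""
    gene_rule: str = ""
    kind: str | None = None  # None -> inferred structurally
    name: str = ""

    def __post_init__(self) -> None:
        self.stoichiometry = {m: as_fraction(c) for m, c in self.stoichiometry.items()}

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def reactants(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]

    def genes(self) -> set[str]:
        return set(re.findall(r"[A-Za-z0-9_.\-]+", self.gene_rule)) - {"and", "or", "AND", "OR"}

    def equation(self) -> str:
        def side(items):
            return " + ".join(
                (f"{c} {m}" if c != 1 else m) for m, c in items)
        lhs = side(sorted((m, -c) for m, c in self.stoichiometry.items() if c < 0))
        rhs = side(sorted((m, c) for m, c in self.stoichiometry.items() if c > 0))
        arrow = "<=>" if self.reversible else ("<--" if self.upper_bound <= 0 else "-->")
        return f"{lhs} {arrow} {rhs}"


class ValidationError(ValueError):
    """Raised when a model violates its structural invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid model:\n" + "\n".join(f"- {v}" for v in violations))


class FormatError(ValueError):
    """Raised when an input file cannot be parsed under the named format."""


class Gem:
    """A genome-scale metabolic model.

    Parameters
    ----------
    metabolites, reactions:
        Iterables of :class:`Metabolite` / :class:`Reaction`.  Order is
        preserved; ids must be unique.
    biomass_id:
        Id of the biomass reaction, if the model has one.  Its reactants
        are the biomass building blocks (BBBs).
    """

    def __init__(self, model_id: str = "model", metabolites=(), reactions=(),
                 compartments: list[str] | None = None, biomass_id: str | None = None,
                 extracellular: str = "e"):
        self.id = model_id
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.extracellular = extracellular
        for m in metabolites:
            self.add_metabolite(m)
        for r in reactions:
            self.add_reaction(r)
        self.compartments = compartments or sorted(
            {m.compartment for m in self.metabolites.values()})
        self.biomass_id = biomass_id

    # -- construction ---------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValidationError([f"duplicate metabolite id {met.id!r}"])
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValidationError([f"duplicate reaction id {rxn.id!r}"])
        self.reactions[rxn.id] = rxn

    def copy(self) -> "Gem":
        gem = Gem(self.id,
                  [replace(m, annotation=dict(m.annotation))
                   for m in self.metabolites.values()],
                  [replace(r, stoichiometry=dict(r.stoichiometry))
                   for r in self.reactions.values()],
                  compartments=list(self.compartments),
                  biomass_id=self.biomass_id,
                  extracellular=self.extracellular)
        return gem

    # -- classification -------------------------------------------------
    def reaction_kind(self, rxn_id: str) -> str:
        """Structural kind: boundary (1 metabolite), transport (>=2
        compartments), else enzymatic.  Explicit ``Reaction.kind`` wins."""
        rxn = self.reactions[rxn_id]
        if rxn.kind is not None:
            return rxn.kind
        if len(rxn.stoichiometry) == 1:
            return BOUNDARY
        comps = {self.metabolites[m].compartment for m in rxn.stoichiometry}
        return TRANSPORT if len(comps) >= 2 else ENZYMATIC

    def boundary_reactions(self) -> list[str]:
        return [r for r in self.reactions if self.reaction_kind(r) == BOUNDARY]

    def transport_reactions(self) -> list[str]:
        return [r for r in self.reactions if self.reaction_kind(r) == TRANSPORT]

    def boundary_of(self, met_id: str) -> list[str]:
        return [r for r in self.boundary_reactions()
                if met_id in self.reactions[r].stoichiometry]

    def extracellular_metabolites(self) -> list[str]:
        return [m for m, met in self.metabolites.items()
                if met.compartment == self.extracellular]

    def bbbs(self) -> list[str]:
        """Biomass building blocks: the reactant side of the biomass reaction."""
        if self.biomass_id is None:
            return []
        return self.reactions[self.biomass_id].reactants()

    def genes(self) -> set[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            out |= r.genes()
        return out

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise ValidationError listing all
        violations at once."""
        bad: list[str] = []
        for r in self.reactions.values():
            for m, c in r.stoichiometry.items():
                if m not in self.metabolites:
                    bad.append(f"reaction {r.id}: undeclared metabolite {m!r}")
                if c == 0:
                    bad.append(f"reaction {r.id}: zero coefficient for {m}")
            if r.lower_bound > r.upper_bound:
                bad.append(f"reaction {r.id}: lower bound > upper bound")
            if not r.stoichiometry:
                bad.append(f"reaction {r.id}: empty stoichiometry")
        for m in self.metabolites.values():
            if m.compartment not in self.compartments:
                bad.append(f"metabolite {m.id}: unknown compartment {m.compartment!r}")
        if self.biomass_id is not None:
            if self.biomass_id not in self.reactions:
                bad.append(f"biomass reaction {self.biomass_id!r} not found")
            elif not self.reactions[self.biomass_id].reactants():
                bad.append("biomass reaction has no reactants")
        if bad:
            raise ValidationError(bad)

    # -- linear algebra -------------------------------------------------
    def stoichiometric_matrix(self):
        """Dense float S (metabolites x reactions) plus id orderings."""
        import numpy as np
        met_ids = sorted(self.metabolites)
        rxn_ids = sorted(self.reactions)
        mi = {m: i for i, m in enumerate(met_ids)}
        s = np.zeros((len(met_ids), len(rxn_ids)))
        for j, r in enumerate(rxn_ids):
            for m, c in self.reactions[r].stoichiometry.items():
                s[mi[m], j] = float(c)
        return s, met_ids, rxn_ids


# ---------------------------------------------------------------------------
# Medium definition and curation
# ---------------------------------------------------------------------------

@dataclass
class MediumDefinition:
    """Extracellular metabolites allowed to be taken up.

    ``uptakes`` maps extracellular metabolite id -> maximal uptake rate in
    mmol/gDW/h (>= 0).  Secretion of any metabolite is open unless listed
    in ``closed_secretions``.
    """
    uptakes: dict[str, float]
    closed_secretions: set[str] = field(default_factory=set)

    def __post_init__(self):
        for m, rate in self.uptakes.items():
            if rate < 0:
                raise ValidationError([f"medium {m}: uptake rate must be >= 0"])

    def validate_against(self, gem: Gem) -> None:
        bad = [m for m in self.uptakes
               if m not in gem.metabolites
               or gem.metabolites[m].compartment != gem.extracellular]
        if bad:
            raise ValidationError(
                [f"medium metabolite {m} is not an extracellular metabolite of the model"
                 for m in bad])


@dataclass
class CurationRule:
    """A predicate-based closure rule for boundary/transport reactions.

    kinds:
      ``close_orphan_exchanges`` — close uptake through exchanges of
      extracellular metabolites that have no transport reaction (an
      exchange for a species the cell cannot actually import).
      ``forbid_transport_cargo`` — close (both directions) transport
      reactions carrying a metabolite whose formula contains ``element``
      or whose name/id matches ``pattern`` (e.g. CoA or ACP conjugates).
    """
    name: str
    kind: str
    element: str | None = None
    pattern: str | None = None

    def matches_metabolite(self, met: Metabolite) -> bool:
        if self.element is not None and self.element in met.element_counts():
            return True
        if self.pattern is not None:
            rx = re.compile(self.pattern, re.IGNORECASE)
            if rx.search(met.name or "") or rx.search(met.id):
                return True
        return False


def default_curation_rules() -> list[CurationRule]:
    """Default boundary-curation rule set: no exchange of species lacking a
    transporter, and no transport of phosphorylated, CoA- or ACP-carrying
    cargo across the membrane."""
    return [
        CurationRule("orphan-exchange", "close_orphan_exchanges"),
        CurationRule("no-P-transport", "forbid_transport_cargo", element="P"),
        CurationRule("no-CoA-transport", "forbid_transport_cargo", pattern=r"coa"),
        CurationRule("no-ACP-transport", "forbid_transport_cargo", pattern=r"acp"),
    ]


@dataclass
class CurationEntry:
    reaction: str
    rule: str
    action: str
    detail: str = ""


@dataclass
class CurationReport:
    entries: list[CurationEntry] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["reaction\trule\taction\tdetail"]
        for e in self.entries:
            lines.append(f"{e.reaction}\t{e.rule}\t{e.action}\t{e.detail}")
        for w in self.warnings:
            lines.append(f"-\twarning\t-\t{w}")
        return "\n".join(lines) + "\n"


def _close_uptake(gem: Gem, rxn: Reaction) -> bool:
    """Close the uptake direction of an exchange; return True if changed.

    For an exchange written ``A_e -->`` (coefficient -1) uptake is negative
    flux, so the lower bound is raised to 0; for the ``--> A_e`` orientation
    the upper bound is cut to 0.
    """
    coef = next(iter(rxn.stoichiometry.values()))
    if coef < 0:
        if rxn.lower_bound < 0:
            rxn.lower_bound = 0.0
            return True
    else:
        if rxn.upper_bound > 0:
            rxn.upper_bound = 0.0
            return True
    return False


def _set_uptake_cap(gem: Gem, rxn: Reaction, rate: float) -> None:
    coef = next(iter(rxn.stoichiometry.values()))
    if coef < 0:
        rxn.lower_bound = max(rxn.lower_bound, -rate)
    else:
        rxn.upper_bound = min(rxn.upper_bound, rate)


def apply_medium_curation(gem: Gem, medium: MediumDefinition,
                          rules: list[CurationRule] | None = None,
                          ) -> tuple[Gem, CurationReport]:
    """Return a curated copy of ``gem`` plus a report of every closure.

    Boundary reactions of extracellular metabolites not in the medium are
    closed for uptake; rule predicates close orphan exchanges and forbidden
    transports.  Curation only ever tightens bounds.
    """
    medium.validate_against(gem)
    rules = list(rules) if rules is not None else []
    out = gem.copy()
    report = CurationReport()

    transported = set()
    for t in out.transport_reactions():
        transported.update(out.reactions[t].stoichiometry)

    for rid in out.boundary_reactions():
        rxn = out.reactions[rid]
        met_id = next(iter(rxn.stoichiometry))
        if met_id in medium.uptakes:
            _set_uptake_cap(out, rxn, medium.uptakes[met_id])
            continue
        if _close_uptake(out, rxn):
            report.entries.append(CurationEntry(
                rid, "non-medium", "uptake closed", f"metabolite {met_id}"))
        if met_id in medium.closed_secretions:
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
            rxn.upper_bound = min(rxn.upper_bound, 0.0)

    for rule in rules:
        if rule.kind == "close_orphan_exchanges":
            for rid in out.boundary_reactions():
                rxn = out.reactions[rid]
                met_id = next(iter(rxn.stoichiometry))
                if met_id not in transported and _close_uptake(out, rxn):
                    report.entries.append(CurationEntry(
                        rid, rule.name, "uptake closed",
                        f"{met_id} has no transport reaction"))
        elif rule.kind == "forbid_transport_cargo":
            for rid in out.transport_reactions():
                rxn = out.reactions[rid]
                hit = [m for m in rxn.stoichiometry
                       if rule.matches_metabolite(out.metabolites[m])]
                if hit and (rxn.lower_bound, rxn.upper_bound) != (0.0, 0.0):
                    rxn.lower_bound = 0.0
                    rxn.upper_bound = 0.0
                    report.entries.append(CurationEntry(
                        rid, rule.name, "blocked", f"cargo {','.join(sorted(hit))}"))
        else:
            raise ValueError(f"unknown curation rule kind {rule.kind!r}")

    for met_id in medium.uptakes:
        if not out.boundary_of(met_id):
            report.warnings.append(
                f"medium metabolite {met_id} has no boundary reaction; "
                "it may still be connected through transports")
    return out, report


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def gem_to_dict(gem: Gem) -> dict:
    return {
        "id": gem.id,
        "compartments": list(gem.compartments),
        "extracellular": gem.extracellular,
        "biomass": gem.biomass_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "formula": m.formula,
             "charge": m.charge, "compartment": m.compartment,
             "annotation": m.annotation}
            for m in gem.metabolites.values()
        ],
        "reactions": [
            {"id": r.id, "name": r.name,
             "stoichiometry": {m: str(c) for m, c in r.stoichiometry.items()},
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
             "subsystem": r.subsystem, "gene_rule": r.gene_rule,
             **({"kind": r.kind} if r.kind is not None else {})}
            for r in gem.reactions.values()
        ],
    }


def gem_from_dict(data: dict) -> Gem:
    try:
        mets = [Metabolite(m["id"], m.get("name", ""), m.get("formula", ""),
                           m.get("charge", 0), m.get("compartment", "c"),
                           m.get("annotation", {}))
                for m in data["metabolites"]]
        rxns = [Reaction(r["id"],
                         {m: Fraction(c) for m, c in r["stoichiometry"].items()},
                         r.get("lower_bound", -DEFAULT_BOUND),
                         r.get("upper_bound", DEFAULT_BOUND),
                         r.get("subsystem", ""), r.get("gene_rule", ""),
                         r.get("kind"), r.get("name", ""))
                for r in data["reactions"]]
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"malformed model record: {exc}") from exc
    gem = Gem(data.get("id", "model"), mets, rxns,
              compartments=data.get("compartments"),
              biomass_id=data.get("biomass"),
              extracellular=data.get("extracellular", "e"))
    gem.validate()
    return gem


def write_json(gem: Gem, path) -> None:
    with open(path, "w") as fh:
        json.dump(gem_to_dict(gem), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path) -> Gem:
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    return gem_from_dict(data)


# ---------------------------------------------------------------------------
# SBML via COBRApy
# ---------------------------------------------------------------------------

def to_cobra(gem: Gem):
    """Convert to a cobra.Model (float stoichiometry)."""
    import cobra

    model = cobra.Model(gem.id)
    cmets = {}
    for m in gem.metabolites.values():
        cm = cobra.Metabolite(m.id, formula=m.formula or None, name=m.name,
                              charge=m.charge, compartment=m.compartment)
        cmets[m.id] = cm
    model.add_metabolites(list(cmets.values()))
    crxns = []
    for r in gem.reactions.values():
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        crxns.append(cr)
    model.add_reactions(crxns)
    subsystems: dict[str, list] = {}
    for r in gem.reactions.values():
        cr = model.reactions.get_by_id(r.id)
        cr.add_metabolites({cmets[m]: float(c) for m, c in r.stoichiometry.items()})
        cr.subsystem = r.subsystem
        if r.subsystem:
            subsystems.setdefault(r.subsystem, []).append(cr)
        if r.gene_rule:
            cr.gene_reaction_rule = r.gene_rule
    # subsystems travel as SBML groups
    model.add_groups([cobra.core.Group(name, members=members)
                      for name, members in sorted(subsystems.items())])
    if gem.biomass_id:
        model.objective = gem.biomass_id
    return model


def from_cobra(model, biomass_id: str | None = None, extracellular: str = "e") -> Gem:
    subsystem_of: dict[str, str] = {}
    for group in getattr(model, "groups", []):
        for member in group.members:
            subsystem_of.setdefault(member.id, group.id)
    mets = [Metabolite(m.id, m.name or "", m.formula or "", int(m.charge or 0),
                       m.compartment or "c")
            for m in model.metabolites]
    rxns = [Reaction(r.id,
                     {m.id: as_fraction(c) for m, c in r.metabolites.items()},
                     float(r.lower_bound), float(r.upper_bound),
                     r.subsystem or subsystem_of.get(r.id, ""),
                     r.gene_reaction_rule or "",
                     None, r.name or "")
            for r in model.reactions]
    if biomass_id is None:
        for r in model.reactions:
            if "biomass" in r.id.lower():
                biomass_id = r.id
                break
    gem = Gem(model.id or "model", mets, rxns, biomass_id=biomass_id,
              extracellular=extracellular)
    gem.validate()
    return gem


def read_sbml(path, **kw) -> Gem:
    from cobra.io import read_sbml_model
    try:
        model = read_sbml_model(str(path))
    except Exception as exc:  # cobra raises various libsbml wrappers
        raise FormatError(f"{path}: SBML parse failure ({exc})") from exc
    return from_cobra(model, **kw)


def write_sbml(gem: Gem, path) -> None:
    from cobra.io import write_sbml_model
    write_sbml_model(to_cobra(gem), str(path))


def load_gem(path, fmt: str | None = None) -> Gem:
    """Load a model from SBML (.xml/.sbml) or the JSON dialect (.json)."""
    p = str(path)
    if fmt is None:
        fmt = "sbml" if p.endswith((".xml", ".sbml")) else "tabular-json"
    if fmt == "sbml":
        return read_sbml(p)
    if fmt == "tabular-json":
        return read_json(p)
    raise ValueError(f"unknown format {fmt!r}")


def write_gem(gem: Gem, path, fmt: str | None = None) -> None:
    p = str(path)
    if fmt is None:
        fmt = "sbml" if p.endswith((".xml", ".sbml")) else "tabular-json"
    if fmt == "sbml":
        write_sbml(gem, p)
    else:
        write_json(gem, p)
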