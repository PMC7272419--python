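"""Deterministic toy models with planted, provable ground truth.

The generator does not sample network structure: every property a test
relies on (which reactions the intra-expansion finds, which bridges exist
at which degree, the minimal-subnetwork size and alternative count per
medium metabolite and per biomass building block, the minimal-medium
size) is built in by construction and — unless ``verify=False`` — is
re-derived by the exhaustive oracles before the fixture is handed out.
The seed only shuffles insertion order of metabolites and reactions; all
algorithms in this package iterate in sorted-id order, so results are
seed-invariant while serialized fixtures are byte-identical per seed.

Blueprint of the planted model (defaults):

    medium  u1_e --T_U1--> u1_c --R_U1--> u2_c --R_U2--> u3_c   [UPPER]
            alt_e --T_ALT--> u1_c                  (alternative carbon)
            med_e --T_MED--> mc0_c --...--> u2_c   (planted-Smin chain)
            n_e  --T_N--> n_c --T_NSEC--> wn_e     (nitrogen in, waste out)
    core    u1_c --R_UX--> u3_c                    (intra-expansion plant)
            u3_c --R_B1--> l1_c                    (degree-1 bridge)
            u3_c --R_B2a--> x1_c --R_B2b--> l1_c   (degree-2 bridge)
            l1_c --R_L1--> l2_c;  l2_c --T_SEC--> sec_e  [LOWER]
    lump    l2_c + cof_c -> q1_c + w_c; q... -> p_c; w_c -> cof_c
    biomass l2_c + p_c + n_c ->
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .lumpgem import classify_bbbs, demand_reaction_id
from .model import BOUNDARY, Gem, MediumDefinition, Metabolite, Reaction
from .oracles import (brute_force_essential_genes, brute_force_min_subnetworks,
                      brute_force_minimal_media, path_connection_reactions)
from .redgem import PROV_INITIAL, PROV_INTRA, CoreConfig, pairwise_connect
from .redgemx import classify
from .thermo import CompartmentData, MetaboliteThermo, ThermoTable

UPPER = "UPPER"
LOWER = "LOWER"
BIOSYN = "BIOSYN"
UPTAKE_FLOOR = 1e-3


class FixtureError(RuntimeError):
    """A generated fixture contradicted its own planted ground truth."""


@dataclass
class FixtureSpec:
    seed: int = 1
    medium_chain_len: int = 2       # planted Smin of the distal medium metabolite
    medium_alternatives: int = 2    # parallel final steps of that chain
    bbb_chain_len: int = 2          # conversions from l2_c to the lumped BBB
    bbb_alternatives: int = 1       # parallel final steps of the BBB chain
    uptake_rate: float = 10.0       # mmol/gDW/h on every exchange
    growth_lb: float = 0.1          # 1/h floor used for the minimal medium
    verify: bool = True

    def __post_init__(self):
        if self.medium_chain_len < 1 or self.bbb_chain_len < 2:
            raise ValueError("medium chain >= 1 and bbb chain >= 2 required")
        if min(self.medium_alternatives, self.bbb_alternatives) < 1:
            raise ValueError("alternative counts must be >= 1")


@dataclass
class GroundTruth:
    core_initial: set[str]
    core_intra: set[str]
    core_degree: dict[int, set[str]]
    medium: MediumDefinition
    medium_targets: dict[str, tuple[int, int]]
    unconnectable_targets: set[str]
    bbb_producible: list[str]
    bbb_targets: dict[str, tuple[int, int]]
    imm_size: int
    imm_alternatives: int
    growth_lb: float
    core_config: CoreConfig
    essential_genes: set[str] = field(default_factory=set)


def _neutral_thermo(gem: Gem) -> ThermoTable:
    """All formation energies zero, errors zero: every conversion has
    DrG'0 = 0 and stays bidirectional over the default concentration box,
    so thermodynamics is attached but non-constraining."""
    return ThermoTable({m: MetaboliteThermo(0.0, 0.0) for m in gem.metabolites},
                       {"c": CompartmentData(), "e": CompartmentData()})


def make_toy_gem(spec: FixtureSpec) -> tuple[Gem, ThermoTable, GroundTruth]:
    """Build the planted fixture; verify every planted property with the
    brute-force oracles unless spec.verify is off."""
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []

    def met(mid, formula, comp):
        mets.append(Metabolite(mid, mid, formula, 0, comp))

    def rxn(rid, stoich, sub="", gene="", lb=0.0, ub=1000.0):
        rxns.append(Reaction(rid, stoich, lb, ub, sub, gene))

    for mid in ("u1", "u2", "u3", "l1", "l2", "x1", "p"):
        met(f"{mid}_c", "C4", "c")
    for k in range(1, spec.bbb_chain_len):
        met(f"q{k}_c", "C4", "c")
    met("cof_c", "C1", "c")
    met("w_c", "C1", "c")
    met("n_c", "N", "c")
    for mid in ("u1", "alt", "med", "sec"):
        met(f"{mid}_e", "C4", "e")
    met("n_e", "N", "e")
    met("wn_e", "N", "e")
    for k in range(spec.medium_chain_len - 1):
        met(f"mc{k}_c", "C4", "c")

    up = spec.uptake_rate
    # exchanges (export-positive orientation) and transports
    for base in ("u1", "alt", "med", "n"):
        rxn(f"EX_{base}_e", {f"{base}_e": -1}, lb=-up, ub=1000.0)
    rxn("EX_sec_e", {"sec_e": -1}, lb=0.0, ub=1000.0)
    rxn("EX_wn_e", {"wn_e": -1}, lb=0.0, ub=1000.0)
    rxn("T_U1", {"u1_e": -1, "u1_c": 1}, gene="gT1")
    rxn("T_ALT", {"alt_e": -1, "u1_c": 1}, gene="gTalt")
    rxn("T_N", {"n_e": -1, "n_c": 1}, gene="gTn")
    rxn("T_NSEC", {"n_c": -1, "wn_e": 1}, "OTHER", "gNsec")

    # UPPER / LOWER subsystems, intra-expansion plant, bridges, carbon sink
    rxn("R_U1", {"u1_c": -1, "u2_c": 1}, UPPER, "gU1")
    rxn("R_U2", {"u2_c": -1, "u3_c": 1}, UPPER, "gU2a or gU2b")
    rxn("R_L1", {"l1_c": -1, "l2_c": 1}, LOWER, "gL1a and gL1b")
    rxn("T_SEC", {"l2_c": -1, "sec_e": 1}, LOWER, "gSec")
    rxn("R_UX", {"u1_c": -1, "u3_c": 1}, "MISC", "gUX")
    rxn("R_B1", {"u3_c": -1, "l1_c": 1}, "OTHER", "gB1")
    rxn("R_B2a", {"u3_c": -1, "x1_c": 1}, "OTHER", "gB2a")
    rxn("R_B2b", {"x1_c": -1, "l1_c": 1}, "OTHER", "gB2b")

    # planted medium chain med_e -> ... -> u2_c with parallel last steps
    med_smin = spec.medium_chain_len
    if med_smin == 1:
        for a in range(spec.medium_alternatives):
            rxn(f"T_MED{a}", {"med_e": -1, "u2_c": 1}, gene=f"gTmed{a}")
    else:
        rxn("T_MED", {"med_e": -1, "mc0_c": 1}, gene="gTmed")
        for k in range(1, med_smin - 1):
            rxn(f"C_MED{k}", {f"mc{k - 1}_c": -1, f"mc{k}_c": 1},
                "TRANSIT", f"gCmed{k}")
        last = f"mc{med_smin - 2}_c"
        for a in range(spec.medium_alternatives):
            rxn(f"C_MEDF{a}", {last: -1, "u2_c": 1}, "TRANSIT", f"gCmedF{a}")

    # planted BBB chain with cofactor regeneration
    rxn("R_P1", {"l2_c": -1, "cof_c": -1, "q1_c": 1, "w_c": 1}, BIOSYN, "gP1")
    for k in range(2, spec.bbb_chain_len):
        rxn(f"R_P{k}", {f"q{k - 1}_c": -1, f"q{k}_c": 1}, BIOSYN, f"gP{k}")
    last_q = f"q{spec.bbb_chain_len - 1}_c"
    for a in range(spec.bbb_alternatives):
        rxn(f"R_PF{a}", {last_q: -1, "p_c": 1}, BIOSYN, f"gPF{a}")
    rxn("R_W", {"w_c": -1, "cof_c": 1}, BIOSYN, "gW")

    rxn("BIOMASS", {"l2_c": -1, "p_c": -1, "n_c": -1})

    rng = random.Random(spec.seed)
    rng.shuffle(mets)
    rng.shuffle(rxns)
    gem = Gem(f"planted_toy_seed{spec.seed}", mets, rxns, biomass_id="BIOMASS")
    gem.validate()
    thermo = _neutral_thermo(gem)

    bbb_smin = spec.bbb_chain_len + 1  # chain + cofactor regeneration
    medium = MediumDefinition({"u1_e": up, "n_e": up, "med_e": up, "wn_e": 0.0})
    config = CoreConfig([UPPER, LOWER], degree=1)
    truth = GroundTruth(
        core_initial={"R_U1", "R_U2", "R_L1", "T_SEC"},
        core_intra={"R_UX"},
        core_degree={1: {"R_B1"}, 2: {"R_B2a", "R_B2b"}},
        medium=medium,
        medium_targets={
            "u1_e": (1, 1), "n_e": (2, 1),
            "med_e": (med_smin, spec.medium_alternatives)},
        unconnectable_targets={"wn_e"},
        bbb_producible=["l2_c", "n_c"],
        bbb_targets={"p_c": (bbb_smin, spec.bbb_alternatives)},
        imm_size=2, imm_alternatives=3,
        growth_lb=spec.growth_lb,
        core_config=config,
    )
    truth.essential_genes = brute_force_essential_genes(gem)
    if spec.verify:
        _verify(gem, truth)
    return gem, thermo, truth


def medium_forcing(gem: Gem, target: str,
                   c: float = UPTAKE_FLOOR,
                   ) -> tuple[Gem, list[tuple[str, float, float]]]:
    """Uptake-forcing setup shared by oracle runs and tests."""
    ex = sorted(gem.boundary_of(target))[0]
    work = gem.copy()
    work.reactions[ex].lower_bound = min(work.reactions[ex].lower_bound, -c)
    return work, [(ex, -float("inf"), -c)]


def _verify(gem: Gem, truth: GroundTruth) -> None:
    """Re-derive every planted property with the independent oracles; a
    fixture that fails is never emitted."""
    config = truth.core_config
    core = pairwise_connect(gem, config)
    found = {tag: {r for r, p in core.reactions.items() if p == tag}
             for tag in (PROV_INITIAL, PROV_INTRA, "degree-1")}
    paths = path_connection_reactions(gem, config.subsystems, 2, set(),
                                      gem.extracellular)
    known = truth.core_initial | truth.core_intra
    if (found[PROV_INITIAL] != truth.core_initial
            or found[PROV_INTRA] != truth.core_intra
            or found["degree-1"] != truth.core_degree[1]
            or paths[1] - known != truth.core_degree[1]
            or (paths[2] - paths[1]) - known != truth.core_degree[2]):
        raise FixtureError("core-network plant contradicted")

    classification = classify(gem, core, truth.medium)
    counted = classification.counted(gem)
    context = set(core.reaction_ids)
    for target, (smin, n_alt) in truth.medium_targets.items():
        work, forcing = medium_forcing(gem, target)
        size, sets = brute_force_min_subnetworks(
            work, counted, forcing, classification.blocked_rxns)
        if size != smin or len(sets) != n_alt:
            raise FixtureError(
                f"medium target {target}: planted ({smin},{n_alt}), "
                f"oracle ({size},{len(sets)})")
        for s in sets:
            context |= s
    for target in truth.unconnectable_targets:
        work, forcing = medium_forcing(gem, target)
        size, _ = brute_force_min_subnetworks(
            work, counted, forcing, classification.blocked_rxns)
        if size is not None:
            raise FixtureError(f"{target} was planted unconnectable")

    bbb_cls = classify_bbbs(gem, context)
    if (bbb_cls.producible != sorted(truth.bbb_producible)
            or bbb_cls.needs_lump != sorted(truth.bbb_targets)):
        raise FixtureError("BBB partition plant contradicted")
    for bbb, (smin, n_alt) in truth.bbb_targets.items():
        work = gem.copy()
        dm = demand_reaction_id(bbb)
        work.add_reaction(Reaction(dm, {bbb: -1}, UPTAKE_FLOOR, 1000.0,
                                   kind=BOUNDARY))
        bbb_counted = {r for r in gem.reactions
                       if r not in context and r != gem.biomass_id
                       and gem.reaction_kind(r) != BOUNDARY}
        size, sets = brute_force_min_subnetworks(
            work, bbb_counted, [(dm, UPTAKE_FLOOR, float("inf"))])
        if size != smin or len(sets) != n_alt:
            raise FixtureError(
                f"BBB {bbb}: planted ({smin},{n_alt}), "
                f"oracle ({size},{len(sets)})")

    size, sets = brute_force_minimal_media(gem, truth.growth_lb)
    if size != truth.imm_size or len(sets) != truth.imm_alternatives:
        raise FixtureError(
            f"minimal medium: planted ({truth.imm_size},"
            f"{truth.imm_alternatives}), oracle ({size},{len(sets)})")


# ---------------------------------------------------------------------------
# Special-purpose fixtures
# ---------------------------------------------------------------------------

def make_thermo_toy() -> tuple[Gem, ThermoTable]:
    """A chain where thermodynamics matters: CONV (a->b, DrG'0 = +70) is
    reverse-only over the default concentration box and blocks the only
    path to biomass; CONV2 (a->c, DrG'0 = -70) is forward-only although
    its flux bounds are reversible."""
    mets = [Metabolite(f"{b}_{c}", f"{b}_{c}", "C2", 0, c)
            for b, c in (("a", "e"), ("a", "c"), ("b", "c"), ("c", "c"))]
    rxns = [
        Reaction("EX_a_e", {"a_e": -1}, -10.0, 1000.0),
        Reaction("T_A", {"a_e": -1, "a_c": 1}, -1000.0, 1000.0),
        Reaction("CONV", {"a_c": -1, "b_c": 1}, 0.0, 10.0),
        Reaction("CONV2", {"a_c": -1, "c_c": 1}, -10.0, 10.0),
        Reaction("DM_C", {"c_c": -1}, -10.0, 10.0),
        Reaction("BIOMASS", {"b_c": -1}, 0.0, 1000.0),
    ]
    gem = Gem("thermo_toy", mets, rxns, biomass_id="BIOMASS")
    gem.validate()
    thermo = ThermoTable(
        {"a_e": MetaboliteThermo(0.0), "a_c": MetaboliteThermo(0.0),
         "b_c": MetaboliteThermo(70.0), "c_c": MetaboliteThermo(-70.0)},
        {"c": CompartmentData(), "e": CompartmentData()})
    return gem, thermo


def make_leukemia_toy() -> tuple[Gem, ThermoTable]:
    """A respiration toy wired so the measured leukemia physiology (growth
    cap 0.035 1/h, O2 uptake cap 2, ATP maintenance 1.07 mmol/gDW/h) is
    simultaneously satisfiable and the growth cap is the active limit."""
    mets = [
        Metabolite("glc_e", "glucose", "C6H12O6", 0, "e"),
        Metabolite("glc_c", "glucose", "C6H12O6", 0, "c"),
        Metabolite("o2_e", "oxygen", "O2", 0, "e"),
        Metabolite("o2_c", "oxygen", "O2", 0, "c"),
        Metabolite("co2_e", "carbon dioxide", "CO2", 0, "e"),
        Metabolite("co2_c", "carbon dioxide", "CO2", 0, "c"),
        Metabolite("h2o_c", "water", "H2O", 0, "c"),
        Metabolite("atp_c", "ATP-equivalent", "C10", 0, "c"),
        Metabolite("adp_c", "ADP-equivalent", "C10", 0, "c"),
    ]
    rxns = [
        Reaction("EX_glc_e", {"glc_e": -1}, -10.0, 1000.0),
        Reaction("EX_o2_e", {"o2_e": -1}, -1000.0, 1000.0),
        Reaction("EX_co2_e", {"co2_e": -1}, 0.0, 1000.0),
        Reaction("T_GLC", {"glc_e": -1, "glc_c": 1}, 0.0, 1000.0,
                 gene_rule="gGLUT"),
        Reaction("T_O2", {"o2_e": -1, "o2_c": 1}, 0.0, 1000.0),
        Reaction("T_CO2", {"co2_c": -1, "co2_e": 1}, 0.0, 1000.0),
        Reaction("RESP",
                 {"glc_c": -1, "o2_c": -6, "adp_c": -10,
                  "co2_c": 6, "atp_c": 10, "h2o_c": 6},
                 0.0, 1000.0, "ENERGY", "gRESP"),
        Reaction("ATPM", {"atp_c": -1, "adp_c": 1}, 0.0, 1000.0, "ENERGY"),
        Reaction("DM_H2O", {"h2o_c": -1}, 0.0, 1000.0),
        Reaction("BIOMASS", {"glc_c": -1, "atp_c": -10, "adp_c": 10},
                 0.0, 1000.0),
    ]
    gem = Gem("leukemia_toy", mets, rxns, biomass_id="BIOMASS")
    gem.validate()
    # physiological (metabolomics-like) concentration window of 1 uM-10 mM
    comp = {"c": CompartmentData(conc_lb=1e-6, conc_ub=1e-2),
            "e": CompartmentData(conc_lb=1e-6, conc_ub=1e-2)}
    thermo = ThermoTable({m: MetaboliteThermo(0.0) for m in gem.metabolites},
                         comp)
    return gem, thermo


def make_min_active_toy(chain_len: int = 4,
                        with_shortcut: bool = True) -> tuple[Gem, int]:
    """A linear chain uptake -> a0 -> ... -> a_k with an optional 2-step
    shortcut a0 -> s -> a_k.  Returns the model and the planted minimal
    number of active reactions (exchange included, demand excluded) needed
    to sustain a demand on a_k.  Small enough (<= 10 reactions) for a full
    2^n brute-force sweep."""
    if chain_len < 1:
        raise ValueError("chain_len >= 1")
    mets = [Metabolite("a0_e", "a0_e", "C2", 0, "e")]
    mets += [Metabolite(f"a{k}_c", f"a{k}_c", "C2", 0, "c")
             for k in range(chain_len + 1)]
    rxns = [Reaction("EX_a0_e", {"a0_e": -1}, -10.0, 1000.0),
            Reaction("T_A0", {"a0_e": -1, "a0_c": 1}, 0.0, 1000.0)]
    for k in range(1, chain_len + 1):
        rxns.append(Reaction(f"R{k}", {f"a{k - 1}_c": -1, f"a{k}_c": 1},
                             0.0, 1000.0))
    best = chain_len
    if with_shortcut and chain_len > 2:
        mets.append(Metabolite("s_c", "s_c", "C2", 0, "c"))
        rxns.append(Reaction("S1", {"a0_c": -1, "s_c": 1}, 0.0, 1000.0))
        rxns.append(Reaction("S2", {"s_c": -1, f"a{chain_len}_c": 1},
                             0.0, 1000.0))
        best = 2
    gem = Gem(f"min_active_toy_{chain_len}", mets, rxns)
    gem.validate()
    # exchange + transport + shortest internal route
    return gem, 2 + best


def default_fixture_suite(base_seed: int = 1, n: int = 10) -> list[FixtureSpec]:
    """A spread of planted shapes for the oracle-equivalence battery,
    sized to stay below the brute-force enumeration cap."""
    shapes = [
        (2, 2, 2, 1), (1, 1, 2, 1), (3, 1, 2, 2), (2, 1, 3, 1),
        (4, 2, 2, 1), (1, 2, 2, 2), (3, 3, 2, 1), (2, 2, 3, 1),
        (2, 1, 4, 1), (2, 3, 2, 1),
    ]
    out = []
    for i in range(n):
        mc, ma, bc, ba = shapes[i % len(shapes)]
        out.append(FixtureSpec(seed=base_seed + i, medium_chain_len=mc,
                               medium_alternatives=ma, bbb_chain_len=bc,
                               bbb_alternatives=ba))
    return out
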