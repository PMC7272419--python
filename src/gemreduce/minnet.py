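"""Minimal-subnetwork search engine shared by the medium-connection and
biosynthetic-lumping algorithms.

Given a set of *counted* reactions (the non-core candidates) and a flux
forcing (uptake of a medium metabolite, or a biomass-building-block
demand), the engine maximizes the number of *inactive* counted reactions:
each counted reaction i gets a binary z_i with

    bF_i + bR_i + z_i <= 1

so z_i = 1 forces the reaction off.  The optimum gives the minimal
subnetwork size Smin = |counted| - max(sum z), and alternative minimal
subnetworks are enumerated with integer cuts: for each found active set A
the cut sum_{i in A} z_i >= 1 excludes A (and, at fixed size, only A)
from subsequent solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import Gem
from .solver import INF
from .tfa import TfaConfig, TfaProblem
from .thermo import ThermoTable

ACTIVE_TOL = 0.5  # binaries are integral to ~1e-9; 0.5 is a safe threshold


@dataclass(frozen=True)
class Subnetwork:
    """A minimal set of counted reactions activating a target, plus the
    witness flux assignment of the MILP solution that certified it."""
    target: str
    reactions: frozenset[str]
    witness: dict[str, float] = field(compare=False, hash=False)

    @property
    def size(self) -> int:
        return len(self.reactions)


@dataclass
class MinNetResult:
    status: str                      # "ok" | "infeasible"
    smin: int | None
    subnetworks: list[Subnetwork]
    truncated: bool = False

    @property
    def n_alternatives(self) -> int:
        return len(self.subnetworks)


def minimal_subnetworks(gem: Gem, thermo: ThermoTable | None,
                        counted: set[str],
                        flux_forcing: list[tuple[str, float, float]],
                        target: str,
                        blocked: set[str] = frozenset(),
                        max_alternatives: int = 32,
                        size_slack: int = 0,
                        use_thermo: bool = True,
                        config: TfaConfig | None = None) -> MinNetResult:
    """Enumerate all minimal active subsets of ``counted`` compatible with
    the forcing constraints.

    ``flux_forcing`` is a list of (reaction id, lower, upper) net-flux
    requirements.  ``blocked`` reactions are clamped to zero before the
    problem is built.  ``size_slack`` > 0 additionally returns subnetworks
    up to Smin + size_slack.
    """
    work = gem.copy()
    for rid in blocked:
        rxn = work.reactions[rid]
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0

    cfg = config or TfaConfig()
    if not use_thermo:
        cfg = TfaConfig(cfg.m_flux, cfg.m_gibbs, use_thermo=False)
    problem = TfaProblem(work, thermo, cfg)
    lp = problem.lp

    z_ids = sorted(counted)
    for rid in z_ids:
        lp.add_binary(f"Z_{rid}")
        lp.add_constr(f"offswitch_{rid}",
                      {problem.bf(rid): 1.0, problem.br(rid): 1.0,
                       f"Z_{rid}": 1.0}, -INF, 1.0)
    for rid, lo, hi in flux_forcing:
        lp.add_constr(f"force_{rid}", problem.net(rid), lo, hi)

    objective = {f"Z_{rid}": 1.0 for rid in z_ids}

    first = lp.solve(objective, "max")
    if not first.ok:
        return MinNetResult("infeasible", None, [])

    smin = len(z_ids) - int(round(first.objective))
    max_size = smin + size_slack
    subnetworks: list[Subnetwork] = []
    truncated = False
    sol = first
    while True:
        active = frozenset(rid for rid in z_ids if sol[f"Z_{rid}"] < ACTIVE_TOL)
        size = len(active)
        if size > max_size:
            break
        witness = {rid: sol[problem.vf(rid)] - sol[problem.vr(rid)]
                   for rid in gem.reactions if rid not in blocked}
        subnetworks.append(Subnetwork(target, active, witness))
        if len(subnetworks) >= max_alternatives:
            truncated = True
            break
        # integer cut: at least one member of the found set must switch off
        lp.add_constr(f"cut_{len(subnetworks)}",
                      {f"Z_{rid}": 1.0 for rid in active}, 1.0, INF)
        sol = lp.solve(objective, "max")
        if not sol.ok:
            break
    return MinNetResult("ok", smin, subnetworks, truncated)


def subset_supports_forcing(gem: Gem, thermo: ThermoTable | None,
                            counted: set[str], active: frozenset | set,
                            flux_forcing: list[tuple[str, float, float]],
                            blocked: set[str] = frozenset(),
                            use_thermo: bool = True) -> bool:
    """Feasibility of the forcing when only ``active`` (of the counted set)
    may carry flux.  Used for irreducibility certificates."""
    res = minimal_subnetworks(
        gem, thermo, set(active), flux_forcing, target="_probe",
        blocked=set(blocked) | (set(counted) - set(active)),
        max_alternatives=1, use_thermo=use_thermo)
    return res.status == "ok"


def subnetwork_is_minimal(gem: Gem, thermo: ThermoTable | None,
                          counted: set[str],
                          flux_forcing: list[tuple[str, float, float]],
                          subnetwork: Subnetwork,
                          blocked: set[str] = frozenset(),
                          use_thermo: bool = True) -> bool:
    """Irreducibility certificate: no proper subset of the returned set
    (obtained by dropping any single member) still supports the forcing."""
    for rid in subnetwork.reactions:
        if subset_supports_forcing(gem, thermo, counted,
                                   subnetwork.reactions - {rid},
                                   flux_forcing, blocked, use_thermo):
            return False
    return True
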