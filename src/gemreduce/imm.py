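"""In-silico minimal medium (iMM): the fewest boundary reactions whose
activity sustains a required growth rate.

Each boundary reaction k gets a binary z_k coupled to the direction
binaries of the TFA problem through

    bF_k + bR_k + C * z_k <= C

so z_k = 1 forces the boundary closed; the objective maximizes the number
of inactive boundaries, sum_k z_k, under a growth requirement
v_biomass >= mu_min.  Any C > 1 makes the coupling exact; C = n_b + 1 is
used because a small constant conditions the MILP better than an
arbitrarily large one.  Alternative minimal media of the same optimal
cardinality are enumerated with integer cuts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import Gem
from .solver import INF
from .tfa import TfaConfig, TfaProblem
from .thermo import ThermoTable


@dataclass
class ImmConfig:
    uptakes_only: bool = False   # count only uptake-capable boundaries
    tfa: TfaConfig | None = None


@dataclass
class MediumResult:
    status: str                       # "ok" | "no-medium-suffices"
    size: int | None
    boundary_ids: frozenset[str]
    metabolite_ids: frozenset[str]

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _build(gem: Gem, thermo: ThermoTable | None, growth_lb: float,
           config: ImmConfig) -> tuple[TfaProblem, list[str]]:
    if gem.biomass_id is None:
        raise ValueError("iMM needs a biomass reaction")
    problem = TfaProblem(gem, thermo, config.tfa or TfaConfig())
    # the biomass drain is never a medium member, whatever its structure
    boundaries = sorted(r for r in gem.boundary_reactions()
                        if r != gem.biomass_id)
    if config.uptakes_only:
        def can_uptake(rid: str) -> bool:
            rxn = gem.reactions[rid]
            coef = next(iter(rxn.stoichiometry.values()))
            return rxn.lower_bound < 0 if coef < 0 else rxn.upper_bound > 0
        boundaries = [r for r in boundaries if can_uptake(r)]
    c_const = len(boundaries) + 1
    for rid in boundaries:
        problem.lp.add_binary(f"Z_{rid}")
        problem.lp.add_constr(
            f"imm_{rid}",
            {problem.bf(rid): 1.0, problem.br(rid): 1.0, f"Z_{rid}": c_const},
            -INF, c_const)
    problem.lp.add_constr("growth_floor", problem.net(gem.biomass_id),
                          growth_lb, INF)
    return problem, boundaries


def _medium_from(sol, gem: Gem, boundaries: list[str]) -> MediumResult:
    active = frozenset(r for r in boundaries if sol[f"Z_{r}"] < 0.5)
    mets = frozenset(next(iter(gem.reactions[r].stoichiometry)) for r in active)
    return MediumResult("ok", len(active), active, mets)


def find_minimal_medium(gem: Gem, thermo: ThermoTable | None,
                        growth_lb: float,
                        config: ImmConfig | None = None) -> MediumResult:
    """Smallest set of active boundary reactions supporting growth_lb.

    The returned set is one optimum; ties between alternative optima are
    solver-dependent (use :func:`enumerate_minimal_media` for all of them).
    """
    config = config or ImmConfig()
    problem, boundaries = _build(gem, thermo, growth_lb, config)
    objective = {f"Z_{r}": 1.0 for r in boundaries}
    sol = problem.lp.solve(objective, "max")
    if not sol.ok:
        return MediumResult("no-medium-suffices", None, frozenset(), frozenset())
    return _medium_from(sol, gem, boundaries)


def enumerate_minimal_media(gem: Gem, thermo: ThermoTable | None,
                            growth_lb: float, max_alternatives: int = 16,
                            config: ImmConfig | None = None,
                            ) -> tuple[list[MediumResult], bool]:
    """All distinct minimal media of optimal size, via integer cuts.

    Returns (media, truncated); truncated is True when the alternative cap
    stopped the enumeration early.
    """
    config = config or ImmConfig()
    problem, boundaries = _build(gem, thermo, growth_lb, config)
    objective = {f"Z_{r}": 1.0 for r in boundaries}
    sol = problem.lp.solve(objective, "max")
    if not sol.ok:
        return [], False
    best = int(round(sol.objective))
    media: list[MediumResult] = []
    while True:
        result = _medium_from(sol, gem, boundaries)
        media.append(result)
        if len(media) >= max_alternatives:
            return media, True
        problem.lp.add_constr(f"cut_{len(media)}",
                              {f"Z_{r}": 1.0 for r in result.boundary_ids},
                              1.0, INF)
        sol = problem.lp.solve(objective, "max")
        if not sol.ok or int(round(sol.objective)) < best:
            return media, False


def check_medium(gem: Gem, thermo: ThermoTable | None, medium: MediumResult,
                 growth_lb: float,
                 config: ImmConfig | None = None) -> tuple[bool, bool]:
    """(sufficient, minimal) certificate for a returned medium.

    Sufficiency: with every other boundary closed for uptake, growth_lb is
    reachable.  Minimality: fully closing any single member breaks it.
    """
    tfa_cfg = (config or ImmConfig()).tfa or TfaConfig()

    def growth_with(closed_full: set[str]) -> bool:
        work = gem.copy()
        for rid in work.boundary_reactions():
            rxn = work.reactions[rid]
            if rid in closed_full:
                rxn.lower_bound = rxn.upper_bound = 0.0
            elif rid not in medium.boundary_ids:
                coef = next(iter(rxn.stoichiometry.values()))
                if coef < 0:
                    rxn.lower_bound = max(rxn.lower_bound, 0.0)
                else:
                    rxn.upper_bound = min(rxn.upper_bound, 0.0)
        problem = TfaProblem(work, thermo, tfa_cfg)
        sol = problem.max_growth()
        return sol.ok and sol.objective >= growth_lb - 1e-7

    sufficient = growth_with(set())
    minimal = all(not growth_with({rid}) for rid in medium.boundary_ids)
    return sufficient, minimal
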