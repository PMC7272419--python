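"""Thin deterministic MILP/LP layer on top of scipy's HiGHS interface.

All optimization problems in this package (flux balance, thermodynamic
flux analysis, minimal-medium and minimal-subnetwork searches) are built
as :class:`LinearProblem` instances.  Variables and constraints are kept
in insertion order, and callers insert them in an id-sorted order, so a
given model always produces the same matrix and the same HiGHS run.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

INF = float("inf")


class Status(enum.Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"
    ERROR = "error"


@dataclass
class Solution:
    status: Status
    objective: float | None
    _values: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status is Status.OPTIMAL

    def __getitem__(self, var: str) -> float:
        return self._values[var]

    def get(self, var: str, default: float = 0.0) -> float:
        return self._values.get(var, default)

    def values(self) -> dict[str, float]:
        return dict(self._values)


class LinearProblem:
    """A mixed-integer linear program with named variables and constraints.

    Constraints are two-sided: ``lb <= sum(coef * var) <= ub``.  Binary
    variables are integer variables with bounds [0, 1].
    """

    def __init__(self) -> None:
        self._var_names: list[str] = []
        self._var_index: dict[str, int] = {}
        self._var_lb: list[float] = []
        self._var_ub: list[float] = []
        self._var_int: list[bool] = []
        # each constraint: (name, {index: coef}, lb, ub)
        self._constraints: list[tuple[str, dict[int, float], float, float]] = []

    # -- construction ---------------------------------------------------
    @property
    def num_variables(self) -> int:
        return len(self._var_names)

    @property
    def num_constraints(self) -> int:
        return len(self._constraints)

    def has_var(self, name: str) -> bool:
        return name in self._var_index

    def add_var(self, name: str, lb: float = 0.0, ub: float = INF,
                integer: bool = False) -> str:
        if name in self._var_index:
            raise ValueError(f"duplicate variable {name!r}")
        self._var_index[name] = len(self._var_names)
        self._var_names.append(name)
        self._var_lb.append(lb)
        self._var_ub.append(ub)
        self._var_int.append(integer)
        return name

    def add_binary(self, name: str) -> str:
        return self.add_var(name, 0.0, 1.0, integer=True)

    def add_constr(self, name: str, coefs: dict[str, float],
                   lb: float = -INF, ub: float = INF) -> None:
        row = {self._var_index[v]: c for v, c in coefs.items() if c != 0.0}
        self._constraints.append((name, row, lb, ub))

    def set_var_bounds(self, name: str, lb: float, ub: float) -> None:
        i = self._var_index[name]
        self._var_lb[i] = lb
        self._var_ub[i] = ub

    def var_bounds(self, name: str) -> tuple[float, float]:
        i = self._var_index[name]
        return self._var_lb[i], self._var_ub[i]

    # -- solving --------------------------------------------------------
    def solve(self, objective: dict[str, float], sense: str = "max",
              extra_constraints: list[tuple[dict[str, float], float, float]] | None = None,
              var_bound_overrides: dict[str, tuple[float, float]] | None = None,
              mip_rel_gap: float = 0.0) -> Solution:
        """Solve and return a :class:`Solution`; never raises on infeasibility.

        ``extra_constraints`` and ``var_bound_overrides`` apply to this solve
        only, which is how variability analysis and integer-cut enumeration
        probe the same problem repeatedly.
        """
        n = self.num_variables
        sign = -1.0 if sense == "max" else 1.0
        c = np.zeros(n)
        for v, coef in objective.items():
            c[self._var_index[v]] += sign * coef

        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        cl: list[float] = []
        cu: list[float] = []
        all_constraints = list(self._constraints)
        if extra_constraints:
            for coefs, lb, ub in extra_constraints:
                row = {self._var_index[v]: co for v, co in coefs.items() if co != 0.0}
                all_constraints.append(("extra", row, lb, ub))
        for k, (_, row, lb, ub) in enumerate(all_constraints):
            for j, coef in row.items():
                rows.append(k)
                cols.append(j)
                vals.append(coef)
            cl.append(lb)
            cu.append(ub)

        lb = np.array(self._var_lb, dtype=float)
        ub = np.array(self._var_ub, dtype=float)
        if var_bound_overrides:
            for v, (lo, hi) in var_bound_overrides.items():
                i = self._var_index[v]
                lb[i], ub[i] = lo, hi

        m = len(all_constraints)
        a = sparse.csr_matrix((vals, (rows, cols)), shape=(m, n))
        constraint = LinearConstraint(a, np.array(cl), np.array(cu))
        integrality = np.array(self._var_int, dtype=np.uint8)
        res = milp(c=c, constraints=constraint, bounds=Bounds(lb, ub),
                   integrality=integrality,
                   options={"mip_rel_gap": mip_rel_gap, "presolve": True})
        if res.status == 0:
            values = {name: float(res.x[i]) for i, name in enumerate(self._var_names)}
            return Solution(Status.OPTIMAL, float(sign * res.fun), values)
        if res.status == 2:
            return Solution(Status.INFEASIBLE, None)
        if res.status == 3:
            return Solution(Status.UNBOUNDED, None)
        return Solution(Status.ERROR, None)

    # -- debugging ------------------------------------------------------
    def to_lp_string(self, objective: dict[str, float] | None = None,
                     sense: str = "max") -> str:
        """Serialize in CPLEX LP format (debugging / external solvers)."""
        lines = ["Maximize" if sense == "max" else "Minimize"]
        obj = objective or {}
        terms = " + ".join(f"{c} {v}" for v, c in obj.items()) or "0 " + (
            self._var_names[0] if self._var_names else "x")
        lines.append(f" obj: {terms}")
        lines.append("Subject To")
        for k, (name, row, lb, ub) in enumerate(self._constraints):
            expr = " + ".join(
                f"{coef} {self._var_names[j]}" for j, coef in sorted(row.items()))
            tag = f"{name}_{k}"
            if lb == ub:
                lines.append(f" {tag}: {expr} = {lb}")
            else:
                if ub < INF:
                    lines.append(f" {tag}_u: {expr} <= {ub}")
                if lb > -INF:
                    lines.append(f" {tag}_l: {expr} >= {lb}")
        lines.append("Bounds")
        for i, name in enumerate(self._var_names):
            lines.append(f" {self._var_lb[i]} <= {name} <= {self._var_ub[i]}")
        ints = [name for i, name in enumerate(self._var_names) if self._var_int[i]]
        if ints:
            lines.append("General")
            lines.append(" " + " ".join(ints))
        lines.append("End")
        return "\n".join(lines) + "\n"
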