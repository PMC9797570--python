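"""Solver-agnostic mixed-integer model container with a HiGHS backend.

Models are built as named variables plus linear constraints (coefficient
maps), tagged with the constraint group they encode, then handed to
``scipy.optimize.milp`` (HiGHS).  An LP-format exporter is provided for
solver-independent inspection.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

__all__ = ["MilpVariable", "MilpConstraint", "MilpModel", "MilpSolution", "solve_milp"]

BINARY = "binary"
CONTINUOUS = "continuous"


@dataclass(frozen=True)
class MilpVariable:
    name: str
    kind: str  # binary | continuous (>= lb)
    index: tuple
    group: str
    lb: float = 0.0
    ub: Optional[float] = None
    aux: bool = False  # linearization helper, excluded from the audit census


@dataclass
class MilpConstraint:
    coeffs: dict[str, float]
    sense: str  # '<=', '>=', '=='
    rhs: float
    group: str


class MilpModel:
    """A minimize-sense MILP as plain data."""

    def __init__(self, name: str = "model"):
        self.name = name
        self.variables: list[MilpVariable] = []
        self._pos: dict[str, int] = {}
        self.constraints: list[MilpConstraint] = []
        self.objective: dict[str, float] = {}
        self.metadata: dict = {}

    # -- construction -------------------------------------------------
    def add_variable(
        self,
        name: str,
        kind: str = BINARY,
        index: tuple = (),
        group: str = "",
        lb: float = 0.0,
        ub: Optional[float] = None,
        aux: bool = False,
    ) -> str:
        if name in self._pos:
            raise ValueError(f"duplicate variable {name!r}")
        if kind == BINARY:
            lb, ub = 0.0, 1.0 if ub is None else ub
        self._pos[name] = len(self.variables)
        self.variables.append(
            MilpVariable(name=name, kind=kind, index=index, group=group, lb=lb, ub=ub, aux=aux)
        )
        return name

    def add_constraint(
        self, coeffs: dict[str, float], sense: str, rhs: float, group: str
    ) -> None:
        if sense not in ("<=", ">=", "=="):
            raise ValueError(f"bad sense {sense!r}")
        if not group:
            raise ValueError("every constraint group needs a tag")
        for v in coeffs:
            if v not in self._pos:
                raise KeyError(f"unknown variable {v!r} in constraint")
        self.constraints.append(MilpConstraint(dict(coeffs), sense, float(rhs), group))

    def set_objective(self, coeffs: dict[str, float]) -> None:
        for v in coeffs:
            if v not in self._pos:
                raise KeyError(f"unknown variable {v!r} in objective")
        self.objective = dict(coeffs)

    # -- introspection ------------------------------------------------
    def __contains__(self, name: str) -> bool:
        return name in self._pos

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def census(self, include_aux: bool = True) -> Counter:
        """Variable counts per group."""
        return Counter(
            v.group for v in self.variables if include_aux or not v.aux
        )

    def constraint_census(self) -> Counter:
        return Counter(c.group for c in self.constraints)

    # -- export -------------------------------------------------------
    def to_lp(self, path) -> None:
        """Write the model in CPLEX LP format."""
        def term(coef: float, var: str) -> str:
            sign = "+" if coef >= 0 else "-"
            return f"{sign} {abs(coef):.12g} {var}"

        lines = ["Minimize", " obj: " + " ".join(term(c, v) for v, c in self.objective.items())]
        lines.append("Subject To")
        for idx, con in enumerate(self.constraints):
            expr = " ".join(term(c, v) for v, c in con.coeffs.items())
            op = {"<=": "<=", ">=": ">=", "==": "="}[con.sense]
            lines.append(f" c{idx}_{con.group}: {expr} {op} {con.rhs:.12g}")
        lines.append("Bounds")
        for v in self.variables:
            if v.kind == CONTINUOUS:
                ub = "+inf" if v.ub is None else f"{v.ub:.12g}"
                lines.append(f" {v.lb:.12g} <= {v.name} <= {ub}")
        binaries = [v.name for v in self.variables if v.kind == BINARY]
        if binaries:
            lines.append("Binary")
            for name in binaries:
                lines.append(f" {name}")
        lines.append("End")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class MilpSolution:
    status: str  # optimal | feasible | infeasible | time_limit | unbounded
    values: dict[str, float] = field(default_factory=dict)
    objective: Optional[float] = None
    gap: Optional[float] = None

    def value(self, name: str) -> float:
        return self.values[name]


def solve_milp(
    model: MilpModel,
    time_limit: float = 600.0,
    rel_gap: float = 0.0,
) -> MilpSolution:
    """Solve a :class:`MilpModel` with HiGHS via ``scipy.optimize.milp``."""
    n = model.n_variables
    if n == 0:
        return MilpSolution(status="optimal", values={}, objective=0.0, gap=0.0)
    pos = model._pos
    c = np.zeros(n)
    for v, coef in model.objective.items():
        c[pos[v]] = coef
    integrality = np.array(
        [1 if v.kind == BINARY else 0 for v in model.variables], dtype=np.int64
    )
    lb = np.array([v.lb for v in model.variables])
    ub = np.array([np.inf if v.ub is None else v.ub for v in model.variables])

    rows, cols, data = [], [], []
    con_lb = np.empty(len(model.constraints))
    con_ub = np.empty(len(model.constraints))
    for r, con in enumerate(model.constraints):
        for v, coef in con.coeffs.items():
            rows.append(r)
            cols.append(pos[v])
            data.append(coef)
        if con.sense == "<=":
            con_lb[r], con_ub[r] = -np.inf, con.rhs
        elif con.sense == ">=":
            con_lb[r], con_ub[r] = con.rhs, np.inf
        else:
            con_lb[r] = con_ub[r] = con.rhs
    A = sp.csr_matrix((data, (rows, cols)), shape=(len(model.constraints), n))

    res = milp(
        c,
        constraints=LinearConstraint(A, con_lb, con_ub),
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"time_limit": float(time_limit), "mip_rel_gap": float(rel_gap)},
    )

    gap = getattr(res, "mip_gap", None)
    if res.status == 0:
        status = "optimal" if (gap is None or gap <= max(rel_gap, 1e-9)) else "feasible"
    elif res.status == 1:
        status = "time_limit"
    elif res.status == 2:
        return MilpSolution(status="infeasible")
    elif res.status == 3:
        return MilpSolution(status="unbounded")
    else:
        status = "time_limit" if res.x is not None else "infeasible"
    if res.x is None:
        return MilpSolution(status=status)
    values = {v.name: float(res.x[i]) for i, v in enumerate(model.variables)}
    return MilpSolution(status=status, values=values, objective=float(res.fun), gap=gap)
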