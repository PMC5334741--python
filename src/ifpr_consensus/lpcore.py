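"""Backend-neutral linear programs and the solve contract shared by all models.

Every consensus model compiles to a :class:`LinearProgram` — named variables
with bounds, a sparse minimization objective, and rows of linear constraints.
:func:`solve_lp` hands the compiled program to scipy's HiGHS backend.
Variables are ordered lexicographically by name at compile time so repeated
runs of a deterministic backend return identical solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

__all__ = ["LinearProgram", "LPSolution", "solve_lp", "variable_range_at_optimum"]

_SENSES = ("<=", "=", ">=")


@dataclass
class _Variable:
    name: str
    lower: float
    upper: float


@dataclass
class _Constraint:
    coeffs: dict[str, float]
    sense: str
    rhs: float
    name: str = ""


@dataclass
class LinearProgram:
    """A minimization LP over named variables.

    >>> lp = LinearProgram()
    >>> lp.add_variable("x", lower=3.0)
    >>> lp.set_objective({"x": 1.0})
    """

    variables: dict[str, _Variable] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)
    constraints: list[_Constraint] = field(default_factory=list)

    def add_variable(self, name: str, lower: float = 0.0, upper: float = np.inf) -> str:
        if name in self.variables:
            raise ValueError(f"variable {name!r} already declared")
        if lower > upper:
            raise ValueError(f"variable {name!r} has lower bound {lower} > upper bound {upper}")
        self.variables[name] = _Variable(name, float(lower), float(upper))
        return name

    def set_objective(self, coeffs: Mapping[str, float]) -> None:
        self._check_names(coeffs)
        self.objective = {k: float(v) for k, v in coeffs.items() if v != 0.0}

    def add_objective_term(self, name: str, coeff: float) -> None:
        self._check_names([name])
        self.objective[name] = self.objective.get(name, 0.0) + float(coeff)

    def add_constraint(
        self, coeffs: Mapping[str, float], sense: str, rhs: float, name: str = ""
    ) -> None:
        if sense not in _SENSES:
            raise ValueError(f"sense must be one of {_SENSES}, got {sense!r}")
        self._check_names(coeffs)
        self.constraints.append(
            _Constraint({k: float(v) for k, v in coeffs.items()}, sense, float(rhs), name)
        )

    def _check_names(self, names: Iterable[str]) -> None:
        unknown = [n for n in names if n not in self.variables]
        if unknown:
            raise ValueError(f"undeclared variables referenced: {unknown}")

    # -- compilation -------------------------------------------------------

    def _compile(self):
        order = sorted(self.variables)
        index = {name: i for i, name in enumerate(order)}
        nvar = len(order)
        c = np.zeros(nvar)
        for name, coeff in self.objective.items():
            c[index[name]] = coeff
        bounds = [(self.variables[name].lower, self.variables[name].upper) for name in order]

        def rows(selected: list[_Constraint], negate: list[bool]):
            data, indices, indptr, rhs = [], [], [0], []
            for con, neg in zip(selected, negate):
                sign = -1.0 if neg else 1.0
                for name, coeff in sorted(con.coeffs.items()):
                    indices.append(index[name])
                    data.append(sign * coeff)
                indptr.append(len(data))
                rhs.append(sign * con.rhs)
            mat = csr_matrix((data, indices, indptr), shape=(len(selected), nvar))
            return mat, np.asarray(rhs)

        ineq = [c for c in self.constraints if c.sense != "="]
        neg = [c.sense == ">=" for c in ineq]
        eq = [c for c in self.constraints if c.sense == "="]
        A_ub, b_ub = rows(ineq, neg) if ineq else (None, None)
        A_eq, b_eq = rows(eq, [False] * len(eq)) if eq else (None, None)
        return order, c, bounds, A_ub, b_ub, A_eq, b_eq

    def to_lp_text(self) -> str:
        """Debug dump in a minimal LP-file-like text format."""
        lines = ["Minimize", " obj: " + " + ".join(f"{v} {k}" for k, v in sorted(self.objective.items()))]
        lines.append("Subject To")
        for idx, con in enumerate(self.constraints):
            expr = " + ".join(f"{v} {k}" for k, v in sorted(con.coeffs.items()))
            lines.append(f" c{idx}{'_' + con.name if con.name else ''}: {expr} {con.sense} {con.rhs}")
        lines.append("Bounds")
        for name in sorted(self.variables):
            var = self.variables[name]
            lines.append(f" {var.lower} <= {name} <= {var.upper}")
        return "\n".join(lines)


@dataclass(frozen=True)
class LPSolution:
    """Outcome of an LP solve: ``status`` is optimal / infeasible / unbounded."""

    status: str
    objective_value: float
    variable_values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.variable_values[name]


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def solve_lp(program: LinearProgram, tolerance: float = 1e-8) -> LPSolution:
    """Solve a compiled program with HiGHS; never raises on infeasibility."""
    order, c, bounds, A_ub, b_ub, A_eq, b_eq = program._compile()
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": tolerance, "dual_feasibility_tolerance": tolerance},
    )
    status = _STATUS.get(res.status, "numerical")
    values = (
        {name: float(x) for name, x in zip(order, res.x)} if res.x is not None else {}
    )
    objective = float(res.fun) if res.fun is not None else float("nan")
    return LPSolution(status, objective, values)


def variable_range_at_optimum(
    program: LinearProgram,
    variable: str,
    optimum: float | None = None,
    slack: float = 1e-7,
) -> tuple[float, float]:
    """Range a variable can take over the optimal face of the LP.

    Pins the original objective to ``optimum`` (re-solved if not given) with a
    small ``slack``, then minimizes and maximizes ``variable``.  A zero-width
    range means the variable's optimal value is unique.
    """
    if optimum is None:
        base = solve_lp(program)
        if base.status != "optimal":
            raise ValueError(f"program is {base.status}, optimal face undefined")
        optimum = base.objective_value
    import copy

    pinned = copy.deepcopy(program)
    pinned.add_constraint(dict(program.objective), "<=", optimum + slack, name="pin_objective")
    lo_prog = copy.deepcopy(pinned)
    lo_prog.set_objective({variable: 1.0})
    hi_prog = copy.deepcopy(pinned)
    hi_prog.set_objective({variable: -1.0})
    lo = solve_lp(lo_prog)
    hi = solve_lp(hi_prog)
    if lo.status != "optimal" or hi.status != "optimal":
        raise ValueError("optimal-face subproblem did not solve")
    return lo.objective_value, -hi.objective_value
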