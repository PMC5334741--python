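"""Consistency checks, priority derivation and ranking.

Two notions of rationality are used for reciprocal preference relations:

*additive* (here "I") consistency
    a crisp relation is additively consistent when ``r_ij + r_js = r_is + 0.5``
    for every triple of pairwise-distinct alternatives; an interval relation
    is I-consistent when some crisp selection inside its intervals is.

*priority-vector* (here "II") consistency
    an interval relation is II-consistent when a normalized nonnegative
    weight vector ω exists with ``l_ij ≤ ω_i/(ω_i+ω_j) ≤ u_ij`` for every
    pair; the witness ω doubles as a priority vector.

Priorities for a crisp relation come from the multiplicative model
``r_ij = ω_i/(ω_i+ω_j)``, inverted by the geometric mean of the odds
``r_ij/r_ji`` per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .lpcore import LinearProgram, solve_lp
from .prefrel import CrispFPR, Interval, IntervalFPR

__all__ = [
    "PriorityVector",
    "Ranking",
    "is_additively_consistent",
    "check_I_consistency",
    "check_II_consistency",
    "derive_priorities_multiplicative",
    "derive_priorities_least_squares",
    "rank",
]


@dataclass(frozen=True)
class PriorityVector:
    """Nonnegative alternative weights summing to one."""

    weights: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        if weights.ndim != 1:
            raise ValueError("weights must be a vector")
        if (weights < -1e-9).any():
            raise ValueError("negative priority weight")
        if abs(float(weights.sum()) - 1.0) > 1e-9:
            raise ValueError(f"priority weights sum to {weights.sum()}, expected 1")
        object.__setattr__(self, "weights", weights)
        labels = tuple(self.labels) if self.labels else tuple(
            f"x{i}" for i in range(1, weights.shape[0] + 1)
        )
        if len(labels) != weights.shape[0]:
            raise ValueError(f"{len(labels)} labels for {weights.shape[0]} weights")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    def __getitem__(self, label: str) -> float:
        return float(self.weights[self.labels.index(label)])


@dataclass(frozen=True)
class Ranking:
    """Tie-aware ordering: groups of labels from best to worst."""

    tie_groups: tuple[tuple[str, ...], ...]
    tie_tolerance: float

    def __str__(self) -> str:
        return " > ".join(
            group[0] if len(group) == 1 else "{" + " = ".join(group) + "}"
            for group in self.tie_groups
        )

    @property
    def best(self) -> tuple[str, ...]:
        return self.tie_groups[0]


def rank(priorities: PriorityVector, tie_tolerance: float = 1e-4) -> Ranking:
    """Order alternatives by weight, merging near-equal weights into tie groups.

    Weights are sorted descending; consecutive weights differing by at most
    ``tie_tolerance`` join the same group (ties chain transitively).  Labels
    inside a group keep their original panel order.
    """
    w = priorities.weights
    order = sorted(range(priorities.n), key=lambda i: (-w[i], i))
    groups: list[list[int]] = [[order[0]]]
    for idx in order[1:]:
        if w[groups[-1][-1]] - w[idx] <= tie_tolerance:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    return Ranking(
        tuple(tuple(priorities.labels[i] for i in sorted(g)) for g in groups),
        tie_tolerance,
    )


def is_additively_consistent(crisp: CrispFPR, tolerance: float = 1e-9) -> bool:
    """True iff ``r_ij + r_js = r_is + 0.5`` for all pairwise-distinct triples."""
    e = crisp.entries
    n = crisp.n
    for i in range(n):
        for j in range(n):
            for s in range(n):
                if i == j or j == s or i == s:
                    continue
                if abs(e[i, j] + e[j, s] - e[i, s] - 0.5) > tolerance:
                    return False
    return True


def check_I_consistency(
    matrix: IntervalFPR,
    alpha_bounds: Interval | tuple[float, float] = (0.0, 1.0),
) -> tuple[bool, dict[tuple[int, int], float] | None]:
    """Feasibility of an additively consistent crisp selection.

    Searches for per-pair selections ``r_ij = l_ij + α_ij (u_ij - l_ij)`` with
    α inside ``alpha_bounds`` (lower triangle by reciprocity) satisfying every
    additive-consistency equation; posed as an LP feasibility problem.
    Returns ``(feasible, witness)`` with the witness mapping 1-based upper
    pairs to α values.
    """
    if not isinstance(alpha_bounds, Interval):
        alpha_bounds = Interval(*alpha_bounds)
    n = matrix.n
    lp = LinearProgram()
    for i in range(n):
        for j in range(i + 1, n):
            lo = matrix.lower[i, j] + alpha_bounds.lower * (matrix.upper[i, j] - matrix.lower[i, j])
            hi = matrix.lower[i, j] + alpha_bounds.upper * (matrix.upper[i, j] - matrix.lower[i, j])
            lp.add_variable(f"r[{i + 1},{j + 1}]", lower=lo, upper=hi)
    # reciprocity collapses every distinct-triple equation onto one per i<j<s
    for i in range(n):
        for j in range(i + 1, n):
            for s in range(j + 1, n):
                lp.add_constraint(
                    {
                        f"r[{i + 1},{j + 1}]": 1.0,
                        f"r[{j + 1},{s + 1}]": 1.0,
                        f"r[{i + 1},{s + 1}]": -1.0,
                    },
                    "=",
                    0.5,
                )
    lp.set_objective({})
    sol = solve_lp(lp)
    if sol.status != "optimal":
        return False, None
    witness: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            width = matrix.upper[i, j] - matrix.lower[i, j]
            r = sol[f"r[{i + 1},{j + 1}]"]
            if width > 1e-12:
                alpha = (r - matrix.lower[i, j]) / width
            else:
                alpha = 0.5 * (alpha_bounds.lower + alpha_bounds.upper)
            witness[(i + 1, j + 1)] = float(np.clip(alpha, alpha_bounds.lower, alpha_bounds.upper))
    return True, witness


def check_II_consistency(
    matrix: IntervalFPR, tolerance: float = 1e-9
) -> tuple[bool, PriorityVector | None]:
    """Feasibility of a priority vector inside all interval bounds.

    Clears denominators: ``l_ij (ω_i + ω_j) ≤ ω_i ≤ u_ij (ω_i + ω_j)`` with
    ``∑ω = 1``, ``ω ≥ 0``; the margin between ω and the bounds is maximized so
    a returned witness sits as deep inside the feasible corridor as possible.
    """
    n = matrix.n
    lp = LinearProgram()
    for i in range(n):
        lp.add_variable(f"w[{i + 1}]", lower=0.0, upper=1.0)
    lp.add_variable("margin", lower=0.0, upper=1.0)
    lp.add_constraint({f"w[{i + 1}]": 1.0 for i in range(n)}, "=", 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            l, u = matrix.lower[i, j], matrix.upper[i, j]
            # l*(wi+wj) - wi <= -margin  and  wi - u*(wi+wj) <= -margin
            lp.add_constraint(
                {f"w[{i + 1}]": l - 1.0, f"w[{j + 1}]": l, "margin": 1.0}, "<=", 0.0
            )
            lp.add_constraint(
                {f"w[{i + 1}]": 1.0 - u, f"w[{j + 1}]": -u, "margin": 1.0}, "<=", 0.0
            )
    lp.set_objective({"margin": -1.0})
    sol = solve_lp(lp)
    if sol.status != "optimal":
        return False, None
    w = np.array([sol[f"w[{i + 1}]"] for i in range(n)])
    w = np.clip(w, 0.0, None)
    w /= w.sum()
    return True, PriorityVector(w, matrix.labels)


def derive_priorities_multiplicative(crisp: CrispFPR) -> PriorityVector:
    """Invert ``r_ij = ω_i/(ω_i+ω_j)`` by the geometric mean of odds.

    ``ω_i ∝ (∏_j r_ij/r_ji)^{1/n}``, normalized to sum one.  Exact whenever
    the relation is multiplicatively consistent for some ω; otherwise the
    standard row-geometric-mean compromise.  Off-diagonal entries of 0 or 1
    give infinite odds and are rejected.
    """
    e = crisp.entries
    n = crisp.n
    off = ~np.eye(n, dtype=bool)
    if (e[off] <= 0.0).any() or (e[off] >= 1.0).any():
        raise ValueError("off-diagonal entries must lie strictly inside (0, 1)")
    odds = np.log(e) - np.log(e.T)
    w = np.exp(odds.sum(axis=1) / n)
    w /= w.sum()
    return PriorityVector(w, crisp.labels)


def derive_priorities_least_squares(crisp: CrispFPR) -> PriorityVector:
    """Least-squares alternative: minimize ``∑ (r_ij(ω_i+ω_j) - ω_i)²``, ∑ω=1.

    Solved in closed form through the KKT system; small negative components
    (possible for wildly inconsistent input) are clipped and renormalized.
    Useful as a sensitivity check on the geometric-mean derivation.
    """
    e = crisp.entries
    n = crisp.n
    # residual rows: for each ordered pair (i, j), a_ij^T w with
    # a_ij[i] = r_ij - 1, a_ij[j] = r_ij
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            a = np.zeros(n)
            a[i] = e[i, j] - 1.0
            a[j] = e[i, j]
            Q += np.outer(a, a)
    kkt = np.zeros((n + 1, n + 1))
    kkt[:n, :n] = 2.0 * Q
    kkt[:n, n] = 1.0
    kkt[n, :n] = 1.0
    rhs = np.zeros(n + 1)
    rhs[n] = 1.0
    sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
    w = np.clip(sol[:n], 0.0, None)
    w /= w.sum()
    return PriorityVector(w, crisp.labels)
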