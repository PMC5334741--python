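"""Interval fuzzy preference relations (IFPRs) and expert panels.

An IFPR on ``n`` alternatives is an ``n x n`` matrix of intervals
``r_ij = [l_ij, u_ij] ⊆ [0, 1]`` expressing the graded preference for
alternative ``i`` over ``j``: ``[0.5, 0.5]`` on the diagonal (an alternative
is indifferent to itself) and the reciprocity conditions

    l_ij + u_ji = 1   and   u_ij + l_ji = 1

off the diagonal, so the judgment for ``(j, i)`` is the complement of the
judgment for ``(i, j)``.  A panel bundles the relations of ``m`` experts with
nonnegative importance weights summing to one.

Indices in error messages and in the documented entry accessors are 1-based,
matching the usual decision-analysis notation; array storage is 0-based.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Interval",
    "IntervalFPR",
    "CrispFPR",
    "ExpertPanel",
    "StructuralError",
    "ValidationError",
    "validate_ifpr",
    "complete_from_upper",
    "extract_upper",
    "read_panel",
    "write_panel",
    "case_study_panel",
    "CASE_STUDY_LABELS",
]

DEFAULT_TOLERANCE = 1e-9

#: Alternatives of the built-in grass-carp case study: four ways of cooking
#: the fish, ranked by how much they reduce persistent-organic-pollutant
#: (POP) concentrations.
CASE_STUDY_LABELS = ("frying", "baking", "poaching", "pressure-cooking")


class StructuralError(ValueError):
    """Input is not even matrix-shaped / numeric (distinct from invariant violations)."""


class ValidationError(ValueError):
    """A preference relation or panel violates its defining invariants."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class Interval:
    """A closed subinterval ``[lower, upper]`` of the unit interval."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lower) and np.isfinite(self.upper)):
            raise StructuralError(f"non-finite interval endpoints ({self.lower}, {self.upper})")
        if self.lower > self.upper + DEFAULT_TOLERANCE:
            raise ValidationError([f"interval has lower {self.lower} > upper {self.upper}"])
        if self.lower < -DEFAULT_TOLERANCE or self.upper > 1 + DEFAULT_TOLERANCE:
            raise ValidationError([f"interval [{self.lower}, {self.upper}] outside [0, 1]"])

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def __iter__(self) -> Iterator[float]:
        yield self.lower
        yield self.upper

    def complement(self) -> "Interval":
        """The reciprocal judgment ``[1 - upper, 1 - lower]``."""
        return Interval(1.0 - self.upper, 1.0 - self.lower)


def _as_bounds_arrays(entries) -> tuple[np.ndarray, np.ndarray]:
    """Split an n x n grid of (lower, upper) pairs into two float arrays."""
    try:
        arr = np.asarray(
            [[tuple(cell) for cell in row] for row in entries], dtype=float
        )
    except (TypeError, ValueError) as exc:
        raise StructuralError(f"entries are not an n x n grid of numeric pairs: {exc}") from None
    if arr.ndim != 3 or arr.shape[2] != 2 or arr.shape[0] != arr.shape[1]:
        raise StructuralError(f"expected an n x n grid of [lower, upper] pairs, got shape {arr.shape}")
    return np.ascontiguousarray(arr[:, :, 0]), np.ascontiguousarray(arr[:, :, 1])


@dataclass(frozen=True)
class IntervalFPR:
    """A reciprocal interval fuzzy preference relation ``R = (r_ij)_{n x n}``.

    Parameters
    ----------
    lower, upper
        ``n x n`` arrays with the interval endpoints ``l_ij`` and ``u_ij``.
    labels
        Alternative names; defaults to ``("x1", ..., "xn")``.
    """

    lower: np.ndarray
    upper: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.ndim != 2 or lower.shape[0] != lower.shape[1] or lower.shape != upper.shape:
            raise StructuralError(f"lower/upper must be square and congruent, got {lower.shape} and {upper.shape}")
        if lower.shape[0] < 2:
            raise StructuralError("need at least 2 alternatives")
        if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
            raise StructuralError("non-finite entries")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        labels = tuple(self.labels) if self.labels else tuple(f"x{i}" for i in range(1, lower.shape[0] + 1))
        if len(labels) != lower.shape[0]:
            raise StructuralError(f"{len(labels)} labels for {lower.shape[0]} alternatives")
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_entries(cls, entries, labels: Sequence[str] = ()) -> "IntervalFPR":
        """Build from an ``n x n`` grid of ``[lower, upper]`` pairs."""
        lower, upper = _as_bounds_arrays(entries)
        return cls(lower, upper, tuple(labels))

    @property
    def n(self) -> int:
        return self.lower.shape[0]

    def entry(self, i: int, j: int) -> Interval:
        """Interval for the (1-based) pair ``(i, j)``."""
        return Interval(float(self.lower[i - 1, j - 1]), float(self.upper[i - 1, j - 1]))

    def to_entries(self) -> list[list[list[float]]]:
        return [
            [[float(self.lower[i, j]), float(self.upper[i, j])] for j in range(self.n)]
            for i in range(self.n)
        ]

    def is_crisp(self, tolerance: float = DEFAULT_TOLERANCE) -> bool:
        return bool(np.all(self.upper - self.lower <= tolerance))

    def midpoints(self) -> np.ndarray:
        return (self.lower + self.upper) / 2.0


@dataclass(frozen=True)
class CrispFPR:
    """A crisp (point-valued) reciprocal fuzzy preference relation."""

    entries: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise StructuralError(f"entries must be square, got shape {entries.shape}")
        if not np.isfinite(entries).all():
            raise StructuralError("non-finite entries")
        object.__setattr__(self, "entries", entries)
        labels = tuple(self.labels) if self.labels else tuple(f"x{i}" for i in range(1, entries.shape[0] + 1))
        if len(labels) != entries.shape[0]:
            raise StructuralError(f"{len(labels)} labels for {entries.shape[0]} alternatives")
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def validate(self, tolerance: float = DEFAULT_TOLERANCE) -> list[str]:
        """Report diagonal / reciprocity / bound violations (empty = valid)."""
        e = self.entries
        out: list[str] = []
        for i in range(self.n):
            if abs(e[i, i] - 0.5) > tolerance:
                out.append(f"diagonal entry ({i + 1},{i + 1}) = {e[i, i]} != 0.5")
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if abs(e[i, j] + e[j, i] - 1.0) > tolerance:
                    out.append(f"reciprocity r({i + 1},{j + 1}) + r({j + 1},{i + 1}) = {e[i, j] + e[j, i]} != 1")
        if (e < -tolerance).any() or (e > 1 + tolerance).any():
            out.append("entries outside [0, 1]")
        return out

    def as_ifpr(self) -> IntervalFPR:
        """Embed as a zero-width interval relation."""
        return IntervalFPR(self.entries.copy(), self.entries.copy(), self.labels)


def validate_ifpr(
    matrix: IntervalFPR,
    tolerance: float = DEFAULT_TOLERANCE,
    scale_warning: bool = True,
) -> list[str]:
    """Check the Definition-1 invariants of an interval preference relation.

    Returns a list of human-readable violations (1-based indices); an empty
    list means the relation is a valid reciprocal IFPR.  Entries outside the
    conventional ``[0.1, 0.9]`` elicitation scale trigger a warning only —
    the consensus models themselves constrain judgments to ``[0, 1]``.
    """
    if not isinstance(matrix, IntervalFPR):
        matrix = IntervalFPR.from_entries(matrix)
    n = matrix.n
    lo, up = matrix.lower, matrix.upper
    violations: list[str] = []
    for i in range(n):
        if abs(lo[i, i] - 0.5) > tolerance or abs(up[i, i] - 0.5) > tolerance:
            violations.append(f"diagonal entry ({i + 1},{i + 1}) = [{lo[i, i]}, {up[i, i]}] != [0.5, 0.5]")
    for i in range(n):
        for j in range(n):
            if lo[i, j] > up[i, j] + tolerance:
                violations.append(f"entry ({i + 1},{j + 1}) has lower {lo[i, j]} > upper {up[i, j]}")
            if lo[i, j] < -tolerance or up[i, j] > 1 + tolerance:
                violations.append(f"entry ({i + 1},{j + 1}) = [{lo[i, j]}, {up[i, j]}] outside [0, 1]")
    for i in range(n):
        for j in range(i + 1, n):
            if abs(lo[i, j] + up[j, i] - 1.0) > tolerance:
                violations.append(
                    f"reciprocity l({i + 1},{j + 1}) + u({j + 1},{i + 1}) = {lo[i, j] + up[j, i]} != 1"
                )
            if abs(up[i, j] + lo[j, i] - 1.0) > tolerance:
                violations.append(
                    f"reciprocity u({i + 1},{j + 1}) + l({j + 1},{i + 1}) = {up[i, j] + lo[j, i]} != 1"
                )
    if scale_warning and not violations:
        off = ~np.eye(n, dtype=bool)
        if (lo[off] < 0.1 - tolerance).any() or (up[off] > 0.9 + tolerance).any():
            warnings.warn(
                "entries outside the conventional [0.1, 0.9] elicitation scale",
                UserWarning,
                stacklevel=2,
            )
    return violations


def extract_upper(matrix: IntervalFPR) -> dict[tuple[int, int], Interval]:
    """Upper-triangle entries as a ``{(i, j): Interval}`` map (1-based, i < j)."""
    return {
        (i + 1, j + 1): Interval(float(matrix.lower[i, j]), float(matrix.upper[i, j]))
        for i in range(matrix.n)
        for j in range(i + 1, matrix.n)
    }


def complete_from_upper(
    upper_entries: Mapping[tuple[int, int], object],
    n: int,
    labels: Sequence[str] = (),
) -> IntervalFPR:
    """Build a full reciprocal IFPR from its upper triangle.

    ``upper_entries`` maps 1-based pairs ``(i, j)`` with ``i < j`` to interval
    pairs; the diagonal is fixed at ``[0.5, 0.5]`` and the lower triangle is
    completed as ``r_ji = [1 - u_ij, 1 - l_ij]``.
    """
    lower = np.full((n, n), 0.5)
    upper = np.full((n, n), 0.5)
    missing = []
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if (i, j) not in upper_entries:
                missing.append((i, j))
    if missing:
        raise ValidationError([f"missing upper-triangle pair {p}" for p in missing])
    for (i, j), cell in upper_entries.items():
        if not (1 <= i < j <= n):
            raise ValidationError([f"pair {(i, j)} is not an upper-triangle pair for n={n}"])
        iv = cell if isinstance(cell, Interval) else Interval(*cell)
        lower[i - 1, j - 1], upper[i - 1, j - 1] = iv.lower, iv.upper
        lower[j - 1, i - 1], upper[j - 1, i - 1] = 1.0 - iv.upper, 1.0 - iv.lower
    return IntervalFPR(lower, upper, tuple(labels))


@dataclass(frozen=True)
class ExpertPanel:
    """``m`` expert relations over shared alternatives plus importance weights.

    The weights ``ŵ_k`` are nonnegative and sum to one; they scale each
    expert's deviation from the ideal relation in every consensus model.
    Construction validates every matrix and the weight normalization.
    """

    matrices: tuple[IntervalFPR, ...]
    expert_weights: np.ndarray
    expert_names: tuple[str, ...] = ()
    tolerance: float = field(default=DEFAULT_TOLERANCE, compare=False)

    def __post_init__(self) -> None:
        matrices = tuple(self.matrices)
        if not matrices:
            raise ValidationError(["panel needs at least one expert"])
        weights = np.asarray(self.expert_weights, dtype=float)
        if weights.ndim != 1 or weights.shape[0] != len(matrices):
            raise StructuralError(f"{weights.shape} weights for {len(matrices)} matrices")
        violations: list[str] = []
        n = matrices[0].n
        labels = matrices[0].labels
        for k, mat in enumerate(matrices, start=1):
            if mat.n != n:
                violations.append(f"expert {k} has n={mat.n}, expected {n}")
                continue
            if mat.labels != labels:
                violations.append(f"expert {k} labels differ from expert 1")
            violations.extend(
                f"expert {k}: {v}" for v in validate_ifpr(mat, self.tolerance, scale_warning=False)
            )
        if (weights < -self.tolerance).any():
            violations.append("negative expert weight")
        if abs(float(weights.sum()) - 1.0) > max(self.tolerance, 1e-9):
            violations.append(f"expert weights sum to {float(weights.sum())}, expected 1")
        if violations:
            raise ValidationError(violations)
        names = tuple(self.expert_names) if self.expert_names else tuple(
            f"d{k}" for k in range(1, len(matrices) + 1)
        )
        if len(names) != len(matrices):
            raise StructuralError(f"{len(names)} expert names for {len(matrices)} matrices")
        object.__setattr__(self, "matrices", matrices)
        object.__setattr__(self, "expert_weights", weights)
        object.__setattr__(self, "expert_names", names)

    @property
    def m(self) -> int:
        return len(self.matrices)

    @property
    def n(self) -> int:
        return self.matrices[0].n

    @property
    def labels(self) -> tuple[str, ...]:
        return self.matrices[0].labels


# --------------------------------------------------------------------------
# Panel file I/O
# --------------------------------------------------------------------------

def write_panel(panel: ExpertPanel, path, format: str | None = None) -> None:
    """Write a panel to JSON or CSV (format inferred from the suffix if omitted)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        payload = {
            "labels": list(panel.labels),
            "experts": [
                {
                    "name": panel.expert_names[k],
                    "weight": float(panel.expert_weights[k]),
                    "matrix": panel.matrices[k].to_entries(),
                }
                for k in range(panel.m)
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
    elif fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["expert", "weight", "i", "j", "lower", "upper"])
            for k in range(panel.m):
                mat = panel.matrices[k]
                for i in range(mat.n):
                    for j in range(mat.n):
                        writer.writerow(
                            [
                                panel.expert_names[k],
                                repr(float(panel.expert_weights[k])),
                                i + 1,
                                j + 1,
                                repr(float(mat.lower[i, j])),
                                repr(float(mat.upper[i, j])),
                            ]
                        )
    else:
        raise ValueError(f"unknown panel format {fmt!r}")


def read_panel(path, format: str | None = None, tolerance: float = DEFAULT_TOLERANCE) -> ExpertPanel:
    """Read a panel from a JSON or CSV file written by :func:`write_panel`."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        payload = json.loads(path.read_text())
        labels = tuple(payload.get("labels") or ())
        matrices = []
        weights = []
        names = []
        for expert in payload["experts"]:
            names.append(str(expert.get("name", f"d{len(names) + 1}")))
            weights.append(float(expert["weight"]))
            matrices.append(IntervalFPR.from_entries(expert["matrix"], labels))
        return ExpertPanel(tuple(matrices), np.asarray(weights), tuple(names), tolerance)
    if fmt == "csv":
        rows: dict[str, dict] = {}
        order: list[str] = []
        with path.open(newline="") as fh:
            for rec in csv.DictReader(fh):
                name = rec["expert"]
                if name not in rows:
                    rows[name] = {"weight": float(rec["weight"]), "cells": {}}
                    order.append(name)
                rows[name]["cells"][(int(rec["i"]), int(rec["j"]))] = (
                    float(rec["lower"]),
                    float(rec["upper"]),
                )
        matrices = []
        weights = []
        for name in order:
            cells = rows[name]["cells"]
            n = max(i for i, _ in cells)
            lower = np.empty((n, n))
            upper = np.empty((n, n))
            for (i, j), (lo, up) in cells.items():
                lower[i - 1, j - 1] = lo
                upper[i - 1, j - 1] = up
            matrices.append(IntervalFPR(lower, upper))
            weights.append(rows[name]["weight"])
        return ExpertPanel(tuple(matrices), np.asarray(weights), tuple(order), tolerance)
    raise ValueError(f"unknown panel format {fmt!r}")


# --------------------------------------------------------------------------
# Built-in case study
# --------------------------------------------------------------------------

# Upper triangles of the three expert relations for the grass-carp study:
# four cooking methods judged by three experts on how strongly each method
# reduces POP concentrations.  The full matrices follow by reciprocity.
_CASE_UPPER = (
    {  # expert d1, weight 0.1
        (1, 2): (0.2, 0.4), (1, 3): (0.3, 0.4), (1, 4): (0.6, 0.9),
        (2, 3): (0.6, 0.7), (2, 4): (0.7, 0.9), (3, 4): (0.7, 0.8),
    },
    {  # expert d2, weight 0.3
        (1, 2): (0.1, 0.3), (1, 3): (0.5, 0.6), (1, 4): (0.7, 0.8),
        (2, 3): (0.5, 0.9), (2, 4): (0.6, 0.8), (3, 4): (0.5, 0.7),
    },
    {  # expert d3, weight 0.6
        (1, 2): (0.3, 0.4), (1, 3): (0.1, 0.4), (1, 4): (0.2, 0.4),
        (2, 3): (0.6, 0.8), (2, 4): (0.5, 0.8), (3, 4): (0.6, 0.9),
    },
)
_CASE_WEIGHTS = (0.1, 0.3, 0.6)


def case_study_panel() -> ExpertPanel:
    """The built-in grass-carp cooking-method panel (m=3 experts, n=4 methods)."""
    matrices = tuple(
        complete_from_upper(cells, 4, CASE_STUDY_LABELS) for cells in _CASE_UPPER
    )
    return ExpertPanel(matrices, np.asarray(_CASE_WEIGHTS))
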