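"""Synthetic expert panels with planted structure, and perturbation studies.

The consistent generator plants a priority vector ω and builds each expert's
interval for a pair ``(i, j)`` around the multiplicative ratio
``ω_i/(ω_i + ω_j)``: the midpoint is jittered by truncated Gaussian noise and
the interval widened to a chosen half-width, always keeping the planted ratio
inside, so every generated relation is II-consistent by construction (and,
at zero width and zero noise, exactly multiplicatively consistent).  The
random generator emulates panels with no planted structure at all.

The perturbation utility shifts selected entries of exactly one expert's
relation — the protocol behind robustness comparisons where one relation is
modified at a time and the stability of the resulting priorities is
inspected across principles and consistency regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import SolverConfig
from .consistency import PriorityVector
from .prefrel import ExpertPanel, IntervalFPR, complete_from_upper

__all__ = [
    "GeneratorSpec",
    "generate_consistent_panel",
    "generate_random_panel",
    "perturb_panel",
    "perturb_study",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for a synthetic panel.

    ``half_width`` is each interval's half-width around its (jittered)
    midpoint; ``noise_scale`` the standard deviation of the midpoint jitter.
    Defaults mirror the reference study's shape: four alternatives judged by
    three experts with moderately wide (±0.1) intervals.
    """

    n: int = 4
    m: int = 3
    planted_priorities: PriorityVector | None = None
    half_width: float = 0.1
    noise_scale: float = 0.02
    seed: int = 0
    expert_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 2 or self.m < 1:
            raise ValueError("need n >= 2 alternatives and m >= 1 experts")
        if not 0.0 <= self.half_width <= 0.5:
            raise ValueError("half_width must lie in [0, 0.5]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")

    def weights(self) -> np.ndarray:
        if self.expert_weights is not None:
            return np.asarray(self.expert_weights, dtype=float)
        return np.full(self.m, 1.0 / self.m)


def generate_consistent_panel(spec: GeneratorSpec) -> ExpertPanel:
    """Panel of II-consistent relations around a planted priority vector.

    Every entry for ``i < j`` contains ``ω_i/(ω_i + ω_j)``; with
    ``half_width = noise_scale = 0`` the relations are crisp and exactly
    multiplicatively consistent.
    """
    if spec.planted_priorities is None:
        raise ValueError("generate_consistent_panel needs planted_priorities")
    w = spec.planted_priorities.weights
    if (w <= 0).any():
        raise ValueError("planted priorities must be strictly positive")
    rng = np.random.default_rng(spec.seed)
    matrices = []
    for _ in range(spec.m):
        cells = {}
        for i in range(1, spec.n + 1):
            for j in range(i + 1, spec.n + 1):
                center = w[i - 1] / (w[i - 1] + w[j - 1])
                jitter = rng.normal(0.0, spec.noise_scale) if spec.noise_scale else 0.0
                # keep the planted ratio inside the interval
                jitter = float(np.clip(jitter, -spec.half_width, spec.half_width))
                mid = center + jitter
                lo = max(0.0, min(mid - spec.half_width, center))
                up = min(1.0, max(mid + spec.half_width, center))
                cells[(i, j)] = (lo, up)
        matrices.append(complete_from_upper(cells, spec.n))
    return ExpertPanel(tuple(matrices), spec.weights())


def generate_random_panel(spec: GeneratorSpec) -> ExpertPanel:
    """Panel of valid reciprocal relations with uniformly random entries."""
    rng = np.random.default_rng(spec.seed)
    matrices = []
    for _ in range(spec.m):
        cells = {}
        for i in range(1, spec.n + 1):
            for j in range(i + 1, spec.n + 1):
                a, b = rng.uniform(0.0, 1.0, size=2)
                cells[(i, j)] = (min(a, b), max(a, b))
        matrices.append(complete_from_upper(cells, spec.n))
    return ExpertPanel(tuple(matrices), spec.weights())


def perturb_panel(
    panel: ExpertPanel,
    expert_index: int,
    pairs: Sequence[tuple[int, int]],
    magnitude: float,
    seed: int = 0,
) -> ExpertPanel:
    """Shift listed upper-triangle entries of exactly one expert's relation.

    Both endpoints of each listed (1-based) pair move jointly by
    ``±magnitude`` (sign drawn per pair from ``seed``), are clipped to
    ``[0, 1]`` preserving the endpoint order, and the lower triangle is
    re-completed by reciprocity.  All other experts' relations are returned
    untouched (same objects).
    """
    if not 0 <= expert_index < panel.m:
        raise IndexError(f"expert_index {expert_index} out of range for m={panel.m}")
    rng = np.random.default_rng(seed)
    target = panel.matrices[expert_index]
    cells = {
        (i + 1, j + 1): (float(target.lower[i, j]), float(target.upper[i, j]))
        for i in range(target.n)
        for j in range(i + 1, target.n)
    }
    for (i, j) in pairs:
        if i == j:
            raise ValueError(f"cannot perturb diagonal pair ({i}, {j})")
        if not (1 <= i < j <= panel.n):
            raise ValueError(f"pair ({i}, {j}) is not an upper-triangle pair")
        shift = magnitude * (1.0 if rng.random() < 0.5 else -1.0)
        lo, up = cells[(i, j)]
        lo = float(np.clip(lo + shift, 0.0, 1.0))
        up = float(np.clip(up + shift, 0.0, 1.0))
        cells[(i, j)] = (min(lo, up), max(lo, up))
    new_matrix = complete_from_upper(cells, panel.n, panel.labels)
    matrices = list(panel.matrices)
    matrices[expert_index] = new_matrix
    return ExpertPanel(tuple(matrices), panel.expert_weights.copy(), panel.expert_names)


@dataclass(frozen=True)
class PerturbationRecord:
    """One cell of a perturbation study."""

    expert_index: int
    pairs: tuple[tuple[int, int], ...]
    magnitude: float
    regime: str
    principle: str
    priorities: np.ndarray
    objective: float
    n_exact_ties: int


def _count_ties(weights: np.ndarray, decimals: int = 4) -> int:
    """Number of alternative pairs whose weights agree to ``decimals`` places."""
    rounded = np.round(weights, decimals)
    ties = 0
    for i in range(len(rounded)):
        for j in range(i + 1, len(rounded)):
            if rounded[i] == rounded[j]:
                ties += 1
    return ties


def perturb_study(
    panel: ExpertPanel,
    magnitudes: Sequence[float] = (0.1,),
    pairs: Sequence[tuple[int, int]] = ((1, 2), (3, 4)),
    principles: Sequence[str] = ("freedom", "fraternity", "equality", "mixed"),
    regimes: Sequence[str] = ("I", "II"),
    seed: int = 0,
    config: SolverConfig | None = None,
) -> list[PerturbationRecord]:
    """Perturb one expert at a time and re-solve across principles and regimes.

    Returns one record per (expert, magnitude, regime, principle) with the
    resulting priorities and the number of exact ties at 4 decimals — a
    dispersion summary: a regime whose priorities collapse to ties under
    perturbation discriminates poorly between alternatives.
    """
    from .consensus_i import solve_consensus_I
    from .consensus_ii import solve_consensus_II
    from .consistency import derive_priorities_multiplicative

    base = config or SolverConfig()
    records = []
    for expert_index in range(panel.m):
        for magnitude in magnitudes:
            perturbed = perturb_panel(panel, expert_index, pairs, magnitude, seed=seed + expert_index)
            for regime in regimes:
                for principle in principles:
                    cfg = SolverConfig(
                        principle=principle,
                        lambda1=base.lambda1,
                        lambda2=base.lambda2,
                        alpha_bounds=base.alpha_bounds,
                        pair_scope=base.pair_scope,
                        tolerance=base.tolerance,
                        seed=seed,
                    )
                    if regime == "I":
                        sol = solve_consensus_I(perturbed, cfg)
                        weights = derive_priorities_multiplicative(sol.ideal).weights
                        objective = sol.objective_value
                    else:
                        sol2 = solve_consensus_II(perturbed, cfg)
                        weights = sol2.priorities.weights
                        objective = sol2.objective_value
                    records.append(
                        PerturbationRecord(
                            expert_index=expert_index,
                            pairs=tuple(tuple(p) for p in pairs),
                            magnitude=magnitude,
                            regime=regime,
                            principle=principle,
                            priorities=weights,
                            objective=objective,
                            n_exact_ties=_count_ties(weights),
                        )
                    )
    return records
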