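"""Model/Results front end for the consensus machinery.

``ConsensusModel`` is constructed from an :class:`~ifpr_consensus.prefrel.ExpertPanel`
plus a regime and principle; ``fit()`` assembles and solves the corresponding
goal program and returns a :class:`ConsensusResults` carrying the ideal
relation, the priority vector, deviation diagnostics and a ``summary()``
table.

>>> from ifpr_consensus import ConsensusModel, case_study_panel
>>> res = ConsensusModel(case_study_panel(), regime="I", principle="freedom").fit()
>>> round(res.objective, 4)
0.201
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .config import PRINCIPLES, SolverConfig
from .consensus_i import ConsensusSolutionI, solve_consensus_I
from .consensus_ii import ConsensusSolutionII, solve_consensus_II
from .consistency import (
    PriorityVector,
    Ranking,
    derive_priorities_least_squares,
    derive_priorities_multiplicative,
    rank,
)
from .prefrel import CrispFPR, ExpertPanel, read_panel

__all__ = ["ConsensusModel", "ConsensusResults"]

REGIMES = ("I", "II")


def safe_priorities(ideal: CrispFPR) -> PriorityVector:
    """Geometric-mean-of-odds priorities, least-squares fallback at 0/1 entries."""
    try:
        return derive_priorities_multiplicative(ideal)
    except ValueError:
        return derive_priorities_least_squares(ideal)


class ConsensusModel:
    """Consensus goal program for an expert panel.

    Parameters
    ----------
    panel
        The expert judgments and weights.
    regime
        ``"I"`` — crisp ideal under additive consistency; ``"II"`` — interval
        ideal and priority vector under the weight-ratio condition.
    principle
        ``freedom``, ``fraternity``, ``equality`` or ``mixed``.
    **config_kwargs
        Forwarded to :class:`~ifpr_consensus.config.SolverConfig`
        (``lambda1``, ``lambda2``, ``alpha_bounds``, ``pair_scope``, ...).
    """

    def __init__(
        self,
        panel: ExpertPanel,
        regime: str = "I",
        principle: str | None = None,
        config: SolverConfig | None = None,
        **config_kwargs,
    ):
        if regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {regime!r}")
        if principle is not None and principle not in PRINCIPLES:
            raise ValueError(f"principle must be one of {PRINCIPLES}, got {principle!r}")
        self.panel = panel
        self.regime = regime
        if config is None:
            config = SolverConfig(principle=principle or "freedom", **config_kwargs)
        else:
            if principle is not None:
                config_kwargs["principle"] = principle
            if config_kwargs:
                config = replace(config, **config_kwargs)
        self.config = config

    @classmethod
    def from_file(cls, path, regime: str = "I", principle: str = "freedom", **kwargs) -> "ConsensusModel":
        """Build from a JSON/CSV panel file."""
        return cls(read_panel(path), regime=regime, principle=principle, **kwargs)

    def fit(self) -> "ConsensusResults":
        """Assemble and solve the goal program."""
        if self.regime == "I":
            solution = solve_consensus_I(self.panel, self.config)
            priorities = safe_priorities(solution.ideal) if solution.status == "optimal" else None
        else:
            solution = solve_consensus_II(self.panel, self.config)
            priorities = solution.priorities if solution.status == "optimal" else None
        return ConsensusResults(self, solution, priorities)


@dataclass
class ConsensusResults:
    """Fitted consensus solution with diagnostics.

    Attributes
    ----------
    solution
        The regime-specific solution object (ideal relation, deviation
        variables, residuals).
    priorities
        Alternative weights: read off the ω variables in regime II, derived
        from the crisp ideal by the geometric mean of odds in regime I.
    """

    model: ConsensusModel
    solution: ConsensusSolutionI | ConsensusSolutionII
    priorities: PriorityVector | None

    @property
    def converged(self) -> bool:
        return self.solution.status == "optimal"

    @property
    def objective(self) -> float:
        """The optimum of the full goal-programming objective."""
        return self.solution.objective_value

    @property
    def reported_objective(self) -> float:
        """Tabulation convention: mixed principle without the λ1 max-deviation term."""
        return self.solution.reported_objective

    def ranking(self, tie_tolerance: float = 1e-4) -> Ranking:
        if self.priorities is None:
            raise ValueError("no priorities: solve did not reach an optimum")
        return rank(self.priorities, tie_tolerance)

    def summary(self, decimals: int = 4) -> str:
        """Plain-text summary table (display rounding only)."""
        model = self.model
        sol = self.solution
        lines = []
        title = f"Consensus model (regime {model.regime}, {model.config.principle} principle)"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"alternatives: {model.panel.n}   experts: {model.panel.m}   status: {sol.status}")
        if not self.converged:
            return "\n".join(lines)
        lines.append(f"objective (min): {sol.objective_value:.{decimals}f}")
        if model.config.principle == "mixed":
            lines.append(f"reported consensus part: {sol.reported_objective:.{decimals}f}")
        if isinstance(sol, ConsensusSolutionI):
            if sol.max_deviation is not None:
                lines.append(f"max weighted deviation D: {sol.max_deviation:.{decimals}f}")
            lines.append(f"consistency residual: {sol.consistency_residual:.{decimals}f}")
        else:
            if sol.d1 is not None:
                lines.append(f"D1: {sol.d1:.{decimals}f}   D2: {sol.d2:.{decimals}f}")
            lines.append(f"reconstruction residual: {sol.ideal.reconstruction_residual:.{decimals}f}")
        dev = ", ".join(f"{d:.{decimals}f}" for d in sol.per_expert_deviation)
        lines.append(f"per-expert weighted deviation: {dev}")
        lines.append("")
        lines.append(f"{'alternative':<20}{'priority':>10}")
        for label, weight in zip(self.priorities.labels, self.priorities.weights):
            lines.append(f"{label:<20}{weight:>10.{decimals}f}")
        lines.append("")
        lines.append(f"ranking: {self.ranking()}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """Machine-readable report (full precision)."""
        sol = self.solution
        out = {
            "regime": self.model.regime,
            "principle": self.model.config.principle,
            "status": sol.status,
            "objective": sol.objective_value,
            "reported_objective": sol.reported_objective,
            "priorities": None if self.priorities is None else list(map(float, self.priorities.weights)),
            "labels": list(self.model.panel.labels),
            "per_expert_deviation": list(map(float, sol.per_expert_deviation)),
        }
        if isinstance(sol, ConsensusSolutionI):
            out["ideal"] = sol.ideal.entries.tolist()
            out["max_deviation"] = sol.max_deviation
            out["consistency_residual"] = sol.consistency_residual
            out["alphas"] = {f"{i},{j},{k}": v for (i, j, k), v in sol.alphas.items()}
        else:
            out["ideal_lower"] = sol.ideal.relation.lower.tolist()
            out["ideal_upper"] = sol.ideal.relation.upper.tolist()
            out["d1"], out["d2"] = sol.d1, sol.d2
            out["reconstruction_residual"] = sol.ideal.reconstruction_residual
        if self.priorities is not None:
            out["ranking"] = [list(g) for g in self.ranking().tie_groups]
        return out
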