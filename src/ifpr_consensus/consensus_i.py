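"""Regime-I consensus models: a crisp ideal relation under additive consistency.

Each model searches for a crisp ideal relation ``r*`` and, per expert ``k``
and pair ``(i, j)``, a selection coefficient ``α_ijk`` picking a crisp value
``r_ijk = l_ijk + α_ijk (u_ijk - l_ijk)`` inside that expert's interval.
Goal-programming deviation pairs measure the disagreement between the
selections and the ideal, weighted by the expert weights ``ŵ_k``; additional
deviation pairs ``d±`` over triples ``i < j < l`` penalize departures of the
ideal from additive consistency (``r*_ij + r*_jl = r*_il + 0.5``).

The four social-choice principles differ only in the objective and a few
coupling rows:

* freedom — minimize the ŵ-weighted total deviation;
* fraternity — minimize the largest per-expert weighted deviation ``D``;
* equality — equalize the expert-pair weighted deviations through η/ρ pairs;
* mixed — ``λ1 D + λ2 (total) + (1 - λ1 - λ2)(equality terms)``.

All objectives also carry the consistency deviations, so the ideal is pulled
toward an exactly consistent relation whenever the data permit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SolverConfig
from .lpcore import LinearProgram, LPSolution, solve_lp
from .prefrel import CrispFPR, ExpertPanel

__all__ = ["ConsensusSolutionI", "assemble_lp_I", "solve_consensus_I"]


def _pairs(n: int, scope: str) -> list[tuple[int, int]]:
    """0-based deviation-pair index list for the configured scope."""
    if scope == "upper":
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    return [(i, j) for i in range(n) for j in range(n) if i != j]


def _ideal_term(i: int, j: int) -> tuple[dict[str, float], float]:
    """Coefficients and constant expressing r*_ij through upper-triangle vars."""
    if i < j:
        return {f"rstar[{i + 1},{j + 1}]": 1.0}, 0.0
    return {f"rstar[{j + 1},{i + 1}]": -1.0}, 1.0


@dataclass(frozen=True)
class ConsensusSolutionI:
    """Solution of a regime-I consensus model.

    ``objective_value`` is the printed "min": consensus deviations under the
    selected principle plus the consistency residual.  ``alphas`` maps
    1-based ``(i, j, k)`` to the optimal selection coefficients.
    """

    ideal: CrispFPR
    objective_value: float
    max_deviation: float | None
    alphas: dict[tuple[int, int, int], float]
    per_expert_deviation: np.ndarray
    consistency_residual: float
    equality_residual: float | None
    status: str
    config: SolverConfig
    lp_solution: LPSolution

    @property
    def reported_objective(self) -> float:
        """Consensus part of the optimum, with the max-deviation term removed.

        For the freedom, fraternity and equality principles this equals
        ``objective_value``.  For the mixed principle the λ1-weighted
        max-deviation term is subtracted: the worst-off expert's deviation
        then enters through its bounding constraints only, which is how the
        mixed optimum is conventionally tabulated.
        """
        if self.config.principle == "mixed" and self.max_deviation is not None:
            return self.objective_value - self.config.lambda1 * self.max_deviation
        return self.objective_value


def assemble_lp_I(panel: ExpertPanel, config: SolverConfig) -> LinearProgram:
    """Compile the selected regime-I model for a panel into a linear program."""
    n, m = panel.n, panel.m
    principle = config.principle
    lam_eq = config.lambda_equality
    needs_D = principle == "fraternity" or (principle == "mixed" and config.lambda1 > 0)
    needs_eq = principle == "equality" or (principle == "mixed" and lam_eq > 0)
    if needs_eq and m < 2:
        raise ValueError("the equality principle needs at least two experts to equalize")

    pairs = _pairs(n, config.pair_scope)
    alo, ahi = config.alpha_bounds.lower, config.alpha_bounds.upper
    lp = LinearProgram()

    for i in range(n):
        for j in range(i + 1, n):
            lp.add_variable(f"rstar[{i + 1},{j + 1}]", lower=0.0, upper=1.0)
    for (i, j) in pairs:
        for k in range(m):
            lp.add_variable(f"alpha[{i + 1},{j + 1},{k + 1}]", lower=alo, upper=ahi)
            lp.add_variable(f"ncons[{i + 1},{j + 1},{k + 1}]", lower=0.0)
            lp.add_variable(f"pcons[{i + 1},{j + 1},{k + 1}]", lower=0.0)
    triples = [
        (i, j, l)
        for i in range(n)
        for j in range(i + 1, n)
        for l in range(j + 1, n)
    ]
    for (i, j, l) in triples:
        lp.add_variable(f"dneg[{i + 1},{j + 1},{l + 1}]", lower=0.0)
        lp.add_variable(f"dpos[{i + 1},{j + 1},{l + 1}]", lower=0.0)
    if needs_D:
        lp.add_variable("Dmax", lower=0.0)
    if needs_eq:
        for (i, j) in pairs:
            for k in range(m - 1):
                for t in range(k + 1, m):
                    lp.add_variable(f"eta[{i + 1},{j + 1},{k + 1},{t + 1}]", lower=0.0)
                    lp.add_variable(f"rho[{i + 1},{j + 1},{k + 1},{t + 1}]", lower=0.0)

    # expert-selection vs ideal:  l + α w - r* = n - p
    for (i, j) in pairs:
        ideal_coeffs, ideal_const = _ideal_term(i, j)
        for k in range(m):
            lo = panel.matrices[k].lower[i, j]
            width = panel.matrices[k].upper[i, j] - lo
            coeffs = {
                f"alpha[{i + 1},{j + 1},{k + 1}]": width,
                f"ncons[{i + 1},{j + 1},{k + 1}]": -1.0,
                f"pcons[{i + 1},{j + 1},{k + 1}]": 1.0,
            }
            for name, c in ideal_coeffs.items():
                coeffs[name] = coeffs.get(name, 0.0) - c
            lp.add_constraint(coeffs, "=", ideal_const - lo, name=f"sel_{i + 1}_{j + 1}_{k + 1}")

    # additive-consistency goals:  r*_ij + r*_jl - r*_il + d- - d+ = 0.5
    for (i, j, l) in triples:
        lp.add_constraint(
            {
                f"rstar[{i + 1},{j + 1}]": 1.0,
                f"rstar[{j + 1},{l + 1}]": 1.0,
                f"rstar[{i + 1},{l + 1}]": -1.0,
                f"dneg[{i + 1},{j + 1},{l + 1}]": 1.0,
                f"dpos[{i + 1},{j + 1},{l + 1}]": -1.0,
            },
            "=",
            0.5,
            name=f"cons_{i + 1}_{j + 1}_{l + 1}",
        )

    if needs_D:  # per-expert weighted totals bounded by D
        for k in range(m):
            coeffs = {"Dmax": -1.0}
            for (i, j) in pairs:
                coeffs[f"ncons[{i + 1},{j + 1},{k + 1}]"] = panel.expert_weights[k]
                coeffs[f"pcons[{i + 1},{j + 1},{k + 1}]"] = panel.expert_weights[k]
            lp.add_constraint(coeffs, "<=", 0.0, name=f"maxdev_{k + 1}")

    if needs_eq:  # equalize weighted deviations across expert pairs
        for (i, j) in pairs:
            for k in range(m - 1):
                for t in range(k + 1, m):
                    lp.add_constraint(
                        {
                            f"ncons[{i + 1},{j + 1},{k + 1}]": panel.expert_weights[k],
                            f"pcons[{i + 1},{j + 1},{k + 1}]": panel.expert_weights[k],
                            f"ncons[{i + 1},{j + 1},{t + 1}]": -panel.expert_weights[t],
                            f"pcons[{i + 1},{j + 1},{t + 1}]": -panel.expert_weights[t],
                            f"eta[{i + 1},{j + 1},{k + 1},{t + 1}]": 1.0,
                            f"rho[{i + 1},{j + 1},{k + 1},{t + 1}]": -1.0,
                        },
                        "=",
                        0.0,
                        name=f"eq_{i + 1}_{j + 1}_{k + 1}_{t + 1}",
                    )

    # objective
    weight_total = {"freedom": 1.0, "fraternity": 0.0, "equality": 0.0, "mixed": config.lambda2}[principle]
    weight_D = {"freedom": 0.0, "fraternity": 1.0, "equality": 0.0, "mixed": config.lambda1}[principle]
    weight_eq = {"freedom": 0.0, "fraternity": 0.0, "equality": 1.0, "mixed": lam_eq}[principle]
    objective: dict[str, float] = {}
    if weight_total:
        for (i, j) in pairs:
            for k in range(m):
                w = weight_total * panel.expert_weights[k]
                objective[f"ncons[{i + 1},{j + 1},{k + 1}]"] = w
                objective[f"pcons[{i + 1},{j + 1},{k + 1}]"] = w
    if weight_D:
        objective["Dmax"] = weight_D
    if weight_eq and needs_eq:
        for (i, j) in pairs:
            for k in range(m - 1):
                for t in range(k + 1, m):
                    objective[f"eta[{i + 1},{j + 1},{k + 1},{t + 1}]"] = weight_eq
                    objective[f"rho[{i + 1},{j + 1},{k + 1},{t + 1}]"] = weight_eq
    for (i, j, l) in triples:
        objective[f"dneg[{i + 1},{j + 1},{l + 1}]"] = 1.0
        objective[f"dpos[{i + 1},{j + 1},{l + 1}]"] = 1.0
    lp.set_objective(objective)
    return lp


def solve_consensus_I(panel: ExpertPanel, config: SolverConfig | None = None) -> ConsensusSolutionI:
    """Solve the selected regime-I model and reconstruct the crisp ideal."""
    config = config or SolverConfig()
    lp = assemble_lp_I(panel, config)
    sol = solve_lp(lp, config.tolerance)
    if sol.status != "optimal":
        return ConsensusSolutionI(
            ideal=CrispFPR(np.full((panel.n, panel.n), 0.5), panel.labels),
            objective_value=float("nan"),
            max_deviation=None,
            alphas={},
            per_expert_deviation=np.full(panel.m, np.nan),
            consistency_residual=float("nan"),
            equality_residual=None,
            status=sol.status,
            config=config,
            lp_solution=sol,
        )
    n, m = panel.n, panel.m
    ideal = np.full((n, n), 0.5)
    for i in range(n):
        for j in range(i + 1, n):
            v = sol[f"rstar[{i + 1},{j + 1}]"]
            ideal[i, j] = v
            ideal[j, i] = 1.0 - v
    pairs = _pairs(n, config.pair_scope)
    alphas = {
        (i + 1, j + 1, k + 1): sol[f"alpha[{i + 1},{j + 1},{k + 1}]"]
        for (i, j) in pairs
        for k in range(m)
    }
    per_expert = np.array(
        [
            panel.expert_weights[k]
            * sum(
                sol[f"ncons[{i + 1},{j + 1},{k + 1}]"] + sol[f"pcons[{i + 1},{j + 1},{k + 1}]"]
                for (i, j) in pairs
            )
            for k in range(m)
        ]
    )
    consistency_residual = sum(
        v for name, v in sol.variable_values.items() if name.startswith(("dneg[", "dpos["))
    )
    equality_residual = None
    if any(name.startswith("eta[") for name in sol.variable_values):
        equality_residual = sum(
            v for name, v in sol.variable_values.items() if name.startswith(("eta[", "rho["))
        )
    return ConsensusSolutionI(
        ideal=CrispFPR(ideal, panel.labels),
        objective_value=sol.objective_value,
        max_deviation=sol.variable_values.get("Dmax"),
        alphas=alphas,
        per_expert_deviation=per_expert,
        consistency_residual=float(consistency_residual),
        equality_residual=equality_residual,
        status=sol.status,
        config=config,
        lp_solution=sol,
    )
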