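"""Regime-II consensus models: interval ideal and priority vector found jointly.

Here the ideal relation keeps interval entries ``r*_ij = [r*l_ij, r*u_ij]``
and consistency is the priority-vector condition
``r*l_ij ≤ ω_i/(ω_i+ω_j) ≤ r*u_ij``.  The natural formulation is bilinear
(products of ideal entries and weights); it is linearized by introducing a
product variable for each ideal endpoint against each of ω_i and ω_j, and by
multiplying the endpoint deviation equations through by ω_i and ω_j as well.
Each "barred" (product) deviation is bounded above by its plain counterpart,
and the plain deviations carry the objective.  The consistency corridor
becomes linear:  ``r*l·ω_i + r*l·ω_j ≤ ω_i ≤ r*u·ω_i + r*u·ω_j``.

The same four social-choice principles as in regime I apply, with separate
max-deviation bounds ``D1``/``D2`` for lower/upper endpoints in the
fraternity model and endpoint-wise equalization rows in the equality model.

The ideal intervals are recovered from the product variables as
``r*l_ij = (r*l·ω_i + r*l·ω_j)/(ω_i + ω_j)`` (and likewise for the upper
endpoint); the disagreement between the two per-side ratios is reported as
``reconstruction_residual``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SolverConfig
from .consistency import PriorityVector
from .lpcore import LinearProgram, LPSolution, solve_lp
from .prefrel import ExpertPanel, IntervalFPR

__all__ = ["IntervalIdeal", "ConsensusSolutionII", "assemble_lp_II", "solve_consensus_II"]


def _pairs(n: int, scope: str) -> list[tuple[int, int]]:
    if scope == "upper":
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    return [(i, j) for i in range(n) for j in range(n) if i != j]


@dataclass(frozen=True)
class IntervalIdeal:
    """Reconstructed interval ideal relation plus its reconstruction residual.

    ``reconstruction_residual`` is the largest disagreement between the
    ω_i-side and ω_j-side product ratios; infinite when a pair's weights both
    vanish (the products then carry no information about the ideal entry).
    """

    relation: IntervalFPR
    reconstruction_residual: float

    @property
    def n(self) -> int:
        return self.relation.n


@dataclass(frozen=True)
class ConsensusSolutionII:
    """Solution of a regime-II consensus model."""

    ideal: IntervalIdeal
    priorities: PriorityVector
    objective_value: float
    d1: float | None
    d2: float | None
    per_expert_deviation: np.ndarray
    equality_residual: float | None
    status: str
    config: SolverConfig
    lp_solution: LPSolution

    @property
    def reported_objective(self) -> float:
        """Consensus part of the optimum, with the max-deviation term removed.

        Equals ``objective_value`` except under the mixed principle, where
        the λ1-weighted ``D1 + D2`` term is subtracted — the worst-off
        expert's endpoint deviations then enter through their bounding
        constraints only, the convention under which the mixed optimum is
        tabulated.
        """
        if self.config.principle == "mixed" and self.d1 is not None:
            return self.objective_value - self.config.lambda1 * (self.d1 + self.d2)
        return self.objective_value


def _var_names(i: int, j: int, k: int | None = None) -> dict[str, str]:
    """Variable names for pair (i, j) (0-based in, 1-based names)."""
    p = f"{i + 1},{j + 1}"
    names = {
        "rl_i": f"rl_i[{p}]", "rl_j": f"rl_j[{p}]",
        "ru_i": f"ru_i[{p}]", "ru_j": f"ru_j[{p}]",
    }
    if k is not None:
        q = f"{p},{k + 1}"
        names.update(
            nl=f"nl[{q}]", pl=f"pl[{q}]", nu=f"nu[{q}]", pu=f"pu[{q}]",
            nl_i=f"nl_i[{q}]", nl_j=f"nl_j[{q}]", pl_i=f"pl_i[{q}]", pl_j=f"pl_j[{q}]",
            nu_i=f"nu_i[{q}]", nu_j=f"nu_j[{q}]", pu_i=f"pu_i[{q}]", pu_j=f"pu_j[{q}]",
        )
    return names


def assemble_lp_II(panel: ExpertPanel, config: SolverConfig) -> LinearProgram:
    """Compile the selected regime-II model for a panel into a linear program."""
    n, m = panel.n, panel.m
    principle = config.principle
    lam_eq = config.lambda_equality
    needs_D = principle == "fraternity" or (principle == "mixed" and config.lambda1 > 0)
    needs_eq = principle == "equality" or (principle == "mixed" and lam_eq > 0)
    if needs_eq and m < 2:
        raise ValueError("the equality principle needs at least two experts to equalize")

    pairs = _pairs(n, config.pair_scope)
    lp = LinearProgram()

    for i in range(n):
        lp.add_variable(f"w[{i + 1}]", lower=0.0, upper=1.0)
    for (i, j) in pairs:
        v = _var_names(i, j)
        for name in v.values():
            lp.add_variable(name, lower=0.0)
        for k in range(m):
            vk = _var_names(i, j, k)
            for key in ("nl", "pl", "nu", "pu", "nl_i", "nl_j", "pl_i", "pl_j",
                        "nu_i", "nu_j", "pu_i", "pu_j"):
                lp.add_variable(vk[key], lower=0.0)
    if needs_D:
        lp.add_variable("D1", lower=0.0)
        lp.add_variable("D2", lower=0.0)
    eqpairs = [(k, t) for k in range(m - 1) for t in range(k + 1, m)]
    if needs_eq:
        for (i, j) in pairs:
            for (k, t) in eqpairs:
                q = f"{i + 1},{j + 1},{k + 1},{t + 1}"
                for stem in ("etal", "rhol", "etau", "rhou"):
                    lp.add_variable(f"{stem}[{q}]", lower=0.0)

    lp.add_constraint({f"w[{i + 1}]": 1.0 for i in range(n)}, "=", 1.0, name="norm")

    for (i, j) in pairs:
        v = _var_names(i, j)
        wi, wj = f"w[{i + 1}]", f"w[{j + 1}]"
        # consistency corridor: r*l(wi+wj) <= wi <= r*u(wi+wj), via products
        lp.add_constraint({v["rl_i"]: 1.0, v["rl_j"]: 1.0, wi: -1.0}, "<=", 0.0)
        lp.add_constraint({wi: 1.0, v["ru_i"]: -1.0, v["ru_j"]: -1.0}, "<=", 0.0)
        # product bounds from r* <= 1
        lp.add_constraint({v["ru_i"]: 1.0, wi: -1.0}, "<=", 0.0)
        lp.add_constraint({v["ru_j"]: 1.0, wj: -1.0}, "<=", 0.0)
        for k in range(m):
            vk = _var_names(i, j, k)
            rl = panel.matrices[k].lower[i, j]
            ru = panel.matrices[k].upper[i, j]
            # endpoint deviation equations multiplied by wi and by wj
            lp.add_constraint({wi: rl, vk["rl_i"]: -1.0, vk["nl_i"]: -1.0, vk["pl_i"]: 1.0}, "=", 0.0)
            lp.add_constraint({wj: rl, vk["rl_j"]: -1.0, vk["nl_j"]: -1.0, vk["pl_j"]: 1.0}, "=", 0.0)
            lp.add_constraint({wi: ru, vk["ru_i"]: -1.0, vk["nu_i"]: -1.0, vk["pu_i"]: 1.0}, "=", 0.0)
            lp.add_constraint({wj: ru, vk["ru_j"]: -1.0, vk["nu_j"]: -1.0, vk["pu_j"]: 1.0}, "=", 0.0)
            # linking bounds: each product deviation below its plain version
            for bar, plain in (("nl_i", "nl"), ("nl_j", "nl"), ("pl_i", "pl"), ("pl_j", "pl"),
                               ("nu_i", "nu"), ("nu_j", "nu"), ("pu_i", "pu"), ("pu_j", "pu")):
                lp.add_constraint({vk[bar]: 1.0, vk[plain]: -1.0}, "<=", 0.0)

    if needs_D:
        for k in range(m):
            low = {"D1": -1.0}
            up = {"D2": -1.0}
            for (i, j) in pairs:
                vk = _var_names(i, j, k)
                low[vk["nl"]] = panel.expert_weights[k]
                low[vk["pl"]] = panel.expert_weights[k]
                up[vk["nu"]] = panel.expert_weights[k]
                up[vk["pu"]] = panel.expert_weights[k]
            lp.add_constraint(low, "<=", 0.0, name=f"maxdev_lo_{k + 1}")
            lp.add_constraint(up, "<=", 0.0, name=f"maxdev_up_{k + 1}")

    if needs_eq:
        for (i, j) in pairs:
            for (k, t) in eqpairs:
                q = f"{i + 1},{j + 1},{k + 1},{t + 1}"
                vk, vt = _var_names(i, j, k), _var_names(i, j, t)
                wk, wt = panel.expert_weights[k], panel.expert_weights[t]
                lp.add_constraint(
                    {vk["nl"]: wk, vk["pl"]: wk, vt["nl"]: -wt, vt["pl"]: -wt,
                     f"etal[{q}]": 1.0, f"rhol[{q}]": -1.0},
                    "=", 0.0,
                )
                lp.add_constraint(
                    {vk["nu"]: wk, vk["pu"]: wk, vt["nu"]: -wt, vt["pu"]: -wt,
                     f"etau[{q}]": 1.0, f"rhou[{q}]": -1.0},
                    "=", 0.0,
                )

    weight_total = {"freedom": 1.0, "fraternity": 0.0, "equality": 0.0, "mixed": config.lambda2}[principle]
    weight_D = {"freedom": 0.0, "fraternity": 1.0, "equality": 0.0, "mixed": config.lambda1}[principle]
    weight_eq = {"freedom": 0.0, "fraternity": 0.0, "equality": 1.0, "mixed": lam_eq}[principle]
    objective: dict[str, float] = {}
    if weight_total:
        for (i, j) in pairs:
            for k in range(m):
                vk = _var_names(i, j, k)
                w = weight_total * panel.expert_weights[k]
                for key in ("nl", "pl", "nu", "pu"):
                    objective[vk[key]] = w
    if weight_D:
        objective["D1"] = weight_D
        objective["D2"] = weight_D
    if weight_eq and needs_eq:
        for name in lp.variables:
            if name.startswith(("etal[", "rhol[", "etau[", "rhou[")):
                objective[name] = weight_eq
    lp.set_objective(objective)
    return lp


def _reconstruct_ideal(panel: ExpertPanel, config: SolverConfig, sol: LPSolution) -> IntervalIdeal:
    n = panel.n
    w = np.array([sol[f"w[{i + 1}]"] for i in range(n)])
    lower = np.full((n, n), 0.5)
    upper = np.full((n, n), 0.5)
    residual = 0.0
    eps = 1e-9
    for i in range(n):
        for j in range(i + 1, n):
            v = _var_names(i, j)
            denom = w[i] + w[j]
            if denom <= eps:
                # pair carries no weight: products are all zero, the ideal
                # entry is undetermined — flag rather than divide
                lower[i, j], upper[i, j] = 0.0, 1.0
                lower[j, i], upper[j, i] = 0.0, 1.0
                residual = float("inf")
                continue
            lo = (sol[v["rl_i"]] + sol[v["rl_j"]]) / denom
            up = (sol[v["ru_i"]] + sol[v["ru_j"]]) / denom
            for side_i, side_j in ((v["rl_i"], v["rl_j"]), (v["ru_i"], v["ru_j"])):
                if w[i] > eps and w[j] > eps:
                    residual = max(residual, abs(sol[side_i] / w[i] - sol[side_j] / w[j]))
            lo, up = float(np.clip(lo, 0.0, 1.0)), float(np.clip(up, 0.0, 1.0))
            if lo > up:
                lo, up = up, lo
            lower[i, j], upper[i, j] = lo, up
            lower[j, i], upper[j, i] = 1.0 - up, 1.0 - lo
    return IntervalIdeal(IntervalFPR(lower, upper, panel.labels), float(residual))


def solve_consensus_II(panel: ExpertPanel, config: SolverConfig | None = None) -> ConsensusSolutionII:
    """Solve the selected regime-II model; priorities come straight from ω."""
    config = config or SolverConfig()
    lp = assemble_lp_II(panel, config)
    sol = solve_lp(lp, config.tolerance)
    n, m = panel.n, panel.m
    if sol.status != "optimal":
        return ConsensusSolutionII(
            ideal=IntervalIdeal(
                IntervalFPR(np.full((n, n), 0.0), np.full((n, n), 1.0), panel.labels),
                float("nan"),
            ),
            priorities=PriorityVector(np.full(n, 1.0 / n), panel.labels),
            objective_value=float("nan"),
            d1=None,
            d2=None,
            per_expert_deviation=np.full(m, np.nan),
            equality_residual=None,
            status=sol.status,
            config=config,
            lp_solution=sol,
        )
    w = np.clip(np.array([sol[f"w[{i + 1}]"] for i in range(n)]), 0.0, None)
    w /= w.sum()
    pairs = _pairs(n, config.pair_scope)
    per_expert = np.array(
        [
            panel.expert_weights[k]
            * sum(
                sol[_var_names(i, j, k)[key]]
                for (i, j) in pairs
                for key in ("nl", "pl", "nu", "pu")
            )
            for k in range(m)
        ]
    )
    equality_residual = None
    if any(name.startswith("etal[") for name in sol.variable_values):
        equality_residual = sum(
            v for name, v in sol.variable_values.items()
            if name.startswith(("etal[", "rhol[", "etau[", "rhou["))
        )
    return ConsensusSolutionII(
        ideal=_reconstruct_ideal(panel, config, sol),
        priorities=PriorityVector(w, panel.labels),
        objective_value=sol.objective_value,
        d1=sol.variable_values.get("D1"),
        d2=sol.variable_values.get("D2"),
        per_expert_deviation=per_expert,
        equality_residual=equality_residual,
        status=sol.status,
        config=config,
        lp_solution=sol,
    )
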