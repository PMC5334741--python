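"""Independent brute-force oracles used to cross-check the LP solvers.

Everything here works by exhaustive grid enumeration on 3x3 instances and is
deliberately independent of the LP assembly code it checks.
"""

from __future__ import annotations

import numpy as np

from ifpr_consensus.prefrel import ExpertPanel, IntervalFPR


def grid_min_consensus_I_freedom(
    panel: ExpertPanel, alpha_lo: float = 0.1, alpha_hi: float = 1.0, step: float = 0.005
) -> float:
    """Exhaustive-grid minimum of the regime-I freedom objective (n=3 only).

    Enumerates the three upper-triangle ideal entries on a grid; for each
    candidate ideal the optimal per-expert selection is the closest point of
    the reachable crisp range ``[l + α_lo(u-l), l + α_hi(u-l)]``, and the
    single additive-consistency equation contributes ``|r12 + r23 - r13 - 0.5|``.
    """
    assert panel.n == 3
    grid = np.arange(0.0, 1.0 + step / 2, step)
    pair_costs = []
    for (i, j) in ((0, 1), (0, 2), (1, 2)):
        cost = np.zeros_like(grid)
        for k in range(panel.m):
            l = panel.matrices[k].lower[i, j]
            u = panel.matrices[k].upper[i, j]
            lo = l + alpha_lo * (u - l)
            hi = l + alpha_hi * (u - l)
            cost += panel.expert_weights[k] * np.maximum.reduce(
                [np.zeros_like(grid), lo - grid, grid - hi]
            )
        pair_costs.append(cost)
    f12, f13, f23 = pair_costs
    total = (
        f12[:, None, None]
        + f13[None, :, None]
        + f23[None, None, :]
        + np.abs(grid[:, None, None] + grid[None, None, :] - grid[None, :, None] - 0.5)
    )
    return float(total.min())


def grid_feasible_II(matrix: IntervalFPR, step: float = 0.001, tol: float = 1e-9):
    """Simplex-grid search for a priority vector inside all interval bounds (n=3).

    Returns (feasible, witness or None, margin) where margin is the best
    worst-case slack found over the grid.
    """
    assert matrix.n == 3
    g = np.arange(0.0, 1.0 + step / 2, step)
    w1, w2 = np.meshgrid(g, g, indexing="ij")
    w3 = 1.0 - w1 - w2
    ok = w3 >= -tol
    slack = np.full(w1.shape, np.inf)
    for (i, j) in ((0, 1), (0, 2), (1, 2)):
        wi = (w1, w2, w3)[i]
        wj = (w1, w2, w3)[j]
        l = matrix.lower[i, j]
        u = matrix.upper[i, j]
        slack = np.minimum(slack, wi - l * (wi + wj))
        slack = np.minimum(slack, u * (wi + wj) - wi)
    slack = np.where(ok, slack, -np.inf)
    best = np.unravel_index(np.argmax(slack), slack.shape)
    margin = float(slack[best])
    if margin >= -tol:
        w = np.array([w1[best], w2[best], max(w3[best], 0.0)])
        return True, w / w.sum(), margin
    return False, None, margin


def grid_feasible_I(
    matrix: IntervalFPR, alpha_lo: float = 0.0, alpha_hi: float = 1.0, step: float = 0.01
):
    """α-grid search for an additively consistent crisp selection (n=3).

    For n=3 every distinct-triple equation reduces by reciprocity to
    ``r12 + r23 = r13 + 0.5``; the search reports the smallest absolute
    residual over the grid, feasibility meaning residual below the grid's
    resolution limit.
    """
    assert matrix.n == 3
    alphas = np.arange(alpha_lo, alpha_hi + step / 2, step)

    def reachable(i, j):
        l = matrix.lower[i, j]
        u = matrix.upper[i, j]
        return l + alphas * (u - l)

    r12 = reachable(0, 1)
    r13 = reachable(0, 2)
    r23 = reachable(1, 2)
    resid = np.abs(
        r12[:, None, None] + r23[None, None, :] - r13[None, :, None] - 0.5
    )
    best = float(resid.min())
    # three independent grids of pitch `step` per axis: anything below the
    # combined resolution limit counts as a hit
    width_scale = max(
        matrix.upper[0, 1] - matrix.lower[0, 1],
        matrix.upper[0, 2] - matrix.lower[0, 2],
        matrix.upper[1, 2] - matrix.lower[1, 2],
        1.0,
    )
    return best <= 1.6 * step * width_scale, best


def grid_min_consensus_II_freedom(panel: ExpertPanel, step: float = 0.002) -> float:
    """Exhaustive-grid minimum of the regime-II freedom objective (n=3 only).

    Enumerates ω on the 2-simplex.  For fixed ω the problem separates per
    pair and endpoint: the products of one scalar ideal endpoint with ω_i and
    ω_j both bound the plain deviations, so each expert contributes
    ``ŵ_k |r^k - r*| max(ω_i, ω_j)``; the optimal scalar endpoint of the
    weighted-L1 cost restricted by the corridor ``r*l ≤ ω_i/(ω_i+ω_j) ≤ r*u``
    is attained at an expert endpoint or at the corridor bound.
    """
    assert panel.n == 3
    g = np.arange(0.0, 1.0 + step / 2, step)
    w1, w2 = np.meshgrid(g, g, indexing="ij")
    w3 = 1.0 - w1 - w2
    valid = w3 >= -1e-12
    w3 = np.where(valid, np.maximum(w3, 0.0), np.nan)
    total = np.zeros(w1.shape)
    for (i, j) in ((0, 1), (0, 2), (1, 2)):
        wi = (w1, w2, w3)[i]
        wj = (w1, w2, w3)[j]
        denom = wi + wj
        scale = np.maximum(wi, wj)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(denom > 0, wi / np.where(denom > 0, denom, 1.0), 0.5)
        for endpoint, side in (("lower", "lo"), ("upper", "up")):
            data = np.array(
                [
                    getattr(panel.matrices[k], endpoint)[i, j]
                    for k in range(panel.m)
                ]
            )
            wts = panel.expert_weights
            # candidate ideal endpoints: expert values and the corridor bound
            cands = [np.full(w1.shape, d) for d in data] + [c]
            best = np.full(w1.shape, np.inf)
            for cand in cands:
                feas = cand <= c + 1e-12 if side == "lo" else cand >= c - 1e-12
                cost = np.zeros(w1.shape)
                for k in range(panel.m):
                    cost += wts[k] * np.abs(data[k] - cand)
                best = np.where(feas, np.minimum(best, cost), best)
            total += np.where(denom > 0, best * scale, 0.0)
    total = np.where(valid, total, np.inf)
    return float(np.nanmin(total))
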