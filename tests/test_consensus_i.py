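import numpy as np
import pytest

from ifpr_consensus import (
    ExpertPanel,
    GeneratorSpec,
    Interval,
    SolverConfig,
    assemble_lp_I,
    complete_from_upper,
    generate_random_panel,
    is_additively_consistent,
    solve_consensus_I,
)
from oracles import grid_min_consensus_I_freedom


def crisp_panel(entries, weights):
    """Panel of identical crisp (zero-width) relations."""
    n = len(entries)
    cells = {
        (i + 1, j + 1): (entries[i][j], entries[i][j])
        for i in range(n)
        for j in range(i + 1, n)
    }
    matrix = complete_from_upper(cells, n)
    return ExpertPanel(tuple(matrix for _ in weights), np.asarray(weights))


class TestAssembly:
    def test_case_study_variable_counts(self, case_panel):
        lp = assemble_lp_I(case_panel, SolverConfig(principle="freedom"))
        names = list(lp.variables)
        assert sum(name.startswith("rstar[") for name in names) == 6  # n(n-1)/2
        assert sum(name.startswith("alpha[") for name in names) == 18  # m * pairs
        assert sum(name.startswith(("ncons[", "pcons[")) for name in names) == 36
        assert sum(name.startswith("dneg[") for name in names) == 4  # C(4,3) triples

    def test_two_alternatives_have_no_consistency_rows(self):
        panel = crisp_panel([[0.5, 0.7], [0.3, 0.5]], [1.0])
        lp = assemble_lp_I(panel, SolverConfig(principle="freedom"))
        assert not any(name.startswith("dneg[") for name in lp.variables)

    def test_mixed_at_unit_lambda2_matches_freedom_coefficients(self, case_panel):
        mixed = assemble_lp_I(case_panel, SolverConfig(principle="mixed", lambda1=1.0, lambda2=0.0))
        frat = assemble_lp_I(case_panel, SolverConfig(principle="fraternity"))
        for name, coeff in frat.objective.items():
            assert mixed.objective.get(name, 0.0) == pytest.approx(coeff)

    def test_equality_needs_two_experts(self):
        panel = crisp_panel([[0.5, 0.7], [0.3, 0.5]], [1.0])
        with pytest.raises(ValueError, match="two experts"):
            assemble_lp_I(panel, SolverConfig(principle="equality"))


class TestSolve:
    def test_identical_consistent_panel_is_fixed_point(self):
        entries = [[0.5, 0.6, 0.7], [0.4, 0.5, 0.6], [0.3, 0.4, 0.5]]
        panel = crisp_panel(entries, [0.5, 0.5])
        sol = solve_consensus_I(panel, SolverConfig(principle="freedom", alpha_bounds=Interval(0, 1)))
        assert sol.objective_value == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(sol.ideal.entries, entries, atol=1e-7)

    def test_ideal_is_reciprocal_and_consistent_at_zero_residual(self, case_panel):
        sol = solve_consensus_I(case_panel, SolverConfig(principle="freedom"))
        assert sol.ideal.validate(tolerance=1e-7) == []
        assert sol.consistency_residual == pytest.approx(0.0, abs=1e-7)
        assert is_additively_consistent(sol.ideal, tolerance=1e-6)

    def test_alphas_respect_bounds(self, case_panel):
        sol = solve_consensus_I(case_panel, SolverConfig(principle="fraternity"))
        values = np.array(list(sol.alphas.values()))
        assert (values >= 0.1 - 1e-8).all() and (values <= 1 + 1e-8).all()

    @pytest.mark.parametrize("edge, matching", [((0.0, 1.0), "freedom"), ((1.0, 0.0), "fraternity")])
    def test_mixed_lambda_edges_recover_pure_principles(self, case_panel, edge, matching):
        lam1, lam2 = edge
        mixed = solve_consensus_I(case_panel, SolverConfig(principle="mixed", lambda1=lam1, lambda2=lam2))
        pure = solve_consensus_I(case_panel, SolverConfig(principle=matching))
        assert mixed.objective_value == pytest.approx(pure.objective_value, abs=1e-7)

    def test_objective_invariant_under_expert_permutation(self, case_panel):
        base = solve_consensus_I(case_panel, SolverConfig(principle="freedom")).objective_value
        perm = [2, 0, 1]
        shuffled = ExpertPanel(
            tuple(case_panel.matrices[k] for k in perm),
            case_panel.expert_weights[perm],
        )
        assert solve_consensus_I(shuffled, SolverConfig(principle="freedom")).objective_value == pytest.approx(base, abs=1e-8)

    def test_widening_intervals_never_increases_freedom_objective(self, case_panel):
        base = solve_consensus_I(case_panel, SolverConfig(principle="freedom")).objective_value
        widened_matrices = []
        for matrix in case_panel.matrices:
            lower = matrix.lower.copy()
            upper = matrix.upper.copy()
            off = ~np.eye(matrix.n, dtype=bool)
            lower[off] = np.clip(lower[off] - 0.05, 0, 1)
            upper[off] = np.clip(upper[off] + 0.05, 0, 1)
            # re-impose exact reciprocity after clipping
            cells = {
                (i + 1, j + 1): (lower[i, j], upper[i, j])
                for i in range(matrix.n)
                for j in range(i + 1, matrix.n)
            }
            widened_matrices.append(complete_from_upper(cells, matrix.n, matrix.labels))
        widened = ExpertPanel(tuple(widened_matrices), case_panel.expert_weights)
        wide_obj = solve_consensus_I(widened, SolverConfig(principle="freedom")).objective_value
        assert wide_obj <= base + 1e-8

    def test_single_expert_crisp_freedom_is_distance_to_nearest_consistent(self):
        # zero-width panel: objective is the L1 distance to the closest
        # additively consistent crisp relation, cross-checked by grid
        panel = crisp_panel([[0.5, 0.9, 0.5], [0.1, 0.5, 0.9], [0.5, 0.1, 0.5]], [1.0])
        sol = solve_consensus_I(panel, SolverConfig(principle="freedom", alpha_bounds=Interval(0, 1)))
        oracle = grid_min_consensus_I_freedom(panel, alpha_lo=0.0, alpha_hi=1.0)
        assert oracle >= sol.objective_value - 1e-6
        assert abs(sol.objective_value - oracle) < 0.01

    @pytest.mark.parametrize("seed", [1, 7, 23])
    def test_matches_grid_oracle_on_random_panels(self, seed):
        panel = generate_random_panel(GeneratorSpec(n=3, m=2, seed=seed, expert_weights=(0.4, 0.6)))
        sol = solve_consensus_I(panel, SolverConfig(principle="freedom"))
        oracle = grid_min_consensus_I_freedom(panel)
        assert oracle >= sol.objective_value - 1e-6
        assert abs(sol.objective_value - oracle) < 0.005
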