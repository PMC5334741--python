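import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ifpr_consensus import (
    CrispFPR,
    PriorityVector,
    check_I_consistency,
    check_II_consistency,
    complete_from_upper,
    derive_priorities_least_squares,
    derive_priorities_multiplicative,
    is_additively_consistent,
    rank,
)
from reference import FREEDOM_IDEAL_I, FREEDOM_PRIORITIES_I
from oracles import grid_feasible_I, grid_feasible_II


def crisp3(r12, r13, r23):
    return CrispFPR(np.array([
        [0.5, r12, r13],
        [1 - r12, 0.5, r23],
        [1 - r13, 1 - r23, 0.5],
    ]))


def interval3(p12, p13, p23, labels=()):
    return complete_from_upper({(1, 2): p12, (1, 3): p13, (2, 3): p23}, 3, labels)


def planted_crisp(weights):
    w = np.asarray(weights, dtype=float)
    n = len(w)
    entries = np.full((n, n), 0.5)
    for i in range(n):
        for j in range(n):
            if i != j:
                entries[i, j] = w[i] / (w[i] + w[j])
    return CrispFPR(entries)


class TestAdditiveConsistency:
    def test_transitive_chain_is_consistent(self):
        assert is_additively_consistent(crisp3(0.6, 0.7, 0.6))

    def test_indifference_is_consistent(self):
        assert is_additively_consistent(CrispFPR(np.full((4, 4), 0.5)))

    def test_violating_triple_detected(self):
        assert not is_additively_consistent(crisp3(0.9, 0.5, 0.9))

    def test_reference_freedom_ideal_is_consistent(self):
        ideal = CrispFPR(np.array(FREEDOM_IDEAL_I))
        assert is_additively_consistent(ideal, tolerance=1e-3)


class TestRegimeIFeasibility:
    def test_pure_indifference_feasible(self):
        feasible, witness = check_I_consistency(interval3((0.5, 0.5), (0.5, 0.5), (0.5, 0.5)))
        assert feasible and witness is not None

    def test_crisp_inconsistent_matrix_infeasible(self):
        feasible, witness = check_I_consistency(
            interval3((0.9, 0.9), (0.5, 0.5), (0.9, 0.9))
        )
        assert not feasible and witness is None

    def test_wide_intervals_admit_consistent_selection(self):
        matrix = interval3((0.55, 0.65), (0.6, 0.8), (0.55, 0.65))
        feasible, witness = check_I_consistency(matrix)
        assert feasible
        # the witness selection really is consistent
        sel = {p: matrix.lower[p[0]-1, p[1]-1]
               + witness[p] * (matrix.upper[p[0]-1, p[1]-1] - matrix.lower[p[0]-1, p[1]-1])
               for p in witness}
        assert sel[(1, 2)] + sel[(2, 3)] == pytest.approx(sel[(1, 3)] + 0.5, abs=1e-6)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_agrees_with_alpha_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.sort(rng.uniform(0, 1, size=(3, 2)), axis=1)
        matrix = interval3(*[tuple(v) for v in vals])
        feasible, _ = check_I_consistency(matrix)
        grid_feasible, residual = grid_feasible_I(matrix)
        if feasible:
            assert grid_feasible, f"LP feasible but grid residual {residual}"
        else:
            assert residual > 1e-9


class TestRegimeIIFeasibility:
    def test_planted_widened_matrix_feasible_with_valid_witness(self):
        w = np.array([0.5, 0.3, 0.2])
        cells = {}
        for i in range(1, 4):
            for j in range(i + 1, 4):
                c = w[i - 1] / (w[i - 1] + w[j - 1])
                cells[(i, j)] = (max(0, c - 0.05), min(1, c + 0.05))
        matrix = complete_from_upper(cells, 3)
        feasible, witness = check_II_consistency(matrix)
        assert feasible
        for i in range(3):
            for j in range(i + 1, 3):
                ratio = witness.weights[i] / (witness.weights[i] + witness.weights[j])
                assert matrix.lower[i, j] - 1e-8 <= ratio <= matrix.upper[i, j] + 1e-8

    def test_pure_indifference_feasible_with_uniform_witness(self):
        feasible, witness = check_II_consistency(
            interval3((0.5, 0.5), (0.5, 0.5), (0.5, 0.5))
        )
        assert feasible
        np.testing.assert_allclose(witness.weights, np.full(3, 1 / 3), atol=1e-6)

    def test_cyclic_dominance_infeasible(self):
        # 1 >> 2 >> 3 but 3 >> 1: no weight vector can satisfy all ratios
        feasible, witness = check_II_consistency(
            interval3((0.8, 0.9), (0.1, 0.2), (0.8, 0.9))
        )
        assert not feasible and witness is None

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_agrees_with_simplex_grid_search(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.sort(rng.uniform(0, 1, size=(3, 2)), axis=1)
        matrix = interval3(*[tuple(v) for v in vals])
        feasible, witness = check_II_consistency(matrix)
        grid_ok, _, margin = grid_feasible_II(matrix)
        if grid_ok:
            assert feasible
        if feasible and margin < -0.003:
            pytest.fail(f"LP feasible but simplex grid strongly infeasible (margin {margin})")


class TestPriorityDerivation:
    def test_exact_inversion_of_planted_weights(self):
        got = derive_priorities_multiplicative(planted_crisp([0.4, 0.35, 0.25]))
        np.testing.assert_allclose(got.weights, [0.4, 0.35, 0.25], atol=1e-12)

    def test_indifference_gives_uniform(self):
        got = derive_priorities_multiplicative(CrispFPR(np.full((5, 5), 0.5)))
        np.testing.assert_allclose(got.weights, np.full(5, 0.2), atol=1e-12)

    def test_reference_freedom_ideal_priorities(self):
        got = derive_priorities_multiplicative(CrispFPR(np.array(FREEDOM_IDEAL_I)))
        np.testing.assert_allclose(got.weights, FREEDOM_PRIORITIES_I, atol=5e-3)

    def test_extreme_entries_rejected(self):
        bad = crisp3(1.0, 0.6, 0.6)
        with pytest.raises(ValueError, match="strictly inside"):
            derive_priorities_multiplicative(bad)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(2, 6), st.integers(0, 10_000))
    def test_exact_on_generated_matrices(self, n, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.05, 1.0, size=n)
        w /= w.sum()
        got = derive_priorities_multiplicative(planted_crisp(w))
        np.testing.assert_allclose(got.weights, w, atol=1e-9)

    def test_relabeling_equivariance(self):
        crisp = planted_crisp([0.4, 0.35, 0.25])
        perm = [2, 0, 1]
        permuted = CrispFPR(crisp.entries[np.ix_(perm, perm)])
        got = derive_priorities_multiplicative(permuted)
        base = derive_priorities_multiplicative(crisp)
        np.testing.assert_allclose(got.weights, base.weights[perm], atol=1e-12)

    def test_least_squares_agrees_on_consistent_input(self):
        crisp = planted_crisp([0.4, 0.35, 0.25])
        ls = derive_priorities_least_squares(crisp)
        np.testing.assert_allclose(ls.weights, [0.4, 0.35, 0.25], atol=1e-8)


class TestRanking:
    def test_strict_order(self):
        r = rank(PriorityVector(np.array(FREEDOM_PRIORITIES_I), ("r1", "r2", "r3", "r4")), 1e-6)
        assert [g[0] for g in r.tie_groups] == ["r2", "r3", "r1", "r4"]
        assert all(len(g) == 1 for g in r.tie_groups)

    def test_near_equal_weights_merge(self):
        r = rank(
            PriorityVector(np.array([0.1714, 0.4, 0.2571, 0.1715]) /
                           sum([0.1714, 0.4, 0.2571, 0.1715]), ("r1", "r2", "r3", "r4")),
            1e-3,
        )
        assert r.tie_groups == (("r2",), ("r3",), ("r1", "r4"))

    def test_uniform_weights_single_group(self):
        r = rank(PriorityVector(np.full(4, 0.25)), 1e-4)
        assert len(r.tie_groups) == 1 and len(r.tie_groups[0]) == 4
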