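"""Index equations against closed forms and hand-solved oracles.

Fixture expectations were computed with the Cramer's-rule oracle in
``_oracles.py`` and frozen; the tests re-derive them at run time as well.
"""

import numpy as np
import pytest
from _oracles import cramer2

from selindex import (
    SingularMatrixError,
    correlated_response,
    cumulative_gain,
    desired_gains_weights,
    expected_gain,
    generalized_desired_gains_weights,
    index_accuracy,
    index_sd,
    selection_intensity,
    smith_hazel_weights,
    solve_index,
)

# frozen Cramer's-rule solves on the Huaxi fixture
B_SH_C1 = (0.006199893693, 0.053997412246)
SIGMA_C1 = 0.362416379102
DG_C1 = (0.140444372417, 0.565812513766)
RHI_C1 = 0.174721913585
B_DG = (0.044154501217, 0.082495944850)
Q_TARGET = np.array([0.4331, 0.1525])


class TestSelectionIntensity:
    def test_no_selection_is_zero(self):
        assert selection_intensity(1.0) == 0.0

    @pytest.mark.parametrize("p, expected", [
        (0.10, 1.754983319325),
        (0.20, 1.399809602039),
    ])
    def test_matches_truncated_normal_mean(self, p, expected):
        assert selection_intensity(p) == pytest.approx(expected, abs=1e-10)

    def test_strictly_decreasing_in_p(self):
        grid = np.linspace(0.01, 1.0, 60)
        vals = [selection_intensity(p) for p in grid]
        assert np.all(np.diff(vals) < 0)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.2])
    def test_out_of_range_rejected(self, p):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            selection_intensity(p)


class TestSmithHazelWeights:
    def test_full_heritability_returns_economic_weights(self):
        P = np.array([[2.0, 0.3], [0.3, 1.0]])
        a = np.array([1.5, -0.5])
        np.testing.assert_allclose(smith_hazel_weights(P, P, a), a,
                                   atol=1e-12)

    def test_single_trait_closed_form(self):
        # b = h^2 * a for one trait with an own record
        b = smith_hazel_weights([[4.0]], [[2.0]], [1.0])
        assert b[0] == pytest.approx(0.5)

    def test_fixture_matches_cramer_oracle(self, huaxi, huaxi_weights):
        b = smith_hazel_weights(huaxi.P, huaxi.G, huaxi_weights)
        np.testing.assert_allclose(b, B_SH_C1, rtol=1e-9)
        oracle = cramer2(huaxi.P, huaxi.G @ huaxi_weights)
        np.testing.assert_allclose(b, oracle, rtol=1e-12)

    def test_singular_P_reported_as_such(self):
        P = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(SingularMatrixError, match="singular"):
            smith_hazel_weights(P, np.eye(2), [1.0, 1.0])


class TestDesiredGainsWeights:
    def test_diagonal_solve(self):
        b = desired_gains_weights(np.diag([2.0, 4.0]), np.eye(2), [1.0, 2.0])
        np.testing.assert_allclose(b, [0.5, 0.5])

    def test_defining_contract(self, huaxi):
        b = desired_gains_weights(huaxi.G, huaxi.R, Q_TARGET)
        np.testing.assert_allclose(huaxi.G.T @ huaxi.R @ b, Q_TARGET,
                                   atol=1e-12)

    def test_fixture_matches_cramer_oracle(self, huaxi):
        b = desired_gains_weights(huaxi.G, huaxi.R, Q_TARGET)
        np.testing.assert_allclose(b, B_DG, rtol=1e-9)
        np.testing.assert_allclose(b, cramer2(huaxi.G.T, Q_TARGET),
                                   rtol=1e-12)

    def test_non_square_rejected_with_pointer(self):
        G = np.array([[1.0], [0.5]])  # n=2 measurements, m=1 goal trait
        with pytest.raises(ValueError, match="generalized"):
            desired_gains_weights(G, np.eye(2), [1.0])


class TestGeneralizedDesiredGains:
    def test_square_case_agrees_with_plain_solve(self, huaxi):
        b_sq = desired_gains_weights(huaxi.G, huaxi.R, Q_TARGET)
        b_gen = generalized_desired_gains_weights(huaxi.P, huaxi.R, huaxi.G,
                                                  Q_TARGET)
        np.testing.assert_allclose(b_gen, b_sq, rtol=1e-9)

    def test_orthogonal_columns_reduction(self):
        # P = R = I reduces the formula to b = G (G'G)^-1 Q
        G = np.array([[1.0, 0.0], [0.0, 2.0], [1.0, 0.0]])
        Q = np.array([0.4, -0.6])
        b = generalized_desired_gains_weights(np.eye(3), np.eye(3), G, Q)
        np.testing.assert_allclose(b, G @ np.linalg.solve(G.T @ G, Q),
                                   atol=1e-12)

    def test_rectangular_contract(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(3, 3))
        P = A @ A.T + 3.0 * np.eye(3)
        G = rng.normal(size=(3, 2))
        Q = rng.normal(size=2)
        b = generalized_desired_gains_weights(P, np.eye(3), G, Q)
        np.testing.assert_allclose(G.T @ b, Q, atol=1e-10)


class TestIndexSd:
    def test_picks_out_sqrt_of_diagonal(self):
        assert index_sd([1.0, 0.0], [[4.0, 1.0], [1.0, 9.0]]) == 2.0

    def test_zero_vector(self):
        assert index_sd([0.0, 0.0], np.eye(2)) == 0.0

    def test_fixture_value(self, huaxi):
        assert index_sd(B_SH_C1, huaxi.P) == pytest.approx(SIGMA_C1, rel=1e-9)

    def test_negative_quadratic_form_rejected(self):
        with pytest.raises(ValueError, match="positive semidefinite"):
            index_sd([1.0], [[-4.0]])


class TestExpectedGain:
    def test_no_selection_no_gain(self, huaxi):
        dG = expected_gain(B_SH_C1, huaxi.G, huaxi.R, 0.0, SIGMA_C1)
        np.testing.assert_array_equal(dG, [0.0, 0.0])

    def test_invariant_under_weight_rescaling(self, huaxi):
        b = np.array(B_SH_C1)
        i = selection_intensity(0.10)
        dG1 = expected_gain(b, huaxi.G, huaxi.R, i, index_sd(b, huaxi.P))
        dG2 = expected_gain(10 * b, huaxi.G, huaxi.R, i,
                            index_sd(10 * b, huaxi.P))
        np.testing.assert_allclose(dG1, dG2, rtol=1e-12)

    def test_fixture_value(self, huaxi):
        dG = expected_gain(B_SH_C1, huaxi.G, huaxi.R,
                           selection_intensity(0.10), SIGMA_C1)
        np.testing.assert_allclose(dG, DG_C1, rtol=1e-8)

    def test_zero_sigma_rejected(self, huaxi):
        with pytest.raises(ValueError, match="sigma_I"):
            expected_gain(B_SH_C1, huaxi.G, huaxi.R, 1.0, 0.0)


class TestCumulativeGain:
    @pytest.mark.parametrize("per_gen, q, total", [
        (0.6807, 4, 2.723),    # printed baseline row
        (0.7686, 4, 3.0744),   # printed swapped-weights row
    ])
    def test_times_q_at_printed_rounding(self, per_gen, q, total):
        got = cumulative_gain(per_gen, q)
        assert np.round(got, 4) == pytest.approx(total, abs=5e-4)

    def test_zero_generations(self):
        np.testing.assert_array_equal(cumulative_gain([0.3, 0.1], 0), [0, 0])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            cumulative_gain([0.3], 1.5)


class TestCorrelatedResponse:
    def test_uncorrelated_trait_has_no_response(self, huaxi):
        per, tot = correlated_response(B_SH_C1, [0.0, 0.0], huaxi.R,
                                       1.75, SIGMA_C1, q=4)
        assert per == 0.0 and tot == 0.0

    def test_column_of_G_reproduces_expected_gain(self, huaxi):
        i = selection_intensity(0.10)
        dG = expected_gain(B_SH_C1, huaxi.G, huaxi.R, i, SIGMA_C1)
        for j in range(2):
            per, tot = correlated_response(B_SH_C1, huaxi.G[:, j], huaxi.R,
                                           i, SIGMA_C1, q=4)
            assert per == pytest.approx(dG[j], rel=1e-12)
            assert tot == pytest.approx(4 * dG[j], rel=1e-12)

    def test_synthetic_secondary_trait(self, huaxi):
        # a third trait genetically tied to the measurements
        per, _ = correlated_response(B_SH_C1, [1.0, -0.5], huaxi.R,
                                     selection_intensity(0.10), SIGMA_C1)
        assert per == pytest.approx(-0.100717216385, rel=1e-8)


class TestIndexAccuracy:
    def test_perfect_index(self):
        # one trait, full heritability, b = a: I coincides with H
        assert index_accuracy([2.0], [[3.0]], [2.0], [[3.0]]) == pytest.approx(1.0)

    def test_single_trait_own_record_equals_h(self):
        # b = h^2 a gives rHI = h; h^2 = 0.25 -> 0.5
        var_P, h2, a = 8.0, 0.25, 1.0
        b = [h2 * a]
        G = [[h2 * var_P]]
        assert index_accuracy(b, [[var_P]], [a], G) == pytest.approx(0.5)

    def test_fixture_value_and_mode_agreement(self, huaxi, huaxi_weights):
        r1 = index_accuracy(B_SH_C1, huaxi.P, huaxi_weights, huaxi.G,
                            mode="ratio")
        r2 = index_accuracy(B_SH_C1, huaxi.P, huaxi_weights, huaxi.G,
                            mode="correlation")
        assert r1 == pytest.approx(RHI_C1, rel=1e-8)
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_degenerate_aggregate_rejected(self):
        with pytest.raises(ValueError, match="a'Ga"):
            index_accuracy([1.0], [[1.0]], [1.0], [[0.0]])


class TestSolveIndex:
    def test_smith_hazel_bundle(self, huaxi, huaxi_weights):
        sol = solve_index(huaxi.P, huaxi.G, huaxi.R, p=0.10, q=4,
                          a=huaxi_weights)
        np.testing.assert_allclose(sol.b, B_SH_C1, rtol=1e-9)
        np.testing.assert_allclose(sol.Q_total, 4 * sol.dG, rtol=1e-14)
        assert sol.rHI == pytest.approx(RHI_C1, rel=1e-8)
        assert sol.aggregate_per_gen == pytest.approx(
            float(huaxi_weights @ sol.dG))

    def test_desired_gains_reports_normalisation_factor(self, huaxi):
        sol = solve_index(huaxi.P, huaxi.G, huaxi.R, p=0.10, q=4,
                          a=np.array([0.5, 1.0]), Q=Q_TARGET,
                          method="desired_gains")
        # realised q * i / sigma_I, reported rather than forced to 1
        assert sol.desired_gains_factor == pytest.approx(
            4 * sol.i_I / sol.sigma_I)
        np.testing.assert_allclose(sol.b, B_DG, rtol=1e-9)

    def test_missing_inputs_rejected(self, huaxi):
        with pytest.raises(ValueError, match="economic weights"):
            solve_index(huaxi.P, huaxi.G, huaxi.R, p=0.10)
        with pytest.raises(ValueError, match="target vector"):
            solve_index(huaxi.P, huaxi.G, huaxi.R, p=0.10,
                        method="desired_gains")
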