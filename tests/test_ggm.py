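"""Graphical lasso solver, EBIC, penalty selection and edge extraction."""

import numpy as np
import pytest

from conftest import glasso_objective, glasso_oracle, iid_ordinal
from symptomnet.association import CorrelationMatrix, spearman_matrix
from symptomnet.ggm import (
    NetworkModel,
    SelectionConfig,
    cross_community_edges,
    ebic,
    gamma_sensitivity,
    glasso_solve,
    lambda_grid,
    n_edges,
    partial_correlations,
    select_network,
)
from symptomnet.simulate import sample_ordinal


def _random_corr(p, seed, scale=0.4):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(p, p)) * scale
    S = A @ A.T + np.eye(p)
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestGlassoSolve:
    def test_large_lambda_gives_diagonal_precision(self):
        S = _random_corr(5, 0)
        lam_max = np.abs(S - np.diag(np.diag(S))).max()
        theta = glasso_solve(S, lam_max * 1.0001)
        off = theta - np.diag(np.diag(theta))
        assert np.abs(off).max() < 1e-10

    def test_lambda_zero_matches_direct_inverse(self):
        S = _random_corr(6, 1)
        theta = glasso_solve(S, 0.0)
        np.testing.assert_allclose(theta, np.linalg.inv(S), atol=1e-6)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            glasso_solve(np.eye(3), -0.1)

    @pytest.mark.parametrize("p,lam", [(3, 0.05), (3, 0.2), (4, 0.05), (4, 0.2)])
    def test_matches_generic_convex_solver_small_p(self, p, lam):
        S = _random_corr(p, p * 10 + 1)
        theta = glasso_solve(S, lam, tol=1e-8, max_iter=2000)
        oracle = glasso_oracle(S, lam)
        assert abs(
            glasso_objective(theta, S, lam) - glasso_objective(oracle, S, lam)
        ) < 1e-4
        np.testing.assert_allclose(theta, oracle, atol=1e-4)

    def test_chain_truth_support_recovered(self):
        # x1--x2--x3 chain: theta_13 should be exactly zero at small lambda
        prec = np.array([
            [1.0, -0.4, 0.0],
            [-0.4, 1.0, -0.4],
            [0.0, -0.4, 1.0],
        ])
        S = np.linalg.inv(prec)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        theta = glasso_solve(S, 0.02)
        assert abs(theta[0, 2]) < 1e-6
        assert abs(theta[0, 1]) > 0.1 and abs(theta[1, 2]) > 0.1


class TestPartialCorrelations:
    def test_diagonal_precision_gives_empty_network(self):
        W = partial_correlations(np.diag([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(W, np.zeros((3, 3)))

    def test_two_by_two_hand_value(self):
        theta = np.array([[1.0, -0.5], [-0.5, 1.0]])
        W = partial_correlations(theta)
        assert W[0, 1] == pytest.approx(0.5)

    def test_sign_flip(self):
        theta = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert partial_correlations(theta)[0, 1] == pytest.approx(-0.3)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            partial_correlations(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_entries_in_open_unit_interval_zero_diagonal(self):
        theta = glasso_solve(_random_corr(6, 3), 0.05)
        W = partial_correlations(theta)
        assert np.all(np.abs(W) < 1)
        np.testing.assert_array_equal(np.diag(W), 0.0)
        np.testing.assert_array_equal(W, W.T)


class TestEBIC:
    def test_identity_pair_is_zero(self):
        # L = (n/2)(logdet I - tr(I)) + (n/2)*p ... the constant-free
        # convention: Theta=I, S=I gives logdet=0, tr=p, so
        # -2L = n(p - 0)... self-consistency: value equals the formula
        val = ebic(np.eye(4), np.eye(4), n=100, gamma=0.5)
        expected = -2 * (100 / 2.0) * (0.0 - 4.0)
        assert val == pytest.approx(expected)

    def test_one_extra_edge_costs_log_n_plus_4_gamma_log_p(self):
        p, n, gamma = 17, 1952, 0.5
        S = np.eye(p)
        theta0 = np.eye(p)
        theta1 = np.eye(p)
        theta1[0, 1] = theta1[1, 0] = 1e-9  # negligible likelihood change
        delta = ebic(theta1, S, n, gamma) - ebic(theta0, S, n, gamma)
        assert delta == pytest.approx(np.log(n) + 4 * gamma * np.log(p),
                                      rel=1e-6)

    def test_gamma_zero_reduces_to_bic(self):
        theta = glasso_solve(_random_corr(5, 4), 0.1)
        S = _random_corr(5, 4)
        E = n_edges(theta)
        assert ebic(theta, S, 50, 0.0) == pytest.approx(
            ebic(theta, S, 50, 0.5) - 4 * 0.5 * E * np.log(5)
        )


class TestLambdaGrid:
    def test_grid_endpoints_length_and_log_spacing(self):
        S = _random_corr(5, 5)
        lam_max = np.abs(S - np.diag(np.diag(S))).max()
        grid = lambda_grid(S, n_lambda=25, lambda_min_ratio=0.01)
        assert grid[0] == pytest.approx(lam_max)
        assert len(grid) == 25
        assert grid[-1] == pytest.approx(lam_max * 0.01)
        ratios = grid[1:] / grid[:-1]
        assert np.ptp(ratios) < 1e-12

    def test_all_zero_off_diagonals_degenerate_grid(self):
        with pytest.warns(UserWarning):
            grid = lambda_grid(np.eye(4), 10, 0.01)
        np.testing.assert_array_equal(grid, [0.0])


class TestSelectNetwork:
    def test_null_data_selects_empty_network(self):
        hits = 0
        for seed in range(10):
            data = iid_ordinal(500, 8, seed)
            model, _ = select_network(
                data, SelectionConfig(n_lambda=20), return_path=False
            )
            hits += model.n_edges == 0
        assert hits >= 9

    def test_determinism_same_seed_same_model(self, default_data):
        cfg = SelectionConfig(n_lambda=15, seed=11)
        m1, p1 = select_network(default_data, cfg)
        m2, p2 = select_network(default_data, cfg)
        assert m1.lambda_used == m2.lambda_used
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(p1.ebic_values, p2.ebic_values)

    def test_planted_support_recovered(self, default_truth, default_data):
        from symptomnet.simulate import recovery_metrics

        model, _ = select_network(
            default_data, SelectionConfig(n_lambda=20), return_path=False
        )
        rep = recovery_metrics(default_truth, model)
        assert rep["tpr_strong"] >= 0.9
        assert rep["sign_agreement"] >= 0.9

    def test_edge_count_nonincreasing_along_increasing_lambda(self, default_data):
        _, path = select_network(default_data, SelectionConfig(n_lambda=15))
        counts = [m.n_edges for m in path.models]  # lambda decreasing
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_cv_mode_runs_and_is_deterministic(self, small_truth):
        data = sample_ordinal(small_truth, n=400, seed=8)
        cfg = SelectionConfig(n_lambda=10, mode="cv_ebic", n_folds=5, seed=3)
        m1, _ = select_network(data, cfg)
        m2, _ = select_network(data, cfg)
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_cv_fold_too_small_raises(self, small_truth):
        data = sample_ordinal(small_truth, n=40, seed=8)
        with pytest.raises(ValueError, match="fewer folds"):
            select_network(data, SelectionConfig(mode="cv_ebic", n_folds=10))


class TestGammaSensitivity:
    def test_single_gamma_no_comparisons(self, small_truth):
        data = sample_ordinal(small_truth, n=300, seed=9)
        out = gamma_sensitivity(data, (0.5,), SelectionConfig(n_lambda=10))
        assert len(out["models"]) == 1
        assert out["comparisons"] == []

    def test_edge_count_nonincreasing_in_gamma(self, default_data):
        out = gamma_sensitivity(default_data, (0.1, 0.5, 0.9),
                                SelectionConfig(n_lambda=15))
        counts = [out["models"][g].n_edges for g in (0.1, 0.5, 0.9)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_jaccard_bounded(self, default_data):
        out = gamma_sensitivity(default_data, (0.1, 0.9),
                                SelectionConfig(n_lambda=15))
        for comp in out["comparisons"]:
            assert 0.0 <= comp["jaccard"] <= 1.0


class TestCrossCommunityEdges:
    def test_block_diagonal_gives_empty_list(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.3
        W[2, 3] = W[3, 2] = 0.2
        model = NetworkModel(W, ["A1", "A2", "D1", "D2"],
                             {"A1": "anxiety", "A2": "anxiety",
                              "D1": "depression", "D2": "depression"},
                             0.1, 0.5)
        assert cross_community_edges(model) == []

    def test_single_cross_edge_and_sorting(self):
        W = np.zeros((4, 4))
        W[0, 2] = W[2, 0] = 0.2
        W[1, 3] = W[3, 1] = -0.4
        model = NetworkModel(W, ["A1", "A2", "D1", "D2"],
                             {"A1": "anxiety", "A2": "anxiety",
                              "D1": "depression", "D2": "depression"},
                             0.1, 0.5)
        edges = cross_community_edges(model)
        assert edges[0] == ("A2", "D2", pytest.approx(-0.4))
        assert edges[1] == ("A1", "D1", pytest.approx(0.2))
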