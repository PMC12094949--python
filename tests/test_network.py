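"""Graphical-lasso estimation and EBIC model selection."""

import numpy as np
import pytest

from musclenet import chain_precision, generate_weight_observations
from musclenet.network import (
    EDGE_TOL,
    ebic_score,
    glasso,
    lambda_path,
    precision_to_partial_corr,
    sample_correlation,
    select_network,
    support_mle,
)
from musclenet.types import WeightObservations
from conftest import pairs_precision
from oracles import glasso_direct


def random_corr(rng, p, n=60):
    X = rng.standard_normal((n, p)) @ rng.standard_normal((p, p))
    return np.corrcoef(X, rowvar=False)


class TestSampleCorrelation:
    def test_identical_columns_have_unit_correlation(self):
        x = np.random.default_rng(0).standard_normal(20)
        S = sample_correlation(np.column_stack([x, x, x + 1.0]))
        assert S[0, 1] == pytest.approx(1.0)

    def test_independent_columns_large_n(self):
        rng = np.random.default_rng(1)
        S = sample_correlation(rng.standard_normal((100_000, 5)))
        assert np.all(np.abs(S[np.triu_indices(5, 1)]) < 0.02)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(2)
        S = sample_correlation(rng.standard_normal((50, 6)))
        assert np.allclose(S, S.T) and np.allclose(np.diag(S), 1.0)

    def test_constant_column_error_names_muscle(self):
        M = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        obs = WeightObservations("c", 1, M, ("SOL", "TA"))
        with pytest.raises(ValueError, match="TA"):
            sample_correlation(obs)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            sample_correlation(np.ones((2, 4)))


class TestGlasso:
    def test_unpenalized_is_inverse(self):
        rng = np.random.default_rng(3)
        S = random_corr(rng, 5)
        assert np.allclose(glasso(S, 0.0), np.linalg.inv(S), atol=1e-10)

    def test_screening_threshold_disconnects(self):
        rng = np.random.default_rng(4)
        S = random_corr(rng, 6)
        rho = np.abs(S - np.eye(6)).max() + 1e-6
        Theta = glasso(S, rho)
        off = Theta[np.triu_indices(6, 1)]
        assert np.all(np.abs(off) <= EDGE_TOL)

    def test_matches_direct_maximization_p3(self):
        """Oracle equivalence: penalized-likelihood optimum within 1e-4."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            S = random_corr(rng, 3, n=40)
            rho = float(rng.uniform(0.02, 0.3))
            mine = glasso(S, rho, tol=1e-7)
            oracle = glasso_direct(S, rho)
            assert np.abs(mine - oracle).max() < 1e-4

    def test_at_least_as_optimal_as_sklearn(self):
        from sklearn.covariance import graphical_lasso as sk_glasso

        rng = np.random.default_rng(6)
        for _ in range(5):
            S = random_corr(rng, 6)
            rho = 0.1

            def obj(T):
                off = np.abs(T).sum() - np.abs(np.diag(T)).sum()
                return np.linalg.slogdet(T)[1] - np.sum(S * T) - rho * off

            mine = glasso(S, rho, tol=1e-7)
            _, sk = sk_glasso(S, alpha=rho, tol=1e-8, max_iter=2000)
            assert obj(mine) >= obj(sk) - 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            glasso(np.array([[1.0, 0.5], [0.2, 1.0]]), 0.1)
        with pytest.raises(ValueError):
            glasso(np.eye(3), -0.1)


class TestLambdaPath:
    def test_shape_and_monotonicity(self):
        rng = np.random.default_rng(7)
        S = random_corr(rng, 5)
        path = lambda_path(S, n_points=40)
        assert len(path) == 40
        assert np.all(np.diff(path) < 0)

    def test_first_penalty_gives_empty_graph(self):
        rng = np.random.default_rng(8)
        S = random_corr(rng, 5)
        rho0 = lambda_path(S)[0]
        Theta = glasso(S, rho0)
        assert np.all(np.abs(Theta[np.triu_indices(5, 1)]) <= EDGE_TOL)


class TestEbic:
    def test_diagonal_theta_is_pure_likelihood_term(self):
        S = np.eye(4)
        Theta = np.diag([1.0, 2.0, 0.5, 1.5])
        n = 25
        loglik = 0.5 * n * (np.linalg.slogdet(Theta)[1] - np.trace(S @ Theta))
        assert ebic_score(Theta, S, n) == pytest.approx(-2 * loglik)

    def test_edge_increment_is_logn_plus_4gamma_logp(self):
        S = np.eye(3)
        diag = np.diag([1.0, 1.0, 1.0])
        one_edge = diag.copy()
        one_edge[0, 1] = one_edge[1, 0] = 0.1
        n, gamma = 40, 0.5
        loglik_term = lambda T: -n * (
            np.linalg.slogdet(T)[1] - np.sum(S * T)
        )  # noqa: E731
        delta = (ebic_score(one_edge, S, n, gamma) - loglik_term(one_edge)) - (
            ebic_score(diag, S, n, gamma) - loglik_term(diag)
        )
        assert delta == pytest.approx(np.log(n) + 4 * gamma * np.log(3))

    def test_gamma_zero_is_plain_bic(self):
        rng = np.random.default_rng(9)
        S = random_corr(rng, 4)
        Theta = glasso(S, 0.1)
        E = np.count_nonzero(np.abs(Theta[np.triu_indices(4, 1)]) > EDGE_TOL)
        diff = ebic_score(Theta, S, 30, gamma=0.5) - ebic_score(
            Theta, S, 30, gamma=0.0
        )
        assert diff == pytest.approx(4 * 0.5 * E * np.log(4))

    def test_indefinite_theta_rejected(self):
        with pytest.raises(ValueError):
            ebic_score(np.diag([1.0, -1.0]), np.eye(2), 10)


class TestPartialCorr:
    def test_diagonal_gives_empty_network(self):
        W = precision_to_partial_corr(np.diag([2.0, 3.0, 1.0]))
        assert not W.any()

    def test_two_node_closed_form(self):
        Theta = np.array([[2.0, -1.0], [-1.0, 2.0]])
        W = precision_to_partial_corr(Theta)
        assert W[0, 1] == pytest.approx(0.5)

    def test_sign_flip_of_precision(self):
        rng = np.random.default_rng(10)
        Theta = chain_precision(5, 0.3)
        W = precision_to_partial_corr(Theta)
        off = ~np.eye(5, dtype=bool)
        nz = off & (np.abs(Theta) > 0)
        assert np.all(np.sign(W[nz]) == -np.sign(Theta[nz]))

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            precision_to_partial_corr(np.diag([1.0, -2.0]))


class TestSupportMle:
    def test_respects_support_and_matches_likelihood(self):
        rng = np.random.default_rng(11)
        S = random_corr(rng, 5)
        support = np.zeros((5, 5), dtype=bool)
        support[0, 1] = support[1, 0] = True
        support[2, 3] = support[3, 2] = True
        Theta = support_mle(S, support)
        off = ~np.eye(5, dtype=bool)
        assert np.all(Theta[off & ~support] == 0.0)
        # stationarity on the support: (Theta^-1)_ij = S_ij on allowed entries
        Sigma = np.linalg.inv(Theta)
        assert np.allclose(Sigma[support], S[support], atol=1e-4)
        assert np.allclose(np.diag(Sigma), np.diag(S), atol=1e-4)

    def test_full_support_is_unconstrained_mle(self):
        rng = np.random.default_rng(12)
        S = random_corr(rng, 4)
        support = ~np.eye(4, dtype=bool)
        assert np.allclose(support_mle(S, support), np.linalg.inv(S), atol=1e-4)


class TestSelectNetwork:
    def test_eight_muscles_have_28_possible_edges(self, chain_obs_30):
        net = select_network(chain_obs_30, n_points=30)
        assert net.possible_edges == 28
        assert 0 <= net.nonzero_edges <= 28

    def test_sparsity_between_empty_and_saturated_at_study_size(self):
        """Detectable edges at n=30: neither empty nor complete."""
        Theta = pairs_precision(8, 0.6)
        counts = []
        for s in range(10):
            X = generate_weight_observations(Theta, 30, seed=500 + s)
            counts.append(select_network(X, n_points=30).nonzero_edges)
        assert np.median(counts) > 0
        assert max(counts) < 28

    def test_support_f1_improves_with_sample_size(self):
        """Chain-graph recovery: median F1 non-decreasing over n, >= 0.8 at 500."""
        Theta = chain_precision(8, 0.4)
        iu = np.triu_indices(8, 1)
        truth = np.abs(Theta[iu]) > 0
        medians = []
        for n in (30, 100, 500):
            f1s = []
            for s in range(20):
                X = generate_weight_observations(Theta, n, seed=1000 + s)
                est = np.abs(select_network(X, n_points=40).weights[iu]) > 0
                tp = np.sum(truth & est)
                fp = np.sum(~truth & est)
                fn = np.sum(truth & ~est)
                f1s.append(2 * tp / (2 * tp + fp + fn) if tp else 0.0)
            medians.append(float(np.median(f1s)))
        assert medians[0] <= medians[1] <= medians[2] + 1e-12
        assert medians[2] >= 0.8

    def test_duplicating_rows_never_sparsifies(self):
        """More evidence (rows x2) keeps or grows the selected edge set."""
        Theta = chain_precision(6, 0.45)
        grew = 0
        for s in range(20):
            X = generate_weight_observations(Theta, 40, seed=2000 + s)
            n1 = select_network(X, n_points=30).nonzero_edges
            X2 = WeightObservations(
                "c", 1, np.vstack([X.matrix, X.matrix]), X.channel_labels
            )
            n2 = select_network(X2, n_points=30).nonzero_edges
            grew += n2 >= n1
        assert grew >= 18

    def test_affine_column_rescaling_invariance(self, chain_obs_30):
        net1 = select_network(chain_obs_30, n_points=30)
        M = chain_obs_30.matrix.copy()
        M[:, 0] = 5.0 * M[:, 0] - 2.0
        M[:, 3] = 0.1 * M[:, 3] + 7.0
        net2 = select_network(
            WeightObservations("c", 1, M, chain_obs_30.channel_labels),
            n_points=30,
        )
        assert np.allclose(net1.weights, net2.weights, atol=1e-8)

    def test_precision_weights_consistency(self, chain_obs_30):
        net = select_network(chain_obs_30, n_points=30)
        assert np.allclose(
            net.weights, precision_to_partial_corr(net.precision), atol=1e-12
        )
        assert np.allclose(net.weights, net.weights.T)
        assert np.abs(net.weights).max() <= 1.0
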