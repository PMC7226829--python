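import numpy as np
import pytest

from imdn.model import (
    LatentModel,
    ModelConfig,
    fit,
    grad_D,
    grad_M,
    load_model,
    loss,
    neighbor_estimate,
    predict_scores,
    save_model,
    sigmoid,
    sigmoid_deriv,
)
from conftest import random_instance


class TestSigmoid:
    def test_symmetry_point(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid_deriv(0.0) == 0.25

    def test_logistic_symmetry(self, rng):
        x = rng.normal(0, 3, 50)
        np.testing.assert_allclose(sigmoid(x) + sigmoid(-x), 1.0, atol=1e-15)

    def test_stable_at_extreme_arguments(self):
        assert sigmoid(700.0) == pytest.approx(1.0)
        assert sigmoid(-700.0) == pytest.approx(0.0, abs=1e-300)
        assert np.isfinite(sigmoid_deriv(np.array([700.0, -700.0]))).all()

    def test_derivative_matches_finite_difference(self, rng):
        x = rng.normal(0, 2, 20)
        h = 1e-6
        fd = (sigmoid(x + h) - sigmoid(x - h)) / (2 * h)
        np.testing.assert_allclose(sigmoid_deriv(x), fd, atol=1e-8)


class TestPredictScores:
    def test_zero_factors_score_half(self):
        model = LatentModel(np.zeros((3, 2)), np.zeros((4, 2)),
                            ModelConfig(latent_dim=2))
        assert (predict_scores(model) == 0.5).all()

    def test_one_dimensional_example(self):
        model = LatentModel(np.array([[2.0]]), np.array([[1.0]]),
                            ModelConfig(latent_dim=1))
        assert predict_scores(model)[0, 0] == pytest.approx(0.8807970779778823)

    def test_invariant_under_joint_rotation(self, rng):
        M = rng.normal(0, 1, (5, 3))
        D = rng.normal(0, 1, (4, 3))
        Q, _ = np.linalg.qr(rng.normal(0, 1, (3, 3)))
        cfg = ModelConfig(latent_dim=3)
        s1 = predict_scores(LatentModel(M, D, cfg))
        s2 = predict_scores(LatentModel(M @ Q, D @ Q, cfg))
        np.testing.assert_allclose(s1, s2, atol=1e-10)


def _loop_loss(R, W, S, M, D, cfg):
    """Four-nested-loop reference for the objective."""
    nm, nd = R.shape
    nl = M.shape[1]
    total = 0.0
    for u in range(nm):
        for i in range(nd):
            logit = sum(M[u, k] * D[i, k] for k in range(nl))
            total += 0.5 * W[u, i] * (R[u, i] - 1 / (1 + np.exp(-logit))) ** 2
    for u in range(nm):
        total += 0.5 * cfg.lambda_m * sum(M[u, k] ** 2 for k in range(nl))
    for i in range(nd):
        total += 0.5 * cfg.lambda_d * sum(D[i, k] ** 2 for k in range(nl))
    for u in range(nm):
        for k in range(nl):
            resid = M[u, k] - sum(S[u, v] * M[v, k] for v in range(nm))
            total += 0.5 * cfg.lambda_s * resid**2
    return total


class TestLoss:
    def test_zero_logit_single_cell(self):
        cfg = ModelConfig(latent_dim=2, lambda_m=0, lambda_d=0, lambda_s=0)
        val = loss(np.array([[1.0]]), np.array([[1.0]]), None,
                   np.zeros((1, 2)), np.zeros((1, 2)), cfg)
        assert val == pytest.approx(0.125)

    def test_zero_weights_annihilate_data_term(self, rng):
        cfg = ModelConfig(latent_dim=3, lambda_m=0, lambda_d=0, lambda_s=0)
        R, W, S, M, D = random_instance(rng)
        assert loss(R, np.zeros_like(W), S, M, D, cfg) == 0.0

    def test_matches_nested_loop_reference(self, rng):
        cfg = ModelConfig(latent_dim=3, lambda_m=0.3, lambda_d=0.2, lambda_s=0.7)
        R, W, S, M, D = random_instance(rng, nm=6, nd=4)
        assert loss(R, W, S, M, D, cfg) == pytest.approx(
            _loop_loss(R, W, S, M, D, cfg), abs=1e-10
        )

    def test_non_finite_input_names_term(self, rng):
        cfg = ModelConfig(latent_dim=3)
        R, W, S, M, D = random_instance(rng)
        M = M.copy()
        M[0, 0] = np.inf
        with pytest.raises(FloatingPointError):
            loss(R, W, S, M, D, cfg)


def _finite_diff_grads(R, W, S, M, D, cfg, h=1e-6):
    gM = np.zeros_like(M)
    for idx in np.ndindex(M.shape):
        Mp, Mm = M.copy(), M.copy()
        Mp[idx] += h
        Mm[idx] -= h
        gM[idx] = (loss(R, W, S, Mp, D, cfg) - loss(R, W, S, Mm, D, cfg)) / (2 * h)
    gD = np.zeros_like(D)
    for idx in np.ndindex(D.shape):
        Dp, Dm = D.copy(), D.copy()
        Dp[idx] += h
        Dm[idx] -= h
        gD[idx] = (loss(R, W, S, M, Dp, cfg) - loss(R, W, S, M, Dm, cfg)) / (2 * h)
    return gM, gD


class TestGradients:
    def test_zero_point_with_zero_data_gradient(self):
        cfg = ModelConfig(latent_dim=2, lambda_m=0, lambda_d=0, lambda_s=0)
        R = np.zeros((3, 2))
        W = np.ones((3, 2))
        M = np.zeros((3, 2))
        D = np.zeros((2, 2))
        assert (grad_M(R, W, None, M, D, cfg) == 0).all()

    @pytest.mark.parametrize("lambda_s", [0.0, 0.1, 1.0])
    def test_match_finite_differences(self, rng, lambda_s):
        cfg = ModelConfig(latent_dim=3, lambda_m=0.05, lambda_d=0.07,
                          lambda_s=lambda_s)
        R, W, S, M, D = random_instance(rng, nm=5, nd=4)
        gM = grad_M(R, W, S, M, D, cfg)
        gD = grad_D(R, W, M, D, cfg)
        fM, fD = _finite_diff_grads(R, W, S, M, D, cfg)
        scale_M = np.abs(fM).max() or 1.0
        scale_D = np.abs(fD).max() or 1.0
        assert np.abs(gM - fM).max() / scale_M < 1e-5
        assert np.abs(gD - fD).max() / scale_D < 1e-5

    def test_lambda_s_zero_reduces_to_weighted_mf_gradient(self, rng):
        cfg = ModelConfig(latent_dim=3, lambda_m=0.1, lambda_s=0.0)
        R, W, S, M, D = random_instance(rng)
        with_S = grad_M(R, W, S, M, D, cfg)
        without_S = grad_M(R, W, None, M, D, cfg)
        np.testing.assert_array_equal(with_S, without_S)

    def test_grad_d_at_zero_m_is_pure_ridge(self, rng):
        cfg = ModelConfig(latent_dim=3, lambda_d=0.4)
        R, W, S, M, D = random_instance(rng)
        gD = grad_D(R, W, np.zeros_like(M), D, cfg)
        np.testing.assert_allclose(gD, 0.4 * D, atol=1e-15)

    def test_grad_d_data_term_linear_in_w(self, rng):
        cfg = ModelConfig(latent_dim=3, lambda_d=0.0)
        R, W, S, M, D = random_instance(rng)
        g1 = grad_D(R, W, M, D, cfg)
        g2 = grad_D(R, 2 * W, M, D, cfg)
        np.testing.assert_allclose(g2, 2 * g1, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        cfg = ModelConfig(latent_dim=3, lambda_m=0.1, lambda_s=0.5)
        R, W, S, M, D = random_instance(rng, nm=6, nd=4)
        perm = rng.permutation(6)
        g = grad_M(R, W, S, M, D, cfg)
        g_perm = grad_M(R[perm], W[perm], S[np.ix_(perm, perm)], M[perm], D, cfg)
        np.testing.assert_allclose(g_perm, g[perm], atol=1e-12)
        assert loss(R, W, S, M, D, cfg) == pytest.approx(
            loss(R[perm], W[perm], S[np.ix_(perm, perm)], M[perm], D, cfg)
        )


class TestNeighborEstimate:
    def test_single_neighbor_copies_its_vector(self):
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        M = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(neighbor_estimate(M, S), [[3, 4], [1, 2]])

    def test_shared_vector_is_fixed_point(self, rng):
        S = rng.random((5, 5))
        np.fill_diagonal(S, 0)
        S /= S.sum(axis=1, keepdims=True)
        m = rng.normal(0, 1, 3)
        M = np.tile(m, (5, 1))
        np.testing.assert_allclose(neighbor_estimate(M, S), M, atol=1e-12)

    def test_matches_loop_reference(self, rng):
        R, W, S, M, D = random_instance(rng)
        est = neighbor_estimate(M, S)
        for u in range(M.shape[0]):
            expected = sum(S[u, v] * M[v] for v in range(M.shape[0]))
            np.testing.assert_allclose(est[u], expected, atol=1e-12)


class TestFit:
    def test_loss_decreases_on_synthetic_instance(self, rng):
        R = (rng.random((30, 20)) < 0.2).astype(float)
        W = np.ones_like(R)
        cfg = ModelConfig(latent_dim=4, max_epochs=200, seed=1)
        model = fit(R, W, None, cfg)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_loss_history_is_non_increasing(self, rng):
        R, W, S, M, D = random_instance(rng, nm=10, nd=8)
        cfg = ModelConfig(latent_dim=3, max_epochs=100, learning_rate=1.0, seed=2)
        model = fit(R, W, S, cfg)
        diffs = np.diff(model.loss_history)
        assert (diffs <= 1e-12).all()

    def test_huge_ridge_shrinks_factors_below_init(self, rng):
        R = (rng.random((10, 8)) < 0.3).astype(float)
        W = np.ones_like(R)
        cfg = ModelConfig(latent_dim=3, lambda_m=1e6, lambda_d=1e6,
                          lambda_s=0.0, max_epochs=100, seed=4,
                          learning_rate=1e-7)
        model = fit(R, W, None, cfg)
        init = np.random.default_rng(4)
        M0 = init.normal(0, cfg.init_scale, (10, 3))
        D0 = init.normal(0, cfg.init_scale, (8, 3))
        assert np.linalg.norm(model.M) < np.linalg.norm(M0)
        assert np.linalg.norm(model.D) < np.linalg.norm(D0)

    def test_same_seed_is_bitwise_identical(self, rng):
        R, W, S, M, D = random_instance(rng, nm=8, nd=6)
        cfg = ModelConfig(latent_dim=3, max_epochs=50, seed=11)
        h1 = fit(R, W, S, cfg).loss_history
        h2 = fit(R, W, S, cfg).loss_history
        assert h1 == h2

    def test_network_pull_drives_residual_to_zero(self, rng):
        # with data and priors off, the optimum satisfies M_u = sum S_uv M_v
        R, W, S, M, D = random_instance(rng, nm=8, nd=6)
        cfg = ModelConfig(latent_dim=3, lambda_m=0.0, lambda_d=0.0,
                          lambda_s=10.0, max_epochs=3000, learning_rate=0.05,
                          tol=0.0, seed=5)
        model = fit(R, np.zeros_like(W), S, cfg)
        residual = model.M - S @ model.M
        init_residual_norm = np.linalg.norm(
            np.random.default_rng(5).normal(0, 0.1, (8, 3))
        )
        assert np.linalg.norm(residual) < 1e-3 * init_residual_norm

    def test_divergent_learning_rate_raises_or_stays_finite(self, rng):
        R, W, S, M, D = random_instance(rng, nm=8, nd=6)
        cfg = ModelConfig(latent_dim=3, max_epochs=30, learning_rate=1e6, seed=6)
        model = fit(R, W, S, cfg)  # guard halves the rate instead of diverging
        assert np.isfinite(model.loss_history).all()


class TestModelPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        R, W, S, M, D = random_instance(rng, nm=5, nd=4)
        cfg = ModelConfig(latent_dim=3, max_epochs=20, seed=9)
        model = fit(R, W, S, cfg,
                    mirna_ids=[f"m{u}" for u in range(5)],
                    disease_ids=[f"d{i}" for i in range(4)])
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        np.testing.assert_allclose(back.M, model.M, atol=0)
        np.testing.assert_allclose(back.D, model.D, atol=0)
        assert back.config == model.config
        assert back.mirna_ids == model.mirna_ids
        assert back.loss_history == pytest.approx(model.loss_history)
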