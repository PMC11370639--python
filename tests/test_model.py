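"""Forward pass, loss, analytic gradients, training loop, prediction."""

import numpy as np
import pytest

from gpnet import GPN, laplacian
from gpnet.model import (
    GPNParams,
    forward,
    grad_alpha,
    grad_beta,
    grad_mu,
    loss,
    predict,
    train,
)


def random_instance(seed, p=8, n=6, c=3, delta=1e-3):
    rng = np.random.default_rng(seed)
    W = np.triu(rng.random((p, p)) * (rng.random((p, p)) < 0.5), 1)
    W = W + W.T
    L = np.diag(W.sum(1)) - W
    X = rng.standard_normal((p, n))
    Y = np.eye(c)[rng.integers(0, c, n)].T
    params = GPNParams(
        alpha=float(rng.uniform(-1, 1)),
        mu=float(rng.uniform(0.1, 2.0)),
        beta=0.5 * rng.standard_normal((p, c)),
        delta=delta,
    )
    return X, L, Y, params


def numerical_gradient(f, x0, h=1e-6):
    return (f(x0 + h) - f(x0 - h)) / (2 * h)


def loss_at(X, L, Y, params):
    _, P = forward(X, L, params)
    return loss(P, Y, params)


class TestForward:
    def test_zero_classifier_gives_uniform_probabilities(self):
        X, L, Y, params = random_instance(0)
        params.beta = np.zeros_like(params.beta)
        _, P = forward(X, L, params)
        np.testing.assert_allclose(P, 1 / 3)

    def test_softmax_shift_invariance_two_class(self):
        # logit columns (a, a + t) must give (1/(1+e^t), e^t/(1+e^t))
        X, L, _, params = random_instance(1, c=2)
        t = np.log(3.0)
        params.beta = np.zeros((X.shape[0], 2))
        prop, _ = forward(X, L, params)
        from gpnet.model import softmax_columns

        S = np.vstack([np.full(4, 2.0), np.full(4, 2.0) + t])
        P = softmax_columns(S)
        np.testing.assert_allclose(P[0], 0.25, atol=1e-12)
        np.testing.assert_allclose(P[1], 0.75, atol=1e-12)

    def test_probability_columns_sum_to_one(self):
        X, L, Y, params = random_instance(2)
        _, P = forward(X, L, params)
        np.testing.assert_allclose(P.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(P > 0) and np.all(P < 1)


class TestLoss:
    def test_near_one_hot_probabilities_drive_loss_to_zero(self):
        Y = np.eye(3)
        params = GPNParams(alpha=0.0, mu=0.0, beta=np.zeros((4, 3)), delta=1e-12)
        for eps in (1e-3, 1e-6, 1e-9):
            P = np.where(Y == 1, 1 - eps, eps / 2)
            assert loss(P, Y, params) < 3 * eps

    def test_uniform_probabilities_give_log_c(self):
        Y = np.eye(3)[:, [0, 1, 2, 0]].reshape(3, 4)
        P = np.full((3, 4), 1 / 3)
        params = GPNParams(alpha=0.0, mu=0.0, beta=np.zeros((2, 3)), delta=1e-3)
        assert loss(P, Y, params) == pytest.approx(np.log(3), abs=1e-12)

    def test_matches_hand_computation_with_regularization(self):
        P = np.array([[0.7, 0.2], [0.2, 0.5], [0.1, 0.3]])
        Y = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        beta = np.array([[1.0, 0.0, 2.0], [0.0, -1.0, 0.0]])
        params = GPNParams(alpha=0.5, mu=2.0, beta=beta, delta=0.001)
        expected_ce = -(np.log(0.7) + np.log(0.3)) / 2
        expected_reg = 0.001 * (0.25 + 4.0 + 6.0)
        assert loss(P, Y, params) == pytest.approx(expected_ce + expected_reg, rel=1e-12)

    def test_nonpositive_probability_rejected(self):
        params = GPNParams(alpha=0.0, mu=0.0, beta=np.zeros((2, 2)), delta=1e-3)
        with pytest.raises(ValueError, match="positive"):
            loss(np.array([[0.0, 1.0], [1.0, 0.0]]), np.eye(2), params)


class TestGradients:
    def test_grad_beta_reduces_to_regularizer_when_fit_is_perfect(self):
        X, L, Y, params = random_instance(3)
        Z = np.random.default_rng(3).standard_normal(X.shape)
        g = grad_beta(Z, Y.copy(), Y, params)
        np.testing.assert_allclose(g, 2 * params.delta * params.beta)

    def test_grad_alpha_reduces_to_regularizer_when_propagation_is_identity(self):
        X, L, Y, params = random_instance(4)
        prop, P = forward(X, L, params)
        g = grad_alpha(X, X.copy(), P, Y, params)
        assert g == pytest.approx(2 * params.delta * params.alpha)

    def test_grad_alpha_data_term_vanishes_at_saturated_theta(self):
        X, L, Y, params = random_instance(5)
        for a in (-40.0, 40.0):
            params.alpha = a
            prop, P = forward(X, L, params)
            g = grad_alpha(X, prop.F, P, Y, params)
            assert g == pytest.approx(2 * params.delta * a, abs=1e-12)

    def test_grad_mu_reduces_to_regularizer_on_edgeless_graph(self):
        X, _, Y, params = random_instance(6)
        L0 = np.zeros((X.shape[0], X.shape[0]))
        _, P = forward(X, L0, params)
        assert grad_mu(X, L0, P, Y, params) == pytest.approx(2 * params.delta * params.mu)

    @pytest.mark.parametrize("seed", range(10))
    def test_all_gradients_match_central_finite_differences(self, seed):
        X, L, Y, params = random_instance(seed, p=10, n=8, c=3)
        prop, P = forward(X, L, params)

        ga = grad_alpha(X, prop.F, P, Y, params)
        fd = numerical_gradient(
            lambda a: loss_at(X, L, Y, GPNParams(a, params.mu, params.beta, params.delta)),
            params.alpha,
        )
        assert abs(ga - fd) / max(abs(fd), 1e-8) < 1e-5

        gm = grad_mu(X, L, P, Y, params)
        fd = numerical_gradient(
            lambda m: loss_at(X, L, Y, GPNParams(params.alpha, m, params.beta, params.delta)),
            params.mu,
        )
        assert abs(gm - fd) / max(abs(fd), 1e-8) < 1e-4

        gb = grad_beta(prop.Z, P, Y, params)
        rng = np.random.default_rng(seed)
        for _ in range(3):
            i, j = rng.integers(0, X.shape[0]), rng.integers(0, Y.shape[0])

            def with_entry(v):
                B = params.beta.copy()
                B[i, j] = v
                return loss_at(X, L, Y, GPNParams(params.alpha, params.mu, B, params.delta))

            fd = numerical_gradient(with_entry, params.beta[i, j])
            assert abs(gb[i, j] - fd) / max(abs(fd), 1e-8) < 1e-5


class TestTrain:
    def test_separable_data_reaches_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        p, n, c = 6, 30, 3
        centers = 4.0 * np.eye(c)[:, :, None]  # class k large on protein k
        labels = np.repeat(np.arange(c), n // c)
        X = np.zeros((p, n))
        for j, k in enumerate(labels):
            X[:, j] = rng.normal(0, 0.1, p)
            X[k, j] += 4.0
        Y = np.eye(c)[labels].T
        L = np.zeros((p, p))
        init = GPNParams(alpha=0.0, mu=0.0, beta=np.zeros((p, c)), delta=1e-6)
        state = train(X, L, Y, init, epochs=1500, seed=0)
        _, P = forward(X, L, state.params)
        assert np.mean(np.argmax(P, 0) == labels) == 1.0
        # loss decreases monotonically after burn-in
        tail = state.loss_history[100:]
        assert all(a >= b - 1e-9 for a, b in zip(tail, tail[1:]))

    def test_huge_regularization_shrinks_beta_and_flattens_probabilities(self):
        X, L, Y, _ = random_instance(1, p=6, n=12)
        init = GPNParams(alpha=0.0, mu=1.0, beta=np.zeros((6, 3)), delta=1e3)
        state = train(X, L, Y, init, epochs=400, seed=1)
        assert np.abs(state.params.beta).max() < 1e-2
        _, P = forward(X, L, state.params)
        np.testing.assert_allclose(P, 1 / 3, atol=0.05)

    def test_same_seed_gives_bit_identical_history(self):
        X, L, Y, _ = random_instance(2, p=6, n=10)
        init = GPNParams(alpha=0.0, mu=0.5, beta=np.zeros((6, 3)), delta=1e-3)
        h1 = train(X, L, Y, init, epochs=200, seed=7).loss_history
        h2 = train(X, L, Y, init, epochs=200, seed=7).loss_history
        assert h1 == h2

    def test_mu_stays_nonnegative_and_theta_in_unit_interval(self):
        X, L, Y, _ = random_instance(3, p=6, n=10)
        init = GPNParams(alpha=0.0, mu=0.01, beta=np.zeros((6, 3)), delta=1e-3)
        state = train(X, L, Y, init, epochs=300, seed=3)
        assert state.params.mu >= 0.0
        assert 0.0 < state.params.theta < 1.0
        assert min(state.loss_history) >= 0.0


class TestPredict:
    def test_training_data_reproduces_final_forward_pass(self):
        X, L, Y, params = random_instance(4)
        _, P_fwd = forward(X, L, params)
        P, idx = predict(X, L, params)
        np.testing.assert_array_equal(P, P_fwd)
        np.testing.assert_array_equal(idx, np.argmax(P_fwd, axis=0))

    def test_single_sample_column_sums_to_one(self):
        X, L, Y, params = random_instance(5)
        P, idx = predict(X[:, :1], L, params)
        assert P.shape == (3, 1)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_samples_returns_empty_without_error(self):
        X, L, Y, params = random_instance(6)
        P, idx = predict(X[:, :0], L, params)
        assert P.shape == (3, 0) and idx.shape == (0,)


class TestGPNModelObject:
    def test_from_frames_fixes_class_order_by_first_appearance(self, random_network):
        import pandas as pd

        net = random_network(p=4, seed=0)
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.standard_normal((4, 6)), index=net.proteins,
            columns=[f"s{i}" for i in range(6)],
        )
        labels = dict(zip(expr.columns, ["MCI", "AD", "MCI", "VD", "AD", "MCI"]))
        model = GPN.from_frames(expr, labels, net)
        assert model.class_names == ["MCI", "AD", "VD"]
        res = model.fit(epochs=50, mu_init=1.0, seed=0)
        P, names = res.predict(expr.to_numpy())
        assert set(names) <= {"MCI", "AD", "VD"}

    def test_results_summary_and_serialization_roundtrip(self, random_network, tmp_path):
        net = random_network(p=4, seed=1)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 9))
        Y = np.eye(3)[rng.integers(0, 3, 9)].T
        res = GPN(X, Y, net).fit(epochs=60, mu_init=0.5, seed=1)
        text = res.summary()
        assert "theta" in text and "mu" in text
        res.save(tmp_path / "model.json")
        loaded = res.load_params(tmp_path / "model.json")
        assert loaded["alpha"] == res.alpha
        np.testing.assert_array_equal(np.asarray(loaded["beta"]), res.beta)

    def test_standardization_is_stored_and_applied_at_predict_time(self, random_network):
        net = random_network(p=4, seed=2)
        rng = np.random.default_rng(2)
        X = 5.0 + 2.0 * rng.standard_normal((4, 12))
        Y = np.eye(3)[rng.integers(0, 3, 12)].T
        model = GPN(X, Y, net, standardize=True)
        np.testing.assert_allclose(model.X.mean(axis=1), 0, atol=1e-12)
        res = model.fit(epochs=40, mu_init=1.0, seed=2)
        P, _ = res.predict(X)
        np.testing.assert_array_equal(P, res.fittedvalues)


class TestAblationOrdering:
    def test_mean_validation_auroc_not_worse_than_no_propagation(self, ablation_study):
        """With diffusion-borne class signal, propagating should not lose
        discriminative power on held-out samples (mean over replicates)."""
        gpn = np.mean([r["auroc_gpn"] for r in ablation_study])
        ablation = np.mean([r["auroc_ablation"] for r in ablation_study])
        assert gpn >= ablation - 0.03
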