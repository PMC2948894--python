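"""MLP forward/backward correctness, trainers, splitting, determinism."""

import numpy as np
import pytest

from petseg import neural as nn


def finite_difference_gradient(model, X, y, eps=1e-6):
    theta = model.get_params()
    grad = np.zeros_like(theta)
    for i in range(theta.size):
        up, dn = theta.copy(), theta.copy()
        up[i] += eps
        dn[i] -= eps
        model.set_params(up)
        f_up = nn.mse(nn.forward_batch(model, X), y)
        model.set_params(dn)
        f_dn = nn.mse(nn.forward_batch(model, X), y)
        grad[i] = (f_up - f_dn) / (2 * eps)
    model.set_params(theta)
    return grad


def flatten_grads(w_grads, b_grads):
    return np.concatenate([np.concatenate([w.ravel(), b])
                           for w, b in zip(w_grads, b_grads)])


class TestActivationAndForward:
    def test_tansig_values(self):
        assert nn.tansig(0.0) == 0.0
        assert nn.tansig(1.0) == pytest.approx(2 / (1 + np.exp(-2)) - 1, abs=1e-10)
        assert nn.tansig(1.0) == pytest.approx(0.76159, abs=1e-5)
        assert nn.tansig(50.0) == pytest.approx(1.0)
        assert nn.tansig(-50.0) == pytest.approx(-1.0)
        x = np.linspace(-3, 3, 13)
        assert nn.tansig(-x) == pytest.approx(-nn.tansig(x))

    def test_zero_model_outputs_zero(self):
        model = nn.MLPModel([np.zeros((3, 4)), np.zeros((1, 3))],
                            [np.zeros(3), np.zeros(1)])
        assert nn.forward(model, np.ones(4)) == 0.0

    def test_single_linear_neuron_identity(self):
        model = nn.MLPModel([np.array([[1.0]])], [np.array([0.0])],
                            hidden_activation="linear")
        assert nn.forward(model, [0.5]) == pytest.approx(0.5)

    def test_matches_hand_coded_matrix_evaluation(self, rng):
        model = nn.init_mlp((6, 4, 1), seed=7)
        P = rng.normal(size=6)
        by_hand = (model.weights[1] @ np.tanh(model.weights[0] @ P + model.biases[0])
                   + model.biases[1])[0]
        assert nn.forward(model, P) == pytest.approx(by_hand, abs=1e-12)

    def test_feature_length_mismatch_rejected(self):
        model = nn.init_mlp((6, 4, 1), seed=0)
        with pytest.raises(ValueError):
            nn.forward(model, np.ones(5))


class TestDeltaRule:
    def test_update_example(self):
        w = nn.delta_rule_step(np.array(0.0), np.array(1.0), 1.0, 0.5, 0.1)
        assert w == pytest.approx(0.05)

    def test_zero_error_no_change(self, rng):
        w = rng.normal(size=4)
        p = rng.normal(size=4)
        assert nn.delta_rule_step(w, p, 2.0, 2.0, 0.3) == pytest.approx(w)

    def test_converges_to_least_squares_weight(self, rng):
        p = rng.normal(size=40)
        t = 3.0 * p + rng.normal(0, 0.05, 40)
        w = 0.0
        for _ in range(300):
            for pi, ti in zip(p, t):
                w = float(nn.delta_rule_step(np.asarray(w), np.asarray(pi),
                                             ti, w * pi, 0.02))
        assert w == pytest.approx(float(p @ t / (p @ p)), abs=0.02)


class TestBackprop:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        model = nn.init_mlp((5, 3, 1), seed=seed)
        X = rng.normal(size=(7, 5))
        y = rng.normal(size=7)
        analytic = flatten_grads(*nn.backprop_gradients(model, X, y))
        numeric = finite_difference_gradient(model, X, y)
        assert analytic == pytest.approx(numeric, rel=1e-6, abs=1e-9)

    def test_zero_error_batch_gives_zero_gradient(self, rng):
        model = nn.init_mlp((4, 3, 1), seed=0)
        X = rng.normal(size=(5, 4))
        y = nn.forward_batch(model, X)
        analytic = flatten_grads(*nn.backprop_gradients(model, X, y))
        assert analytic == pytest.approx(np.zeros_like(analytic), abs=1e-12)

    def test_linear_net_matches_normal_equation_residual(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        w = rng.normal(size=3)
        b = 0.3
        model = nn.MLPModel([w[None, :]], [np.array([b])], hidden_activation="linear")
        w_grads, b_grads = nn.backprop_gradients(model, X, y)
        resid = X @ w + b - y
        assert w_grads[0].ravel() == pytest.approx(2 / 20 * X.T @ resid)
        assert b_grads[0] == pytest.approx(2 / 20 * resid.sum())

    def test_empty_batch_rejected(self):
        model = nn.init_mlp((4, 3, 1), seed=0)
        with pytest.raises(ValueError):
            nn.backprop_gradients(model, np.empty((0, 4)), np.empty(0))


class TestGradientDescent:
    def xor_problem(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([0.0, 1, 1, 0])
        return X, y

    def test_learns_xor_toy_problem(self):
        X, y = self.xor_problem()
        model = nn.init_mlp((2, 8, 1), seed=0)
        config = nn.TrainingConfig(algorithm="gd", learning_rate=0.3, max_epochs=1000)
        trained, rec = nn.train_gd(model, (X, y), config)
        assert rec.train_mse[-1] < 0.05
        assert np.all(np.isfinite(rec.train_mse))

    def test_zero_learning_rate_leaves_model_unchanged(self):
        X, y = self.xor_problem()
        model = nn.init_mlp((2, 4, 1), seed=1)
        config = nn.TrainingConfig(algorithm="gd", learning_rate=0.0, max_epochs=5)
        trained, _ = nn.train_gd(model, (X, y), config)
        for w0, w1 in zip(model.weights, trained.weights):
            assert np.array_equal(w0, w1)

    def test_divergence_aborts_with_message(self):
        X, y = self.xor_problem()
        model = nn.init_mlp((2, 8, 1), seed=0)
        config = nn.TrainingConfig(algorithm="gd", learning_rate=50.0, max_epochs=2000)
        with pytest.raises(RuntimeError, match="diverged"):
            nn.train_gd(model, (X, y), config)

    def test_adaptive_rate_never_accepts_much_worse_steps(self):
        X, y = self.xor_problem()
        model = nn.init_mlp((2, 8, 1), seed=0)
        config = nn.TrainingConfig(algorithm="gda", learning_rate=0.5, max_epochs=300)
        _, rec = nn.train_gd(model, (X, y), config)
        trace = np.array(rec.train_mse)
        assert np.all(trace[1:] <= trace[:-1] * 1.04 + 1e-12)


class TestLevenbergMarquardt:
    def test_recovers_linear_model(self):
        x = np.linspace(-1, 1, 11)[:, None]
        y = 2 * x[:, 0] + 1
        model = nn.MLPModel([np.array([[0.3]])], [np.array([-0.2])],
                            hidden_activation="linear")
        config = nn.TrainingConfig(algorithm="lm", max_epochs=50)
        trained, _ = nn.train_lm(model, (x, y), config)
        assert trained.weights[0][0, 0] == pytest.approx(2.0, abs=1e-6)
        assert trained.biases[0][0] == pytest.approx(1.0, abs=1e-6)

    def test_accepted_mse_strictly_decreasing(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1]
        model = nn.init_mlp((4, 6, 1), seed=0)
        config = nn.TrainingConfig(algorithm="lm", max_epochs=30)
        _, rec = nn.train_lm(model, (X, y), config)
        trace = rec.train_mse
        assert all(a > b for a, b in zip(trace, trace[1:]))

    def test_beats_gd_at_equal_epochs_seed_matched(self, rng):
        X = rng.normal(size=(40, 6))
        y = np.tanh(X @ rng.normal(size=6)) * 0.5
        init = nn.init_mlp((6, 10, 1), seed=3)
        lm_cfg = nn.TrainingConfig(algorithm="lm", max_epochs=20)
        gd_cfg = nn.TrainingConfig(algorithm="gd", learning_rate=0.05, max_epochs=20)
        _, lm_rec = nn.train_lm(init.copy(), (X, y), lm_cfg)
        _, gd_rec = nn.train_gd(init.copy(), (X, y), gd_cfg)
        assert lm_rec.train_mse[-1] < gd_rec.train_mse[-1]

    def test_large_lambda_step_is_scaled_gradient(self, rng):
        # as lambda -> inf, (J^T J + lambda I)^-1 J^T e -> (1/lambda) * J^T e
        X = rng.normal(size=(12, 3))
        y = rng.normal(size=12)
        model = nn.MLPModel([rng.normal(size=(1, 3))], [rng.normal(size=1)],
                            hidden_activation="linear")
        J, out = nn._lm_jacobian(model, X)
        e = y - out
        lam = 1e9
        delta = np.linalg.solve(J.T @ J + lam * np.eye(J.shape[1]), J.T @ e)
        assert delta == pytest.approx(J.T @ e / lam, rel=1e-4)

    def test_zero_lambda_step_is_gauss_newton(self, rng):
        # for a linear model, the lambda=0 step jumps to the least-squares optimum
        X = rng.normal(size=(15, 2))
        y = rng.normal(size=15)
        model = nn.MLPModel([np.array([[0.1, -0.4]])], [np.array([0.0])],
                            hidden_activation="linear")
        J, out = nn._lm_jacobian(model, X)
        delta = np.linalg.solve(J.T @ J, J.T @ (y - out))
        theta = model.get_params() + delta
        lstsq = np.linalg.lstsq(np.column_stack([X, np.ones(15)]), y, rcond=None)[0]
        assert theta == pytest.approx(lstsq, abs=1e-8)

    def test_dual_and_primal_solves_agree(self, rng):
        # fewer samples than parameters triggers the dual (n x n) system
        X = rng.normal(size=(5, 6))
        y = rng.normal(size=5)
        model = nn.init_mlp((6, 4, 1), seed=1)
        J, out = nn._lm_jacobian(model, X)
        e = y - out
        lam = 1e-2
        primal = np.linalg.solve(J.T @ J + lam * np.eye(J.shape[1]), J.T @ e)
        dual = J.T @ np.linalg.solve(J @ J.T + lam * np.eye(5), e)
        assert dual == pytest.approx(primal, abs=1e-9)


class TestSplitAndMSE:
    def test_slice_split_46_10_10(self):
        train, val, test = nn.split_data(range(66), seed=0)
        assert (len(train), len(val), len(test)) == (46, 10, 10)
        assert sorted(train + val + test) == list(range(66))

    def test_all_train_fractions(self):
        train, val, test = nn.split_data(range(10), fractions=(1.0, 0.0, 0.0))
        assert len(train) == 10 and not val and not test

    def test_same_seed_same_split(self):
        assert nn.split_data(range(30), seed=5) == nn.split_data(range(30), seed=5)
        assert nn.split_data(range(30), seed=5) != nn.split_data(range(30), seed=6)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nn.split_data(range(3), fractions=(0.7, 0.15, 0.15))

    def test_mse_examples(self, rng):
        assert nn.mse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert nn.mse([0.0], [1.0]) == 1.0
        p, t = rng.normal(size=17), rng.normal(size=17)
        assert nn.mse(p, t) == pytest.approx(sum((a - b) ** 2 for a, b in zip(p, t)) / 17)
        with pytest.raises(ValueError):
            nn.mse([1.0], [1.0, 2.0])


class TestDeterminismAndSerialization:
    def test_fixed_seed_identical_training(self, rng):
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        config = nn.TrainingConfig(algorithm="lm", max_epochs=10)
        a, _ = nn.train_lm(nn.init_mlp((5, 4, 1), seed=2), (X, y), config)
        b, _ = nn.train_lm(nn.init_mlp((5, 4, 1), seed=2), (X, y), config)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_json_round_trip(self, tmp_path):
        model = nn.init_mlp((8, 3, 1), seed=4)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = nn.MLPModel.from_json(path)
        assert back.layer_sizes == model.layer_sizes
        for wa, wb in zip(model.weights, back.weights):
            assert wa == pytest.approx(wb, abs=1e-15)

    def test_init_respects_fan_in_bound(self):
        model = nn.init_mlp((100, 10, 1), seed=0)
        assert np.max(np.abs(model.weights[0])) <= 0.1


class TestHiddenSizeSweep:
    def test_reports_mean_mse_per_size(self, rng):
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(float)
        config = nn.TrainingConfig(algorithm="lm", max_epochs=5)
        res = nn.hidden_size_sweep(X, y, [2, 6], repeats=2, config=config, seed=0)
        assert set(res) == {2, 6}
        assert all(np.isfinite(v) and v >= 0 for v in res.values())
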