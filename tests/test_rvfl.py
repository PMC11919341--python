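import numpy as np
import pytest

from dcsflow import (
    ELMModel,
    RandomLayer,
    RVFLModel,
    count_params_flops,
    design_matrix,
    init_random_layer,
    load_model,
    predict,
    save_model,
    train_elm,
    train_rvfl,
)
from dcsflow.errors import DimensionError, InvalidConfigError, InvalidParameterError


class TestRandomLayer:
    def test_seed_determinism_and_shapes(self):
        a = init_random_layer(128, 500, "sigmoid", seed=7)
        b = init_random_layer(128, 500, "sigmoid", seed=7)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.sigma_bias, b.sigma_bias)
        assert a.W.shape == (500, 128) and a.sigma_bias.shape == (500,)
        assert np.all(np.abs(a.W) <= 1) and np.all((a.sigma_bias >= 0)
                                                   & (a.sigma_bias <= 1))

    def test_sigmoid_of_zero_is_half(self):
        layer = RandomLayer(W=np.zeros((3, 2)), sigma_bias=np.zeros(3),
                            activation="sigmoid", seed=0)
        H = design_matrix(layer, np.zeros((1, 2)), "elm")
        np.testing.assert_array_equal(H, 0.5)

    def test_unknown_activation_rejected(self):
        with pytest.raises(InvalidConfigError):
            init_random_layer(4, 2, activation="relu")


class TestDesignMatrix:
    def test_rvfl_with_no_hidden_nodes_is_identity_on_inputs(self):
        layer = init_random_layer(5, 0)
        X = np.random.default_rng(0).normal(size=(7, 5))
        np.testing.assert_array_equal(design_matrix(layer, X, "rvfl"), X)

    def test_sigmoid_outputs_in_open_unit_interval(self):
        layer = init_random_layer(6, 20, "sigmoid", seed=1)
        X = np.random.default_rng(1).normal(size=(9, 6))
        H = design_matrix(layer, X, "elm")
        assert np.all((H > 0) & (H < 1))

    def test_matches_elementwise_loop_oracle(self):
        layer = init_random_layer(2, 2, "sigmoid", seed=0)
        X = np.array([[0.3, -1.2], [2.0, 0.1], [-0.5, 0.7]])
        H = design_matrix(layer, X, "rvfl")
        for i in range(3):
            for k in range(2):
                z = sum(layer.W[k, j] * X[i, j] for j in range(2)) \
                    + layer.sigma_bias[k]
                assert H[i, 2 + k] == pytest.approx(1 / (1 + np.exp(-z)))
            assert H[i, 0] == X[i, 0] and H[i, 1] == X[i, 1]

    def test_shape_mismatch_raises(self):
        layer = init_random_layer(4, 3)
        with pytest.raises(DimensionError):
            design_matrix(layer, np.ones((2, 5)), "rvfl")


class TestTrainRVFL:
    def test_recovers_exact_linear_map(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 10))
        A = rng.normal(size=(10, 2))
        model = train_rvfl(X, X @ A, init_random_layer(10, 30, seed=2), 1e-12)
        mae = np.abs(predict(model, X) - X @ A).mean()
        assert mae < 1e-8

    def test_primal_and_dual_branches_agree_on_boundary(self):
        # N = n + L, where both closed forms apply
        rng = np.random.default_rng(3)
        n, L = 10, 20
        N = n + L
        X = rng.normal(size=(N, n))
        Y = rng.normal(size=(N, 2))
        layer = init_random_layer(n, L, seed=4)
        H = design_matrix(layer, X, "rvfl")
        lam = 1e-3
        primal = np.linalg.solve(H.T @ H + lam * np.eye(n + L), H.T @ Y)
        dual = H.T @ np.linalg.solve(H @ H.T + lam * np.eye(N), Y)
        np.testing.assert_allclose(primal, dual, atol=1e-8)
        # the trained model takes the primal branch here and matches both
        model = train_rvfl(X, Y, layer, lam)
        np.testing.assert_allclose(model.omega, primal, atol=1e-8)

    def test_dual_branch_used_when_underdetermined(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 10))   # N=15 < n+L=40
        Y = rng.normal(size=(15, 2))
        layer = init_random_layer(10, 30, seed=5)
        model = train_rvfl(X, Y, layer, 1e-8)
        # near-interpolation in the underdetermined regime
        assert np.abs(predict(model, X) - Y).max() < 1e-4

    def test_huge_lambda_shrinks_weights_to_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 8))
        Y = rng.normal(size=(50, 2))
        model = train_rvfl(X, Y, init_random_layer(8, 10, seed=6), 1e6)
        assert np.linalg.norm(model.omega) < 1e-3
        assert np.abs(predict(model, X)).max() < 0.1

    def test_training_error_nonincreasing_as_lambda_decreases(self):
        # ridge theory guarantees monotonicity of the squared training
        # error; MAE tracks it on these instances
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 6))
        Y = rng.normal(size=(100, 2))
        layer = init_random_layer(6, 12, seed=7)
        sses = [np.sum((predict(train_rvfl(X, Y, layer, lam), X) - Y) ** 2)
                for lam in (1e2, 1e0, 1e-2, 1e-4, 1e-6)]
        assert all(a >= b - 1e-12 for a, b in zip(sses, sses[1:]))

    def test_lambda_zero_rejected(self):
        with pytest.raises(InvalidParameterError, match="lam"):
            train_rvfl(np.ones((4, 2)), np.ones((4, 1)),
                       init_random_layer(2, 2), 0.0)

    def test_l0_lambda_to_zero_equals_ordinary_least_squares(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 5))
        Y = rng.normal(size=(60, 2))
        model = train_rvfl(X, Y, init_random_layer(5, 0), 1e-12)
        ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
        np.testing.assert_allclose(model.omega, ols, atol=1e-8)


class TestTrainELM:
    def test_square_nonsingular_interpolates(self):
        rng = np.random.default_rng(9)
        n, L = 6, 12
        layer = init_random_layer(n, L, seed=9)
        X = rng.normal(size=(L, n))   # N = L -> square H
        Y = rng.normal(size=(L, 2))
        model = train_elm(X, Y, layer)
        assert np.abs(predict(model, X) - Y).max() < 1e-8

    def test_overdetermined_matches_ridge_oracle(self):
        rng = np.random.default_rng(10)
        layer = init_random_layer(5, 8, seed=10)
        X = rng.normal(size=(100, 5))
        Y = rng.normal(size=(100, 2))
        model = train_elm(X, Y, layer)
        H = design_matrix(layer, X, "elm")
        oracle = np.linalg.solve(H.T @ H + 1e-12 * np.eye(8), H.T @ Y)
        np.testing.assert_allclose(model.omega, oracle, atol=1e-6)

    def test_zero_targets_give_zero_weights(self):
        layer = init_random_layer(4, 6, seed=11)
        X = np.random.default_rng(11).normal(size=(20, 4))
        model = train_elm(X, np.zeros((20, 2)), layer)
        np.testing.assert_allclose(model.omega, 0.0, atol=1e-12)

    def test_all_zero_design_warns_and_returns_zero(self):
        layer = RandomLayer(W=np.zeros((3, 2)), sigma_bias=np.zeros(3),
                            activation="sine", seed=0)
        with pytest.warns(RuntimeWarning, match="zero"):
            model = train_elm(np.zeros((5, 2)), np.ones((5, 1)), layer)
        np.testing.assert_array_equal(model.omega, 0.0)


class TestPredict:
    def test_single_row_output_shape(self):
        layer = init_random_layer(4, 6, seed=12)
        model = train_elm(np.random.default_rng(12).normal(size=(20, 4)),
                          np.zeros((20, 2)), layer)
        assert predict(model, np.ones(4)).shape == (1, 2)

    def test_matches_hand_computed_h_omega(self):
        layer = init_random_layer(2, 2, "sigmoid", seed=0)
        omega = np.array([[1.0, 0.0], [0.0, 2.0], [0.5, 0.5], [-1.0, 1.0]])
        model = RVFLModel(layer=layer, omega=omega, lam=1e-6)
        x = np.array([[0.2, -0.4]])
        H = design_matrix(layer, x, "rvfl")
        np.testing.assert_allclose(predict(model, x), H @ omega)


class TestCountParamsFlops:
    @pytest.mark.parametrize("n, L, m, arch, params", [
        (128, 500, 2, "elm", 65_500),
        (128, 500, 2, "rvfl", 65_756),
        (1, 1, 1, "elm", 3),
    ])
    def test_parameter_counts(self, n, L, m, arch, params):
        assert count_params_flops(n, L, m, arch)[0] == params

    def test_rejects_bad_arch(self):
        with pytest.raises(InvalidConfigError):
            count_params_flops(2, 2, 2, "cnn")


def test_model_json_round_trip(tmp_path):
    rng = np.random.default_rng(13)
    X = rng.normal(size=(30, 4))
    Y = rng.normal(size=(30, 2))
    layer = init_random_layer(4, 5, "rbf", seed=13)
    for trainer in (lambda: train_rvfl(X, Y, layer, 1e-4),
                    lambda: train_elm(X, Y, layer)):
        model = trainer()
        path = tmp_path / f"{model.arch}.json"
        save_model(model, path)
        back = load_model(path)
        assert type(back) is type(model)
        np.testing.assert_allclose(back.omega, model.omega, rtol=1e-15)
        np.testing.assert_allclose(back.layer.W, model.layer.W, rtol=1e-15)
        np.testing.assert_allclose(predict(back, X), predict(model, X),
                                   rtol=1e-12)
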