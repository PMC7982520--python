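"""LSTM cell equations, network stack, backprop exactness, SGDM training."""

import numpy as np
import pytest

from erpdecode import lstm
from erpdecode.lstm import (
    LSTMParams,
    NetworkConfig,
    TrainConfig,
    bp_config,
    deep_lstm_config,
    init_network,
    lstm_forward,
    network_forward,
    predict,
    recurrent_config,
    train,
)


def _random_params(H, F, rng):
    return LSTMParams(
        W_f=rng.standard_normal((H, H + F)), W_c=rng.standard_normal((H, H + F)),
        W_U=rng.standard_normal((H, H + F)), W_o=rng.standard_normal((H, H + F)),
        b_f=rng.standard_normal(H), b_c=rng.standard_normal(H),
        b_U=rng.standard_normal(H), b_o=rng.standard_normal(H),
    )


def _zero_params(H, F):
    Z = np.zeros((H, H + F))
    z = np.zeros(H)
    return LSTMParams(W_f=Z.copy(), W_c=Z.copy(), W_U=Z.copy(), W_o=Z.copy(),
                      b_f=z.copy(), b_c=z.copy(), b_U=z.copy(), b_o=z.copy())


def _oracle_trajectory(params, sequence):
    """Independent per-timestep calculator for the gate equations."""
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    H = params.hidden_size
    h = np.zeros(H)
    C = np.zeros(H)
    states = []
    for x in sequence:
        z = np.concatenate([h, x])
        f = sig(params.W_f @ z + params.b_f)
        cbar = np.tanh(params.W_c @ z + params.b_c)
        U = sig(params.W_U @ z + params.b_U)
        O = sig(params.W_o @ z + params.b_o)
        C = f * C + U * cbar
        h = O * np.tanh(C)
        states.append((f, U, O, cbar, C.copy(), h.copy()))
    return states


class TestLstmForward:
    def test_zero_parameters_give_half_gates_zero_states(self):
        # sigmoid(0) = 0.5 and tanh(0) = 0 force C_t = h_t = 0 for every t
        params = _zero_params(4, 3)
        state = lstm_forward(params, np.ones((5, 3)))
        np.testing.assert_array_equal(state.f, 0.5)
        np.testing.assert_array_equal(state.U, 0.5)
        np.testing.assert_array_equal(state.O, 0.5)
        np.testing.assert_array_equal(state.cbar, 0.0)
        np.testing.assert_array_equal(state.C, 0.0)
        np.testing.assert_array_equal(state.h, 0.0)

    def test_gates_bounded_hidden_state_bounded(self, rng):
        params = _random_params(6, 4, rng)
        state = lstm_forward(params, 3.0 * rng.standard_normal((10, 4)))
        for gate in (state.f, state.U, state.O):
            assert np.all(gate > 0) and np.all(gate < 1)
        assert np.all(np.abs(state.h) < 1)
        assert np.all(np.abs(state.cbar) < 1)

    def test_matches_independent_per_step_oracle(self, rng):
        params = _random_params(5, 3, rng)
        seq = rng.standard_normal((3, 3))
        state = lstm_forward(params, seq)
        for t, (f, U, O, cbar, C, h) in enumerate(_oracle_trajectory(params, seq)):
            np.testing.assert_allclose(state.f[t], f, atol=1e-12)
            np.testing.assert_allclose(state.U[t], U, atol=1e-12)
            np.testing.assert_allclose(state.O[t], O, atol=1e-12)
            np.testing.assert_allclose(state.cbar[t], cbar, atol=1e-12)
            np.testing.assert_allclose(state.C[t], C, atol=1e-12)
            np.testing.assert_allclose(state.h[t], h, atol=1e-12)

    def test_shape_mismatch(self, rng):
        params = _random_params(4, 3, rng)
        with pytest.raises(ValueError):
            lstm_forward(params, rng.standard_normal((5, 2)))


class TestNetworkConfig:
    def test_must_end_with_softmax_classification(self):
        with pytest.raises(ValueError):
            NetworkConfig(layers=(("lstm", {"hidden": 4}), ("softmax", {})))

    def test_exactly_one_sequence_to_label(self):
        with pytest.raises(ValueError):
            NetworkConfig(layers=(
                ("lstm", {"hidden": 4, "mode": "sequence_to_sequence"}),
                ("fully_connected", {"units": 2}),
                ("softmax", {}),
                ("classification", {"n_classes": 2}),
            ))

    def test_standard_architectures_valid(self):
        assert recurrent_config(hidden=80).n_classes == 2
        kinds = [k for k, _ in deep_lstm_config().layers]
        assert kinds.count("lstm") == 2
        bp = bp_config()
        units = [o["units"] for k, o in bp.layers if k == "fully_connected"]
        assert units == [20, 10, 2]


class TestNetworkForward:
    def test_zero_weight_network_is_uniform(self):
        net = init_network(recurrent_config(hidden=4), input_features=3, seed=0)
        for arr in net.parameters().values():
            arr[:] = 0.0
        probs = network_forward(net, np.ones((5, 6, 3)))
        np.testing.assert_allclose(probs, 0.5, atol=1e-15)

    def test_probabilities_sum_to_one(self, rng):
        net = init_network(recurrent_config(hidden=8), input_features=5, seed=1)
        probs = network_forward(net, rng.standard_normal((7, 4, 5)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_dropout_identity_in_evaluation(self, rng):
        net = init_network(recurrent_config(hidden=8, dropout=0.5), input_features=5, seed=1)
        X = rng.standard_normal((4, 3, 5))
        p1 = network_forward(net, X, training_mode=False)
        p2 = network_forward(net, X, training_mode=False)
        np.testing.assert_array_equal(p1, p2)

    def test_dropout_inverted_scaling_preserves_expectation(self, rng):
        # Monte-Carlo: the mean kept-unit scale factor is ~1
        layer = lstm._DropoutLayer(0.2)
        X = np.ones((200, 500))
        out = layer.forward(X, training=True, rng=np.random.default_rng(0))
        assert abs(out.mean() - 1.0) < 0.02

    def test_batch_invariance(self, rng):
        net = init_network(recurrent_config(hidden=6), input_features=4, seed=3)
        X = rng.standard_normal((5, 3, 4))
        batch_labels, batch_probs = predict(net, X)
        one_labels, one_probs = predict(net, X[2:3])
        np.testing.assert_allclose(one_probs[0], batch_probs[2], atol=1e-12)
        assert one_labels[0] == batch_labels[2]


class TestLossAndGradients:
    def test_loss_limits(self, rng):
        net = init_network(recurrent_config(hidden=4), input_features=3, seed=0)
        for arr in net.parameters().values():
            arr[:] = 0.0
        X = rng.standard_normal((6, 2, 3))
        loss, _ = net.loss_and_gradients(X, np.zeros(6, dtype=int))
        assert loss == pytest.approx(np.log(2.0), abs=1e-12)  # uniform prediction

    def test_label_validation(self, rng):
        net = init_network(recurrent_config(hidden=4), input_features=3, seed=0)
        with pytest.raises(ValueError):
            net.loss_and_gradients(rng.standard_normal((2, 2, 3)), np.asarray([0, 5]))

    @pytest.mark.parametrize("config_fn,input_shape", [
        (lambda: recurrent_config(hidden=3, dropout=0.0), (4, 2, 4)),
        (lambda: deep_lstm_config(front_hidden=3, hidden=2, dropout=0.0), (3, 2, 3)),
        (lambda: bp_config(hidden=(4, 3)), (5, 4)),
    ])
    def test_gradients_match_finite_differences(self, rng, config_fn, input_shape):
        # every parameter of every architecture: central differences at 1e-4
        net = init_network(config_fn(), input_features=input_shape[-1], seed=7)
        X = rng.standard_normal(input_shape)
        y = rng.integers(0, 2, size=input_shape[0])
        _, grads = net.loss_and_gradients(X, y)
        params = net.parameters()
        eps = 1e-6
        for name, arr in params.items():
            g = grads[name]
            flat = arr.reshape(-1)
            for idx in range(0, flat.size, max(1, flat.size // 5)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _ = net.loss_and_gradients(X, y)
                flat[idx] = orig - eps
                lm, _ = net.loss_and_gradients(X, y)
                flat[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert abs(g.reshape(-1)[idx] - fd) <= 1e-4 * max(1.0, abs(fd)), name

    def test_gradients_with_frozen_dropout_match_finite_differences(self, rng):
        # a fixed dropout seed makes the loss deterministic, so central
        # differences remain valid through the mask
        net = init_network(recurrent_config(hidden=3, dropout=0.3), input_features=3, seed=2)
        X = rng.standard_normal((4, 2, 3))
        y = np.asarray([0, 1, 0, 1])
        _, grads = net.loss_and_gradients(X, y, dropout_seed=99)
        params = net.parameters()
        name, arr = "0.W_c", params["0.W_c"]
        eps = 1e-6
        for idx in (0, 5):
            flat = arr.reshape(-1)
            orig = flat[idx]
            flat[idx] = orig + eps
            lp, _ = net.loss_and_gradients(X, y, dropout_seed=99)
            flat[idx] = orig - eps
            lm, _ = net.loss_and_gradients(X, y, dropout_seed=99)
            flat[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert abs(grads[name].reshape(-1)[idx] - fd) <= 1e-4 * max(1.0, abs(fd))


class TestTrain:
    def test_iteration_count(self, rng):
        X = rng.standard_normal((50, 2, 3))
        y = rng.integers(0, 2, size=50)
        net = init_network(recurrent_config(hidden=3), input_features=3, seed=0)
        cfg = TrainConfig(epochs=4, batch_size=20, seed=0)
        _, history = train(net, X, y, cfg)
        assert history["n_iterations"] == 4 * int(np.ceil(50 / 20))  # 12

    def test_zero_learning_rate_is_identity(self, rng):
        X = rng.standard_normal((20, 2, 3))
        y = rng.integers(0, 2, size=20)
        net = init_network(recurrent_config(hidden=3), input_features=3, seed=0)
        before = {k: v.copy() for k, v in net.parameters().items()}
        train(net, X, y, TrainConfig(learning_rate=0.0, epochs=2, batch_size=10, seed=0))
        for k, v in net.parameters().items():
            np.testing.assert_array_equal(v, before[k])

    def test_seed_reproducibility(self, rng):
        X = rng.standard_normal((30, 3, 4))
        y = rng.integers(0, 2, size=30)
        results = []
        for _ in range(2):
            net = init_network(recurrent_config(hidden=4), input_features=4, seed=5)
            net, history = train(net, X, y, TrainConfig(epochs=3, batch_size=10, seed=5))
            results.append((net.parameters(), history))
        for k in results[0][0]:
            np.testing.assert_array_equal(results[0][0][k], results[1][0][k])
        assert results[0][1]["loss"] == results[1][1]["loss"]

    def test_separable_toy_reaches_high_accuracy(self):
        # two constant-feature classes: a threshold on the feature mean
        # classifies perfectly, so the network must too
        rng = np.random.default_rng(0)
        n = 60
        X = np.concatenate([
            np.full((n // 2, 4, 2), 1.0), np.full((n // 2, 4, 2), -1.0)
        ]) + 0.05 * rng.standard_normal((n, 4, 2))
        y = np.asarray([0] * (n // 2) + [1] * (n // 2))
        net = init_network(recurrent_config(hidden=5, dropout=0.0), input_features=2, seed=1)
        net, history = train(net, X, y, TrainConfig(
            learning_rate=0.05, epochs=20, batch_size=20, seed=1))
        labels, _ = predict(net, X)
        assert np.mean(labels == y) >= 0.99

    def test_empty_training_set_rejected(self, rng):
        net = init_network(recurrent_config(hidden=3), input_features=3, seed=0)
        with pytest.raises(ValueError):
            train(net, np.empty((0, 2, 3)), np.empty(0, dtype=int), TrainConfig())

    def test_validation_cadence(self, rng):
        X = rng.standard_normal((40, 2, 3))
        y = rng.integers(0, 2, size=40)
        net = init_network(recurrent_config(hidden=3), input_features=3, seed=0)
        cfg = TrainConfig(epochs=5, batch_size=10, seed=0, val_every=10)
        _, history = train(net, X, y, cfg, X[:8], y[:8])
        assert history["val_iteration"][0] == 0
        assert history["val_iteration"][-1] == history["n_iterations"] - 1
        assert all(v % 10 == 0 or v == history["n_iterations"] - 1
                   for v in history["val_iteration"])


class TestPredict:
    def test_argmax_and_confusion_trace(self, rng):
        net = init_network(recurrent_config(hidden=5), input_features=4, seed=2)
        X = rng.standard_normal((20, 3, 4))
        y = rng.integers(0, 2, size=20)
        labels, probs = predict(net, X)
        np.testing.assert_array_equal(labels, probs.argmax(axis=1))
        # accuracy equals the confusion-matrix trace ratio
        cm = np.zeros((2, 2), dtype=int)
        for t, p in zip(y, labels):
            cm[t, p] += 1
        assert np.trace(cm) / cm.sum() == pytest.approx(np.mean(labels == y))

    def test_feature_dim_mismatch(self, rng):
        net = init_network(recurrent_config(hidden=5), input_features=4, seed=2)
        with pytest.raises(ValueError):
            predict(net, rng.standard_normal((3, 3, 5)))
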