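"""Regression models: architectures, gradients, training behavior."""

import numpy as np
import pytest

from bedfall.models import (
    ModelSpec,
    TrainConfig,
    build_lstm_sequences,
    build_model,
    fit_family,
    skeleton_adjacency,
    train,
    train_rf,
)
from bedfall.models._nn import CNNNet, GCNNet, LSTMNet, MLPNet, _conv1d_forward


def _linear_data(rng, n, noise=0.0, dim=26):
    X = rng.normal(size=(n, dim))
    w = rng.normal(size=dim) / np.sqrt(dim)
    y = X @ w + 0.1 + noise * rng.normal(size=n)
    return X, y


class TestArchitectures:
    def test_mlp_parameter_count(self):
        # 26*256+256 + 256*128+128 + 128*1+1
        assert build_model(ModelSpec("mlp"), 0).n_parameters() == 39_937

    def test_gcn_head_input_dimension(self):
        net = build_model(ModelSpec("gcn"), 0)
        assert net.params["W1"].shape == (832, 256)  # 13 nodes x 64 features

    def test_cnn_conv_stack_shapes(self):
        net = build_model(ModelSpec("cnn"), 0)
        x = CNNNet.reshape_input(np.zeros((4, 26)))
        assert x.shape == (4, 2, 13)
        h1 = _conv1d_forward(x, net.params["Wc1"], net.params["bc1"])
        assert h1.shape == (4, 32, 11)
        h2 = _conv1d_forward(np.maximum(h1, 0), net.params["Wc2"], net.params["bc2"])
        assert h2.shape == (4, 64, 9)  # 13 - 2 - 2 positions, pooled to one 64-vector

    def test_gcn_adjacency_is_symmetric_with_self_loops(self):
        A = skeleton_adjacency()
        assert np.array_equal(A, A.T)
        net = build_model(ModelSpec("gcn"), 0)
        assert np.all(np.diag(net.A) > 0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            build_model(ModelSpec("transformer"), 0)


@pytest.mark.parametrize(
    "net_factory,x_shape",
    [
        (lambda: MLPNet(3), (8, 26)),
        (lambda: CNNNet(3), (8, 26)),
        (lambda: GCNNet(3, skeleton_adjacency()), (8, 26)),
        (lambda: LSTMNet(3), (8, 5, 26)),
    ],
    ids=["mlp", "cnn", "gcn", "lstm"],
)
def test_backward_matches_numerical_gradient(net_factory, x_shape):
    """Hand-written backprop agrees with central finite differences."""
    net = net_factory()
    rng = np.random.default_rng(0)
    X = rng.normal(size=x_shape)
    y = rng.normal(size=x_shape[0])

    def loss():
        yhat, _ = net.forward(X, train=False)
        return np.mean((yhat - y) ** 2)

    yhat, cache = net.forward(X, train=False)
    grads = net.backward(cache, 2.0 * (yhat - y) / len(y))
    eps = 1e-6
    for name in net.params:
        flat = net.params[name].reshape(-1)
        for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[idx]
            flat[idx] = orig + eps
            up = loss()
            flat[idx] = orig - eps
            down = loss()
            flat[idx] = orig
            numeric = (up - down) / (2 * eps)
            analytic = grads[name].reshape(-1)[idx]
            assert analytic == pytest.approx(numeric, rel=1e-4, abs=1e-7), name


class TestTraining:
    def test_constant_target_recovery(self):
        # small batches so Adam takes enough steps within the epoch budget
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10_000, 26))
        y = np.full(10_000, 0.5)
        net = build_model(ModelSpec("mlp"), 41)
        model = train(net, (X[:9000], y[:9000]), (X[9000:], y[9000:]), TrainConfig(batch_size=64))
        assert np.allclose(model.predict(rng.normal(size=(200, 26))), 0.5, atol=0.01)

    def test_noiseless_linear_function_is_learned(self):
        rng = np.random.default_rng(2)
        X, y = _linear_data(rng, 10_000)
        net = build_model(ModelSpec("mlp"), 41)
        model = train(net, (X[:9000], y[:9000]), (X[9000:], y[9000:]), TrainConfig(batch_size=64))
        val_mse = np.mean((model.predict(X[9000:]) - y[9000:]) ** 2)
        assert val_mse < 1e-3

    def test_seeded_training_is_bitwise_deterministic(self):
        rng = np.random.default_rng(3)
        X, y = _linear_data(rng, 1000, noise=0.1)
        losses = []
        for _ in range(2):
            net = build_model(ModelSpec("mlp"), 41)
            model = train(net, (X[:900], y[:900]), (X[900:], y[900:]), TrainConfig(max_epochs=5))
            losses.append(model.history[-1]["val_mse"])
        assert losses[0] == losses[1]

    def test_checkpoint_is_validation_minimum(self):
        rng = np.random.default_rng(4)
        X, y = _linear_data(rng, 800, noise=0.3)
        net = build_model(ModelSpec("mlp"), 42)
        model = train(net, (X[:700], y[:700]), (X[700:], y[700:]), TrainConfig(max_epochs=10))
        best = min(h["val_mse"] for h in model.history)
        assert model.history[model.selected_epoch - 1]["val_mse"] == best

    def test_prediction_batching_invariance(self):
        net = build_model(ModelSpec("mlp"), 7)
        X = np.random.default_rng(5).normal(size=(20, 26))
        batched = net.predict(X)
        single = np.concatenate([net.predict(X[i : i + 1]) for i in range(20)])
        assert np.allclose(batched, single, atol=1e-10)


class TestRandomForest:
    def test_overfit_ordering_and_output_range(self):
        rng = np.random.default_rng(6)
        X, y = _linear_data(rng, 600, noise=0.5)
        model = train_rf((X[:500], y[:500]), seed=41)
        train_mse = np.mean((model.predict(X[:500]) - y[:500]) ** 2)
        test_mse = np.mean((model.predict(X[500:]) - y[500:]) ** 2)
        assert train_mse < test_mse
        preds = model.predict(X[500:])
        assert preds.min() >= y[:500].min() and preds.max() <= y[:500].max()

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        X, y = _linear_data(rng, 300, noise=0.2)
        p1 = train_rf((X, y), seed=41).predict(X[:20])
        p2 = train_rf((X, y), seed=41).predict(X[:20])
        assert np.array_equal(p1, p2)


class TestLstm:
    def test_sequence_shape_contract(self):
        frames = np.zeros((10, 5, 26))
        assert build_lstm_sequences(frames).shape == (10, 5, 26)
        with pytest.raises(ValueError):
            build_lstm_sequences(np.zeros((10, 4, 26)))

    def test_static_sequences_are_valid_inputs(self):
        net = build_model(ModelSpec("lstm"), 41)
        u = np.random.default_rng(8).normal(size=(6, 26))
        seq = np.repeat(u[:, None, :], 5, axis=1)
        out = net.predict(seq)
        assert out.shape == (6,)
        assert np.array_equal(out, net.predict(seq))  # deterministic inference

    def test_shape_mismatch_rejected(self):
        model = fit_family(
            "lstm",
            np.zeros((64, 5, 26)),
            np.zeros(64),
            np.zeros((16, 5, 26)),
            np.zeros(16),
            seed=41,
            config=TrainConfig(max_epochs=1),
        )
        with pytest.raises(ValueError):
            model.predict(np.zeros((4, 26)))
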