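"""MLP core: initialization, forward pass, Jacobian, LM training, search."""

import numpy as np
import pandas as pd
import pytest

from barnflux.mlp import (
    EarlyStopping,
    MLPRegression,
    TrainConfig,
    architecture_search,
    forward,
    init_weights,
    load_model,
    save_model,
    train_lm,
)
from barnflux.mlp import _jacobian


class TestInit:
    def test_deterministic_per_seed(self):
        a = init_weights((4, 6, 1), seed=3)
        b = init_weights((4, 6, 1), seed=3)
        np.testing.assert_array_equal(a.to_vector(), b.to_vector())

    def test_different_seeds_differ(self):
        a = init_weights((4, 6, 1), seed=3)
        b = init_weights((4, 6, 1), seed=4)
        assert not np.array_equal(a.to_vector(), b.to_vector())

    def test_parameter_count_20_10(self):
        net = init_weights((22, 20, 10, 1), seed=0)
        assert net.n_params == 22 * 20 + 20 + 20 * 10 + 10 + 10 * 1 + 1  # 681

    def test_zero_size_layer_rejected(self):
        with pytest.raises(ValueError):
            init_weights((4, 0, 1), seed=0)

    def test_vector_round_trip(self):
        net = init_weights((3, 5, 2, 1), seed=1)
        theta = net.to_vector()
        np.testing.assert_array_equal(net.from_vector(theta).to_vector(), theta)


class TestForward:
    def test_zero_network_outputs_zero(self):
        net = init_weights((3, 4, 1), seed=0)
        net = net.from_vector(np.zeros(net.n_params))
        out = forward(net, np.random.default_rng(0).normal(size=(10, 3)))
        np.testing.assert_array_equal(out, np.zeros((10, 1)))

    def test_single_hidden_unit_by_hand(self):
        net = init_weights((1, 1, 1), seed=0)
        # y = v*tanh(w*x + b) + c
        w, b, v, c = 0.7, -0.2, 1.3, 0.4
        net.weights[0][:] = w
        net.biases[0][:] = b
        net.weights[1][:] = v
        net.biases[1][:] = c
        x = np.array([[0.5]])
        expected = np.tanh(w * 0.5 + b) * v + c
        assert forward(net, x)[0, 0] == pytest.approx(expected, rel=1e-14)

    def test_batch_equals_rowwise(self):
        net = init_weights((4, 7, 3, 1), seed=2)
        X = np.random.default_rng(5).normal(size=(6, 4))
        batch = forward(net, X)
        rows = np.vstack([forward(net, X[i:i + 1]) for i in range(6)])
        np.testing.assert_allclose(batch, rows, rtol=1e-14)

    def test_width_mismatch_rejected(self):
        net = init_weights((4, 3, 1), seed=0)
        with pytest.raises(ValueError, match="width"):
            forward(net, np.zeros((2, 5)))


class TestJacobian:
    @pytest.mark.parametrize("sizes", [(2, 3, 1), (3, 4, 2, 1), (1, 5, 1)])
    def test_matches_central_differences(self, sizes, rng):
        net = init_weights(sizes, seed=8)
        X = rng.normal(size=(7, sizes[0]))
        _, J = _jacobian(net, X)
        theta = net.to_vector()
        h = 1e-6
        J_fd = np.empty_like(J)
        for k in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += h
            tm[k] -= h
            J_fd[:, k] = (
                forward(net.from_vector(tp), X)[:, 0]
                - forward(net.from_vector(tm), X)[:, 0]
            ) / (2 * h)
        np.testing.assert_allclose(J, J_fd, rtol=1e-6, atol=1e-8)


class TestEarlyStopping:
    def test_stops_after_exactly_patience_worsenings(self):
        es = EarlyStopping(patience=6)
        assert not es.update(1.0, 1)
        stops = [es.update(1.0 + 0.1 * k, 1 + k) for k in range(1, 7)]
        assert stops == [False] * 5 + [True]
        assert es.best_epoch == 1

    def test_improvement_resets_counter(self):
        es = EarlyStopping(patience=2)
        es.update(1.0, 1)
        assert not es.update(1.5, 2)
        assert not es.update(0.9, 3)   # new best resets
        assert not es.update(1.1, 4)
        assert es.update(1.2, 5)
        assert es.best_epoch == 3


def _realizable_linear():
    rng = np.random.default_rng(0)
    x = rng.uniform(-1, 1, size=(60, 1))
    y = 2 * x[:, 0] + 1
    xv = rng.uniform(-1, 1, size=(20, 1))
    yv = 2 * xv[:, 0] + 1
    return x, y, xv, yv


class TestTrainLM:
    def test_fits_noiseless_linear_target(self):
        x, y, xv, yv = _realizable_linear()
        net = init_weights((1, 5, 1), seed=0)
        res = train_lm(net, x, y, xv, yv, TrainConfig(max_epochs=200))
        assert res.train_trace[res.best_epoch - 1] < 1e-6
        assert res.epochs_run <= 200

    def test_xor_pattern_learned(self):
        x = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([0.0, 1.0, 1.0, 0.0])
        net = init_weights((2, 5, 2, 1), seed=1)
        res = train_lm(net, x, y, x, y, TrainConfig(max_epochs=300))
        pred = forward(res.network, x)[:, 0]
        assert ((pred > 0.5) == (y > 0.5)).all()

    def test_train_trace_non_increasing(self):
        x, y, xv, yv = _realizable_linear()
        net = init_weights((1, 4, 1), seed=2)
        res = train_lm(net, x, y + 0.1 * np.sin(17 * x[:, 0]), xv, yv,
                       TrainConfig(max_epochs=50))
        assert (np.diff(res.train_trace) <= 1e-15).all()

    def test_deterministic_given_seed_and_data(self):
        x, y, xv, yv = _realizable_linear()
        runs = []
        for _ in range(2):
            net = init_weights((1, 4, 1), seed=5)
            runs.append(train_lm(net, x, y, xv, yv, TrainConfig(max_epochs=30)))
        np.testing.assert_array_equal(runs[0].network.to_vector(),
                                      runs[1].network.to_vector())
        np.testing.assert_array_equal(runs[0].val_trace, runs[1].val_trace)

    def test_best_validation_weights_restored(self, rng):
        x = rng.uniform(-1, 1, size=(40, 1))
        y = np.sin(3 * x[:, 0]) + rng.normal(0, 0.3, 40)
        xv = rng.uniform(-1, 1, size=(15, 1))
        yv = np.sin(3 * xv[:, 0]) + rng.normal(0, 0.3, 15)
        net = init_weights((1, 12, 1), seed=0)
        res = train_lm(net, x, y, xv, yv, TrainConfig(max_epochs=200))
        val_mse = float(np.mean((forward(res.network, xv)[:, 0] - yv) ** 2))
        assert val_mse == pytest.approx(res.val_trace.min(), rel=1e-9)

    def test_capacity_20_10_fits_smooth_function(self, rng):
        x = np.sort(rng.uniform(-1, 1, size=(50, 1)), axis=0)
        y = np.sin(2.5 * x[:, 0]) * np.exp(-x[:, 0] ** 2)
        net = init_weights((1, 20, 10, 1), seed=3)
        res = train_lm(net, x, y, x, y, TrainConfig(max_epochs=400))
        assert res.train_trace.min() < 1e-4

    def test_empty_partition_rejected(self):
        net = init_weights((1, 3, 1), seed=0)
        with pytest.raises(ValueError):
            train_lm(net, np.zeros((0, 1)), np.zeros(0), np.zeros((2, 1)), np.zeros(2))


class TestArchitectureSearch:
    def test_easy_target_stops_at_simplest(self, rng):
        x = rng.uniform(-1, 1, size=(120, 1))
        y = np.tanh(2 * x[:, 0])
        sel, log = architecture_search(x[:80], y[:80], x[80:], y[80:],
                                       config=TrainConfig(max_epochs=80))
        assert sel == (5,)
        assert len(log) == 1 and log[0]["satisfied"]

    def test_pure_noise_returns_best_so_far_unsatisfied(self, rng):
        x = rng.uniform(-1, 1, size=(80, 2))
        y = rng.normal(size=80)
        sel, log = architecture_search(x[:60], y[:60], x[60:], y[60:],
                                       config=TrainConfig(max_epochs=10))
        assert len(log) == 5          # full schedule evaluated
        assert not any(e["satisfied"] for e in log)
        assert sel in [e["hidden"] for e in log]


class TestModelInterface:
    def test_fit_predict_and_summary(self, rng):
        x = pd.DataFrame({"x": rng.uniform(-1, 1, 120)})
        y = 3 * x["x"] ** 2 + 1
        res = MLPRegression(y, x, hidden_layers=(6,)).fit(seed=0)
        m = res.metrics("test")
        assert m.R2 > 0.95
        text = res.summary()
        assert "structure: 6" in text and "test" in text

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MLPRegression([1.0, 2.0], pd.DataFrame({"x": [1.0]}))

    def test_missing_columns_named(self, tiny_study):
        with pytest.raises(KeyError, match="nope"):
            MLPRegression.from_dataframe(tiny_study.records, "C_NH3_in", ["nope"])

    def test_save_load_round_trip(self, tmp_path, rng):
        x = pd.DataFrame({"x": rng.uniform(-1, 1, 60)})
        y = 2 * x["x"]
        res = MLPRegression(y, x, hidden_layers=(4,)).fit(seed=1)
        path = tmp_path / "model.json"
        save_model(path, res)
        net, x_norm, y_norm = load_model(path)
        np.testing.assert_array_equal(net.to_vector(), res.network.to_vector())
        pd.testing.assert_series_equal(x_norm.data_min_, res.x_norm.data_min_)
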