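"""Back-propagation network: forward pass, gradients, training, scaling."""

import numpy as np
import pytest

from qsabr.bpann import (
    BPANNModel,
    Scaler,
    TrainingConfig,
    fit_bpann,
    forward,
    init_network,
    loo_rms,
    scale_fit,
    train,
)


def numerical_gradient(w_hidden, w_out, x, t, eps=1e-6):
    """Central finite differences of E = 1/2 (t - out)^2 w.r.t. all weights."""

    def loss(wh, wo):
        xa = np.append(x, 1.0)
        h = 1.0 / (1.0 + np.exp(-(wh @ xa)))
        o = 1.0 / (1.0 + np.exp(-(wo @ np.append(h, 1.0))))
        return 0.5 * np.sum((t - o) ** 2)

    grads = []
    for which, W in (("h", w_hidden), ("o", w_out)):
        g = np.zeros_like(W)
        for idx in np.ndindex(W.shape):
            Wp, Wm = W.copy(), W.copy()
            Wp[idx] += eps
            Wm[idx] -= eps
            if which == "h":
                g[idx] = (loss(Wp, w_out) - loss(Wm, w_out)) / (2 * eps)
            else:
                g[idx] = (loss(w_hidden, Wp) - loss(w_hidden, Wm)) / (2 * eps)
        grads.append(g)
    return grads


class TestInitAndForward:
    def test_seeded_init_is_reproducible(self):
        cfg = TrainingConfig(seed=42)
        a, b = init_network(7, cfg), init_network(7, cfg)
        assert np.array_equal(a.w_hidden, b.w_hidden)
        assert np.array_equal(a.w_out, b.w_out)
        c = init_network(7, TrainingConfig(seed=43))
        assert not np.array_equal(a.w_hidden, c.w_hidden)

    def test_shapes_include_bias_column(self):
        net = init_network(7, TrainingConfig(n_hidden=5, seed=0))
        assert net.w_hidden.shape == (5, 8)
        assert net.w_out.shape == (1, 6)
        assert np.all(net.dw_hidden_prev == 0) and np.all(net.dw_out_prev == 0)
        assert np.all(np.abs(net.w_hidden) <= 0.5)

    def test_zero_input_rejected(self):
        with pytest.raises(ValueError):
            init_network(0, TrainingConfig(seed=0))

    def test_zero_weights_give_half_activations(self):
        net = init_network(3, TrainingConfig(n_hidden=2, seed=0))
        net.w_hidden[:] = 0.0
        net.w_out[:] = 0.0
        out, (hidden, _) = forward(net, np.array([0.2, 0.8, 0.5]))
        assert np.allclose(hidden, 0.5)
        assert np.allclose(out, 0.5)

    def test_hand_evaluated_2_2_1_chain(self):
        net = init_network(2, TrainingConfig(n_hidden=2, seed=0))
        net.w_hidden = np.array([[0.3, -0.2, 0.1], [0.5, 0.4, -0.6]])
        net.w_out = np.array([[0.7, -0.8, 0.25]])
        x = np.array([0.6, 0.9])

        def sig(v):
            return 1.0 / (1.0 + np.exp(-v))

        h1 = sig(0.3 * 0.6 + (-0.2) * 0.9 + 0.1 * 1.0)
        h2 = sig(0.5 * 0.6 + 0.4 * 0.9 + (-0.6) * 1.0)
        expected = sig(0.7 * h1 + (-0.8) * h2 + 0.25 * 1.0)
        out, _ = forward(net, x)
        assert out[0] == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch_rejected(self):
        net = init_network(3, TrainingConfig(seed=0))
        with pytest.raises(ValueError):
            forward(net, np.zeros(4))


class TestTraining:
    def test_zero_learning_rate_is_a_no_op(self):
        cfg = TrainingConfig(learning_rate=0.0, momentum=0.2, epochs=5, seed=3)
        net = init_network(2, cfg)
        w0h, w0o = net.w_hidden.copy(), net.w_out.copy()
        X = np.random.default_rng(0).uniform(0, 1, (6, 2))
        y = np.random.default_rng(1).uniform(0.1, 0.9, (6, 1))
        net, _ = train(net, X, y, cfg)
        assert np.array_equal(net.w_hidden, w0h)
        assert np.array_equal(net.w_out, w0o)

    def test_single_update_matches_finite_difference_gradient(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n_in = int(rng.integers(1, 5))
            cfg = TrainingConfig(
                n_hidden=int(rng.integers(1, 4)),
                learning_rate=0.37,
                momentum=0.0,
                epochs=1,
                seed=int(rng.integers(1_000_000)),
            )
            x = rng.uniform(0, 1, n_in)
            t = float(rng.uniform(0.1, 0.9))
            net = init_network(n_in, cfg)
            w0h, w0o = net.w_hidden.copy(), net.w_out.copy()
            net, _ = train(net, x[None, :], np.array([[t]]), cfg)
            gh, go = numerical_gradient(w0h, w0o, x, t)
            for dW, g in ((net.w_hidden - w0h, gh), (net.w_out - w0o, go)):
                expected = -cfg.learning_rate * g
                rel = np.abs(dW - expected) / np.maximum(np.abs(expected), 1e-10)
                assert rel.max() < 1e-4

    def test_error_decreases_on_noiseless_linear_problem(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, (20, 1))
        y = 2.0 * X.ravel() + 1.0
        model = fit_bpann(X, y, TrainingConfig(epochs=2000, seed=2))
        assert model.rms_trace[-1] < model.rms_trace[0]

    def test_end_to_end_determinism(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, (15, 3))
        y = X @ [1.0, -0.5, 2.0]
        cfg = TrainingConfig(epochs=50, seed=9)
        m1 = fit_bpann(X, y, cfg)
        m2 = fit_bpann(X, y, cfg)
        assert np.array_equal(m1.net.w_hidden, m2.net.w_hidden)
        assert np.array_equal(m1.net.w_out, m2.net.w_out)

    def test_model_json_roundtrip_preserves_predictions(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, (12, 2))
        y = X @ [1.0, 2.0]
        model = fit_bpann(X, y, TrainingConfig(epochs=30, seed=1))
        clone = BPANNModel.from_dict(model.to_dict())
        assert np.allclose(model.predict(X), clone.predict(X))


class TestScaling:
    def test_roundtrip_identity(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25) * 10
        scaler = scale_fit(X, y)
        ys = scaler.scale_y(y)
        assert np.allclose(scaler.unscale_y(ys), y, atol=1e-12)
        assert ys.min() == pytest.approx(0.1) and ys.max() == pytest.approx(0.9)
        Xs, flags = scaler.scale_x(X)
        assert Xs.min() >= 0.0 and Xs.max() <= 1.0
        assert not flags.any()

    def test_target_affine_map(self):
        scaler = Scaler(np.zeros(1), np.ones(1), y_min=-5.0, y_max=15.0)
        assert scaler.scale_y(np.array([5.0]))[0] == pytest.approx(0.5)

    def test_out_of_range_query_is_flagged(self, rng):
        X = rng.uniform(0, 1, (10, 2))
        scaler = scale_fit(X, rng.normal(size=10))
        Xs, flags = scaler.scale_x(X.min(axis=0) - 1.0)
        assert flags.all() and (Xs < 0).any()

    def test_constant_column_rejected(self, rng):
        X = np.column_stack([np.full(10, 2.0), rng.normal(size=10)])
        with pytest.raises(ValueError, match="0"):
            scale_fit(X, rng.normal(size=10))


class TestLOORMS:
    def test_constant_target_is_learned(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(-1, 1, (5, 1))
        y = np.full(5, 20.0)
        cfg = TrainingConfig(n_hidden=1, epochs=300, seed=8)
        rms = loo_rms(X, y, cfg)
        assert rms < 0.05  # scaler assigns a unit-wide band to a flat target

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(-1, 1, (6, 1))
        y = X.ravel() * 3.0
        cfg = TrainingConfig(n_hidden=2, epochs=100, seed=5)
        assert loo_rms(X, y, cfg) == loo_rms(X, y, cfg)

    def test_too_few_objects_rejected(self):
        with pytest.raises(ValueError):
            loo_rms(np.zeros((2, 1)), np.zeros(2), TrainingConfig(seed=0))
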