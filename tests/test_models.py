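"""Neural primitives and classifier families: oracles, contracts, training sanity."""

import numpy as np
import pytest

from ppgfatigue.models import (
    CANONICAL_WINDOW,
    FatigueClassifier,
    ModelConfig,
    _build_network,
    build_extractor,
    extractor_output_shape,
    load_checkpoint,
    predict,
    save_checkpoint,
    train_model,
)
from ppgfatigue.nnops import (
    BiLSTM,
    SoftmaxCrossEntropy,
    bilstm_forward,
    conv1d_forward,
    sgd_step,
    softmax,
)


def naive_conv1d(x, W, b, stride=1):
    """Nested-loop valid cross-correlation oracle for (C_in, T) inputs."""
    c_out, c_in, k = W.shape
    t_out = (x.shape[1] - k) // stride + 1
    out = np.zeros((c_out, t_out))
    for j in range(c_out):
        for t in range(t_out):
            acc = b[j]
            for i in range(c_in):
                for kk in range(k):
                    acc += x[i, t * stride + kk] * W[j, i, kk]
            out[j, t] = acc
    return out


class TestConv1d:
    def test_hand_convolution(self):
        out = conv1d_forward(np.array([[1.0, 2, 3, 4]]), np.array([[[1.0, 0, -1]]]), np.zeros(1))
        assert np.allclose(out, [[-2.0, -2.0]])

    def test_zero_kernels_reduce_to_activated_bias(self):
        x = np.random.default_rng(0).standard_normal((3, 20))
        W = np.zeros((2, 3, 5))
        b = np.array([0.3, -1.2])
        out = conv1d_forward(x, W, b, activation="sigmoid")
        expected = 1 / (1 + np.exp(-b))
        assert np.allclose(out, expected[:, None])

    @pytest.mark.parametrize("stride", [1, 2])
    def test_matches_nested_loop_oracle(self, stride):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((8, 32))
        W = rng.standard_normal((4, 8, 5))
        b = rng.standard_normal(4)
        fast = conv1d_forward(x, W, b, stride=stride)
        assert np.max(np.abs(fast - naive_conv1d(x, W, b, stride))) < 1e-10

    def test_channel_mismatch_names_dimensions(self):
        with pytest.raises(ValueError, match="channels"):
            conv1d_forward(np.zeros((2, 10)), np.zeros((1, 3, 3)), np.zeros(1))


class TestSoftmax:
    def test_symmetric_pair(self):
        assert np.allclose(softmax(np.array([0.0, 0.0])), [0.5, 0.5])

    def test_log_ratio_example(self):
        assert np.allclose(softmax(np.array([np.log(1), np.log(3)])), [0.25, 0.75])

    def test_large_beta_concentrates_mass(self):
        assert softmax(np.array([1.0, 2.0]), beta=100.0)[1] > 0.999

    def test_normalisation_and_shift_invariance(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((5, 4)) * 100
        p = softmax(z, beta=0.7)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.allclose(softmax(z + 17.3, beta=0.7), p, atol=1e-12)

    def test_extreme_logits_do_not_overflow(self):
        p = softmax(np.array([1e4, -1e4]))
        assert np.isfinite(p).all() and p.sum() == pytest.approx(1.0)


class TestSgdStep:
    def test_plain_gradient_step(self):
        new, delta = sgd_step(np.array(1.0), np.array(2.0), np.array(0.0),
                              learning_rate=0.1, batch_size=1)
        assert delta == pytest.approx(-0.2)
        assert new == pytest.approx(0.8)

    def test_pure_momentum_carries_previous_delta(self):
        _, delta = sgd_step(np.array(1.0), np.array(0.0), np.array(1.0),
                            learning_rate=0.1, momentum=0.9)
        assert delta == pytest.approx(0.9)

    def test_decay_only_shrinks_weights_by_the_decoupled_factor(self):
        w = np.array(2.0)
        new, _ = sgd_step(w, np.array(0.0), np.array(0.0),
                          learning_rate=0.1, weight_decay=0.5, r=10)
        assert new == pytest.approx(2.0 * (1 - 0.1 * 0.5 / 10))

    def test_biases_carry_no_decay(self):
        new, _ = sgd_step(np.array(2.0), np.array(0.0), np.array(0.0),
                          learning_rate=0.1, weight_decay=0.5, r=10, is_bias=True)
        assert new == pytest.approx(2.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            sgd_step(np.zeros(3), np.zeros(2), np.zeros(3), learning_rate=0.1)

    def test_descends_a_quadratic_monotonically(self):
        # loss 0.5 * w^2: lr below curvature bound must reduce loss each step
        w = np.array(5.0)
        delta = np.array(0.0)
        losses = []
        for _ in range(20):
            losses.append(0.5 * float(w) ** 2)
            w, delta = sgd_step(w, w.copy(), delta, learning_rate=0.5)
        assert all(b < a for a, b in zip(losses, losses[1:]))


class TestBiLstm:
    def test_sequence_contract(self):
        out = bilstm_forward(np.random.default_rng(0).standard_normal((7, 3)), hidden=5)
        assert out.shape == (7, 10)

    def test_time_reversal_symmetry(self):
        # with both directions sharing weights, the backward half of the
        # output is exactly the forward pass on the reversed input, re-reversed
        rng = np.random.default_rng(1)
        net = BiLSTM(3, 4, rng)
        for src, dst in zip(net.fwd.parameters(), net.bwd.parameters()):
            dst.value[...] = src.value
        x = rng.standard_normal((2, 6, 3))
        out = net.forward(x)
        assert np.array_equal(out[:, :, 4:], net.fwd.forward(x[:, ::-1])[:, ::-1])

    def test_matches_scalar_recurrence_oracle(self):
        rng = np.random.default_rng(2)
        net = BiLSTM(2, 3, rng)
        x = rng.standard_normal((1, 5, 2))

        def scalar_lstm(cell, seq):
            h = np.zeros(cell.hidden)
            c = np.zeros(cell.hidden)
            hh = cell.hidden
            outs = []
            for t in range(seq.shape[0]):
                z = seq[t] @ cell.Wx.value + h @ cell.Wh.value + cell.b.value
                i = 1 / (1 + np.exp(-z[:hh]))
                f = 1 / (1 + np.exp(-z[hh:2 * hh]))
                g = np.tanh(z[2 * hh:3 * hh])
                o = 1 / (1 + np.exp(-z[3 * hh:]))
                c = f * c + i * g
                h = o * np.tanh(c)
                outs.append(h.copy())
            return np.array(outs)

        expected = np.concatenate(
            [scalar_lstm(net.fwd, x[0]), scalar_lstm(net.bwd, x[0, ::-1])[::-1]], axis=1
        )
        assert np.max(np.abs(net.forward(x)[0] - expected)) < 1e-8

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            bilstm_forward(np.zeros((0, 3)), hidden=2)


class TestExtractors:
    def test_residual_reference_shape_contract(self):
        cfg = ModelConfig.reference_resnet()
        assert extractor_output_shape("resnet", cfg, CANONICAL_WINDOW) == (15, 132)

    def test_separable_reference_shape_contract(self):
        cfg = ModelConfig.reference_xception()
        assert extractor_output_shape("xception", cfg, CANONICAL_WINDOW) == (64, 132)

    def test_doubling_window_doubles_steps_not_channels(self):
        cfg = ModelConfig.reference_resnet()
        assert extractor_output_shape("resnet", cfg, 2 * CANONICAL_WINDOW) == (15, 264)

    @pytest.mark.parametrize(
        "family,layers", [("resnet", 36), ("resnet", 21), ("xception", 37), ("xception", 31)]
    )
    def test_weighted_layer_count_matches_config(self, family, layers):
        cfg = ModelConfig(family=family if family != "xception" else "xception_bilstm",
                          layers=layers, kernels=4, kernel_size=5)
        net = build_extractor(family, cfg)
        assert net.n_weighted_layers == layers

    def test_too_shallow_config_rejected(self):
        with pytest.raises(ValueError, match="layers"):
            build_extractor("resnet", ModelConfig(layers=3))


class TestGradients:
    def test_backprop_matches_finite_differences_on_two_window_batch(self):
        cfg = ModelConfig(family="resnet_bilstm", layers=6, kernels=3, kernel_size=5,
                          bilstm_hidden=4, total_stride=8, seed=3)
        net = _build_network(cfg)
        rng = np.random.default_rng(0)
        # jitter all parameters so no pre-activation sits exactly on a ReLU kink
        for p in net.parameters():
            p.value += rng.normal(0, 0.03, p.value.shape)
        head = SoftmaxCrossEntropy(beta=1.3)
        X = rng.standard_normal((2, 1, 64))
        y = np.array([0, 1])
        net.zero_grad()
        head.forward(net.forward(X), y)
        net.backward(head.backward())
        eps = 1e-5
        for p in net.parameters():
            direction = rng.standard_normal(p.value.shape)
            direction /= np.linalg.norm(direction)
            p.value += eps * direction
            lp = head.forward(net.forward(X), y)[0]
            p.value -= 2 * eps * direction
            lm = head.forward(net.forward(X), y)[0]
            p.value += eps * direction
            fd = (lp - lm) / (2 * eps)
            bp = float((p.grad * direction).sum())
            assert abs(fd - bp) <= 1e-4 * max(abs(fd), abs(bp), 1e-3), p.name


class TestTraining:
    def _toy(self, rng):
        X = np.concatenate([np.zeros((20, 1, 128)), np.ones((20, 1, 128))])
        X += rng.standard_normal(X.shape) * 0.05
        y = np.array([0] * 20 + [1] * 20)
        return X, y

    def _cfg(self, **kw):
        base = dict(layers=6, kernels=4, kernel_size=5, bilstm_hidden=8,
                    total_stride=8, epochs=30, batch_size=16, seed=0)
        base.update(kw)
        return ModelConfig(**base)

    def test_separable_two_level_windows_reach_full_accuracy(self, rng):
        X, y = self._toy(rng)
        result = FatigueClassifier(self._cfg(epochs=50)).fit(X, y)
        assert result.train_accuracy == 1.0
        assert result.history.loss.iloc[-1] < result.history.loss.iloc[0]

    def test_history_spans_every_epoch(self, rng):
        X, y = self._toy(rng)
        result = FatigueClassifier(self._cfg(epochs=7)).fit(X, y)
        assert len(result.history) == 7
        assert {"epoch", "loss", "rmse"} <= set(result.history.columns)

    def test_same_seed_reproduces_weights_exactly(self, rng):
        X, y = self._toy(rng)
        runs = []
        for _ in range(2):
            res = FatigueClassifier(self._cfg(epochs=5)).fit(X, y)
            runs.append([p.value.copy() for p in res.model.network.parameters()])
        assert all(np.array_equal(a, b) for a, b in zip(*runs))

    def test_single_class_training_set_rejected(self, rng):
        X, _ = self._toy(rng)
        with pytest.raises(ValueError, match="both classes"):
            FatigueClassifier(self._cfg()).fit(X, np.zeros(len(X), dtype=int))

    def test_probabilities_sum_to_one_and_untrained_model_is_uncommitted(self, rng):
        cfg = self._cfg()
        clf = FatigueClassifier(cfg)
        clf.network = _build_network(cfg)
        probs = clf.predict_proba(rng.standard_normal((4, 1, 128)))
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.all(np.abs(probs - 0.5) < 0.2)

    def test_predictions_match_labels_after_training(self, rng):
        X, y = self._toy(rng)
        result = FatigueClassifier(self._cfg(epochs=50)).fit(X, y)
        p = predict(result, X[0])
        assert p.shape == (2,) and np.argmax(p) == 0

    def test_train_model_accepts_windows(self, rng):
        from ppgfatigue.dataset import Window

        X, y = self._toy(rng)
        windows = [
            Window("S01" if yi == 0 else "S02", i, xi[0], "ppg",
                   "non_fatigue" if yi == 0 else "fatigue")
            for i, (xi, yi) in enumerate(zip(X, y))
        ]
        result = train_model(windows, self._cfg(epochs=3))
        assert result.n_train == 40

    def test_checkpoint_roundtrip_preserves_predictions(self, rng, tmp_path):
        X, y = self._toy(rng)
        result = FatigueClassifier(self._cfg(epochs=5)).fit(X, y)
        path = tmp_path / "model.npz"
        save_checkpoint(result, path)
        restored = load_checkpoint(path)
        assert np.allclose(restored.predict_proba(X), result.predict_proba(X))

    def test_mismatched_channel_count_rejected(self, rng):
        X, y = self._toy(rng)
        result = FatigueClassifier(self._cfg(epochs=2)).fit(X, y)
        with pytest.raises(ValueError, match="channels"):
            result.predict_proba(rng.standard_normal((2, 3, 128)))
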