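import numpy as np
import pytest

from auscon.network import (Adam, BatchNorm1d, Checkpoint, Conv2d, Encoder,
                            EncoderConfig, LeakyReLU, Linear, LinearHead,
                            ProjectionHead, SSLEvaluator, Sequential,
                            bce_with_logits, load_state_dict, n_parameters,
                            sigmoid, state_dict)

from .conftest import make_spectrogram


TINY = EncoderConfig(architecture="tiny_cnn", embedding_dim=8, projection_dim=6)


def manual_conv2d(x, W, b, slope=None):
    """Loop-based same-padding convolution oracle (single image)."""
    c_out, c_in, k, _ = W.shape
    p = (k - 1) // 2
    H, Wd = x.shape[1], x.shape[2]
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    out = np.zeros((c_out, H, Wd))
    for f in range(c_out):
        for i in range(H):
            for j in range(Wd):
                out[f, i, j] = (xp[:, i:i + k, j:j + k] * W[f]).sum() + b[f]
    if slope is not None:
        out = np.where(out > 0, out, slope * out)
    return out


class TestEncoder:
    def test_deterministic_for_fixed_weights(self):
        enc = Encoder(TINY, seed=0)
        spec = make_spectrogram(8, 8, seed=1)
        a = enc.encode(spec)
        b = enc.encode(spec)
        assert np.array_equal(a, b)

    def test_different_inputs_differ(self):
        enc = Encoder(TINY, seed=0)
        a = enc.encode(make_spectrogram(8, 8, seed=1))
        b = enc.encode(make_spectrogram(8, 8, seed=2))
        assert not np.allclose(a, b)

    def test_output_length_is_embedding_dim(self):
        enc = Encoder(EncoderConfig(embedding_dim=13), seed=0)
        assert enc.encode(make_spectrogram(16, 20)).shape == (1, 13)

    def test_geometry_mismatch_names_shapes(self):
        enc = Encoder(EncoderConfig(input_shape=(16, 20)), seed=0)
        with pytest.raises(ValueError, match=r"\(8, 8\).*\(16, 20\)"):
            enc.encode(make_spectrogram(8, 8))

    def test_tiny_cnn_matches_hand_unrolled_forward(self):
        enc = Encoder(TINY, seed=3)
        spec = make_spectrogram(8, 8, seed=4)
        got = enc.encode(spec)[0]
        # unroll: conv -> leaky relu -> 2x2 avg pool -> conv -> leaky relu
        # -> global avg pool -> linear
        x = spec.values[None]
        layers = enc.net.layers
        h = manual_conv2d(x, layers[0].params["W"], layers[0].params["b"],
                          slope=0.1)
        pooled = h.reshape(h.shape[0], 4, 2, 4, 2).mean(axis=(2, 4))
        h2 = manual_conv2d(pooled, layers[3].params["W"], layers[3].params["b"],
                           slope=0.1)
        gap = h2.mean(axis=(1, 2))
        want = layers[6].params["W"] @ gap + layers[6].params["b"]
        assert np.allclose(got, want, atol=1e-10)

    def test_input_standardization_applied(self):
        cfg = EncoderConfig(architecture="tiny_cnn", embedding_dim=4,
                            input_offset=-40.0, input_scale=8.0)
        enc = Encoder(cfg, seed=0)
        spec = make_spectrogram(8, 8, seed=5)
        shifted = make_spectrogram(8, 8, seed=5)
        shifted.values[:] = (shifted.values + 40.0) / 8.0 * 8.0 - 40.0
        assert np.allclose(enc.encode(spec), enc.encode(shifted))


class TestProjectionHead:
    def test_zero_input_returns_bias(self):
        head = ProjectionHead(TINY, seed=0)
        z = head.project(np.zeros((1, 8)))
        assert np.allclose(z[0], head.net.layers[0].params["b"])

    def test_affine_identity(self):
        head = ProjectionHead(TINY, seed=1)
        h = np.random.default_rng(0).normal(size=(1, 8))
        a = 2.5
        bias = head.net.layers[0].params["b"]
        lhs = head.project(a * h) - a * head.project(h)
        assert np.allclose(lhs[0], (1 - a) * bias)

    def test_matches_matrix_vector_oracle(self):
        head = ProjectionHead(TINY, seed=2)
        h = np.random.default_rng(1).normal(size=8)
        W = head.net.layers[0].params["W"]
        b = head.net.layers[0].params["b"]
        assert np.allclose(head.project(h[None])[0], W @ h + b)


class TestLinearHead:
    def test_zero_weights_give_half(self):
        head = LinearHead(8, seed=0)
        head.net.layers[0].params["W"][:] = 0.0
        head.net.layers[0].params["b"][:] = 0.0
        assert head.predict_proba(np.ones((3, 8))) == pytest.approx([0.5] * 3)

    def test_monotone_in_logit(self):
        head = LinearHead(2, seed=1)
        head.net.layers[0].params["W"][:] = [[1.0, 0.0]]
        xs = np.array([[-2.0, 0.0], [0.0, 0.0], [3.0, 0.0]])
        p = head.predict_proba(xs)
        assert p[0] < p[1] < p[2]

    def test_matches_dot_sigmoid_oracle(self):
        head = LinearHead(5, seed=2)
        h = np.random.default_rng(3).normal(size=5)
        W = head.net.layers[0].params["W"][0]
        b = head.net.layers[0].params["b"][0]
        want = 1.0 / (1.0 + np.exp(-(W @ h + b)))
        assert head.predict_proba(h[None])[0] == pytest.approx(want)


class TestSSLEvaluator:
    def test_outputs_in_unit_interval(self):
        ev = SSLEvaluator(8, seed=0)
        h = np.random.default_rng(0).normal(size=(6, 8))
        ev.logits(h, train=True)  # populate running stats
        p = ev.predict_proba(h)
        assert np.all((p > 0) & (p < 1))

    def test_eval_mode_deterministic(self):
        ev = SSLEvaluator(4, seed=1)
        h = np.random.default_rng(1).normal(size=(5, 4))
        ev.logits(h, train=True)
        assert np.array_equal(ev.predict_proba(h), ev.predict_proba(h))

    def test_train_batch_of_one_errors(self):
        ev = SSLEvaluator(4, seed=2)
        with pytest.raises(ValueError, match="batch"):
            ev.logits(np.ones((1, 4)), train=True)

    def test_two_dim_hand_arithmetic(self):
        ev = SSLEvaluator(2, seed=3)
        l1, bn, _, l2 = ev.net.layers
        l1.params["W"][:] = np.eye(2)
        l1.params["b"][:] = 0.0
        bn.running_mean[:] = 0.0
        bn.running_var[:] = 1.0
        l2.params["W"][:] = [[1.0, 1.0]]
        l2.params["b"][:] = 0.5
        h = np.array([[2.0, -3.0]])
        # eval mode: bn is identity (eps-scaled), relu clips the negative
        xhat = h / np.sqrt(1.0 + bn.eps)
        want = 1.0 / (1.0 + np.exp(-(xhat[0, 0] + 0.0 + 0.5)))
        assert ev.predict_proba(h)[0] == pytest.approx(want, rel=1e-6)


class TestTrainingMechanics:
    def test_layer_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = Sequential([Linear(6, 5, rng), LeakyReLU(), BatchNorm1d(5),
                          Linear(5, 1, rng)])
        x = rng.normal(size=(8, 6))
        y = rng.integers(0, 2, size=8).astype(float)

        def loss_value():
            return bce_with_logits(net.forward(x, train=True), y)[0]

        base, grad_out = bce_with_logits(net.forward(x, train=True), y)
        net.backward(grad_out)
        eps = 1e-6
        for _, layer, name in net.named_params():
            g = layer.grads[name]
            flat_idx = (0,) * layer.params[name].ndim
            layer.params[name][flat_idx] += eps
            up = loss_value()
            layer.params[name][flat_idx] -= 2 * eps
            dn = loss_value()
            layer.params[name][flat_idx] += eps
            assert g[flat_idx] == pytest.approx((up - dn) / (2 * eps),
                                                rel=1e-4, abs=1e-8)

    def test_conv_backward_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        conv = Conv2d(2, 3, 3, rng)
        x = rng.normal(size=(2, 2, 5, 6))

        def loss(xx):
            return (conv.forward(xx, True) ** 2).sum()

        out = conv.forward(x, True)
        dx = conv.backward(2 * out)
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (1, 1, 2, 3), (0, 1, 4, 5)]:
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            num = (loss(xp) - loss(xm)) / (2 * eps)
            assert dx[idx] == pytest.approx(num, rel=1e-5)
        # weight gradient too
        gW = conv.grads["W"]
        conv.forward(x, True)
        w_idx = (2, 1, 0, 2)
        conv.params["W"][w_idx] += eps
        up = loss(x)
        conv.params["W"][w_idx] -= 2 * eps
        dn = loss(x)
        conv.params["W"][w_idx] += eps
        assert gW[w_idx] == pytest.approx((up - dn) / (2 * eps), rel=1e-5)

    def test_adam_reduces_simple_loss(self):
        rng = np.random.default_rng(2)
        net = Sequential([Linear(4, 1, rng)])
        opt = Adam([net], lr=0.05)
        x = rng.normal(size=(32, 4))
        y = (x[:, 0] > 0).astype(float)
        first = None
        for _ in range(100):
            loss, grad = bce_with_logits(net.forward(x, True), y)
            first = first if first is not None else loss
            opt.zero_grad()
            net.backward(grad)
            opt.step()
        assert loss < first * 0.5

    def test_parameter_count_report(self):
        enc = Encoder(TINY, seed=0)
        # conv1: 4*(1*9)+4, conv2: 8*(4*9)+8, linear: 8*8+8
        want = (4 * 9 + 4) + (8 * 36 + 8) + (8 * 8 + 8)
        assert n_parameters(enc) == want


class TestCheckpoint:
    def test_round_trip_reproduces_encoder(self, tmp_path):
        enc = Encoder(TINY, seed=9)
        ckpt = Checkpoint(encoder_config=TINY, encoder_state=state_dict(enc),
                          projection_state=None, seed=9, scheme="time_mask",
                          loss_curve=[1.0, 0.5])
        path = tmp_path / "ckpt.npz"
        ckpt.save(path)
        loaded = Checkpoint.load(path)
        spec = make_spectrogram(8, 8, seed=2)
        assert np.array_equal(loaded.build_encoder().encode(spec),
                              enc.encode(spec))
        assert loaded.scheme == "time_mask"
        assert loaded.loss_curve == [1.0, 0.5]
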