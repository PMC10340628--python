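"""Numpy NN core: primitive ops vs. brute-force oracles, gradient checks."""

import numpy as np
import pytest

from pdscreen import nn
from pdscreen.nn.losses import softmax_cross_entropy
from pdscreen.speech import (Conv1DSpec, LSTMState, LSTMStepWeights,
                             conv1d_apply, conv2d_apply, lstm_step)

from oracles import (conv1d_bruteforce, conv2d_bruteforce, lstm_step_scalar,
                     numeric_grad)


class TestConv1dApply:
    def test_identity_kernel(self):
        spec = Conv1DSpec(weights=np.ones((1, 1, 1)), bias=np.zeros(1))
        x = np.array([[1.0, -2.0, 3.0]])
        np.testing.assert_allclose(conv1d_apply(x, spec), x)

    def test_sliding_sum(self):
        spec = Conv1DSpec(weights=np.array([[[1.0, 1.0]]]), bias=np.zeros(1))
        np.testing.assert_allclose(conv1d_apply([[1, 2, 3]], spec), [[3, 5]])

    def test_two_channel_sum_with_bias(self):
        spec = Conv1DSpec(weights=np.ones((1, 2, 1)), bias=np.array([5.0]))
        out = conv1d_apply(np.array([[1.0, 2.0], [3.0, 4.0]]), spec)
        np.testing.assert_allclose(out, [[9.0, 11.0]])

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(100):
            c_in, c_out = rng.integers(1, 4, 2)
            K = int(rng.integers(1, 5))
            L = int(rng.integers(K, K + 8))
            W = rng.standard_normal((c_out, c_in, K))
            b = rng.standard_normal(c_out)
            x = rng.standard_normal((c_in, L))
            np.testing.assert_allclose(
                conv1d_apply(x, Conv1DSpec(W, b)), conv1d_bruteforce(x, W, b),
                atol=1e-6)

    def test_kernel_longer_than_input_rejected(self):
        spec = Conv1DSpec(weights=np.ones((1, 1, 5)), bias=np.zeros(1))
        with pytest.raises(ValueError, match="shorter than kernel"):
            conv1d_apply([[1.0, 2.0]], spec)


class TestConv2dApply:
    def test_identity_kernel(self, rng):
        I = rng.standard_normal((4, 5))
        np.testing.assert_allclose(conv2d_apply(I, [[1.0]]), I)

    def test_ramp_with_ones_kernel(self):
        I = np.arange(1.0, 10.0).reshape(3, 3)
        np.testing.assert_allclose(conv2d_apply(I, np.ones((2, 2))),
                                   [[12, 16], [24, 28]])

    def test_flip_relation_to_cross_correlation(self, rng):
        I = rng.standard_normal((6, 6))
        H = rng.standard_normal((2, 3))  # asymmetric
        conv = conv2d_apply(I, H[::-1, ::-1])
        # cross-correlation via sliding windows
        xcorr = np.array([
            [(I[m:m + 2, n:n + 3] * H).sum() for n in range(4)]
            for m in range(5)])
        np.testing.assert_allclose(conv, xcorr, atol=1e-12)

    def test_matches_literal_double_sum(self, rng):
        for _ in range(100):
            hi, wi = rng.integers(2, 7, 2)
            hk = int(rng.integers(1, hi + 1))
            wk = int(rng.integers(1, wi + 1))
            I = rng.standard_normal((hi, wi))
            H = rng.standard_normal((hk, wk))
            np.testing.assert_allclose(conv2d_apply(I, H),
                                       conv2d_bruteforce(I, H), atol=1e-6)

    def test_kernel_bigger_than_image_rejected(self):
        with pytest.raises(ValueError, match="larger than image"):
            conv2d_apply(np.ones((2, 2)), np.ones((3, 3)))


class TestLstmStep:
    def _weights(self, H, D, fill=0.0, b_f=0.0):
        z = lambda: np.full((H, H + D), fill)
        return LSTMStepWeights(W_f=z(), W_i=z(), W_c=z(), W_o=z(),
                               b_f=np.full(H, b_f), b_i=np.zeros(H),
                               b_c=np.zeros(H), b_o=np.zeros(H))

    def test_zero_weights_halve_cell_state(self):
        c = np.array([0.4, -1.2])
        out = lstm_step(np.zeros(3), LSTMState(h=np.zeros(2), c=c),
                        self._weights(2, 3))
        np.testing.assert_allclose(out.c, 0.5 * c)
        np.testing.assert_allclose(out.h, 0.5 * np.tanh(0.5 * c))

    def test_saturated_forget_gate_preserves_memory(self):
        c = np.array([2.0, -3.0])
        out = lstm_step(np.zeros(1), LSTMState(h=np.zeros(2), c=c),
                        self._weights(2, 1, b_f=100.0))
        # f ~= 1 and i = 0.5, c~ = 0 => c_t ~= c_{t-1}
        np.testing.assert_allclose(out.c, c, atol=1e-8)

    def test_scalar_case_matches_hand_computation(self, rng):
        for _ in range(50):
            w = rng.standard_normal(12)
            x, h0, c0 = rng.standard_normal(3)
            weights = LSTMStepWeights(
                W_f=np.array([[w[0], w[4]]]), W_i=np.array([[w[1], w[5]]]),
                W_c=np.array([[w[2], w[6]]]), W_o=np.array([[w[3], w[7]]]),
                b_f=w[8:9], b_i=w[9:10], b_c=w[10:11], b_o=w[11:12])
            out = lstm_step(np.array([x]), LSTMState(h=np.array([h0]),
                                                     c=np.array([c0])), weights)
            h, c = lstm_step_scalar(x, h0, c0, w[0], w[1], w[2], w[3],
                                    w[4], w[5], w[6], w[7],
                                    w[8], w[9], w[10], w[11])
            assert abs(out.h[0] - h) < 1e-10 and abs(out.c[0] - c) < 1e-10

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            lstm_step(np.array([np.nan]), LSTMState(h=np.zeros(1), c=np.zeros(1)),
                      self._weights(1, 1))


class TestLayerGradients:
    """Analytic backward passes vs. central finite differences (float64)."""

    def _check(self, layer, x, train=True, tol=1e-5):
        R = np.random.default_rng(0).standard_normal(
            layer.forward(x, train=train).shape)

        def loss():
            return float((layer.forward(x, train=train) * R).sum())

        layer.forward(x, train=train)
        dx = layer.backward(R.copy())
        analytic = {id(p): p.grad.copy() for p in layer.params()}
        np.testing.assert_allclose(dx, numeric_grad(loss, x), atol=tol,
                                   err_msg="input gradient")
        for p in layer.params():
            for q in layer.params():
                q.grad[...] = 0.0
            np.testing.assert_allclose(
                analytic[id(p)], numeric_grad(loss, p.data), atol=tol,
                err_msg=p.name)

    def test_dense(self, float64_params, rng):
        self._check(nn.Dense(4, 3, rng), rng.standard_normal((5, 4)))

    def test_conv1d_strided(self, float64_params, rng):
        self._check(nn.Conv1d(2, 3, 4, rng, stride=2),
                    rng.standard_normal((2, 2, 11)))

    def test_conv2d_padded_strided(self, float64_params, rng):
        self._check(nn.Conv2d(2, 3, 3, rng, stride=2, pad=1),
                    rng.standard_normal((2, 2, 7, 6)))

    def test_batchnorm2d_train_mode(self, float64_params, rng):
        self._check(nn.BatchNorm2d(3), rng.standard_normal((4, 3, 2, 3)))

    def test_lstm_bptt(self, float64_params, rng):
        self._check(nn.LSTM(3, 4, rng), rng.standard_normal((2, 5, 3)))

    def test_maxpool1d_and_2d(self, float64_params, rng):
        self._check(nn.MaxPool1d(2), rng.standard_normal((2, 3, 7)))
        self._check(nn.MaxPool2d(3, 2, pad=1), rng.standard_normal((2, 2, 6, 5)))

    def test_residual_block_projection(self, float64_params, rng):
        self._check(nn.ResidualBlock(2, 4, rng, stride=2),
                    rng.standard_normal((2, 2, 6, 6)), tol=1e-4)


class TestTrainingMachinery:
    def test_dropout_scaling_and_eval_identity(self, rng):
        drop = nn.Dropout(0.4, rng)
        x = np.ones((200, 50))
        out = drop.forward(x, train=True)
        assert 0.3 < (out == 0).mean() < 0.5
        assert out[out != 0].flat[0] == pytest.approx(1 / 0.6)
        np.testing.assert_array_equal(drop.forward(x, train=False), x)

    def test_adam_minimizes_quadratic(self):
        p = nn.Param(np.array([5.0, -3.0]))
        opt = nn.Adam([p], lr=0.1)
        for _ in range(300):
            opt.zero_grad()
            p.grad += 2 * p.data
            opt.step()
        assert np.abs(p.data).max() < 1e-3

    def test_softmax_cross_entropy_gradient(self, rng):
        logits = rng.standard_normal((6, 2))
        y = rng.integers(0, 2, 6)
        _, dl = softmax_cross_entropy(logits, y)

        def loss_at(z):
            l, _ = softmax_cross_entropy(z, y)
            return l

        np.testing.assert_allclose(dl, numeric_grad(lambda: loss_at(logits),
                                                    logits), atol=1e-6)
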