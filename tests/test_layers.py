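"""Unit oracles for the NumPy layers: closed-form examples, brute-force
references and finite-difference gradient checks."""

import numpy as np
import pytest
from scipy.special import expit

from gaitphase.nn.layers import (
    LSTM,
    Activation,
    BatchNorm,
    Conv2D,
    Dense,
    cross_entropy,
    predict_class,
    softmax,
    softmax_cross_entropy,
)


class TestSoftmax:
    def test_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros(4)), [0.25] * 4, atol=1e-12)

    def test_known_ratios(self):
        """Logits ln(1), ln(2), ln(3), ln(4) give probabilities 0.1..0.4."""
        q = softmax(np.log([1.0, 2.0, 3.0, 4.0]))
        np.testing.assert_allclose(q, [0.1, 0.2, 0.3, 0.4], atol=1e-9)

    def test_normalization_and_shift_invariance_random(self, rng):
        z = rng.normal(scale=10.0, size=(1000, 4))
        q = softmax(z)
        np.testing.assert_allclose(q.sum(axis=1), 1.0, atol=1e-9)
        q_shifted = softmax(z + rng.normal(size=(1000, 1)))
        np.testing.assert_allclose(q, q_shifted, atol=1e-9)

    def test_extreme_logits_stable(self):
        q = softmax(np.array([1e4, 0.0, -1e4, 0.0]))
        assert np.isfinite(q).all() and q[0] == pytest.approx(1.0)


class TestPredictClass:
    @pytest.mark.parametrize(
        "q,expected",
        [
            ([0.1, 0.2, 0.3, 0.4], 3),
            ([0.25, 0.25, 0.25, 0.25], 0),  # tie -> lowest index
            ([0.0, 1.0, 0.0, 0.0], 1),
        ],
    )
    def test_argmax_with_tie_rule(self, q, expected):
        assert predict_class(np.array(q)) == expected


class TestCrossEntropy:
    def test_closed_forms(self):
        y = np.array([1.0, 0, 0, 0])
        assert cross_entropy(y, np.array([1.0, 0, 0, 0])) == pytest.approx(0.0)
        assert cross_entropy(y, np.full(4, 0.25)) == pytest.approx(np.log(4))
        assert cross_entropy(y, np.array([0.1, 0.3, 0.3, 0.3])) == pytest.approx(
            -np.log(0.1)
        )

    def test_clamped_at_zero_probability(self):
        y = np.array([1.0, 0, 0, 0])
        val = cross_entropy(y, np.array([0.0, 0.5, 0.25, 0.25]))
        assert np.isfinite(val) and val == pytest.approx(-np.log(1e-12))

    def test_fused_gradient(self, rng):
        logits = rng.normal(size=(8, 4))
        labels = rng.integers(0, 4, size=8)
        loss, q, dlogits = softmax_cross_entropy(logits, labels)
        y = np.zeros_like(q)
        y[np.arange(8), labels] = 1
        np.testing.assert_allclose(dlogits, (q - y) / 8, atol=1e-12)


class TestBatchNorm:
    def test_hand_computed_example(self):
        """Batch {0, 2, 4}: mean 2, population variance 8/3, so the
        standardized values are -1.2247, 0, 1.2247."""
        bn = BatchNorm(1, eps=1e-12)
        out = bn.forward(np.array([[0.0], [2.0], [4.0]]), training=True)
        np.testing.assert_allclose(
            out.ravel(), [-1.22474487, 0.0, 1.22474487], atol=1e-4
        )

    def test_already_standardized_batch_unchanged(self):
        bn = BatchNorm(1, eps=1e-12)
        out = bn.forward(np.array([[-1.0], [1.0]]), training=True)
        np.testing.assert_allclose(out.ravel(), [-1.0, 1.0], atol=1e-6)

    def test_gamma_zero_gives_beta(self, rng):
        bn = BatchNorm(3)
        bn.gamma[...] = 0.0
        bn.beta[...] = 5.0
        out = bn.forward(rng.normal(size=(16, 3)), training=True)
        np.testing.assert_allclose(out, 5.0, atol=1e-12)

    def test_training_output_moments(self, rng):
        """Per-feature mean beta and variance ~ gamma^2 (eps -> 0)."""
        bn = BatchNorm(5, eps=1e-12)
        bn.gamma[...] = 2.0
        bn.beta[...] = -1.0
        out = bn.forward(rng.normal(size=(256, 5)), training=True)
        np.testing.assert_allclose(out.mean(axis=0), -1.0, atol=1e-6)
        np.testing.assert_allclose(out.var(axis=0), 4.0, rtol=1e-6)

    def test_running_stats_used_at_inference(self, rng):
        bn = BatchNorm(2, momentum=0.0)  # running stats = last batch
        x = rng.normal(loc=3.0, scale=2.0, size=(512, 2))
        bn.forward(x, training=True)
        out = bn.forward(x, training=False)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-2)

    def test_single_example_training_rejected(self):
        with pytest.raises(ValueError, match="m >= 2"):
            BatchNorm(3).forward(np.ones((1, 3)), training=True)

    def test_conv_input_normalizes_per_channel(self, rng):
        bn = BatchNorm(7)
        x = rng.normal(size=(8, 2, 2, 7))
        out = bn.forward(x, training=True)
        flat = out.reshape(-1, 7)
        np.testing.assert_allclose(flat.mean(axis=0), 0.0, atol=1e-9)


class TestConv2D:
    def test_all_ones_sums_kernel(self, rng):
        conv = Conv2D(4, 1, 1, np.random.default_rng(0))
        conv.W[...] = 1.0
        conv.b[...] = 0.0
        out = conv.forward(np.ones((1, 5, 5, 1)))
        assert out.shape == (1, 2, 2, 1)
        np.testing.assert_allclose(out, 16.0)

    def test_one_by_one_identity(self, rng):
        conv = Conv2D(1, 1, 1, np.random.default_rng(0))
        conv.W[...] = 1.0
        conv.b[...] = 0.0
        x = rng.normal(size=(3, 4, 4, 1))
        np.testing.assert_allclose(conv.forward(x), x, atol=1e-12)

    def test_output_shape_contract(self):
        conv = Conv2D(4, 3, 20, np.random.default_rng(0))
        out = conv.forward(np.zeros((2, 5, 5, 3)))
        assert out.shape == (2, 2, 2, 20)

    def test_matches_direct_cross_correlation(self, rng):
        """Brute-force sliding dot product agrees with the im2col path."""
        conv = Conv2D(3, 2, 4, np.random.default_rng(1))
        x = rng.normal(size=(2, 6, 6, 2))
        out = conv.forward(x)
        for n in (0, 1):
            for i in range(4):
                for j in range(4):
                    for f in range(4):
                        ref = (
                            x[n, i : i + 3, j : j + 3, :] * conv.W[:, :, :, f]
                        ).sum() + conv.b[f]
                        assert out[n, i, j, f] == pytest.approx(ref, rel=1e-9)

    def test_kernel_too_large_rejected(self):
        conv = Conv2D(4, 1, 1, np.random.default_rng(0), name="conv9")
        with pytest.raises(ValueError, match="conv9"):
            conv.forward(np.zeros((1, 3, 3, 1)))


class TestLSTM:
    def test_output_dimension(self, rng):
        lstm = LSTM(6, 36, np.random.default_rng(0))
        for t in (1, 5, 20):
            out = lstm.forward(rng.normal(size=(3, t, 6)))
            assert out.shape == (3, 36)

    def test_zero_weights_one_step_closed_form(self):
        """All-zero weights and inputs, one step: i = o = sigmoid(0) = 1/2,
        f = sigmoid(0.7), g = act(0) = 0, so c = 0 and h = 0."""
        lstm = LSTM(3, 4, np.random.default_rng(0), forget_bias=0.7)
        for p in lstm.params.values():
            p[...] = 0.0
        out = lstm.forward(np.zeros((2, 1, 3)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_forget_bias_enters_forget_gate(self):
        """With candidate forced positive via the input bias, two steps of
        the recurrence expose sigmoid(forget_bias) in closed form."""
        u = 2
        lstm = LSTM(1, u, np.random.default_rng(0), forget_bias=0.7,
                    activation="relu")
        for p in lstm.params.values():
            p[...] = 0.0
        # candidate block is last in the (i, f, o, g) column layout
        lstm.b[3 * u :] = 1.0  # candidate pre-activation g = relu(1) = 1
        out1 = lstm.forward(np.zeros((1, 1, 1)))[0, 0]
        out2 = lstm.forward(np.zeros((1, 2, 1)))[0, 0]
        sig0, sig07 = expit(0.0), expit(0.7)
        c1 = sig0 * 1.0
        h1_expected = sig0 * c1
        c2 = sig07 * c1 + sig0 * 1.0
        h2_expected = sig0 * c2
        assert out1 == pytest.approx(h1_expected, rel=1e-6)
        assert out2 == pytest.approx(h2_expected, rel=1e-6)

    def test_matches_naive_recurrence(self, rng):
        """Step-by-step reference implementation agrees with the buffered
        time-major path for both activations."""
        for act, fn in (("relu", lambda z: np.maximum(z, 0.0)), ("tanh", np.tanh)):
            lstm = LSTM(3, 5, np.random.default_rng(2), activation=act)
            seq = rng.normal(size=(4, 9, 3))
            u = 5
            h = np.zeros((4, u))
            c = np.zeros((4, u))
            for k in range(9):
                z = seq[:, k] @ lstm.Wx + h @ lstm.Wh + lstm.b
                i = expit(z[:, :u])
                f = expit(z[:, u : 2 * u] + lstm.forget_bias)
                o = expit(z[:, 2 * u : 3 * u])
                g = fn(z[:, 3 * u :])
                c = f * c + i * g
                h = o * fn(c)
            np.testing.assert_allclose(lstm.forward(seq), h, atol=1e-12)

    def test_empty_sequence_rejected(self):
        lstm = LSTM(3, 4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            lstm.forward(np.zeros((2, 0, 3)))


class TestActivationLayer:
    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown activation"):
            Activation("gelu")

    @pytest.mark.parametrize("name", ["relu", "leaky_relu", "tanh", "linear"])
    def test_forward_backward_consistency(self, name, rng):
        act = Activation(name)
        z = rng.normal(size=(6, 7)) + 0.05  # keep clear of the relu kink
        out = act.forward(z)
        eps = 1e-6
        num = (act.fn(z + eps) - act.fn(z - eps)) / (2 * eps)
        grad = act.backward(np.ones_like(z))
        np.testing.assert_allclose(grad, num, atol=1e-6)


def _fd_grad(fn, arr, eps=1e-6):
    """Central finite differences of scalar fn w.r.t. every entry of arr."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = fn()
        arr[idx] = orig - eps
        fm = fn()
        arr[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


class TestGradients:
    """Analytic backward passes against central finite differences.

    Smooth activations (tanh) are used so the difference quotient is valid
    everywhere; the layers under test are exactly those used by the models.
    """

    def _check_layer(self, layer, x, rng, tol=1e-6):
        w = rng.normal(size=layer.forward(x, training=True).shape)

        def loss():
            return float((layer.forward(x, training=True) * w).sum())

        layer.forward(x, training=True)
        layer.zero_grad()
        dx = layer.backward(w)
        np.testing.assert_allclose(_fd_grad(loss, x), dx, atol=tol)
        for name, p in layer.params.items():
            np.testing.assert_allclose(
                _fd_grad(loss, p), layer.grads[name], atol=tol, err_msg=name
            )

    def test_dense(self, rng):
        self._check_layer(Dense(4, 3, np.random.default_rng(0)),
                          rng.normal(size=(5, 4)), rng)

    def test_conv(self, rng):
        self._check_layer(Conv2D(2, 2, 3, np.random.default_rng(0)),
                          rng.normal(size=(3, 4, 4, 2)), rng)

    def test_batchnorm(self, rng):
        self._check_layer(BatchNorm(3), rng.normal(size=(6, 3)), rng, tol=1e-5)

    def test_lstm(self, rng):
        self._check_layer(
            LSTM(3, 4, np.random.default_rng(1), activation="tanh"),
            rng.normal(size=(3, 6, 3)), rng, tol=1e-5,
        )

    def test_softmax_cross_entropy(self, rng):
        logits = rng.normal(size=(5, 4))
        labels = rng.integers(0, 4, size=5)
        _, _, dlogits = softmax_cross_entropy(logits, labels)

        def loss():
            return softmax_cross_entropy(logits, labels)[0]

        np.testing.assert_allclose(_fd_grad(loss, logits), dlogits, atol=1e-7)
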