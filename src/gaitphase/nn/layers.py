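"""Minimal NumPy neural-network layers with hand-written backpropagation.

Everything the gait-phase networks need — valid 2-D convolution, batch
normalization with running inference statistics, an LSTM with a forget-gate
bias offset, dense layers, the usual activations and the softmax /
cross-entropy head — implemented directly on NumPy arrays.  Each layer
caches what its backward pass needs; ``backward`` consumes the gradient of
the loss w.r.t. the layer output and returns the gradient w.r.t. the input,
accumulating parameter gradients in ``.grads``.

Shapes follow the channels-last convention: feature maps are
``(N, H, W, C)``, sequences ``(N, T, F)``, vectors ``(N, F)``.

Every layer optionally holds a *stack* of ``M`` independent replicate
models (``rng`` given as a list of M generators).  A stacked layer stores
parameters with a leading model axis and processes inputs of shape
``(M, N, ...)`` with batched matmuls, which is how replicate training runs
(e.g. seed averages) are executed efficiently; the arithmetic per member is
identical to an unstacked layer initialized from the same generator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense", "BatchNorm", "Conv2D", "LSTM", "Activation",
    "softmax", "predict_class", "cross_entropy", "softmax_cross_entropy",
]


# ---------------------------------------------------------------------------
# activations

def _relu(z):
    return np.maximum(z, 0.0)


def _drelu(a):
    # derivative from the activation value (sign of a matches sign of z)
    return (a > 0).astype(a.dtype)


def _leaky_relu(z, slope=0.01):
    return np.where(z > 0, z, slope * z)


def _dleaky_relu(a, slope=0.01):
    return np.where(a > 0, a.dtype.type(1.0), a.dtype.type(slope))


def _tanh(z):
    return np.tanh(z)


def _dtanh(a):
    return 1.0 - a * a


def _linear(z):
    return z


def _dlinear(a):
    return np.ones_like(a)


#: name -> (activation, derivative-from-activation-value).  All activations
#: used here are monotone with act(0) = 0, so the derivative is recoverable
#: from the output value alone.
_ACTIVATIONS = {
    "relu": (_relu, _drelu),
    "leaky_relu": (_leaky_relu, _dleaky_relu),
    "tanh": (_tanh, _dtanh),
    "linear": (_linear, _dlinear),
}


def _get_activation(name: str):
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; options: {sorted(_ACTIVATIONS)}"
        ) from None


class Layer:
    """Base class: parameter bookkeeping shared by all layers.

    ``stack`` is the number of stacked replicate models (None = single)."""

    def __init__(self, rng=None):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        if isinstance(rng, (list, tuple)):
            self.stack: int | None = len(rng)
            self._rngs = list(rng)
        else:
            self.stack = None
            self._rngs = [rng] if rng is not None else []

    def _register(self, name: str, value: np.ndarray) -> np.ndarray:
        self.params[name] = value
        self.grads[name] = np.zeros_like(value)
        return value

    def _init_uniform(self, shape, fan_in: int, dtype) -> np.ndarray:
        """Fan-in-scaled uniform init; stacked layers draw one tensor per
        member generator so each member matches a single-model init."""
        bound = 1.0 / np.sqrt(fan_in)
        draws = [
            rng.uniform(-bound, bound, size=shape).astype(dtype)
            for rng in self._rngs
        ]
        return np.stack(draws) if self.stack is not None else draws[0]

    def _zeros(self, shape, dtype) -> np.ndarray:
        if self.stack is not None:
            return np.zeros((self.stack, 1, *shape), dtype=dtype)
        return np.zeros(shape, dtype=dtype)

    def _ones(self, shape, dtype) -> np.ndarray:
        if self.stack is not None:
            return np.ones((self.stack, 1, *shape), dtype=dtype)
        return np.ones(shape, dtype=dtype)

    def zero_grad(self) -> None:
        for g in self.grads.values():
            g[...] = 0.0

    def n_params(self) -> int:
        total = sum(p.size for p in self.params.values())
        return total // self.stack if self.stack else total


class Activation(Layer):
    """Elementwise activation layer (relu / leaky_relu / tanh / linear)."""

    def __init__(self, name: str):
        super().__init__()
        self.name = name
        self.fn, self.dfn = _get_activation(name)
        self._a = None

    def forward(self, z: np.ndarray, training: bool = False) -> np.ndarray:
        a = self.fn(z)
        self._a = a
        return a

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self.dfn(self._a)


class Dense(Layer):
    """Affine map ``y = x W + b`` with ``W`` of shape (in, out).

    Stacked form: ``W`` is (M, in, out), inputs (M, N, in), batched matmul.
    """

    def __init__(self, d_in: int, d_out: int, rng, dtype=np.float64):
        super().__init__(rng)
        self.d_in, self.d_out = d_in, d_out
        self.W = self._register("W", self._init_uniform((d_in, d_out), d_in, dtype))
        self.b = self._register("b", self._zeros((d_out,), dtype))
        self._x = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return np.matmul(x, self.W) + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += np.matmul(np.swapaxes(self._x, -1, -2), dout)
        if self.stack is not None:
            self.grads["b"] += dout.sum(axis=-2, keepdims=True)
        else:
            self.grads["b"] += dout.sum(axis=0)
        return np.matmul(dout, np.swapaxes(self.W, -1, -2))


class BatchNorm(Layer):
    """Per-feature batch normalization with learnable scale/shift.

    In training mode features are standardized with the batch mean and the
    (population, 1/m) batch variance, then rescaled by the learnable pair
    (gamma, beta).  Running statistics (exponential moving average, momentum
    0.9) are updated for use at inference.  For 4-D conv inputs the feature
    axis is the channel axis and statistics pool over batch and space; in a
    stacked layer every member normalizes over its own batch.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.9,
                 rng=None, dtype=np.float64):
        super().__init__(rng if isinstance(rng, (list, tuple)) else None)
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = self._register("gamma", self._ones((num_features,), dtype))
        self.beta = self._register("beta", self._zeros((num_features,), dtype))
        self.running_mean = self._zeros((num_features,), dtype)
        self.running_var = self._ones((num_features,), dtype)
        self._cache = None
        self._shape = None

    def _flat(self, x: np.ndarray) -> np.ndarray:
        if self.stack is not None:
            return x.reshape(self.stack, -1, self.num_features)
        return x.reshape(-1, self.num_features)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        x2 = self._flat(x)
        m = x2.shape[-2]
        if training:
            if m < 2:
                raise ValueError(
                    f"batch normalization in training mode needs m >= 2, got m={m}"
                )
            mu = x2.mean(axis=-2, keepdims=True)
            var = ((x2 - mu) ** 2).mean(axis=-2, keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            ) if self.stack is not None else (
                self.momentum * self.running_mean + (1 - self.momentum) * mu[0]
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ) if self.stack is not None else (
                self.momentum * self.running_var + (1 - self.momentum) * var[0]
            )
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x2 - mu) * inv_std
        out = self.gamma * xhat + self.beta
        self._cache = (xhat, inv_std, m, training)
        return out.reshape(self._shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, m, training = self._cache
        d2 = self._flat(dout)
        dgamma = (d2 * xhat).sum(axis=-2, keepdims=True)
        dbeta = d2.sum(axis=-2, keepdims=True)
        if self.stack is not None:
            self.grads["gamma"] += dgamma
            self.grads["beta"] += dbeta
        else:
            self.grads["gamma"] += dgamma[0]
            self.grads["beta"] += dbeta[0]
        dxhat = d2 * self.gamma
        if training:
            dx = (
                inv_std
                / m
                * (
                    m * dxhat
                    - dxhat.sum(axis=-2, keepdims=True)
                    - xhat * (dxhat * xhat).sum(axis=-2, keepdims=True)
                )
            )
        else:
            dx = dxhat * inv_std
        return dx.reshape(self._shape)


class Conv2D(Layer):
    """Valid (no padding) 2-D cross-correlation with bias.

    Weights have shape (k, k, C_in, C_out); input ``(N, H, W, C_in)`` maps
    to ``(N, H', W', C_out)`` with ``H' = (H - k)//stride + 1``.  Stacked
    form: weights (M, k, k, C_in, C_out), inputs (M, N, H, W, C_in).
    Implemented as an im2col matmul.
    """

    def __init__(self, kernel: int, c_in: int, c_out: int, rng,
                 stride: int = 1, name: str = "conv", dtype=np.float64):
        super().__init__(rng)
        self.k, self.c_in, self.c_out, self.stride = kernel, c_in, c_out, stride
        self.name = name
        fan_in = kernel * kernel * c_in
        self.W = self._register(
            "W", self._init_uniform((kernel, kernel, c_in, c_out), fan_in, dtype)
        )
        self.b = self._register("b", self._zeros((c_out,), dtype))
        self._cache = None

    @property
    def _wmat(self) -> np.ndarray:
        if self.stack is not None:
            return self.W.reshape(self.stack, -1, self.c_out)
        return self.W.reshape(-1, self.c_out)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h, w, c = x.shape[-3:]
        lead = x.shape[:-3]  # (N,) or (M, N)
        if c != self.c_in:
            raise ValueError(
                f"layer {self.name}: expected {self.c_in} input channels, got {c}"
            )
        if h < self.k or w < self.k:
            raise ValueError(
                f"layer {self.name}: input {h}x{w} smaller than kernel "
                f"{self.k}x{self.k}"
            )
        ho = (h - self.k) // self.stride + 1
        wo = (w - self.k) // self.stride + 1
        win = np.lib.stride_tricks.sliding_window_view(
            x, (self.k, self.k), axis=(-3, -2)
        )  # (..., HO', WO', C, k, k)
        win = win[..., :: self.stride, :: self.stride, :, :, :]
        arr = np.moveaxis(win, -3, -1)  # (..., ho, wo, k, k, C)
        if self.stack is not None:
            cols = np.ascontiguousarray(arr).reshape(self.stack, -1, self.k * self.k * c)
        else:
            cols = np.ascontiguousarray(arr).reshape(-1, self.k * self.k * c)
        out = np.matmul(cols, self._wmat) + self.b
        self._cache = (cols, x.shape, (ho, wo))
        return out.reshape(*lead, ho, wo, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape, (ho, wo) = self._cache
        if self.stack is not None:
            d2 = dout.reshape(self.stack, -1, self.c_out)
        else:
            d2 = dout.reshape(-1, self.c_out)
        self.grads["W"] += np.matmul(
            np.swapaxes(cols, -1, -2), d2
        ).reshape(self.W.shape)
        if self.stack is not None:
            self.grads["b"] += d2.sum(axis=-2, keepdims=True)
        else:
            self.grads["b"] += d2.sum(axis=0)
        dcols = np.matmul(d2, np.swapaxes(self._wmat, -1, -2))
        lead = x_shape[:-3]
        dcols = dcols.reshape(*lead, ho, wo, self.k, self.k, self.c_in)
        dx = np.zeros(x_shape, dtype=d2.dtype)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                dx[..., i : i + ho * s : s, j : j + wo * s : s, :] += dcols[
                    ..., i, j, :
                ]
        return dx


class LSTM(Layer):
    """Single-layer LSTM returning the final hidden state.

    Standard recurrence; the configured ``forget_bias`` is added to the
    forget-gate pre-activation as a constant offset.  ``activation``
    (default relu, per the network configuration; tanh available) is applied
    to both the candidate and the cell output.

        i_t = sigm(z_i)          f_t = sigm(z_f + forget_bias)
        g_t = act(z_g)           o_t = sigm(z_o)
        c_t = f_t c_{t-1} + i_t g_t
        h_t = o_t act(c_t)

    Implementation notes: weight columns are laid out (i, f, o, g) so the
    three sigmoid gates form one contiguous block; all state is kept
    time-major so per-step slices are contiguous; the input projection and
    the weight gradients are single large (batched) matmuls, and only the
    hidden-to-hidden product runs per step.  Inputs are ``(N, T, F)``, or
    ``(M, N, T, F)`` for a stacked layer.
    """

    def __init__(self, d_in: int, units: int, rng, forget_bias: float = 0.7,
                 activation: str = "relu", dtype=np.float64):
        super().__init__(rng)
        self.d_in, self.units = d_in, units
        self.forget_bias = forget_bias
        self.act_name = activation
        self.fn, self.dfn = _get_activation(activation)
        fan_in = d_in + units
        self.Wx = self._register(
            "Wx", self._init_uniform((d_in, 4 * units), fan_in, dtype)
        )
        self.Wh = self._register(
            "Wh", self._init_uniform((units, 4 * units), fan_in, dtype)
        )
        self.b = self._register("b", self._zeros((4 * units,), dtype))
        self._cache = None
        self._bufkey = None
        self._bufs = None

    def _buffers(self, t: int, mn: int):
        """Reusable state/scratch arrays for a (t, mn) problem size; training
        repeats the same shape every iteration, so allocate once."""
        key = (t, mn)
        if self._bufkey != key:
            u = self.units
            dt = self.Wx.dtype
            self._bufs = {
                "S": np.empty((t, mn, 3 * u), dt),
                "G": np.empty((t, mn, u), dt),
                "C": np.empty((t, mn, u), dt),
                "AC": np.empty((t, mn, u), dt),
                "H": np.zeros((t + 1, mn, u), dt),  # H[0] stays zero
                "dZ": np.empty((t, mn, 4 * u), dt),
                "z": np.empty((mn, 4 * u), dt),
                "tmp": np.empty((mn, u), dt),
                "tmp2": np.empty((mn, u), dt),
            }
            self._bufkey = key
        return self._bufs

    def _dims(self, seq: np.ndarray):
        if self.stack is not None:
            if seq.ndim != 4 or seq.shape[0] != self.stack:
                raise ValueError(
                    f"stacked LSTM input must be ({self.stack}, N, T, F)"
                )
            m, n, t, f = seq.shape
        else:
            if seq.ndim != 3:
                raise ValueError("LSTM input must be (N, T, F)")
            m = 1
            n, t, f = seq.shape
        if t < 1:
            raise ValueError("LSTM requires a sequence of length >= 1")
        if f != self.d_in:
            raise ValueError(f"LSTM expected {self.d_in} features, got {f}")
        return m, n, t, f

    def forward(self, seq: np.ndarray, training: bool = False) -> np.ndarray:
        m, n, t, f = self._dims(seq)
        u = self.units
        dt = self.Wx.dtype
        seq = np.ascontiguousarray(seq, dtype=dt)
        # input projection as one flat gemm per member, then time-major
        seq_m = seq.reshape(m, n * t, f)
        wx = self.Wx if self.stack is not None else self.Wx[None]
        b = self.b if self.stack is not None else self.b[None, None]
        zx = np.matmul(seq_m, wx)
        zx += b
        zx[..., u : 2 * u] += dt.type(self.forget_bias)
        mn = m * n
        ZX = np.ascontiguousarray(
            np.moveaxis(zx.reshape(m, n, t, 4 * u), 2, 0)
        ).reshape(t, mn, 4 * u)

        bufs = self._buffers(t, mn)
        # time-major state: sigmoid gates (i, f, o), candidate, cell,
        # activated cell, hidden (H[0] = 0)
        S, G, C, AC, H = bufs["S"], bufs["G"], bufs["C"], bufs["AC"], bufs["H"]
        wh = self.Wh if self.stack is not None else self.Wh[None]
        zbuf, tmp = bufs["z"], bufs["tmp"]
        one, zero = dt.type(1.0), dt.type(0.0)
        tanh_act = self.act_name == "tanh"
        generic = self.act_name not in ("relu", "tanh")
        # exp(-z) -> inf gives sigmoid 0; NaNs from a diverged run propagate
        # to the loss, where training aborts with a diagnostic
        with np.errstate(over="ignore", invalid="ignore"):
            for k in range(t):
                np.matmul(
                    H[k].reshape(m, n, u), wh, out=zbuf.reshape(m, n, 4 * u)
                )
                z = ZX[k]
                z += zbuf
                s = S[k]
                np.negative(z[:, : 3 * u], out=s)   # sigmoid = 1/(1+exp(-z))
                np.exp(s, out=s)
                s += one
                np.divide(one, s, out=s)
                g = G[k]
                zg = z[:, 3 * u :]
                if generic:
                    g[...] = self.fn(zg)
                elif tanh_act:
                    np.tanh(zg, out=g)
                else:
                    np.maximum(zg, zero, out=g)
                c = C[k]
                np.multiply(s[:, :u], g, out=c)
                c_prev = C[k - 1] if k > 0 else H[0]  # zeros at k = 0
                np.multiply(s[:, u : 2 * u], c_prev, out=tmp)
                c += tmp
                ac = AC[k]
                if generic:
                    ac[...] = self.fn(c)
                elif tanh_act:
                    np.tanh(c, out=ac)
                else:
                    np.maximum(c, zero, out=ac)
                np.multiply(s[:, 2 * u :], ac, out=H[k + 1])
        self._cache = (seq_m, S, G, C, AC, H, (m, n, t, f))
        h_final = H[t]
        if self.stack is not None:
            return h_final.reshape(m, n, u).copy()
        return h_final.copy()

    def backward(self, dh_final: np.ndarray) -> np.ndarray:
        seq_m, S, G, C, AC, H, (m, n, t, f) = self._cache
        u = self.units
        dt = self.Wx.dtype
        mn = m * n
        bufs = self._buffers(t, mn)
        dZ = bufs["dZ"]
        wh = self.Wh if self.stack is not None else self.Wh[None]
        whT = np.ascontiguousarray(np.swapaxes(wh, -1, -2))
        dh = np.ascontiguousarray(dh_final, dtype=dt).reshape(mn, u)
        dhbuf = bufs["tmp2"]
        dc = np.zeros((mn, u), dt)
        tmp = bufs["tmp"]
        mask = np.empty((mn, u), dt)
        zeros = bufs["H"][0]  # permanently zero
        one = dt.type(1.0)
        zero = dt.type(0.0)
        relu_act = self.act_name == "relu"
        tanh_act = self.act_name == "tanh"

        def dact(a, out):
            # activation derivative from the activation value, into a buffer
            if relu_act:
                np.greater(a, zero, out=out)
            elif tanh_act:
                np.multiply(a, a, out=out)
                np.subtract(one, out, out=out)
            else:
                out[...] = self.dfn(a)
            return out

        for k in range(t - 1, -1, -1):
            s = S[k]
            i, fg, o = s[:, :u], s[:, u : 2 * u], s[:, 2 * u :]
            g, ac = G[k], AC[k]
            c_prev = C[k - 1] if k > 0 else zeros
            dz = dZ[k]
            dz3 = dz[:, : 3 * u]
            dzi = dz[:, :u]
            dzf = dz[:, u : 2 * u]
            dzo = dz[:, 2 * u : 3 * u]
            dzg = dz[:, 3 * u :]
            # sigmoid derivative s(1 - s) for all three gates in one block
            np.subtract(one, s, out=dz3)
            dz3 *= s
            # dc += dh * o * act'(c), derivative recovered from act(c)
            np.multiply(dh, o, out=tmp)
            tmp *= dact(ac, mask)
            dc += tmp
            # output gate: dz_o = (dh * ac) * o * (1 - o)
            dzo *= dh
            dzo *= ac
            # input gate: dz_i = dc * g * i * (1 - i)
            dzi *= dc
            dzi *= g
            # forget gate: dz_f = dc * c_prev * f * (1 - f)
            dzf *= dc
            dzf *= c_prev
            # candidate: dz_g = dc * i * act'(z_g), derivative from g
            np.multiply(dc, i, out=dzg)
            dzg *= dact(g, mask)
            dc *= fg  # flows to c_{k-1}
            dh = np.matmul(
                dz.reshape(m, n, 4 * u), whT, out=dhbuf.reshape(m, n, u)
            ).reshape(m * n, u)
        # weight gradients as one flat gemm per member: regroup everything
        # into (M, N*T, .) blocks aligned with seq_m
        if "dZm" not in bufs or bufs["dZm"].shape != (m, n * t, 4 * u):
            bufs["dZm"] = np.empty((m, n * t, 4 * u), dt)
            bufs["Hm"] = np.empty((m, n * t, u), dt)
        dZm, Hm = bufs["dZm"], bufs["Hm"]
        np.copyto(
            dZm.reshape(m, n, t, 4 * u),
            np.moveaxis(dZ.reshape(t, m, n, 4 * u), 0, 2),
        )
        np.copyto(
            Hm.reshape(m, n, t, u),
            np.moveaxis(H[:t].reshape(t, m, n, u), 0, 2),
        )
        dWx = np.matmul(np.swapaxes(seq_m, -1, -2), dZm)
        dWh = np.matmul(np.swapaxes(Hm, -1, -2), dZm)
        db = dZm.sum(axis=-2)
        if self.stack is not None:
            self.grads["Wx"] += dWx
            self.grads["Wh"] += dWh
            self.grads["b"] += db[:, None, :]
        else:
            self.grads["Wx"] += dWx[0]
            self.grads["Wh"] += dWh[0]
            self.grads["b"] += db[0]
        wx = self.Wx if self.stack is not None else self.Wx[None]
        dseq = np.matmul(dZm, np.swapaxes(wx, -1, -2))  # (M, N*T, F)
        if self.stack is not None:
            return dseq.reshape(m, n, t, f)
        return dseq.reshape(n, t, f)


# ---------------------------------------------------------------------------
# classification head

def softmax(logits: np.ndarray) -> np.ndarray:
    """Softmax over the last axis, stabilized by max subtraction."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def predict_class(q: np.ndarray) -> np.ndarray:
    """Index of the maximal probability; ties break to the lowest index."""
    return np.argmax(q, axis=-1)


def cross_entropy(y_onehot: np.ndarray, q: np.ndarray, clamp: float = 1e-12) -> float:
    """Mean cross-entropy  -sum_i y_i log q_i  with probabilities clamped at
    ``clamp`` so a confidently wrong prediction yields a large finite loss."""
    q = np.clip(q, clamp, 1.0)
    per_example = -(np.atleast_2d(y_onehot) * np.log(np.atleast_2d(q))).sum(axis=-1)
    return float(per_example.mean())


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Fused softmax + mean cross-entropy.

    ``logits`` is (N, K) with integer ``labels`` (N,), or (M, N, K) with
    labels (M, N) for a stacked model.  Returns ``(loss, probs, dlogits)``
    where the loss averages over examples (and members) and ``dlogits`` is
    the gradient of the *per-member* mean loss, ``(q - y) / N``.
    """
    q = softmax(logits)
    n = q.shape[-2]
    y = np.zeros_like(q)
    np.put_along_axis(y, np.asarray(labels)[..., None], 1.0, axis=-1)
    loss = cross_entropy(y, q)
    dlogits = (q - y) / n
    return loss, q, dlogits
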