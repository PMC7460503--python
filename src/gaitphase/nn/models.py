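"""Gait-phase network variants.

The full model (``fmsnet``) is a serial hybrid: a three-layer CNN encodes
each 5x5x3 sub-window map into a short feature code, an LSTM consumes the S
codes in order, and the classifier head receives the *concatenation* of the
LSTM output with the network's raw flattened input (the skip connection —
explicitly concatenation, not addition), through fully connected layers of
160, 60 and 4 units with batch normalization on each pre-activation.

Ablations:

``no_skip``
    identical, but the first FC layer sees only the LSTM output (dim 36);
``lstm_cnn``
    the serial CNN->LSTM->FC stack without the skip *and* without batch
    normalization;
``lstm``
    the plain recurrent baseline: the raw (L*S)-step triaxial sequence into
    an LSTM(36) followed by FC(60) and FC(4).

All variants end in softmax over the four phases and train by mini-batch
gradient descent on the mean cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..preprocessing import ExampleSet, WindowingSpec
from .layers import (
    LSTM,
    Activation,
    BatchNorm,
    Conv2D,
    Dense,
    Layer,
    predict_class,
    softmax,
)

__all__ = [
    "ConvLayerSpec", "LSTMSpec", "ModelConfig", "ForwardTrace",
    "skip_concat", "build_model", "VARIANTS", "ConvLSTMNet", "LSTMNet",
]

VARIANTS = ("fmsnet", "no_skip", "lstm_cnn", "lstm")

N_CLASSES = 4


@dataclass(frozen=True)
class ConvLayerSpec:
    """One valid-convolution layer: square kernel, output channels, stride,
    activation."""

    kernel: int
    filters: int
    stride: int = 1
    activation: str = "relu"


#: Default CNN stack for a 5x5x3 sub-window map: 4x4/20 -> 2x2x20,
#: 2x2/5 -> 1x1x5, 1x1/1 -> 1x1x1.  (A 1x1 kernel cannot take 2x2 to 1x1,
#: so the middle layer uses a 2x2 kernel, honoring the target feature-map
#: shapes.)
DEFAULT_CONV_STACK = (
    ConvLayerSpec(kernel=4, filters=20),
    ConvLayerSpec(kernel=2, filters=5),
    ConvLayerSpec(kernel=1, filters=1),
)


@dataclass(frozen=True)
class LSTMSpec:
    """LSTM hyper-parameters: 36 units, forget-gate bias offset 0.7, relu
    activation (tanh available for stability experiments)."""

    num_units: int = 36
    forget_bias: float = 0.7
    activation: str = "relu"


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to build any variant deterministically."""

    windowing: WindowingSpec = field(default_factory=WindowingSpec)
    conv_stack: tuple[ConvLayerSpec, ...] = DEFAULT_CONV_STACK
    lstm: LSTMSpec = field(default_factory=LSTMSpec)
    fc_units: tuple[int, int, int] = (160, 60, 4)
    fc_activation: str = "leaky_relu"
    bn_eps: float = 1e-5
    bn_momentum: float = 0.9
    seed: int = 0
    #: parameter/compute precision; float32 is the training default,
    #: float64 is available for finite-difference gradient verification
    dtype: str = "float32"


@dataclass
class ForwardTrace:
    """Intermediate quantities of one forward pass through the classifier
    head, for inspection and testing."""

    olstm: np.ndarray      # (N, units) final LSTM hidden state
    x: np.ndarray | None   # (N, 3*L*S) raw flattened input (None: no skip)
    xFC1: np.ndarray       # (N, .) input actually fed to FC1
    logits: np.ndarray     # (N, 4)
    probs: np.ndarray      # (N, 4) softmax output, rows sum to 1
    predicted: np.ndarray  # (N,) argmax class


def skip_concat(olstm: np.ndarray, x: np.ndarray) -> np.ndarray:
    """The skip connection: ``[olstm || x]``, LSTM output first.

    Plain concatenation along the feature axis — values pass through
    unchanged and the result has ``olstm.shape[-1] + x.shape[-1]`` features.
    """
    olstm = np.atleast_2d(olstm)
    x = np.atleast_2d(x)
    if not (np.all(np.isfinite(olstm)) and np.all(np.isfinite(x))):
        raise ValueError("skip_concat requires finite inputs")
    return np.concatenate([olstm, x], axis=-1)


class _ModelBase:
    """Shared training plumbing: parameter iteration and the SGD step."""

    layers: list[Layer]
    stack: int | None = None

    def iter_layers(self):
        return iter(self.layers)

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def sgd_step(self, lr: float) -> None:
        for layer in self.layers:
            for name, p in layer.params.items():
                p -= lr * layer.grads[name]

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    # -- inference helpers ---------------------------------------------------

    def predict_proba(self, examples: ExampleSet, batch_size: int = 1024) -> np.ndarray:
        """Class probabilities, (N, 4); a stacked model returns (M, N, 4)
        with every member scoring the same examples."""
        inputs = self.make_inputs(examples)
        out = []
        for lo in range(0, len(examples), batch_size):
            sl = slice(lo, lo + batch_size)
            batch = tuple(a[sl] for a in inputs)
            if self.stack is not None:
                batch = tuple(
                    np.broadcast_to(b, (self.stack, *b.shape)) for b in batch
                )
            logits = self.forward(*batch, training=False)
            out.append(softmax(logits))
        return np.concatenate(out, axis=-2)

    def predict(self, examples: ExampleSet, batch_size: int = 1024) -> np.ndarray:
        return predict_class(self.predict_proba(examples, batch_size))

    def extract_member(self, j: int):
        """Copy member ``j`` of a stacked model into a standalone model."""
        if self.stack is None:
            raise ValueError("not a stacked model")
        if not 0 <= j < self.stack:
            raise IndexError(f"member {j} out of range 0..{self.stack - 1}")
        single = build_model(self.variant, self.config)
        for src, dst in zip(self.layers, single.layers):
            for name, p in src.params.items():
                dst.params[name][...] = p[j, 0] if p.ndim - 1 > dst.params[name].ndim else p[j]
            if hasattr(src, "running_mean"):
                dst.running_mean[...] = src.running_mean[j, 0]
                dst.running_var[...] = src.running_var[j, 0]
        return single


class ConvLSTMNet(_ModelBase):
    """The CNN->LSTM->FC stack (variants fmsnet / no_skip / lstm_cnn).

    Per sub-window the conv stack runs to completion; the LSTM's per-step
    input is the concatenation of the flattened outputs of the last two conv
    layers (5 + 1 = 6 features with the default stack), so every conv layer
    contributes.  ``use_skip`` routes the raw flattened input to FC1
    alongside the LSTM output; ``use_bn`` inserts batch normalization after
    every conv and FC pre-activation (never on the raw skip path).
    """

    def __init__(self, config: ModelConfig, use_skip: bool, use_bn: bool,
                 stack_seeds=None):
        self.config = config
        self.use_skip = use_skip
        self.use_bn = use_bn
        self.stack = len(stack_seeds) if stack_seeds is not None else None
        if stack_seeds is not None:
            rng = [np.random.default_rng(s) for s in stack_seeds]
        else:
            rng = np.random.default_rng(config.seed)
        dtype = np.dtype(config.dtype)
        self.dtype = dtype
        w = config.windowing
        r, c = w.map_shape

        self.convs: list[Conv2D] = []
        self.conv_bns: list[BatchNorm | None] = []
        self.conv_acts: list[Activation] = []
        shapes = [(r, c, 3)]
        ch = 3
        hh, ww = r, c
        for li, spec in enumerate(config.conv_stack):
            conv = Conv2D(spec.kernel, ch, spec.filters, rng,
                          stride=spec.stride, name=f"conv{li + 1}", dtype=dtype)
            ho = (hh - spec.kernel) // spec.stride + 1
            wo = (ww - spec.kernel) // spec.stride + 1
            if ho < 1 or wo < 1:
                raise ValueError(
                    f"conv{li + 1}: kernel {spec.kernel} does not fit {hh}x{ww}"
                )
            self.convs.append(conv)
            self.conv_bns.append(
                BatchNorm(spec.filters, config.bn_eps, config.bn_momentum,
                          rng=rng, dtype=dtype)
                if use_bn else None
            )
            self.conv_acts.append(Activation(spec.activation))
            hh, ww, ch = ho, wo, spec.filters
            shapes.append((hh, ww, ch))
        self._conv_shapes = shapes
        if len(self.convs) < 2:
            raise ValueError("need at least two conv layers")

        s2 = shapes[-2]
        s3 = shapes[-1]
        self._feat2 = s2[0] * s2[1] * s2[2]
        self._feat3 = s3[0] * s3[1] * s3[2]
        lstm_in = self._feat2 + self._feat3
        self.lstm = LSTM(lstm_in, config.lstm.num_units, rng,
                         forget_bias=config.lstm.forget_bias,
                         activation=config.lstm.activation, dtype=dtype)

        x_dim = 3 * w.sub_len * w.n_sub
        fc1_in = config.lstm.num_units + (x_dim if use_skip else 0)
        self.fc_layers: list[Dense] = []
        self.fc_bns: list[BatchNorm | None] = []
        self.fc_acts: list[Activation | None] = []
        d_in = fc1_in
        for fi, units in enumerate(config.fc_units):
            self.fc_layers.append(Dense(d_in, units, rng, dtype=dtype))
            last = fi == len(config.fc_units) - 1
            self.fc_bns.append(
                BatchNorm(units, config.bn_eps, config.bn_momentum, rng=rng,
                          dtype=dtype)
                if (use_bn and not last) else None
            )
            self.fc_acts.append(None if last else Activation(config.fc_activation))
            d_in = units

        self.layers = [
            lay
            for lay in (
                *self.convs, *self.conv_bns, *self.conv_acts,
                self.lstm, *self.fc_layers, *self.fc_bns, *self.fc_acts,
            )
            if lay is not None
        ]

    # -- plumbing ------------------------------------------------------------

    def conv_shapes(self) -> list[tuple[int, int, int]]:
        """Feature-map shape ledger: input map then each conv layer output."""
        return list(self._conv_shapes)

    def make_inputs(self, examples: ExampleSet) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.ascontiguousarray(examples.maps, dtype=self.dtype),
            np.ascontiguousarray(examples.x, dtype=self.dtype),
        )

    # -- forward / backward --------------------------------------------------

    def forward(self, maps: np.ndarray, x: np.ndarray, training: bool = False,
                trace: bool = False):
        if self.stack is not None:
            lead = maps.shape[:1]  # (M,)
        else:
            lead = ()
        n, s = maps.shape[len(lead) : len(lead) + 2]
        a = maps.reshape(*lead, n * s, *maps.shape[len(lead) + 2 :])
        feats_parts = []
        for li, conv in enumerate(self.convs):
            a = conv.forward(a, training)
            if self.conv_bns[li] is not None:
                a = self.conv_bns[li].forward(a, training)
            a = self.conv_acts[li].forward(a, training)
            if li >= len(self.convs) - 2:
                feats_parts.append(a.reshape(*lead, n * s, -1))
        feats = np.concatenate(feats_parts, axis=-1).reshape(*lead, n, s, -1)
        olstm = self.lstm.forward(feats, training)
        h = skip_concat(olstm, x) if self.use_skip else olstm
        xfc1 = h
        for fi, fc in enumerate(self.fc_layers):
            h = fc.forward(h, training)
            if self.fc_bns[fi] is not None:
                h = self.fc_bns[fi].forward(h, training)
            if self.fc_acts[fi] is not None:
                h = self.fc_acts[fi].forward(h, training)
        if trace:
            probs = softmax(h)
            return ForwardTrace(
                olstm=olstm,
                x=x if self.use_skip else None,
                xFC1=xfc1,
                logits=h,
                probs=probs,
                predicted=predict_class(probs),
            )
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for fi in range(len(self.fc_layers) - 1, -1, -1):
            if self.fc_acts[fi] is not None:
                d = self.fc_acts[fi].backward(d)
            if self.fc_bns[fi] is not None:
                d = self.fc_bns[fi].backward(d)
            d = self.fc_layers[fi].backward(d)
        units = self.config.lstm.num_units
        dolstm = d[..., :units] if self.use_skip else d
        dfeats = self.lstm.backward(dolstm)
        lead = dfeats.shape[:1] if self.stack is not None else ()
        n, s = dfeats.shape[len(lead) : len(lead) + 2]
        dflat = dfeats.reshape(*lead, n * s, -1)
        d2 = dflat[..., : self._feat2]
        d3 = dflat[..., self._feat2 :]

        last = len(self.convs) - 1
        shape3 = self._conv_shapes[last + 1]
        d = self.conv_acts[last].backward(
            np.ascontiguousarray(d3).reshape(*lead, n * s, *shape3)
        )
        if self.conv_bns[last] is not None:
            d = self.conv_bns[last].backward(d)
        d = self.convs[last].backward(d)
        # skip contribution into the penultimate conv output
        d = d + d2.reshape(d.shape)
        for li in range(last - 1, -1, -1):
            d = self.conv_acts[li].backward(d)
            if self.conv_bns[li] is not None:
                d = self.conv_bns[li].backward(d)
            d = self.convs[li].backward(d)

    def forward_trace(self, examples: ExampleSet) -> ForwardTrace:
        maps, x = self.make_inputs(examples)
        return self.forward(maps, x, training=False, trace=True)


class LSTMNet(_ModelBase):
    """Plain recurrent baseline: raw triaxial sequence -> LSTM -> FC head."""

    def __init__(self, config: ModelConfig, stack_seeds=None):
        self.config = config
        self.stack = len(stack_seeds) if stack_seeds is not None else None
        if stack_seeds is not None:
            rng = [np.random.default_rng(s) for s in stack_seeds]
        else:
            rng = np.random.default_rng(config.seed)
        dtype = np.dtype(config.dtype)
        self.dtype = dtype
        self.lstm = LSTM(3, config.lstm.num_units, rng,
                         forget_bias=config.lstm.forget_bias,
                         activation=config.lstm.activation, dtype=dtype)
        hidden = config.fc_units[-2]  # 60 with the default head
        self.fc1 = Dense(config.lstm.num_units, hidden, rng, dtype=dtype)
        self.act1 = Activation(config.fc_activation)
        self.fc2 = Dense(hidden, N_CLASSES, rng, dtype=dtype)
        self.layers = [self.lstm, self.fc1, self.act1, self.fc2]

    def make_inputs(self, examples: ExampleSet) -> tuple[np.ndarray]:
        return (np.ascontiguousarray(examples.sequences, dtype=self.dtype),)

    def forward(self, seq: np.ndarray, training: bool = False, trace: bool = False):
        olstm = self.lstm.forward(seq, training)
        h = self.act1.forward(self.fc1.forward(olstm, training), training)
        logits = self.fc2.forward(h, training)
        if trace:
            probs = softmax(logits)
            return ForwardTrace(
                olstm=olstm, x=None, xFC1=olstm, logits=logits,
                probs=probs, predicted=predict_class(probs),
            )
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc2.backward(dlogits)
        d = self.act1.backward(d)
        d = self.fc1.backward(d)
        self.lstm.backward(d)

    def forward_trace(self, examples: ExampleSet) -> ForwardTrace:
        (seq,) = self.make_inputs(examples)
        return self.forward(seq, training=False, trace=True)


def build_model(variant: str, config: ModelConfig | None = None,
                stack_seeds=None):
    """Instantiate a model variant with seed-controlled initialization.

    ``stack_seeds`` builds a stack of independent replicate models (one per
    seed) that train in lock-step with batched arithmetic; each member is
    initialized exactly as a single model with that seed would be.
    """
    config = config or ModelConfig()
    if variant == "fmsnet":
        model = ConvLSTMNet(config, use_skip=True, use_bn=True,
                            stack_seeds=stack_seeds)
    elif variant == "no_skip":
        model = ConvLSTMNet(config, use_skip=False, use_bn=True,
                            stack_seeds=stack_seeds)
    elif variant == "lstm_cnn":
        model = ConvLSTMNet(config, use_skip=False, use_bn=False,
                            stack_seeds=stack_seeds)
    elif variant == "lstm":
        model = LSTMNet(config, stack_seeds=stack_seeds)
    else:
        raise ValueError(f"unknown variant {variant!r}; options: {VARIANTS}")
    model.variant = variant
    return model
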