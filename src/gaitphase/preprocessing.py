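"""Windowing of labeled recordings into fixed-shape training examples.

A recording is cut into overlapping spans of ``S`` consecutive sub-windows of
``L`` samples each.  Every span yields one example holding

* ``maps`` — S sub-window tensors of shape (rows, cols, 3): each L-sample
  block per axis reshaped row-major into a small 2-D map (default 5x5) with
  the three axes as channels, the CNN input;
* ``x`` — the flattened raw vector of the whole span, length ``3*L*S``,
  ordered ax then ay then az, time-ascending within each axis, the
  skip-connection input;
* a label: the phase code at the span's final sample (causal labeling, the
  phase a real-time controller would need *now*).

No normalization is applied to ``x``; batch-norm layers inside the network
handle scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import AccelRecording

__all__ = ["WindowingSpec", "SplitSpec", "ExampleSet", "build_examples",
           "build_examples_cohort", "split_train_test"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowingSpec:
    """Geometry of the sliding-window segmentation.

    ``sub_len`` samples per sub-window (must equal rows*cols of
    ``map_shape``), ``n_sub`` sub-windows per example, ``stride`` samples
    between consecutive example end points.  Defaults: L=25 (125 ms at
    200 Hz) reshaped to 5x5, S=8 (1 s of context), stride 5.
    """

    sub_len: int = 25
    n_sub: int = 8
    stride: int = 5
    map_shape: tuple[int, int] = (5, 5)

    def __post_init__(self) -> None:
        r, c = self.map_shape
        if self.sub_len != r * c:
            raise ValueError(
                f"sub_len ({self.sub_len}) must equal map rows*cols ({r}*{c})"
            )
        if self.n_sub < 1 or self.stride < 1:
            raise ValueError("n_sub and stride must be >= 1")

    @property
    def span(self) -> int:
        """Samples covered by one example (L*S)."""
        return self.sub_len * self.n_sub


@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition: 70% train by default, window- or subject-level."""

    train_fraction: float = 0.70
    seed: int = 0
    mode: str = "window"  # "window" | "subject"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.mode not in ("window", "subject"):
            raise ValueError(f"mode must be 'window' or 'subject', got {self.mode!r}")


@dataclass
class ExampleSet:
    """A batch of windowed examples.

    ``raw`` stores the untouched span samples, shape (N, L*S, 3) time-major;
    ``maps``, ``x`` and ``sequences`` are derived views for the different
    model inputs, so un-flattening is the identity by construction.
    """

    raw: np.ndarray  # (N, L*S, 3)
    labels: np.ndarray  # (N,)
    spec: WindowingSpec
    subject_ids: np.ndarray = field(default=None)  # (N,) str, optional

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.raw.ndim != 3 or self.raw.shape[2] != 3:
            raise ValueError("raw must have shape (N, span, 3)")
        if self.raw.shape[1] != self.spec.span:
            raise ValueError("raw span does not match windowing spec")
        if len(self.labels) != len(self.raw):
            raise ValueError("labels and raw disagree in length")
        if self.subject_ids is None:
            self.subject_ids = np.array(["s0"] * len(self.raw))
        else:
            self.subject_ids = np.asarray(self.subject_ids)

    def __len__(self) -> int:
        return len(self.raw)

    @property
    def maps(self) -> np.ndarray:
        """(N, S, rows, cols, 3) CNN input maps (row-major reshape per axis)."""
        n = len(self)
        s, (r, c) = self.spec.n_sub, self.spec.map_shape
        return self.raw.reshape(n, s, self.spec.sub_len, 3).reshape(n, s, r, c, 3)

    @property
    def x(self) -> np.ndarray:
        """(N, 3*L*S) flattened raw vector: ax block, then ay, then az."""
        n = len(self)
        return np.concatenate(
            [self.raw[:, :, 0], self.raw[:, :, 1], self.raw[:, :, 2]], axis=1
        ).reshape(n, -1)

    @property
    def sequences(self) -> np.ndarray:
        """(N, L*S, 3) per-timestep triaxial sequence (for the LSTM baseline)."""
        return self.raw

    def subset(self, idx: np.ndarray) -> "ExampleSet":
        return ExampleSet(
            raw=self.raw[idx],
            labels=self.labels[idx],
            spec=self.spec,
            subject_ids=self.subject_ids[idx],
        )

    @staticmethod
    def concatenate(parts: list["ExampleSet"]) -> "ExampleSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        spec = parts[0].spec
        if any(p.spec != spec for p in parts):
            raise ValueError("all parts must share one windowing spec")
        return ExampleSet(
            raw=np.concatenate([p.raw for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            spec=spec,
            subject_ids=np.concatenate([p.subject_ids for p in parts]),
        )


def unflatten_x(x: np.ndarray, spec: WindowingSpec) -> np.ndarray:
    """Inverse of :attr:`ExampleSet.x`: (N, 3*L*S) -> (N, L*S, 3) raw spans."""
    x = np.atleast_2d(x)
    span = spec.span
    return np.stack([x[:, :span], x[:, span : 2 * span], x[:, 2 * span :]], axis=2)


def build_examples(rec: AccelRecording, spec: WindowingSpec | None = None) -> ExampleSet:
    """Slide a span of L*S samples over a recording with the given stride.

    Yields ``floor((T - L*S)/stride) + 1`` examples, each labeled by the
    phase at its final sample.  A recording shorter than one span returns an
    empty set (with a warning logged).
    """
    spec = spec or WindowingSpec()
    t = len(rec)
    span = spec.span
    if t < span:
        logger.warning(
            "recording %s has %d samples, shorter than one span (%d); no examples",
            rec.subject_id, t, span,
        )
        return ExampleSet(
            raw=np.empty((0, span, 3)),
            labels=np.empty(0, dtype=np.int64),
            spec=spec,
            subject_ids=np.empty(0, dtype=object),
        )
    n = (t - span) // spec.stride + 1
    sig = rec.signal  # (T, 3)
    starts = np.arange(n) * spec.stride
    windows = np.lib.stride_tricks.sliding_window_view(sig, span, axis=0)
    raw = windows[starts].transpose(0, 2, 1).copy()  # (N, span, 3)
    labels = rec.labels[starts + span - 1]
    return ExampleSet(
        raw=raw,
        labels=labels,
        spec=spec,
        subject_ids=np.array([rec.subject_id] * n),
    )


def build_examples_cohort(
    recs: list[AccelRecording], spec: WindowingSpec | None = None
) -> ExampleSet:
    """Window each recording independently (never across recording
    boundaries) and pool the examples."""
    spec = spec or WindowingSpec()
    return ExampleSet.concatenate([build_examples(r, spec) for r in recs])


def split_train_test(
    examples: ExampleSet, spec: SplitSpec | None = None
) -> tuple[ExampleSet, ExampleSet]:
    """Partition examples into train/test, |train| = round(fraction * N).

    ``mode="window"`` shuffles examples; ``mode="subject"`` keeps each
    subject wholly on one side (train gets the first subjects of a shuffled
    subject list whose cumulative example count first reaches the target).
    Deterministic for a fixed seed; the two sides are disjoint and
    exhaustive.
    """
    spec = spec or SplitSpec()
    n = len(examples)
    if n < 2:
        raise ValueError("need at least 2 examples to split")
    rng = np.random.default_rng(spec.seed)
    n_train = int(round(spec.train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    if spec.mode == "window":
        perm = rng.permutation(n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
    else:
        # base subject = id up to an optional repeat suffix is NOT collapsed:
        # repeats carry the subject prefix in subject_ids ("s03r1" -> "s03")
        base = np.array([s.split("r")[0] for s in examples.subject_ids])
        subjects = np.unique(base)
        if len(subjects) < 2:
            raise ValueError("subject-level split requires >= 2 subjects")
        order = rng.permutation(subjects)
        counts = {s: int(np.sum(base == s)) for s in subjects}
        train_subjects, acc = [], 0
        for s in order:
            if acc >= n_train or len(train_subjects) == len(subjects) - 1:
                break
            train_subjects.append(s)
            acc += counts[s]
        mask = np.isin(base, train_subjects)
        train_idx, test_idx = np.flatnonzero(mask), np.flatnonzero(~mask)
    return examples.subset(train_idx), examples.subset(test_idx)
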