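"""Mini-batch gradient-descent training on mean cross-entropy."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ..preprocessing import ExampleSet
from .layers import softmax_cross_entropy

__all__ = ["TrainConfig", "TrainResult", "TrainingDivergedError", "train"]

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters: plain SGD at learning rate 0.05 for
    10 000 iterations by default (scaled runs use fewer), batch size 64."""

    lr: float = 0.05
    iterations: int = 10_000
    batch_size: int = 64
    seed: int = 0
    log_every: int = 200


@dataclass
class TrainResult:
    """Loss history as (iteration, mean batch cross-entropy) pairs."""

    losses: list[tuple[int, float]] = field(default_factory=list)

    @property
    def initial_loss(self) -> float:
        return self.losses[0][1]

    @property
    def final_loss(self) -> float:
        return self.losses[-1][1]


def train(
    model,
    examples: ExampleSet,
    cfg: TrainConfig | None = None,
    member_seeds=None,
) -> TrainResult:
    """Train ``model`` in place; deterministic for a fixed ``cfg.seed``.

    Batches are drawn by reshuffling the example order every epoch with a
    seed-derived generator.  A non-finite loss aborts with a diagnostic
    (lower the learning rate, or configure the LSTM with tanh activation —
    relu recurrences can diverge).

    For a stacked replicate model each member draws its own batch order from
    its own generator (seeded by ``member_seeds``, default
    ``cfg.seed + member index``), so members evolve as independent runs that
    merely execute in lock-step.
    """
    cfg = cfg or TrainConfig()
    m = model.stack
    multi = isinstance(examples, (list, tuple))
    if multi and m is None:
        raise ValueError("a list of example sets requires a stacked model")
    if m is not None:
        if member_seeds is None:
            member_seeds = [cfg.seed + j for j in range(m)]
        if len(member_seeds) != m:
            raise ValueError(f"need {m} member seeds, got {len(member_seeds)}")
        rngs = [np.random.default_rng(s) for s in member_seeds]
        sets = list(examples) if multi else [examples] * m
        if len(sets) != m:
            raise ValueError(f"need {m} example sets, got {len(sets)}")
    else:
        rngs = [np.random.default_rng(cfg.seed)]
        sets = [examples]
    sizes = [len(s) for s in sets]
    if min(sizes) == 0:
        raise ValueError("training set is empty")
    bs = min(cfg.batch_size, min(sizes))
    # members sharing one example set share the prepared input arrays
    prepared: dict[int, tuple] = {}
    inputs = []
    for s in sets:
        if id(s) not in prepared:
            prepared[id(s)] = model.make_inputs(s)
        inputs.append(prepared[id(s)])
    labels = [s.labels for s in sets]
    n_inputs = len(inputs[0])
    result = TrainResult()
    orders = [rng.permutation(nj) for rng, nj in zip(rngs, sizes)]
    pos = 0
    for it in range(cfg.iterations):
        if pos + bs > min(sizes):
            orders = [rng.permutation(nj) for rng, nj in zip(rngs, sizes)]
            pos = 0
        idxs = [order[pos : pos + bs] for order in orders]
        pos += bs
        if m is None:
            batch = tuple(a[idxs[0]] for a in inputs[0])
            y = labels[0][idxs[0]]
        else:
            batch = tuple(
                np.stack([inputs[j][ai][idxs[j]] for j in range(m)])
                for ai in range(n_inputs)
            )
            y = np.stack([labels[j][idxs[j]] for j in range(m)])
        logits = model.forward(*batch, training=True)
        loss, _, dlogits = softmax_cross_entropy(logits, y)
        if not math.isfinite(loss):
            raise TrainingDivergedError(
                f"non-finite loss at iteration {it}; try a lower learning rate "
                f"than {cfg.lr} or lstm activation='tanh'"
            )
        if it % cfg.log_every == 0 or it == cfg.iterations - 1:
            result.losses.append((it, loss))
            logger.debug("iter %d: loss %.4f", it, loss)
        model.zero_grad()
        model.backward(dlogits)
        model.sgd_step(cfg.lr)
    return result
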