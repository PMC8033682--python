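"""Training: cross-entropy with optional Outlier Exposure regularization.

The classifier is optimized with Adam on mini-batch cross-entropy over
in-distribution reads. With Outlier Exposure (OE) enabled, every
in-distribution mini-batch is paired with an outlier mini-batch (sampled
with replacement from the outlier set) and the objective gains an auxiliary
term: lambda times the KL divergence from the uniform distribution to the
model's predictive distribution on the outliers,

    L = mean_in CE(g(x), y) + lambda * mean_out KL(U || g(x')).

Pushing outlier predictions toward uniform lowers their max-softmax scores,
which is what makes a softmax threshold separate in- from out-of-
distribution reads. lambda defaults to 0.5; lambda = 0 recovers the plain
cross-entropy objective exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoding import encode_batch
from .nn import (
    ModelConfig,
    ModelParams,
    backward,
    forward,
    init_model,
    zero_grads,
)
from .simulate import LabeledDataset

EPS = 1e-12  # log clamp; numerical safety, bias far below measurement noise


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 10
    oe_lambda: float = 0.5
    oe_enabled: bool = False
    holdout_fraction: float = 0.1
    augment_error_rates: tuple[float, ...] = (0.0, 0.10)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.oe_lambda < 0:
            raise ValueError("oe_lambda must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainResult:
    params: ModelParams
    config: ModelConfig
    loss_trajectory: list[float] = field(default_factory=list)
    holdout_accuracy: list[float] = field(default_factory=list)


def cross_entropy_loss(probabilities: np.ndarray, label: int) -> float:
    """-ln p[label], with p clamped to [EPS, 1]."""
    p = np.asarray(probabilities, dtype=np.float64)
    if not 0 <= label < p.shape[-1]:
        raise IndexError(f"label {label} out of range for {p.shape[-1]} classes")
    return float(-np.log(np.clip(p[label], EPS, 1.0)))


def oe_penalty(Q: np.ndarray) -> float:
    """KL(P || Q) with P uniform over the classes; Q clamped to [EPS, 1]."""
    q = np.clip(np.asarray(Q, dtype=np.float64), EPS, 1.0)
    K = q.shape[-1]
    return float(np.mean(np.log(1.0 / K) - np.log(q)))


def objective_from_probs(
    probs_in: np.ndarray,
    labels: np.ndarray,
    probs_out: np.ndarray | None,
    oe_lambda: float,
) -> float:
    """Mean CE over the in-batch + lambda * mean KL-to-uniform over the out-batch."""
    pin = np.clip(probs_in[np.arange(len(labels)), labels], EPS, 1.0)
    total = float(np.mean(-np.log(pin)))
    if oe_lambda > 0:
        if probs_out is None or len(probs_out) == 0:
            raise ValueError("OE is enabled but the outlier batch is empty")
        K = probs_in.shape[1]
        q = np.clip(probs_out, EPS, 1.0)
        total += oe_lambda * float(np.mean(np.log(1.0 / K) - np.log(q)))
    return total


def total_objective(
    params: ModelParams,
    config: ModelConfig,
    batch_in: tuple[np.ndarray, np.ndarray, np.ndarray],
    batch_out: tuple[np.ndarray, np.ndarray] | None,
    oe_lambda: float,
) -> float:
    """Objective value on encoded batches (eval mode, no dropout).

    batch_in = (tensors, lengths, labels); batch_out = (tensors, lengths)
    or None when OE is disabled.
    """
    tens, lens, labels = batch_in
    probs_in = forward(params, config, tens, lens)
    probs_out = None
    if batch_out is not None and len(batch_out[0]):
        probs_out = forward(params, config, batch_out[0], batch_out[1])
    return objective_from_probs(probs_in, labels, probs_out, oe_lambda)


class _Adam:
    def __init__(self, arrays: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for a, g, m, v in zip(arrays, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            a -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _flat_grads(grads: dict) -> list[np.ndarray]:
    out = []
    for gW, gb in grads["fixed"]:
        out += [gW, gb]
    for gW, gb in grads["multi"]:
        out += [gW, gb]
    out += [grads["Wh"], grads["bh"], grads["Wo"], grads["bo"]]
    return out


def _accuracy(params, config, tens, lens, labels, batch=256) -> float:
    correct = 0
    for i in range(0, len(labels), batch):
        p = forward(params, config, tens[i : i + batch], lens[i : i + batch])
        correct += int(np.sum(p.argmax(axis=1) == labels[i : i + batch]))
    return correct / max(len(labels), 1)


def train(
    model_config: ModelConfig,
    d_in: LabeledDataset,
    d_out: LabeledDataset | None,
    config: TrainConfig,
    params: ModelParams | None = None,
) -> TrainResult:
    """Mini-batch Adam on the (optionally OE-augmented) objective.

    Deterministic given ``config.seed`` (init, shuffling, dropout and
    outlier sampling all derive from it). Raises if any class has no
    training read, or if OE is enabled without outliers.
    """
    labels = d_in.labels()
    K = model_config.n_classes
    present = set(labels.tolist())
    missing = [k for k in range(K) if k not in present]
    if missing:
        raise ValueError(f"classes missing from training data: {missing}")
    if config.oe_enabled and (d_out is None or len(d_out) == 0):
        raise ValueError("OE is enabled but no outlier dataset was given")

    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_model(model_config, seed=config.seed)

    tens, lens = encode_batch(d_in.sequences(), model_config.window)
    n = len(labels)
    n_hold = int(round(config.holdout_fraction * n))
    order = rng.permutation(n)
    hold_idx, train_idx = order[:n_hold], order[n_hold:]

    out_tens = out_lens = None
    if config.oe_enabled:
        out_tens, out_lens = encode_batch(
            d_out.sequences(), model_config.window
        )

    arrays = params.flat()
    opt = _Adam(arrays, config.learning_rate)
    result = TrainResult(params, model_config)

    for _epoch in range(config.epochs):
        perm = rng.permutation(len(train_idx))
        epoch_losses = []
        for s in range(0, len(perm), config.batch_size):
            bi = train_idx[perm[s : s + config.batch_size]]
            bt, bl, by = tens[bi], lens[bi], labels[bi]
            grads = zero_grads(params)
            probs, cache = forward(
                params, model_config, bt, bl,
                train=True, dropout_rng=rng, return_cache=True,
            )
            B = len(bi)
            onehot = np.zeros_like(probs)
            onehot[np.arange(B), by] = 1.0
            backward(params, model_config, cache, (probs - onehot) / B, grads)
            loss = objective_from_probs(probs, by, None, 0.0)

            if config.oe_enabled and config.oe_lambda > 0:
                oi = rng.integers(0, len(out_tens), size=B)
                q, qcache = forward(
                    params, model_config, out_tens[oi], out_lens[oi],
                    train=True, dropout_rng=rng, return_cache=True,
                )
                dl = config.oe_lambda * (q - 1.0 / K) / B
                backward(params, model_config, qcache, dl, grads)
                loss += config.oe_lambda * float(
                    np.mean(np.log(1.0 / K) - np.log(np.clip(q, EPS, 1.0)))
                )
            opt.step(arrays, _flat_grads(grads))
            epoch_losses.append(loss)
        result.loss_trajectory.append(float(np.mean(epoch_losses)))
        if len(hold_idx):
            acc = _accuracy(
                params, model_config,
                tens[hold_idx], lens[hold_idx], labels[hold_idx],
            )
        else:
            acc = float("nan")
        result.holdout_accuracy.append(acc)
    return result
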