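"""Per-fold optimization: cross-entropy + Adam with elementwise gradient
clipping, teacher-forced previous-stage inputs, and top-fraction checkpoint
selection ranked by validation macro-F1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataio import Recording
from .inference import sequential_infer
from .metrics import compute_metrics
from .network import ModelConfig, SleepStageModel, uniform_stage_vector
from .stages import N_STAGES


@dataclass
class TrainConfig:
    batch_size: int = 64
    n_epochs: int = 70
    learning_rate: float = 1e-4
    grad_clip_value: float = 0.1
    seed: int = 0
    checkpoint_fraction: float = 0.10
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_epsilon: float = 1e-8
    class_weights: np.ndarray | None = None  # off by default

    def __post_init__(self):
        if self.batch_size < 1 or self.n_epochs < 1:
            raise ValueError("batch_size and n_epochs must be positive")
        if self.learning_rate <= 0 or self.grad_clip_value <= 0:
            raise ValueError("learning_rate and grad_clip_value must be positive")
        if not 0 < self.checkpoint_fraction <= 1:
            raise ValueError("checkpoint_fraction must be in (0, 1]")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_accuracy: float
    val_mf1: float
    checkpoint_id: int


@dataclass
class TrainHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def cross_entropy_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """-log probability of the true class; probabilities clipped away from 0."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.clip(np.asarray(y_hat, dtype=np.float64), 1e-12, None)
    if y.ndim == 1:
        return float(-(y * np.log(y_hat)).sum())
    return float(-(y * np.log(y_hat)).sum(axis=1).mean())


def clip_gradients(grads: dict[str, np.ndarray], clip_value: float) -> dict[str, np.ndarray]:
    """Elementwise clipping of every gradient component to [-clip, +clip]."""
    return {k: np.clip(g, -clip_value, clip_value) for k, g in grads.items()}


class AdamOptimizer:
    """Standard Adam with bias correction; state keyed like the param dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, epsilon: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.epsilon = beta1, beta2, epsilon
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.epsilon)


def build_training_arrays(recordings: list[Recording]):
    """Flatten recordings into (X, prev_onehot, y) with teacher forcing.

    The first epoch of every recording gets the uniform previous-stage vector;
    later epochs get the one-hot ground truth of their predecessor.
    """
    if not recordings:
        raise ValueError("empty training set")
    xs, prevs, ys = [], [], []
    for rec in recordings:
        n = rec.n_epochs
        prev = np.zeros((n, N_STAGES))
        prev[0] = uniform_stage_vector()
        if n > 1:
            prev[np.arange(1, n), rec.labels[:-1]] = 1.0
        xs.append(rec.epochs)
        prevs.append(prev)
        ys.append(rec.labels)
    return np.concatenate(xs), np.concatenate(prevs), np.concatenate(ys)


def select_checkpoints(history: TrainHistory, fraction: float = 0.10) -> list[int]:
    """Top ceil(fraction * n) checkpoint ids by validation MF1, ties -> later epoch."""
    if not history.records:
        raise ValueError("empty training history")
    k = math.ceil(fraction * len(history.records))
    ranked = sorted(history.records, key=lambda r: (r.val_mf1, r.epoch), reverse=True)
    return [r.checkpoint_id for r in ranked[:k]]


def train_fold(
    train_recordings: list[Recording],
    val_recording: Recording,
    model_config: ModelConfig,
    train_config: TrainConfig,
    callback=None,
) -> tuple[SleepStageModel, TrainHistory, list[dict]]:
    """Train one LOSO fold; returns the model, history and one snapshot per epoch."""
    X, prev, y_int = build_training_arrays(train_recordings)
    n = len(y_int)
    y = np.zeros((n, N_STAGES))
    y[np.arange(n), y_int] = 1.0
    if train_config.class_weights is not None:
        sample_w = np.asarray(train_config.class_weights)[y_int]
    else:
        sample_w = None

    model = SleepStageModel(model_config)
    opt = AdamOptimizer(
        model.params, train_config.learning_rate,
        train_config.adam_beta1, train_config.adam_beta2, train_config.adam_epsilon,
    )
    rng = np.random.default_rng(train_config.seed)
    history = TrainHistory()
    checkpoints: list[dict] = []
    bs = train_config.batch_size
    for epoch in range(train_config.n_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            cache: dict = {}
            probs = model.forward(X[idx], prev[idx], train=True, rng=rng, cache_out=cache)
            yb = y[idx]
            if sample_w is not None:
                yb = yb * sample_w[idx][:, None]
            losses.append(cross_entropy_loss(y[idx], probs))
            grads = model.backward(cache, yb)
            grads = clip_gradients(grads, train_config.grad_clip_value)
            opt.step(model.params, grads)
        trace = sequential_infer(val_recording, model)
        report = compute_metrics(val_recording.labels, trace.stages)
        checkpoints.append(model.snapshot())
        rec = EpochRecord(
            epoch=epoch,
            train_loss=float(np.mean(losses)),
            val_accuracy=report.accuracy,
            val_mf1=report.macro_f1,
            checkpoint_id=epoch,
        )
        history.records.append(rec)
        if callback is not None:
            callback(rec)
    return model, history, checkpoints
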