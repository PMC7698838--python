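"""Sequential decoding with previous-stage feedback, checkpoint ensembling,
and the decision-level fusion baselines (vote / maximum posterior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stages import N_STAGES


@dataclass
class PredictionTrace:
    """Per-epoch probabilities, hard stages and attention weights."""

    probs: np.ndarray  # (n_epochs, 5)
    stages: np.ndarray  # (n_epochs,)
    alphas: np.ndarray | None = None  # (n_epochs, C) when attention is active

    def __len__(self) -> int:
        return len(self.stages)


def sequential_infer(rec, model, initial_prev: np.ndarray | None = None) -> PredictionTrace:
    """Decode a recording epoch by epoch, feeding each output probability
    vector into the next epoch's refinement input.

    Branch features and attention weights do not depend on the previous-stage
    input, so they are computed once in a batch; only the classifier head runs
    sequentially. ``initial_prev`` overrides the uniform first-epoch vector,
    which lets a decode be resumed from any cut point.
    """
    from .network import uniform_stage_vector  # local import avoids cycle

    cfg = model.config
    x = rec.epochs
    n = x.shape[0]
    fused, _, alpha = model._fuse_forward(x, train=False, cache=None)
    logits_f = fused @ model.params["cls.Wf"].T + model.params["cls.b"]
    probs = np.empty((n, N_STAGES))
    if cfg.use_refinement:
        E, eb = model.params["enc.E"], model.params["enc.b"]
        Wc = model.params["cls.Wc"]
        prev = uniform_stage_vector() if initial_prev is None else np.asarray(initial_prev)
        for t in range(n):
            v_c = E @ prev + eb
            logit = logits_f[t] + Wc @ v_c
            logit = logit - logit.max()
            e = np.exp(logit)
            probs[t] = e / e.sum()
            prev = probs[t]
    else:
        z = logits_f - logits_f.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs[:] = e / e.sum(axis=1, keepdims=True)
    stages = probs.argmax(axis=1)
    return PredictionTrace(probs=probs, stages=stages, alphas=alpha)


def ensemble_predict(traces: list[PredictionTrace]) -> np.ndarray:
    """Maximum-likelihood ensemble: per-epoch product of model probabilities
    (sum of logs), argmax with ties resolved to the lowest stage index.
    """
    if not traces:
        raise ValueError("need at least one trace")
    n = len(traces[0])
    if any(len(t) != n for t in traces):
        raise ValueError("traces have mismatched lengths")
    log_sum = np.zeros((n, N_STAGES))
    for t in traces:
        log_sum += np.log(np.clip(t.probs, 1e-12, None))
    return log_sum.argmax(axis=1)


def decision_fusion(per_channel_traces: list[PredictionTrace], mode: str) -> np.ndarray:
    """Fuse independent per-channel classifiers at the decision level.

    vote: per-epoch plurality over channel argmaxes; map: argmax of the
    product of channel probability vectors. Ties -> lowest stage index.
    """
    if not per_channel_traces:
        raise ValueError("need at least one trace")
    n = len(per_channel_traces[0])
    if any(len(t) != n for t in per_channel_traces):
        raise ValueError("traces have mismatched lengths")
    if mode == "vote":
        votes = np.stack([t.stages for t in per_channel_traces], axis=1)
        out = np.empty(n, dtype=np.int64)
        for t in range(n):
            out[t] = np.bincount(votes[t], minlength=N_STAGES).argmax()
        return out
    if mode == "map":
        return ensemble_predict(per_channel_traces)
    raise ValueError(f"unknown decision fusion mode {mode!r}")
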