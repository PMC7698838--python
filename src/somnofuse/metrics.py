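"""Evaluation: confusion matrix, accuracy, macro-F1, Cohen's kappa, per-stage
precision/recall/F1, and the transition/nontransition stratification.

Accuracy and F1-style metrics are reported as percentages (one decimal when
formatted); kappa stays unitless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stages import N_STAGES, STAGE_NAMES, validate_hypnogram


def mark_transitions(hyp: np.ndarray) -> np.ndarray:
    """True where an epoch's stage differs from either neighbour's.

    Boundary epochs compare only to the neighbour that exists.
    """
    hyp = validate_hypnogram(hyp)
    n = len(hyp)
    if n == 0:
        raise ValueError("empty hypnogram")
    mask = np.zeros(n, dtype=bool)
    if n == 1:
        return mask
    diff_prev = hyp[1:] != hyp[:-1]
    mask[1:] |= diff_prev
    mask[:-1] |= diff_prev
    return mask


@dataclass
class StageScores:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class MetricsReport:
    confusion: np.ndarray  # (5, 5), rows = truth, cols = prediction
    accuracy: float  # percent
    macro_f1: float  # percent
    kappa: float
    per_stage: dict[str, StageScores] = field(default_factory=dict)
    n: int = 0

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy": round(self.accuracy, 1),
            "macro_f1": round(self.macro_f1, 1),
            "kappa": round(self.kappa, 2),
            "confusion": self.confusion.tolist(),
            "per_stage": {
                name: {
                    "precision": round(s.precision, 1),
                    "recall": round(s.recall, 1),
                    "f1": round(s.f1, 1),
                    "support": s.support,
                }
                for name, s in self.per_stage.items()
            },
        }

    def format_table(self) -> str:
        lines = [
            f"n = {self.n}",
            f"accuracy  {self.accuracy:5.1f}",
            f"macro F1  {self.macro_f1:5.1f}",
            f"kappa     {self.kappa:5.2f}",
            f"{'stage':<6}{'prec':>7}{'rec':>7}{'f1':>7}{'n':>7}",
        ]
        for name, s in self.per_stage.items():
            lines.append(f"{name:<6}{s.precision:7.1f}{s.recall:7.1f}{s.f1:7.1f}{s.support:7d}")
        return "\n".join(lines)


def confusion_matrix(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    cm = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    np.add.at(cm, (truth, pred), 1)
    return cm


def compute_metrics(
    truth: np.ndarray, pred: np.ndarray, mask: np.ndarray | None = None
) -> MetricsReport:
    """Standard confusion-matrix metrics over (optionally masked) epochs.

    Macro-F1 averages only over stages present in the truth of the selection.
    Kappa uses the marginal-product chance agreement.
    """
    truth = validate_hypnogram(truth)
    pred = validate_hypnogram(pred)
    if len(truth) != len(pred):
        raise ValueError("truth and prediction lengths differ")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if len(mask) != len(truth):
            raise ValueError("mask length differs from hypnogram length")
        truth, pred = truth[mask], pred[mask]
    n = len(truth)
    if n == 0:
        raise ValueError("empty evaluation selection")
    cm = confusion_matrix(truth, pred)
    accuracy = 100.0 * np.trace(cm) / n

    per_stage: dict[str, StageScores] = {}
    f1s = []
    for k in range(N_STAGES):
        tp = cm[k, k]
        support = int(cm[k].sum())
        pred_k = int(cm[:, k].sum())
        precision = 100.0 * tp / pred_k if pred_k else 0.0
        recall = 100.0 * tp / support if support else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        per_stage[STAGE_NAMES[k]] = StageScores(precision, recall, f1, support)
        if support:
            f1s.append(f1)
    macro_f1 = float(np.mean(f1s)) if f1s else 0.0

    p_o = np.trace(cm) / n
    p_e = float((cm.sum(axis=1) / n) @ (cm.sum(axis=0) / n))
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0

    return MetricsReport(
        confusion=cm, accuracy=float(accuracy), macro_f1=macro_f1,
        kappa=float(kappa), per_stage=per_stage, n=n,
    )


def compute_split_metrics(truth: np.ndarray, pred: np.ndarray) -> dict[str, MetricsReport]:
    """Overall plus transition / nontransition stratified reports."""
    t_mask = mark_transitions(truth)
    out = {"overall": compute_metrics(truth, pred)}
    if t_mask.any():
        out["transition"] = compute_metrics(truth, pred, t_mask)
    if (~t_mask).any():
        out["nontransition"] = compute_metrics(truth, pred, ~t_mask)
    return out


def pool_folds(fold_results: list[tuple[np.ndarray, np.ndarray]]) -> MetricsReport:
    """Pool raw epoch-level (truth, pred) pairs across folds, then score once."""
    if not fold_results:
        raise ValueError("no folds to pool")
    truth = np.concatenate([validate_hypnogram(t) for t, _ in fold_results])
    pred = np.concatenate([validate_hypnogram(p) for _, p in fold_results])
    return compute_metrics(truth, pred)
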