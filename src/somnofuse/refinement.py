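"""Post-hoc hypnogram refinement baselines.

Two methods: (1) expert-rule smoothing over stage triples with a global
positional rule for pre-N2 REM epochs, and (2) a discrete HMM whose
transition/emission tables are fitted by frequency counting on validation
(truth, prediction) pairs and decoded with Viterbi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stages import N1, N2, N_STAGES, REM, W, validate_hypnogram

# triple rules: (left, middle, right) pattern with None as wildcard -> new middle
TRIPLE_RULES = (
    ((W, REM, N2), N1),    # rule 2
    ((N1, REM, N2), N1),   # rule 3
    ((N2, None, N2), N2),  # rule 4
    ((REM, None, REM), REM),  # rule 5
)


def apply_rules(hyp: np.ndarray) -> np.ndarray:
    """Expert-rule smoothing, applied deterministically.

    Rule 1 first: every REM epoch strictly before the first appearance of N2
    becomes N1 (without any N2 the rule has no anchor and is skipped). Then
    each triple rule runs as one full left-to-right in-place pass with
    stride 1, so rewrites can cascade.
    """
    out = validate_hypnogram(hyp).copy()
    n2_pos = np.where(out == N2)[0]
    cutoff = n2_pos[0] if len(n2_pos) else 0
    early_rem = (out[:cutoff] == REM)
    out[:cutoff][early_rem] = N1
    for (left, mid, right), new_mid in TRIPLE_RULES:
        for t in range(1, len(out) - 1):
            if out[t - 1] == left and out[t + 1] == right and (mid is None or out[t] == mid):
                out[t] = new_mid
    return out


@dataclass
class HMMParams:
    """Discrete HMM over the 5 stages: hidden truth emits observed predictions."""

    A: np.ndarray  # (5, 5) transition
    B: np.ndarray  # (5, 5) emission, hidden -> observed
    pi: np.ndarray  # (5,) initial

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        for name, arr in (("A", self.A), ("B", self.B)):
            if arr.shape != (N_STAGES, N_STAGES):
                raise ValueError(f"{name} must be 5x5")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"rows of {name} must sum to 1")
        if self.pi.shape != (N_STAGES,) or not np.isclose(self.pi.sum(), 1.0, atol=1e-9):
            raise ValueError("pi must be a length-5 distribution")


def _as_sequences(seqs) -> list[np.ndarray]:
    if isinstance(seqs, np.ndarray) or (seqs and np.isscalar(seqs[0])):
        return [validate_hypnogram(np.asarray(seqs))]
    return [validate_hypnogram(np.asarray(s)) for s in seqs]


def fit_hmm(truth, observed, smoothing: float = 1.0) -> HMMParams:
    """Frequency-count HMM fit on aligned (truth, observed) stage sequences.

    Accepts single sequences or lists of per-recording sequences; transition
    counts never cross recording boundaries. ``smoothing`` is a Laplace
    pseudo-count keeping every probability positive.
    """
    t_seqs = _as_sequences(truth)
    o_seqs = _as_sequences(observed)
    if len(t_seqs) != len(o_seqs):
        raise ValueError("truth and observed must have the same number of sequences")
    A = np.full((N_STAGES, N_STAGES), smoothing, dtype=float)
    B = np.full((N_STAGES, N_STAGES), smoothing, dtype=float)
    pi = np.full(N_STAGES, smoothing, dtype=float)
    total = 0
    for t_seq, o_seq in zip(t_seqs, o_seqs):
        if len(t_seq) != len(o_seq):
            raise ValueError("truth/observed length mismatch")
        total += len(t_seq)
        np.add.at(A, (t_seq[:-1], t_seq[1:]), 1)
        np.add.at(B, (t_seq, o_seq), 1)
        np.add.at(pi, t_seq, 1)
    if total < 2:
        raise ValueError("need at least 2 aligned epochs to fit an HMM")
    A /= A.sum(axis=1, keepdims=True)
    B /= B.sum(axis=1, keepdims=True)
    pi /= pi.sum()
    return HMMParams(A=A, B=B, pi=pi)


def viterbi_decode(observed: np.ndarray, params: HMMParams) -> np.ndarray:
    """Most probable hidden stage sequence in log space; ties -> lowest index."""
    obs = validate_hypnogram(observed)
    n = len(obs)
    if n == 0:
        return obs.copy()
    with np.errstate(divide="ignore"):
        logA = np.log(params.A)
        logB = np.log(params.B)
        logpi = np.log(params.pi)
    delta = logpi + logB[:, obs[0]]
    back = np.zeros((n, N_STAGES), dtype=np.int64)
    for t in range(1, n):
        scores = delta[:, None] + logA  # (from, to)
        back[t] = scores.argmax(axis=0)  # argmax takes the lowest index on ties
        delta = scores[back[t], np.arange(N_STAGES)] + logB[:, obs[t]]
    path = np.empty(n, dtype=np.int64)
    path[-1] = int(delta.argmax())
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def hmm_refine(
    test_observed: np.ndarray,
    val_truth,
    val_observed,
    smoothing: float = 1.0,
) -> np.ndarray:
    """Fit on validation (truth, prediction) pairs, Viterbi-decode the test run."""
    params = fit_hmm(val_truth, val_observed, smoothing=smoothing)
    return viterbi_decode(test_observed, params)
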