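"""Canonical 5-class stage coding used everywhere in the package.

Integer codes are fixed: W=0, N1=1, N2=2, N3=3, REM=4. Tie-breaking rules
elsewhere (argmax over probabilities, plurality votes, Viterbi backtracking)
resolve toward the lowest stage index, i.e. W < N1 < N2 < N3 < REM.
"""

from __future__ import annotations

import numpy as np

N_STAGES = 5

W, N1, N2, N3, REM = range(N_STAGES)

STAGE_NAMES = ("W", "N1", "N2", "N3", "REM")

STAGE_TO_INDEX = {name: i for i, name in enumerate(STAGE_NAMES)}


def validate_hypnogram(stages: np.ndarray) -> np.ndarray:
    """Return ``stages`` as a 1-D int array, checking all codes are in 0..4."""
    arr = np.asarray(stages)
    if arr.ndim != 1:
        raise ValueError(f"hypnogram must be 1-D, got shape {arr.shape}")
    arr = arr.astype(np.int64)
    if arr.size and (arr.min() < 0 or arr.max() >= N_STAGES):
        bad = sorted(set(arr[(arr < 0) | (arr >= N_STAGES)].tolist()))
        raise ValueError(f"hypnogram contains out-of-range stage codes: {bad}")
    return arr


def stages_to_names(stages: np.ndarray) -> list[str]:
    return [STAGE_NAMES[s] for s in validate_hypnogram(stages)]


def names_to_stages(names) -> np.ndarray:
    out = np.empty(len(names), dtype=np.int64)
    for i, name in enumerate(names):
        key = str(name).strip()
        if key not in STAGE_TO_INDEX:
            raise ValueError(f"unknown stage label {key!r}")
        out[i] = STAGE_TO_INDEX[key]
    return out
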