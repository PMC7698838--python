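"""Recording container, preprocessing, text I/O and LOSO split planning.

Preprocessing follows the standard pipeline for 30-s epoch sleep scoring:
merge the R&K N4 stage into N3, z-score each channel over the whole
recording, resample channels to a common rate, and cut the continuous
signal into fixed-length epochs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .stages import (
    N3,
    STAGE_TO_INDEX,
    names_to_stages,
    stages_to_names,
    validate_hypnogram,
)

logger = logging.getLogger(__name__)

# R&K 6-stage label set plus common unscored markers
RK_MAP = {
    "W": 0,
    "N1": 1,
    "N2": 2,
    "N3": 3,
    "N4": N3,  # merged into N3 (slow-wave sleep)
    "REM": 4,
}
UNSCORED = {"?", "MOVEMENT", "UNSCORED", "M"}


@dataclass
class Recording:
    """One night of epoched multi-channel signal plus per-epoch labels."""

    subject_id: str
    epochs: np.ndarray  # [n_epochs, samples_per_epoch, n_channels]
    labels: np.ndarray  # [n_epochs] int codes 0..4
    channels: tuple[str, ...]
    sampling_rate: float
    night_id: str = "1"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = validate_hypnogram(self.labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be [n_epochs, samples, channels]")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError(
                f"label count {len(self.labels)} != epoch count {self.epochs.shape[0]}"
            )
        if self.epochs.shape[2] != len(self.channels):
            raise ValueError("channel name count must match epoch channel axis")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def merge_rk_stages(raw_labels, signal_mask_out: list | None = None) -> np.ndarray:
    """Map R&K 6-stage labels to the 5-class coding, dropping unscored epochs.

    ``signal_mask_out``, if given, receives a boolean keep-mask so callers can
    drop the matching signal epochs.
    """
    keep = []
    out = []
    for lab in raw_labels:
        key = str(lab).strip().upper()
        if key in UNSCORED:
            keep.append(False)
            continue
        if key not in RK_MAP:
            raise ValueError(f"unknown stage label {lab!r}")
        keep.append(True)
        out.append(RK_MAP[key])
    if signal_mask_out is not None:
        signal_mask_out.extend(keep)
    return np.asarray(out, dtype=np.int64)


def zscore_per_channel(rec: Recording) -> Recording:
    """Standardize each channel to zero mean / unit sd over the recording."""
    x = rec.epochs
    flat = x.reshape(-1, x.shape[2])
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    degenerate = np.where(sd < 1e-12)[0]
    if degenerate.size:
        names = [rec.channels[i] for i in degenerate]
        raise ValueError(f"zero-variance channel(s): {names}")
    z = (x - mean[None, None, :]) / sd[None, None, :]
    return replace(rec, epochs=z)


def resample_channel(
    signal: np.ndarray, from_rate: float, to_rate: float, method: str = "linear"
) -> np.ndarray:
    """Resample a 1-D series by linear interpolation (or zero-order hold)."""
    if from_rate <= 0 or to_rate <= 0:
        raise ValueError("rates must be > 0")
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("expected a 1-D series")
    if from_rate == to_rate:
        return signal.copy()
    if to_rate < from_rate:
        logger.info("decimating from %g Hz to %g Hz via interpolation", from_rate, to_rate)
    n_out = int(round(len(signal) * to_rate / from_rate))
    t_in = np.arange(len(signal)) / from_rate
    t_out = np.arange(n_out) / to_rate
    if method == "linear":
        return np.interp(t_out, t_in, signal)
    if method == "hold":
        idx = np.minimum((t_out * from_rate).astype(np.int64), len(signal) - 1)
        return signal[idx]
    raise ValueError(f"unknown resampling method {method!r}")


def epoch_signals(continuous: np.ndarray, rate: float, epoch_seconds: float = 30.0) -> np.ndarray:
    """Cut a [samples, channels] series into [n_epochs, samples_per_epoch, channels].

    A trailing partial epoch is dropped.
    """
    continuous = np.asarray(continuous, dtype=np.float64)
    if continuous.ndim == 1:
        continuous = continuous[:, None]
    if continuous.ndim != 2:
        raise ValueError("continuous signal must be [samples] or [samples, channels]")
    spe = int(round(rate * epoch_seconds))
    n_epochs = continuous.shape[0] // spe
    if n_epochs < 1:
        raise ValueError(
            f"need at least {spe} samples for one epoch, got {continuous.shape[0]}"
        )
    trimmed = continuous[: n_epochs * spe]
    return trimmed.reshape(n_epochs, spe, continuous.shape[1])


@dataclass
class SplitPlan:
    """Leave-one-subject-out folds: (train_subjects, val_subject, test_subject)."""

    folds: list[tuple[tuple[str, ...], str, str]]


def make_loso_splits(subjects: list[str]) -> SplitPlan:
    """One fold per subject as test; the cyclic successor validates."""
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects for leave-one-subject-out")
    if len(set(subjects)) != len(subjects):
        raise ValueError("subject ids must be unique")
    folds = []
    n = len(subjects)
    for i, test in enumerate(subjects):
        val = subjects[(i + 1) % n]
        train = tuple(s for s in subjects if s not in (test, val))
        folds.append((train, val, test))
    return SplitPlan(folds=folds)


# ----------------------------------------------------------------------------
# Plain-text recording format: one CSV of samples (columns = channels) plus a
# hypnogram text file (one label per line) and a JSON metadata sidecar.
# ----------------------------------------------------------------------------


def write_recording(rec: Recording, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{rec.subject_id}_{rec.night_id}"
    flat = rec.epochs.reshape(-1, rec.epochs.shape[2])
    header = ",".join(rec.channels)
    np.savetxt(directory / f"{stem}_signals.csv", flat, delimiter=",",
               header=header, comments="", fmt="%.10g")
    (directory / f"{stem}_hypnogram.txt").write_text(
        "\n".join(stages_to_names(rec.labels)) + "\n"
    )
    meta = {
        "subject_id": rec.subject_id,
        "night_id": rec.night_id,
        "sampling_rate": rec.sampling_rate,
        "samples_per_epoch": int(rec.epochs.shape[1]),
        "channels": list(rec.channels),
    }
    (directory / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2))


def read_recording(directory: str | Path, subject_id: str, night_id: str = "1") -> Recording:
    directory = Path(directory)
    stem = f"{subject_id}_{night_id}"
    meta = json.loads((directory / f"{stem}_meta.json").read_text())
    flat = np.loadtxt(directory / f"{stem}_signals.csv", delimiter=",", skiprows=1, ndmin=2)
    labels = names_to_stages(
        (directory / f"{stem}_hypnogram.txt").read_text().split()
    )
    spe = meta["samples_per_epoch"]
    epochs = flat.reshape(-1, spe, len(meta["channels"]))
    return Recording(
        subject_id=meta["subject_id"],
        night_id=meta["night_id"],
        epochs=epochs,
        labels=labels,
        channels=tuple(meta["channels"]),
        sampling_rate=meta["sampling_rate"],
    )


def read_hypnogram_file(path: str | Path) -> np.ndarray:
    """Read a one-label-per-line hypnogram (names or integer codes)."""
    tokens = Path(path).read_text().split()
    if all(tok in STAGE_TO_INDEX for tok in tokens):
        return names_to_stages(tokens)
    return validate_hypnogram(np.array([int(t) for t in tokens]))


def write_hypnogram_file(path: str | Path, stages: np.ndarray) -> None:
    Path(path).write_text("\n".join(stages_to_names(stages)) + "\n")
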