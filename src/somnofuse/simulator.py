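"""Synthetic polysomnography: Markov hypnograms + stage-conditioned signals.

Hypnograms are drawn from a first-order Markov chain with strong sleep
continuity (diagonal-dominant transition matrix). Signals are synthesized per
30-s epoch as a sum of band-limited Gaussian noise components whose relative
band powers depend on the current stage and the channel role (EEG/EOG/EMG),
plus white observation noise. Channels listed as uninformative carry white
noise only, which gives a controlled probe for attention-weight behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .stages import N_STAGES, REM, STAGE_NAMES, N1, N2, N3, W, validate_hypnogram


@dataclass
class StageProfile:
    """Spectral signature of one sleep stage for one channel role.

    ``band_powers`` maps (low_hz, high_hz) intervals to relative power;
    ``amplitude_scale`` multiplies the whole channel for this stage.
    """

    stage: int
    band_powers: dict[tuple[float, float], float]
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.stage < N_STAGES):
            raise ValueError(f"stage code {self.stage} out of range")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be > 0")
        if not self.band_powers:
            raise ValueError("band_powers must be non-empty")
        for (lo, hi), p in self.band_powers.items():
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}) must have low < high")
            if p < 0:
                raise ValueError("band powers must be >= 0")
        if not any(p > 0 for p in self.band_powers.values()):
            raise ValueError("at least one band must have power > 0")


@dataclass
class TransitionModel:
    """First-order Markov model over the 5 stages."""

    matrix: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.matrix.shape != (N_STAGES, N_STAGES):
            raise ValueError("transition matrix must be 5x5")
        if self.initial.shape != (N_STAGES,):
            raise ValueError("initial distribution must have length 5")
        if (self.matrix < 0).any() or (self.initial < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        vals, vecs = np.linalg.eig(self.matrix.T)
        idx = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()


@dataclass
class SimConfig:
    """Knobs for one synthetic dataset."""

    n_subjects: int = 6
    epochs_per_subject: int = 300
    sampling_rate: float = 100.0
    epoch_seconds: float = 30.0
    channels: tuple[str, ...] = ("EEG Fpz-Cz", "EEG Pz-Oz", "EOG", "EMG")
    channel_roles: tuple[str, ...] = ("EEG", "EEG", "EOG", "EMG")
    noise_sigma: float = 0.5
    uninformative_channels: tuple[str, ...] = ()
    amplitude_jitter: float = 0.10  # per-subject multiplicative jitter, 0 disables
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("channels must be non-empty")
        if len(self.channel_roles) != len(self.channels):
            raise ValueError("channel_roles must match channels")
        n = self.epoch_seconds * self.sampling_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_seconds * sampling_rate must be an integer")
        unknown = set(self.uninformative_channels) - set(self.channels)
        if unknown:
            raise ValueError(f"uninformative_channels not in channels: {sorted(unknown)}")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_seconds * self.sampling_rate))


def default_transition_model(diagonal: float = 0.85) -> TransitionModel:
    """Diagonal-dominant stage transition model with plausible structure.

    Off-diagonal mass favours physiologically adjacent moves (W<->N1, N1->N2,
    N2<->N3, N2->REM, REM->N1/W); `diagonal` sets the self-transition mass.
    """
    if not 0.0 <= diagonal < 1.0:
        raise ValueError("diagonal must be in [0, 1)")
    # relative off-diagonal affinities, row = from-stage
    off = np.array(
        [
            # W     N1    N2    N3    REM
            [0.0, 0.70, 0.15, 0.05, 0.10],  # W
            [0.25, 0.0, 0.55, 0.05, 0.15],  # N1
            [0.10, 0.20, 0.0, 0.45, 0.25],  # N2
            [0.05, 0.10, 0.75, 0.0, 0.10],  # N3
            [0.20, 0.40, 0.30, 0.10, 0.0],  # REM
        ]
    )
    off = off / off.sum(axis=1, keepdims=True) * (1.0 - diagonal)
    matrix = off + np.eye(N_STAGES) * diagonal
    initial = np.array([0.6, 0.2, 0.1, 0.05, 0.05])
    return TransitionModel(matrix=matrix, initial=initial)


def default_profiles() -> dict[str, dict[int, StageProfile]]:
    """Default stage signatures per channel role.

    W: alpha-band EEG and high EMG tone; N1: theta EEG; N2: theta background
    with sigma-band (spindle-frequency) energy; N3: high-amplitude delta;
    REM: low-amplitude broadband EEG, minimal EMG, large slow EOG deflections.
    """
    delta, theta, alpha, sigma = (0.5, 4.0), (4.0, 8.0), (8.0, 12.0), (12.0, 14.0)
    broad = (0.5, 14.0)
    eog_slow, emg_band = (0.3, 2.0), (5.0, 14.0)
    eeg = {
        W: StageProfile(W, {alpha: 1.0, broad: 0.3}),
        N1: StageProfile(N1, {theta: 1.0, broad: 0.3}),
        N2: StageProfile(N2, {theta: 0.8, sigma: 0.8, broad: 0.2}),
        N3: StageProfile(N3, {delta: 1.0, broad: 0.15}, amplitude_scale=2.0),
        REM: StageProfile(REM, {broad: 1.0}, amplitude_scale=0.7),
    }
    eog = {
        W: StageProfile(W, {eog_slow: 0.6, broad: 0.4}),
        N1: StageProfile(N1, {eog_slow: 0.8, broad: 0.3}),
        N2: StageProfile(N2, {broad: 0.4}),
        N3: StageProfile(N3, {broad: 0.3}),
        REM: StageProfile(REM, {eog_slow: 1.5, broad: 0.3}, amplitude_scale=1.5),
    }
    emg = {
        W: StageProfile(W, {emg_band: 1.0}, amplitude_scale=1.5),
        N1: StageProfile(N1, {emg_band: 0.7}),
        N2: StageProfile(N2, {emg_band: 0.5}),
        N3: StageProfile(N3, {emg_band: 0.4}),
        REM: StageProfile(REM, {emg_band: 0.3}, amplitude_scale=0.3),
    }
    return {"EEG": eeg, "EOG": eog, "EMG": emg}


def simulate_hypnogram(model: TransitionModel, n_epochs: int, seed: int) -> np.ndarray:
    """Draw a stage sequence from the Markov chain; reproducible per seed."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty(n_epochs, dtype=np.int64)
    out[0] = rng.choice(N_STAGES, p=model.initial)
    for t in range(1, n_epochs):
        out[t] = rng.choice(N_STAGES, p=model.matrix[out[t - 1]])
    return out


def _band_noise(rng: np.random.Generator, n: int, lo: float, hi: float, rate: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz."""
    nyq = rate / 2.0
    lo = min(lo, nyq * 0.98)
    hi = min(hi, nyq * 0.99)
    if hi <= lo:
        return np.zeros(n)
    x = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def simulate_signals(
    hyp: np.ndarray,
    config: SimConfig,
    profiles: dict[str, dict[int, StageProfile]] | None = None,
    seed: int | None = None,
    amplitude_factor: float = 1.0,
) -> np.ndarray:
    """Synthesize stage-conditioned epochs [n_epochs, samples, n_channels]."""
    hyp = validate_hypnogram(hyp)
    if profiles is None:
        profiles = default_profiles()
    for role in set(config.channel_roles):
        role_profiles = profiles.get(role)
        if role_profiles is None:
            raise ValueError(f"no profiles for channel role {role!r}")
        missing = [STAGE_NAMES[s] for s in range(N_STAGES) if s not in role_profiles]
        if missing:
            raise ValueError(f"role {role!r} missing stage profiles: {missing}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_samples = config.samples_per_epoch
    n_ch = len(config.channels)
    out = np.empty((len(hyp), n_samples, n_ch), dtype=np.float64)
    uninformative = set(config.uninformative_channels)
    for t, stage in enumerate(hyp):
        for c, (name, role) in enumerate(zip(config.channels, config.channel_roles)):
            if name in uninformative:
                out[t, :, c] = rng.standard_normal(n_samples)
                continue
            prof = profiles[role][int(stage)]
            x = np.zeros(n_samples)
            for (lo, hi), power in prof.band_powers.items():
                if power > 0:
                    x += np.sqrt(power) * _band_noise(rng, n_samples, lo, hi, config.sampling_rate)
            x *= prof.amplitude_scale * amplitude_factor
            x += rng.standard_normal(n_samples) * config.noise_sigma
            out[t, :, c] = x
    return out


def make_dataset(
    config: SimConfig,
    model: TransitionModel | None = None,
    profiles: dict[str, dict[int, StageProfile]] | None = None,
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """One (subject_id, epochs, hypnogram) triple per subject, deterministic."""
    if model is None:
        model = default_transition_model()
    root = np.random.default_rng(config.seed)
    # draw per-subject sub-seeds up front so output is stable in subject count
    sub_seeds = root.integers(0, 2**31 - 1, size=(config.n_subjects, 3))
    recordings = []
    for i in range(config.n_subjects):
        hyp_seed, sig_seed, jit_seed = (int(s) for s in sub_seeds[i])
        hyp = simulate_hypnogram(model, config.epochs_per_subject, seed=hyp_seed)
        jitter = 1.0
        if config.amplitude_jitter > 0:
            jrng = np.random.default_rng(jit_seed)
            jitter = 1.0 + config.amplitude_jitter * jrng.uniform(-1.0, 1.0)
        epochs = simulate_signals(
            hyp, config, profiles=profiles, seed=sig_seed, amplitude_factor=jitter
        )
        recordings.append((f"S{i:03d}", epochs, hyp))
    return recordings
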