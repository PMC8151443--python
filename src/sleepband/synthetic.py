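"""Seeded synthetic cohorts of two-channel sleep EEG.

The private clinical dataset behind this pipeline is not deposited, so
every downstream stage is exercised on simulated overnight recordings
that reproduce the properties the pipeline actually relies on:

* 2-channel frontal EEG at 500 samples/s, amplitudes in µV;
* a hypnogram from a 5-state Markov chain whose stationary law matches
  the clinical stage distribution (W 22.45%, N1 6.95%, N2 47.86%,
  N3 11.07%, REM 11.66%) and whose self-transitions keep stages in
  multi-epoch runs;
* stage-dependent spectra built as sums of band-limited Gaussian noise
  (alpha-dominant wake, theta-dominant N1, spindle-band bump in N2,
  high-amplitude delta in N3, low-amplitude mixed REM);
* high inter-channel correlation when clean (shared source plus small
  independent per-channel noise);
* sporadic single-channel high-amplitude corruption with known ground
  truth, detectable by the correlation/amplitude cleaning rule;
* an optional device shift (gain + added noise) producing "HB" and
  "PSG" renderings of the same underlying source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import EPOCH_SEC, STAGE_INDEX, STAGES
from .preprocess import Hypnogram, Recording

__all__ = [
    "StageProfile",
    "CorruptionSpec",
    "DeviceShift",
    "SyntheticCohortConfig",
    "SubjectData",
    "default_profiles",
    "transition_matrix",
    "generate_hypnogram",
    "generate_stage_signal",
    "inject_corruption",
    "generate_cohort",
]

#: Clinical stage frequencies the default Markov chain is calibrated to.
CLINICAL_STAGE_DISTRIBUTION: dict[str, float] = {
    "W": 0.2245,
    "N1": 0.0695,
    "N2": 0.4786,
    "N3": 0.1107,
    "REM": 0.1166,
}

DEFAULT_SAMPLE_RATE = 500.0


@dataclass
class StageProfile:
    """Spectral and dynamic description of one sleep stage.

    ``band_powers`` maps frequency intervals (Hz) to relative power
    (nonnegative, summing to 1). ``amplitude_scale`` is the RMS of the
    clean two-channel signal in µV. ``transition_row`` is the Markov
    transition probability vector over (W, N1, N2, N3, REM) per 30-s
    step.
    """

    stage: str
    band_powers: dict[tuple[float, float], float]
    amplitude_scale: float
    transition_row: np.ndarray

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.amplitude_scale <= 0:
            raise ValueError("amplitude_scale must be positive")
        powers = np.array(list(self.band_powers.values()), dtype=float)
        if np.any(powers < 0) or abs(powers.sum() - 1.0) > 1e-9:
            raise ValueError("band powers must be nonnegative and sum to 1")
        self.transition_row = np.asarray(self.transition_row, dtype=float)
        if self.transition_row.shape != (5,) or np.any(self.transition_row < 0):
            raise ValueError("transition_row must be a length-5 probability vector")
        if abs(self.transition_row.sum() - 1.0) > 1e-9:
            raise ValueError("transition_row must sum to 1")


@dataclass
class CorruptionSpec:
    """Sporadic single-channel high-amplitude artifact injection.

    ``artifact_rms`` (µV) should sit well above the cleaning rule's
    amplitude threshold so injected corruption is detectable by design.
    The artifact is band-limited to roughly 0.5–10 Hz so its amplitude
    survives the 0.5–12 Hz preprocessing band-pass.
    """

    fraction_of_epochs: float = 0.05
    affected_channel: str = "random"  # {"1", "2", "random"}
    artifact_rms: float = 150.0
    artifact_kind: str = "broadband_noise"  # {"broadband_noise", "rail_drift"}

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_of_epochs <= 1.0:
            raise ValueError("fraction_of_epochs must be in [0, 1]")
        if str(self.affected_channel) not in ("1", "2", "random"):
            raise ValueError("affected_channel must be '1', '2' or 'random'")
        if self.artifact_kind not in ("broadband_noise", "rail_drift"):
            raise ValueError(f"unknown artifact_kind {self.artifact_kind!r}")
        if self.artifact_rms <= 0:
            raise ValueError("artifact_rms must be positive")


@dataclass
class DeviceShift:
    """Per-device rendering offsets emulating HB-vs-PSG covariate shift.

    The headband rendering is ``gain`` times the shared source plus
    band-limited noise of in-band RMS ``noise_rms_uv``.
    """

    gain: float = 1.2
    noise_rms_uv: float = 5.0


@dataclass
class SyntheticCohortConfig:
    n_subjects: int = 6
    record_hours: float = 2.0
    sample_rate: float = DEFAULT_SAMPLE_RATE
    seed: int = 0
    stage_profiles: list[StageProfile] = field(default_factory=lambda: default_profiles())
    corruption: CorruptionSpec | None = None
    device_shift: DeviceShift | None = None
    channel_noise_ratio: float = 0.1

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 (leave-one-out needs 2)")
        if self.record_hours <= 0:
            raise ValueError("record_hours must be positive")
        stages = [p.stage for p in self.stage_profiles]
        if stages != list(STAGES):
            raise ValueError(f"stage_profiles must cover {STAGES} in order, got {stages}")

    @property
    def n_epochs(self) -> int:
        return int(self.record_hours * 3600 // EPOCH_SEC)


@dataclass
class SubjectData:
    """One simulated subject: recording(s), hypnogram, corruption truth."""

    recording: Recording
    hypnogram: Hypnogram
    corrupt_epochs: np.ndarray
    psg_recording: Recording | None = None


def transition_matrix(
    stationary: dict[str, float] | None = None, persistence: float = 0.88
) -> np.ndarray:
    """Markov matrix ``P = a*I + (1-a)*1 pi^T`` with stationary law ``pi``.

    Any convex mixture of the identity and the rank-one kernel keeps the
    target law stationary while raising self-transitions to at least
    ``persistence`` (so stages occur in multi-epoch runs, which the
    overlapping-window augmentation needs).
    """
    pi = np.array(
        [(stationary or CLINICAL_STAGE_DISTRIBUTION)[s] for s in STAGES], dtype=float
    )
    pi = pi / pi.sum()
    return persistence * np.eye(5) + (1 - persistence) * np.outer(np.ones(5), pi)


def default_profiles(persistence: float = 0.88) -> list[StageProfile]:
    """Well-separated default stage spectra.

    Wake is alpha-dominant, N1/N2 theta-dominant with a narrow
    spindle-band (11.5–12 Hz) bump distinguishing N2, N3 is
    delta-dominant at double amplitude, and REM is mixed 4–10 Hz. True
    12–14 Hz spindles are truncated by the 0.5–12 Hz analysis band,
    hence the 11.5–12 Hz surrogate. Apart from N3's doubled amplitude,
    stages share the same RMS so that identity is carried by spectral
    shape rather than by gain.
    """
    P = transition_matrix(persistence=persistence)
    bands: dict[str, dict[tuple[float, float], float]] = {
        "W": {(0.5, 4.0): 0.15, (4.0, 8.0): 0.15, (8.0, 12.0): 0.70},
        "N1": {(0.5, 4.0): 0.20, (4.0, 8.0): 0.65, (8.0, 12.0): 0.15},
        "N2": {(0.5, 4.0): 0.25, (4.0, 8.0): 0.50, (8.0, 11.5): 0.05, (11.5, 12.0): 0.20},
        "N3": {(0.5, 4.0): 0.90, (4.0, 8.0): 0.07, (8.0, 12.0): 0.03},
        "REM": {(0.5, 4.0): 0.15, (4.0, 10.0): 0.85},
    }
    amplitude = {"W": 15.0, "N1": 15.0, "N2": 20.0, "N3": 30.0, "REM": 15.0}
    return [
        StageProfile(
            stage=s,
            band_powers=bands[s],
            amplitude_scale=amplitude[s],
            transition_row=P[STAGE_INDEX[s]],
        )
        for s in STAGES
    ]


def generate_hypnogram(
    profiles: list[StageProfile],
    n_epochs: int,
    seed: int | np.random.SeedSequence,
    start: str = "W",
) -> Hypnogram:
    """Simulate a stage-label sequence from the profiles' Markov chain."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    P = np.stack([p.transition_row for p in profiles])
    if P.shape != (5, 5) or np.any(P < 0) or np.max(np.abs(P.sum(axis=1) - 1)) > 1e-9:
        raise ValueError("transition matrix rows must be probability vectors")
    rng = np.random.default_rng(seed)
    states = np.empty(n_epochs, dtype=np.int64)
    s = STAGE_INDEX[start]
    # inverse-CDF draws keep the chain reproducible for a fixed seed
    u = rng.random(n_epochs)
    cdf = np.cumsum(P, axis=1)
    for i in range(n_epochs):
        states[i] = s
        s = int(np.searchsorted(cdf[s], u[i], side="right"))
        s = min(s, 4)
    return Hypnogram(stages=np.array(STAGES, dtype="<U3")[states])


def _band_noise(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band_powers: dict[tuple[float, float], float],
) -> np.ndarray:
    """Unit-RMS Gaussian noise with the given relative band powers.

    Shaped in the frequency domain: independent complex-Gaussian rFFT
    coefficients weighted so each band carries its prescribed share of
    the variance, which gives a 1/f-free but realistically textured
    random signal with exact (in expectation) band fractions.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    weights = np.zeros_like(freqs)
    for (lo, hi), p in band_powers.items():
        mask = (freqs >= lo) & (freqs < hi)
        k = int(mask.sum())
        if k == 0:
            raise ValueError(f"band {(lo, hi)} Hz empty at fs={fs}, n={n}")
        weights[mask] = np.sqrt(p / k)
    spec = weights * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_stage_signal(
    profile: StageProfile,
    duration: float,
    sample_rate: float,
    seed: int | np.random.SeedSequence,
    channel_noise_ratio: float = 0.1,
) -> np.ndarray:
    """Two-channel clean signal for one stage, shape (2, duration*fs), µV.

    Both channels share one band-shaped source plus independent
    per-channel noise of the same spectral shape at amplitude ratio
    ``channel_noise_ratio`` (default 1:10), so clean 30-s epochs
    correlate at about ``1 / (1 + ratio**2)`` ≈ 0.99.
    """
    if duration <= 0 or (duration / EPOCH_SEC) % 1 != 0:
        raise ValueError("duration must be a positive multiple of 30 s")
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    source = _band_noise(rng, n, sample_rate, profile.band_powers)
    chans = np.empty((2, n))
    norm = np.sqrt(1.0 + channel_noise_ratio**2)
    for c in range(2):
        if channel_noise_ratio > 0:
            noise = _band_noise(rng, n, sample_rate, profile.band_powers)
            chans[c] = (source + channel_noise_ratio * noise) / norm
        else:
            chans[c] = source
    return profile.amplitude_scale * chans


ARTIFACT_BAND = (0.5, 10.0)


def _artifact(
    rng: np.random.Generator, n: int, fs: float, kind: str, rms: float
) -> np.ndarray:
    if kind == "broadband_noise":
        x = _band_noise(rng, n, fs, {ARTIFACT_BAND: 1.0})
    else:  # rail_drift: slow drift clipped at the rails
        x = _band_noise(rng, n, fs, {(0.5, 1.5): 1.0})
        x = np.clip(x, -1.2, 1.2)
        x /= np.sqrt(np.mean(x**2))
    return rms * x


def inject_corruption(
    recording: Recording,
    spec: CorruptionSpec,
    seed: int | np.random.SeedSequence,
) -> tuple[Recording, np.ndarray]:
    """Replace one channel of randomly chosen epochs with artifact.

    Exactly ``round(fraction_of_epochs * n_epochs)`` epochs are drawn
    without replacement (deterministic under the seed). Returns the
    corrupted copy and the sorted injected epoch indices — the ground
    truth for evaluating the cleaning rule.
    """
    rng = np.random.default_rng(seed)
    fs = recording.sample_rate
    epoch_n = int(round(EPOCH_SEC * fs))
    n_epochs = recording.n_samples // epoch_n
    k = int(round(spec.fraction_of_epochs * n_epochs))
    out = recording.copy()
    if k == 0:
        return out, np.array([], dtype=np.int64)
    if k == n_epochs:
        warnings.warn("corruption fraction leaves no clean epochs", stacklevel=2)
    idx = np.sort(rng.choice(n_epochs, size=k, replace=False))
    for i in idx:
        if spec.affected_channel == "random":
            ch = int(rng.integers(0, 2))
        else:
            ch = int(spec.affected_channel) - 1
        sl = slice(i * epoch_n, (i + 1) * epoch_n)
        out.signal[ch, sl] = _artifact(rng, epoch_n, fs, spec.artifact_kind, spec.artifact_rms)
    return out, idx.astype(np.int64)


HB_CHANNELS = ("F3-A1", "F4-A2")
PSG_CHANNELS = ("F3-M2", "F4-M1")


def generate_cohort(config: SyntheticCohortConfig) -> list[SubjectData]:
    """Simulate ``n_subjects`` independent overnight recordings.

    Signals are generated per contiguous same-stage run (not per epoch),
    so same-stage neighbours are seamless — the situation the
    overlapping-window augmentation exploits. With ``device_shift`` set,
    each subject additionally carries a PSG rendering of the same
    underlying source; corruption is injected into the HB rendering
    only.
    """
    root = np.random.SeedSequence(config.seed)
    subjects = []
    for si, child in enumerate(root.spawn(config.n_subjects)):
        ss_hyp, ss_sig, ss_cor, ss_dev = child.spawn(4)
        hyp = generate_hypnogram(config.stage_profiles, config.n_epochs, ss_hyp)
        profile_of = {p.stage: p for p in config.stage_profiles}

        pieces = []
        run_seeds = ss_sig.spawn(config.n_epochs)  # at most one run per epoch
        ri = 0
        i = 0
        stages = hyp.stages
        while i < len(stages):
            j = i
            while j < len(stages) and stages[j] == stages[i]:
                j += 1
            pieces.append(
                generate_stage_signal(
                    profile_of[stages[i]],
                    (j - i) * EPOCH_SEC,
                    config.sample_rate,
                    run_seeds[ri],
                    config.channel_noise_ratio,
                )
            )
            ri += 1
            i = j
        base = np.concatenate(pieces, axis=1)

        sid = f"S{si:02d}"
        psg = None
        if config.device_shift is not None:
            psg = Recording(
                subject_id=sid,
                device="PSG",
                channel_names=PSG_CHANNELS,
                sample_rate=config.sample_rate,
                signal=base.copy(),
            )
            rng_dev = np.random.default_rng(ss_dev)
            hb_sig = config.device_shift.gain * base
            if config.device_shift.noise_rms_uv > 0:
                for c in range(2):
                    hb_sig[c] += config.device_shift.noise_rms_uv * _band_noise(
                        rng_dev, base.shape[1], config.sample_rate, {(0.5, 12.0): 1.0}
                    )
        else:
            hb_sig = base
        hb = Recording(
            subject_id=sid,
            device="HB",
            channel_names=HB_CHANNELS,
            sample_rate=config.sample_rate,
            signal=hb_sig,
        )
        if config.corruption is not None:
            hb, corrupt = inject_corruption(hb, config.corruption, ss_cor)
        else:
            corrupt = np.array([], dtype=np.int64)
        subjects.append(
            SubjectData(recording=hb, hypnogram=hyp, corrupt_epochs=corrupt, psg_recording=psg)
        )
    return subjects
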