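"""Recording containers and the preprocessing chain.

The pipeline mirrors standard practice for low-channel-count sleep EEG:
a linear-phase FIR band-pass (0.5–12 Hz), downsampling to 25 Hz, and
segmentation into label-aligned, nonoverlapping 30-s epochs. Epochs are
0-based with epoch ``i`` covering the half-open interval
``[30*i, 30*(i+1))`` seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .constants import BAND_HIGH, BAND_LOW, EPOCH_SAMPLES, EPOCH_SEC, STAGES, TARGET_RATE

__all__ = [
    "Recording",
    "Hypnogram",
    "EpochArray",
    "read_recording",
    "read_hypnogram_csv",
    "bandpass_filter",
    "fir_bandpass_kernel",
    "apply_fir",
    "downsample",
    "make_epochs",
]


class AlignmentError(ValueError):
    """Hypnogram does not cover the recording."""


class ChannelNotFoundError(KeyError):
    """Requested EEG channel pair is absent from the file."""


@dataclass
class Recording:
    """One subject's continuous two-channel EEG.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject.
    device : {"HB", "PSG"}
        Acquisition device tag. Headband (HB) data is eligible for the
        correlation/amplitude cleaning rule; PSG is not, by default.
    channel_names : tuple of str
        The two derivations, e.g. ``("F3-A1", "F4-A2")`` for the headband.
    sample_rate : float
        Samples per second.
    signal : ndarray, shape (2, n_samples)
        Amplitudes in microvolts.
    exclusion_intervals : list of (float, float)
        ``(start_s, end_s)`` spans to drop before epoching (e.g. segments
        removed after visual inspection for hardware failure).
    """

    subject_id: str
    device: str
    channel_names: tuple[str, str]
    sample_rate: float
    signal: np.ndarray
    exclusion_intervals: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] != 2:
            raise ValueError(f"signal must have shape (2, n), got {self.signal.shape}")
        if self.device not in ("HB", "PSG"):
            raise ValueError(f"device must be 'HB' or 'PSG', got {self.device!r}")
        if self.sample_rate < TARGET_RATE:
            raise ValueError(f"sample_rate must be >= {TARGET_RATE} samples/s")
        dur = self.duration_s
        spans = sorted(self.exclusion_intervals)
        for k, (a, b) in enumerate(spans):
            if not (0 <= a < b <= dur + 1e-9):
                raise ValueError(f"exclusion interval {(a, b)} outside record")
            if k and a < spans[k - 1][1]:
                raise ValueError("exclusion intervals overlap")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    def copy(self) -> "Recording":
        return dataclasses.replace(
            self,
            signal=self.signal.copy(),
            exclusion_intervals=list(self.exclusion_intervals),
        )


@dataclass
class Hypnogram:
    """Per-30-s sleep-stage labels (AASM 5-class)."""

    stages: np.ndarray
    epoch_length: int = EPOCH_SEC

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype="<U3")
        if self.epoch_length != EPOCH_SEC:
            raise ValueError(f"epoch_length must be {EPOCH_SEC} s")
        if self.stages.size == 0:
            raise ValueError("hypnogram is empty")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.stages.size)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "epoch_index": np.arange(len(self)),
                "onset_s": np.arange(len(self)) * self.epoch_length,
                "stage": self.stages,
            }
        )
        df.to_csv(path, index=False)


def read_hypnogram_csv(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    return Hypnogram(stages=df["stage"].to_numpy(dtype="<U3"))


@dataclass
class EpochArray:
    """Label-aligned 30-s epochs at 25 Hz.

    ``data`` has shape (n_epochs, 750, 2): samples-by-channels per epoch,
    in microvolts. ``epoch_index`` keeps each epoch's original temporal
    index within its recording so that downstream steps (augmentation)
    can tell truly contiguous epochs from neighbours separated by a
    dropped or excluded epoch. ``subjects`` is per-epoch so arrays from
    several subjects can be concatenated for training.
    """

    data: np.ndarray
    labels: np.ndarray
    subject_id: str
    device: str
    epoch_index: np.ndarray = None  # type: ignore[assignment]
    subjects: np.ndarray = None  # type: ignore[assignment]
    is_validation: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype="<U3")
        if self.data.ndim != 3 or self.data.shape[1:] != (EPOCH_SAMPLES, 2):
            raise ValueError(
                f"data must have shape (n, {EPOCH_SAMPLES}, 2), got {self.data.shape}"
            )
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("labels length must equal number of epochs")
        if self.epoch_index is None:
            self.epoch_index = np.arange(self.data.shape[0])
        self.epoch_index = np.asarray(self.epoch_index, dtype=np.int64)
        if self.subjects is None:
            self.subjects = np.full(self.data.shape[0], self.subject_id, dtype="<U16")
        self.subjects = np.asarray(self.subjects, dtype="<U16")

    @property
    def n_epochs(self) -> int:
        return int(self.data.shape[0])

    def __len__(self) -> int:
        return self.n_epochs

    def select(self, idx) -> "EpochArray":
        idx = np.asarray(idx)
        return EpochArray(
            data=self.data[idx],
            labels=self.labels[idx],
            subject_id=self.subject_id,
            device=self.device,
            epoch_index=self.epoch_index[idx],
            subjects=self.subjects[idx],
            is_validation=self.is_validation,
        )

    @staticmethod
    def concatenate(parts: list["EpochArray"]) -> "EpochArray":
        if not parts:
            raise ValueError("nothing to concatenate")
        return EpochArray(
            data=np.concatenate([p.data for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            subject_id="+".join(dict.fromkeys(p.subject_id for p in parts)),
            device=parts[0].device,
            epoch_index=np.concatenate([p.epoch_index for p in parts]),
            subjects=np.concatenate([p.subjects for p in parts]),
            is_validation=all(p.is_validation for p in parts),
        )

    def save_npz(self, path: str | Path) -> None:
        np.savez(
            path,
            data=self.data,
            labels=self.labels,
            epoch_index=self.epoch_index,
            subjects=self.subjects,
            subject_id=np.array(self.subject_id),
            device=np.array(self.device),
        )

    @staticmethod
    def load_npz(path: str | Path) -> "EpochArray":
        z = np.load(path, allow_pickle=False)
        return EpochArray(
            data=z["data"],
            labels=z["labels"],
            subject_id=str(z["subject_id"]),
            device=str(z["device"]),
            epoch_index=z["epoch_index"],
            subjects=z["subjects"],
        )


# ---------------------------------------------------------------------------
# EDF reading
# ---------------------------------------------------------------------------

def read_recording(
    path: str | Path,
    device_tag: str,
    channels: tuple[str, str] | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read a two-channel EEG recording from an EDF file.

    Uses MNE's EDF reader and converts to microvolts. If ``channels`` is
    None the first two channels in the file are used.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    if channels is None:
        if len(names) < 2:
            raise ChannelNotFoundError(
                f"need 2 EEG channels, file has {len(names)}: {names}"
            )
        channels = (names[0], names[1])
    for ch in channels:
        if ch not in names:
            raise ChannelNotFoundError(f"channel {ch!r} not in file (has {names})")
    data = raw.get_data(picks=list(channels)) * 1e6  # MNE returns volts
    if raw.info["sfreq"] < 50:
        raise ValueError(
            "recordings must be sampled at >= 50 samples/s to support the "
            "0.5-12 Hz passband and the 25 Hz analysis rate"
        )
    return Recording(
        subject_id=subject_id or Path(path).stem,
        device=device_tag,
        channel_names=(channels[0], channels[1]),
        sample_rate=float(raw.info["sfreq"]),
        signal=data,
    )


# ---------------------------------------------------------------------------
# FIR band-pass
# ---------------------------------------------------------------------------

def _hamming_taps(transition_hz: float, fs: float) -> int:
    # Hamming window: ~53 dB stopband, transition ~3.3/N cycles/sample.
    n = int(np.ceil(3.3 * fs / transition_hz))
    return n + 1 if n % 2 == 0 else n


def fir_bandpass_kernel(
    fs: float,
    low: float = BAND_LOW,
    high: float = BAND_HIGH,
    trans_low: float = 0.5,
    trans_high: float = 2.0,
) -> np.ndarray:
    """Windowed-sinc (Hamming) band-pass kernel.

    Built as a cascade of a high-pass (transition ``trans_low``) and a
    low-pass (transition ``trans_high``) so the two edges can have
    different transition widths; the result is linear-phase with odd
    length.
    """
    if not (0 < low < high < fs / 2):
        raise ValueError(f"need 0 < low < high < Nyquist; got {low}, {high} at fs={fs}")
    n_hp = _hamming_taps(trans_low, fs)
    n_lp = _hamming_taps(min(trans_high, fs / 2 - high), fs)
    hp = sps.firwin(n_hp, low, window="hamming", pass_zero=False, fs=fs)
    lp = sps.firwin(n_lp, high, window="hamming", pass_zero=True, fs=fs)
    return np.convolve(hp, lp)


def apply_fir(x: np.ndarray, kernel: np.ndarray, axis: int = -1) -> np.ndarray:
    """Apply a linear-phase FIR along ``axis`` with group-delay compensation.

    A single forward pass; the (kernel_len-1)/2-sample delay of the
    symmetric kernel is removed so features stay aligned with the
    hypnogram's time base.
    """
    n = x.shape[axis]
    delay = (len(kernel) - 1) // 2
    y = sps.fftconvolve(x, _shape_kernel(kernel, x.ndim, axis), mode="full", axes=axis)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(delay, delay + n)
    return y[tuple(sl)]


def _shape_kernel(kernel: np.ndarray, ndim: int, axis: int) -> np.ndarray:
    shape = [1] * ndim
    shape[axis % ndim] = len(kernel)
    return kernel.reshape(shape)


def bandpass_filter(
    recording: Recording, low: float = BAND_LOW, high: float = BAND_HIGH
) -> Recording:
    """Band-pass a recording with the 0.5–12 Hz linear-phase FIR."""
    kernel = fir_bandpass_kernel(recording.sample_rate, low, high)
    out = recording.copy()
    out.signal = apply_fir(recording.signal, kernel, axis=1)
    return out


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------

def downsample(recording: Recording, target_rate: float = TARGET_RATE) -> Recording:
    """Resample to ``target_rate`` by a rational polyphase factor.

    The recording is assumed already band-limited below
    ``target_rate / 2`` (the 12 Hz band-pass guarantees this for the
    default 25 Hz target); ``resample_poly``'s own anti-alias filter is
    kept as a safeguard.
    """
    if recording.sample_rate == target_rate:
        return recording.copy()
    ratio = Fraction(target_rate).limit_denominator(1000) / Fraction(
        recording.sample_rate
    ).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    if up > 10_000 or down > 10_000:
        raise ValueError(
            f"resampling {recording.sample_rate} -> {target_rate} is not a "
            "manageable rational ratio"
        )
    out = recording.copy()
    out.signal = sps.resample_poly(recording.signal, up, down, axis=1)
    out.sample_rate = float(target_rate)
    return out


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def make_epochs(recording: Recording, hypnogram: Hypnogram) -> EpochArray:
    """Cut a 25 Hz recording into label-aligned nonoverlapping 30-s epochs.

    The trailing partial epoch is discarded. Epochs overlapping an
    exclusion interval are dropped together with their labels; the
    surviving epochs keep their original temporal indices.
    """
    if recording.sample_rate != TARGET_RATE:
        raise ValueError(
            f"epoching expects {TARGET_RATE} Hz input, got {recording.sample_rate}"
        )
    n_full = recording.n_samples // EPOCH_SAMPLES
    if len(hypnogram) < n_full:
        raise AlignmentError(
            f"hypnogram has {len(hypnogram)} labels but recording contains "
            f"{n_full} full epochs"
        )
    keep = np.ones(n_full, dtype=bool)
    for a, b in recording.exclusion_intervals:
        for i in range(n_full):
            t0, t1 = i * EPOCH_SEC, (i + 1) * EPOCH_SEC
            if t0 < b and a < t1:  # open-interval overlap
                keep[i] = False
    idx = np.nonzero(keep)[0]
    data = recording.signal[:, : n_full * EPOCH_SAMPLES]
    data = data.reshape(2, n_full, EPOCH_SAMPLES).transpose(1, 2, 0)
    return EpochArray(
        data=data[idx],
        labels=hypnogram.stages[:n_full][idx],
        subject_id=recording.subject_id,
        device=recording.device,
        epoch_index=idx,
    )


def preprocess_recording(
    recording: Recording,
    hypnogram: Hypnogram,
    low: float = BAND_LOW,
    high: float = BAND_HIGH,
    target_rate: float = TARGET_RATE,
) -> EpochArray:
    """Full chain: band-pass at native rate, downsample, epoch."""
    return make_epochs(downsample(bandpass_filter(recording, low, high), target_rate), hypnogram)
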