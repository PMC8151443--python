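"""Overlapping-window data augmentation for training folds.

Contiguous 30-s epochs of the same sleep stage are concatenated in the
time domain and re-sliced into new 30-s epochs overlapping by a chosen
fraction (default 75%). Every generated window lies wholly inside one
same-stage run, so no window spans a stage transition, a subject
boundary, or a gap left by dropped/excluded epochs. Augmentation is a
training-set-only operation: windows that overlap almost entirely with
their neighbours would otherwise leak between the train and validation
sides of a fold.

For overlap ``p`` the window step is ``30*(1-p)`` seconds, and a run of
``L`` epochs yields ``floor((30L - 30)/step) + 1`` windows; with
``p = 0.75`` this is ``4L - 3``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .constants import EPOCH_SAMPLES, EPOCH_SEC
from .preprocess import EpochArray

__all__ = [
    "AugmentationConfig",
    "Block",
    "contiguous_blocks",
    "slice_windows",
    "augment",
    "window_count",
]


@dataclass(frozen=True)
class AugmentationConfig:
    overlap: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")


@dataclass
class Block:
    """One maximal run of same-stage epochs, concatenated."""

    stage: str
    signal: np.ndarray  # (run_len * 750, 2)
    source_epochs: np.ndarray  # original epoch indices
    subject: str

    @property
    def duration_s(self) -> int:
        return self.signal.shape[0] // EPOCH_SAMPLES * EPOCH_SEC


def contiguous_blocks(epochs: EpochArray) -> list[Block]:
    """Run-length-encode the epoch sequence into same-stage blocks.

    A run breaks at a stage change, a subject change, or a jump in the
    original epoch index (an excluded or dropped epoch in between).
    """
    blocks: list[Block] = []
    n = epochs.n_epochs
    i = 0
    while i < n:
        j = i + 1
        while (
            j < n
            and epochs.labels[j] == epochs.labels[i]
            and epochs.subjects[j] == epochs.subjects[i]
            and epochs.epoch_index[j] == epochs.epoch_index[j - 1] + 1
        ):
            j += 1
        blocks.append(
            Block(
                stage=str(epochs.labels[i]),
                signal=epochs.data[i:j].reshape(-1, 2),
                source_epochs=epochs.epoch_index[i:j].copy(),
                subject=str(epochs.subjects[i]),
            )
        )
        i = j
    return blocks


def _step_fraction(overlap: float) -> Fraction:
    step = (1 - Fraction(overlap).limit_denominator(10_000)) * EPOCH_SEC
    if step <= 0:
        raise ValueError("overlap must leave a positive step")
    return step


def window_count(duration_s: int, overlap: float) -> int:
    """Number of fully contained 30-s windows in a block of ``duration_s``."""
    step = _step_fraction(overlap)
    return int((Fraction(duration_s) - EPOCH_SEC) / step) + 1


def slice_windows(block: Block, overlap: float) -> np.ndarray:
    """Re-slice a block into 30-s windows starting at multiples of the step.

    Returns an array of shape (n_windows, 750, 2). Window starts are
    exact multiples of ``30*(1-overlap)`` seconds (rounded to the
    nearest sample where the step is a non-integer number of samples);
    only fully contained windows are kept.
    """
    n_total = block.signal.shape[0]
    step = _step_fraction(overlap)  # seconds, exact
    fs = Fraction(EPOCH_SAMPLES, EPOCH_SEC)  # samples per second
    count = window_count(n_total // EPOCH_SAMPLES * EPOCH_SEC, overlap)
    out = np.empty((count, EPOCH_SAMPLES, 2), dtype=block.signal.dtype)
    for k in range(count):
        start = int(round(float(k * step * fs)))
        out[k] = block.signal[start : start + EPOCH_SAMPLES]
    return out


def augment(train_epochs: EpochArray, cfg: AugmentationConfig = AugmentationConfig()) -> EpochArray:
    """Expand a training fold by overlapping windows over same-stage runs.

    With overlap 0 the output reproduces the input partition exactly.
    Refuses to run on an array marked as a validation fold.
    """
    if train_epochs.is_validation:
        raise ValueError("augmentation must not be applied to a validation fold")
    data, labels, subjects = [], [], []
    for block in contiguous_blocks(train_epochs):
        wins = slice_windows(block, cfg.overlap)
        data.append(wins)
        labels.extend([block.stage] * len(wins))
        subjects.extend([block.subject] * len(wins))
    out_data = np.concatenate(data) if data else np.empty((0, EPOCH_SAMPLES, 2))
    return EpochArray(
        data=out_data,
        labels=np.array(labels, dtype="<U3"),
        subject_id=train_epochs.subject_id,
        device=train_epochs.device,
        epoch_index=np.arange(len(labels)),
        subjects=np.array(subjects, dtype="<U16"),
    )
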