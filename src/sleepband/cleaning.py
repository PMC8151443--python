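"""Rule-based corrupted-epoch detection and repair for headband EEG.

Frontal headband channels mirror each other closely when both electrodes
make good contact, so a clean epoch shows high inter-channel correlation
and physiological amplitude. An epoch is flagged as corrupted when the
Pearson correlation between the two channels falls below
``min_correlation`` (default 0.9) AND the mean absolute amplitude of at
least one channel exceeds ``max_amplitude`` (default 40 µV). Repair
replaces the corrupted channel with a copy of the valid one rather than
discarding the epoch.

"Mean amplitude" is the mean absolute value of the band-passed 25 Hz
epoch per channel; correlation is signed Pearson. A zero-variance
channel gets correlation 0 (maximally dissimilar), never an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochArray

__all__ = [
    "CleaningThresholds",
    "CleaningReport",
    "GridSearchResult",
    "epoch_stats",
    "detect_corrupted",
    "repair",
    "clean_epochs",
    "threshold_grid_search",
]


@dataclass(frozen=True)
class CleaningThresholds:
    min_correlation: float = 0.9
    max_amplitude: float = 40.0  # µV

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_correlation <= 1.0:
            raise ValueError("min_correlation must be in [0, 1]")
        if self.max_amplitude <= 0:
            raise ValueError("max_amplitude must be positive")


@dataclass
class CleaningReport:
    """Per-epoch statistics and the actions taken."""

    thresholds: CleaningThresholds
    correlation: np.ndarray  # (n,)
    mean_amplitude: np.ndarray  # (n, 2), µV
    flagged: np.ndarray  # sorted indices into the input array
    actions: list[str] = field(default_factory=list)  # kept/repaired_ch1/repaired_ch2/dropped

    def to_dict(self) -> dict:
        return {
            "thresholds": {
                "min_correlation": self.thresholds.min_correlation,
                "max_amplitude": self.thresholds.max_amplitude,
            },
            "flagged": [int(i) for i in self.flagged],
            "per_epoch": [
                {
                    "correlation": float(self.correlation[i]),
                    "mean_amp_ch1": float(self.mean_amplitude[i, 0]),
                    "mean_amp_ch2": float(self.mean_amplitude[i, 1]),
                    "action": self.actions[i] if self.actions else "kept",
                }
                for i in range(len(self.correlation))
            ],
        }


@dataclass
class GridSearchResult:
    grid: list[tuple[CleaningThresholds, float, float]]  # (thr, mean acc %, std %)
    best: CleaningThresholds


def epoch_stats(epoch: np.ndarray) -> tuple[float, float, float]:
    """Pearson correlation and per-channel mean |amplitude| of one epoch.

    ``epoch`` is (750, 2). Zero-variance channels yield correlation 0.
    """
    epoch = np.asarray(epoch, dtype=float)
    if not np.all(np.isfinite(epoch)):
        raise ValueError("epoch contains non-finite values")
    x, y = epoch[:, 0], epoch[:, 1]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(x, y)[0, 1])
    return corr, float(np.mean(np.abs(x))), float(np.mean(np.abs(y)))


def _stats_vectorized(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = data - data.mean(axis=1, keepdims=True)
    sx = x.std(axis=1)  # (n, 2)
    cov = np.mean(x[:, :, 0] * x[:, :, 1], axis=1)
    denom = sx[:, 0] * sx[:, 1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    amp = np.mean(np.abs(data), axis=1)  # (n, 2)
    return corr, amp


def detect_corrupted(epochs: EpochArray, thr: CleaningThresholds) -> CleaningReport:
    """Flag epochs failing the correlation-AND-amplitude rule.

    An epoch is flagged iff its correlation is below
    ``thr.min_correlation`` and at least one channel's mean amplitude
    exceeds ``thr.max_amplitude`` — low correlation alone (e.g. quiet
    dissimilar channels) is not enough.
    """
    corr, amp = _stats_vectorized(epochs.data)
    flagged = np.nonzero((corr < thr.min_correlation) & np.any(amp > thr.max_amplitude, axis=1))[0]
    return CleaningReport(
        thresholds=thr, correlation=corr, mean_amplitude=amp, flagged=flagged
    )


def repair(epochs: EpochArray, report: CleaningReport) -> tuple[EpochArray, CleaningReport]:
    """Duplicate the valid channel into the corrupted one; drop double hits.

    For each flagged epoch: if exactly one channel's mean amplitude
    exceeds the threshold, that channel is overwritten with the other
    one; if both exceed it there is no valid channel to copy and the
    epoch (with its label) is dropped. Unflagged epochs are untouched.
    """
    thr = report.thresholds
    data = epochs.data.copy()
    actions = ["kept"] * epochs.n_epochs
    keep = np.ones(epochs.n_epochs, dtype=bool)
    for i in report.flagged:
        over = report.mean_amplitude[i] > thr.max_amplitude
        if over.all():
            keep[i] = False
            actions[i] = "dropped"
        else:
            # the louder channel is the corrupted one
            bad = int(np.argmax(report.mean_amplitude[i]))
            data[i, :, bad] = data[i, :, 1 - bad]
            actions[i] = f"repaired_ch{bad + 1}"
    out = EpochArray(
        data=data[keep],
        labels=epochs.labels[keep],
        subject_id=epochs.subject_id,
        device=epochs.device,
        epoch_index=epochs.epoch_index[keep],
        subjects=epochs.subjects[keep],
        is_validation=epochs.is_validation,
    )
    report.actions = actions
    return out, report


def clean_epochs(
    epochs: EpochArray,
    thr: CleaningThresholds = CleaningThresholds(),
    force: bool = False,
) -> tuple[EpochArray, CleaningReport]:
    """Detect-and-repair in one call.

    Cleaning targets headband data; PSG-tagged epochs are refused unless
    ``force=True`` (hospital PSG does not exhibit the single-electrode
    dropout the rule encodes).
    """
    if epochs.device == "PSG" and not force:
        raise ValueError(
            "cleaning is defined for HB data; pass force=True to clean PSG epochs"
        )
    report = detect_corrupted(epochs, thr)
    return repair(epochs, report)


def threshold_grid_search(
    cohort,
    eval_fn,
    corr_values: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9),
    amp_values: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0),
) -> GridSearchResult:
    """Exhaustive search over threshold combinations.

    ``eval_fn(cohort, thresholds) -> (mean_accuracy_pct, std_pct)`` is
    injected: the reference protocol scores each combination by mean
    leave-one-subject-out accuracy of the downstream classifier, but
    tests can substitute a cheap objective. Ties break toward larger
    ``min_correlation``, then smaller ``max_amplitude``.
    """
    if not corr_values or not amp_values:
        raise ValueError("threshold grids must be nonempty")
    grid: list[tuple[CleaningThresholds, float, float]] = []
    for c in corr_values:
        for a in amp_values:
            thr = CleaningThresholds(min_correlation=c, max_amplitude=a)
            mean, std = eval_fn(cohort, thr)
            grid.append((thr, float(mean), float(std)))
    best = max(grid, key=lambda g: (g[1], g[0].min_correlation, -g[0].max_amplitude))[0]
    return GridSearchResult(grid=grid, best=best)
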