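"""Leave-one-subject-out evaluation, metrics and model probing.

Metrics follow the sleep-staging literature: overall accuracy, per-stage
recall (percent of epochs of a true stage predicted as that stage) and
balanced accuracy (the arithmetic mean of the per-stage recalls, robust
to the heavy W/N2 imbalance of overnight recordings). Confusion matrices
use the fixed stage order (W, N1, N2, N3, REM), rows = true.

Band probing re-filters held-out epochs into narrow frequency bands and
passes them through the already-trained classifier, revealing which
bands carry each stage's predictive information. The covariate-shift
check trains a simple linear origin classifier to distinguish two sets
of epochs; cross-validated accuracy near 50% means the distributions
match, near 100% means a strong shift (as between headband and PSG
hardware).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .augmentation import AugmentationConfig, augment
from .cleaning import CleaningThresholds, clean_epochs
from .constants import BAND_HIGH, BAND_LOW, STAGES, TARGET_RATE
from .model import (
    DESK_SCALE_TRAIN,
    ModelConfig,
    SleepModel,
    TrainConfig,
    build_model,
    predict,
    train_fold,
)
from .preprocess import EpochArray, apply_fir, fir_bandpass_kernel

__all__ = [
    "PROBE_BANDS",
    "PipelineConfig",
    "FoldResult",
    "EvalResult",
    "compute_metrics",
    "balanced_accuracy_from_recalls",
    "loocv",
    "band_probe",
    "covariate_shift_check",
]

#: Probe bands (Hz): delta, theta as printed (6–8 Hz, leaving 4–6 Hz
#: unassigned), and alpha+beta truncated at the 12 Hz passband edge.
PROBE_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (6.0, 8.0),
    "alphabeta": (8.0, 12.0),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one LOOCV fold needs."""

    cleaning: CleaningThresholds | None = CleaningThresholds()
    augmentation: AugmentationConfig | None = AugmentationConfig()
    model: ModelConfig = ModelConfig()
    train: TrainConfig = DESK_SCALE_TRAIN
    classifier: str = "cnn_lstm"  # {"cnn_lstm", "bagged_trees"}


@dataclass
class FoldResult:
    subject_id: str
    accuracy: float  # %
    balanced_accuracy: float  # %
    per_stage_recall: dict[str, float]  # %, NaN if stage absent from truth
    confusion: np.ndarray  # (5,5) int, rows=true
    model: object | None = None
    validation: EpochArray | None = None


@dataclass
class EvalResult:
    per_fold: list[FoldResult]
    mean_accuracy: float
    std_accuracy: float
    mean_balanced_accuracy: float
    std_balanced_accuracy: float

    @classmethod
    def from_folds(cls, folds: list[FoldResult]) -> "EvalResult":
        acc = np.array([f.accuracy for f in folds])
        bacc = np.array([f.balanced_accuracy for f in folds])
        return cls(
            per_fold=folds,
            mean_accuracy=float(acc.mean()),
            std_accuracy=float(acc.std(ddof=0)),
            mean_balanced_accuracy=float(bacc.mean()),
            std_balanced_accuracy=float(bacc.std(ddof=0)),
        )


def compute_metrics(true_labels, predicted_labels):
    """Accuracy %, balanced accuracy %, per-stage recall %, confusion matrix.

    Stages absent from the truth are excluded from the balanced-accuracy
    mean (their recall is NaN) — a warning is emitted since the
    comparison then covers fewer than 5 stages.
    """
    true_labels = np.asarray(true_labels, dtype="<U3")
    predicted_labels = np.asarray(predicted_labels, dtype="<U3")
    if true_labels.size == 0:
        raise ValueError("empty label sequences")
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label sequences differ in length")
    n = len(STAGES)
    confusion = np.zeros((n, n), dtype=np.int64)
    for i, s_true in enumerate(STAGES):
        mask = true_labels == s_true
        for j, s_pred in enumerate(STAGES):
            confusion[i, j] = int(np.sum(predicted_labels[mask] == s_pred))
    accuracy = float(np.trace(confusion) / confusion.sum()) * 100.0
    row = confusion.sum(axis=1)
    recalls = {}
    for i, s in enumerate(STAGES):
        recalls[s] = float(confusion[i, i] / row[i]) * 100.0 if row[i] else float("nan")
    present = [v for v in recalls.values() if not np.isnan(v)]
    if len(present) < n:
        import warnings

        warnings.warn(
            "balanced accuracy averages only the stages present in the truth",
            stacklevel=2,
        )
    balanced = float(np.mean(present))
    return accuracy, balanced, recalls, confusion


def balanced_accuracy_from_recalls(recalls) -> float:
    """Arithmetic mean of per-stage recalls (percent in, percent out)."""
    recalls = np.asarray(list(recalls), dtype=float)
    if recalls.size == 0:
        raise ValueError("no recalls given")
    return float(recalls.mean())


def _fit_and_predict(train: EpochArray, val: EpochArray, cfg: PipelineConfig, fold_seed: int):
    if cfg.classifier == "cnn_lstm":
        model = build_model(cfg.model, seed=fold_seed)
        tc = TrainConfig(
            learning_rate=cfg.train.learning_rate,
            beta1=cfg.train.beta1,
            beta2=cfg.train.beta2,
            batch_size=cfg.train.batch_size,
            n_train_epochs=cfg.train.n_train_epochs,
            seed=fold_seed,
            weight_mode=cfg.train.weight_mode,
        )
        model, _ = train_fold(model, train, val, tc)
        _, stages = predict(model, val)
        return model, stages
    if cfg.classifier == "bagged_trees":
        from .baseline import epoch_features, minmax_scale, train_bagged_trees

        ftr = np.stack([epoch_features(e) for e in train.data])
        fva = np.stack([epoch_features(e) for e in val.data])
        clf = train_bagged_trees(minmax_scale(ftr, ftr), train.labels, seed=fold_seed)
        return clf, clf.predict(minmax_scale(ftr, fva))
    raise ValueError(f"unknown classifier {cfg.classifier!r}")


def loocv(
    cohort: list[EpochArray],
    cfg: PipelineConfig = PipelineConfig(),
    keep_models: bool = False,
) -> EvalResult:
    """Leave-one-subject-out cross-validation over preprocessed subjects.

    For each held-out subject the remaining subjects are cleaned (HB
    only, when thresholds are set), pooled, augmented, and used to train
    a fresh classifier; the held-out subject is cleaned with the same
    thresholds but never augmented. Per-fold seeds derive from the train
    config's seed, so a rerun reproduces every fold exactly.
    """
    if len(cohort) < 2:
        raise ValueError("leave-one-out needs at least 2 subjects")
    ids = [s.subject_id for s in cohort]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate subject ids: {ids}")
    folds = []
    for k, held_out in enumerate(cohort):
        train_parts = []
        for s in cohort:
            if s.subject_id == held_out.subject_id:
                continue
            if cfg.cleaning is not None and s.device == "HB":
                s, _ = clean_epochs(s, cfg.cleaning)
            train_parts.append(s)
        train = EpochArray.concatenate(train_parts)
        if set(train.subjects) & {held_out.subject_id}:
            raise ValueError("subject leakage: held-out subject present in training data")
        if cfg.augmentation is not None:
            train = augment(train, cfg.augmentation)
        val = held_out
        if cfg.cleaning is not None and val.device == "HB":
            val, _ = clean_epochs(val, cfg.cleaning)
        else:
            val = dataclasses.replace(val)
        val.is_validation = True
        fold_seed = (cfg.train.seed * 1000 + k) % (2**31 - 1)
        model, stages = _fit_and_predict(train, val, cfg, fold_seed)
        acc, bacc, recalls, confusion = compute_metrics(val.labels, stages)
        folds.append(
            FoldResult(
                subject_id=held_out.subject_id,
                accuracy=acc,
                balanced_accuracy=bacc,
                per_stage_recall=recalls,
                confusion=confusion,
                model=model if keep_models else None,
                validation=val if keep_models else None,
            )
        )
    return EvalResult.from_folds(folds)


def band_probe(
    model: SleepModel,
    epochs: EpochArray,
    bands: dict[str, tuple[float, float]] = PROBE_BANDS,
) -> dict[str, np.ndarray]:
    """Confusion matrices of the trained model on band-filtered epochs.

    Each band is isolated with the same windowed-sinc FIR machinery as
    preprocessing (applied at 25 Hz along the sample axis of each
    epoch); the model is never retrained. Bands must lie inside the
    0.5–12 Hz pipeline passband.
    """
    out = {}
    for name, (lo, hi) in bands.items():
        if lo < BAND_LOW - 1e-9 or hi > BAND_HIGH + 1e-9:
            raise ValueError(f"band {name} {(lo, hi)} outside the {BAND_LOW}-{BAND_HIGH} Hz passband")
        kernel = fir_bandpass_kernel(TARGET_RATE, lo, hi, trans_low=0.5, trans_high=1.0)
        filtered = apply_fir(epochs.data, kernel, axis=1)
        _, stages = predict(model, filtered)
        _, _, _, confusion = compute_metrics(epochs.labels, stages)
        out[name] = confusion
    return out


def covariate_shift_check(
    epochs_a: EpochArray, epochs_b: EpochArray, seed: int = 0
) -> float:
    """Origin-classification accuracy (%) between two epoch sets.

    A logistic-regression origin classifier on log absolute band powers
    (the 11 RSP bands per channel, unnormalized so gain shifts remain
    visible), scored by 5-fold cross-validation with contiguous folds
    built per set. Contiguous (unshuffled) folds keep temporally
    neighbouring — and, in the degenerate identical-sets case, duplicated
    — epochs on the same side of each split, so the score reflects
    distributional difference rather than epoch memorization. About 50%
    means the two sets are statistically alike; near 100% flags a strong
    covariate shift.
    """
    from scipy import signal as sps
    from sklearn.linear_model import LogisticRegression

    if epochs_a.n_epochs < 20 or epochs_b.n_epochs < 20:
        raise ValueError("need at least 20 epochs per set")

    def band_features(arr: EpochArray) -> np.ndarray:
        freqs, psd = sps.welch(
            arr.data, fs=TARGET_RATE, window="hamming", nperseg=100, noverlap=50, axis=1
        )
        edges = np.linspace(0.5, 12.0, 12)
        feats = []
        for i in range(11):
            hi = edges[i + 1] + (1e-9 if i == 10 else 0)
            mask = (freqs >= edges[i]) & (freqs < hi)
            feats.append(np.log(psd[:, mask, :].sum(axis=1) + 1e-12))
        return np.concatenate(feats, axis=1)  # (n, 22)

    Xa, Xb = band_features(epochs_a), band_features(epochs_b)
    X = np.concatenate([Xa, Xb])
    y = np.concatenate([np.zeros(len(Xa)), np.ones(len(Xb))])
    folds_a = np.array_split(np.arange(len(Xa)), 5)
    folds_b = np.array_split(len(Xa) + np.arange(len(Xb)), 5)
    accs = []
    for fa, fb in zip(folds_a, folds_b):
        test = np.concatenate([fa, fb])
        train = np.setdiff1d(np.arange(len(X)), test)
        clf = LogisticRegression(max_iter=2000, C=1.0, random_state=seed)
        clf.fit(X[train], y[train])
        accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    return float(np.mean(accs)) * 100.0
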