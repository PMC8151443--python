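"""Hand-crafted-feature baseline: 62 features per channel + bagged trees.

Feature bank per 750-sample (30 s at 25 Hz) channel, 62 features in 8
groups:

* RSP (11) — relative spectral power in 11 contiguous equal-width bands
  spanning 0.5–12 Hz (Welch, 4-s Hamming windows, 50% overlap).
* HP (15) — harmonic parameters: center frequency, bandwidth and the
  spectral value at the center frequency for the 5 sub-bands 0.5–4,
  4–6, 6–8, 8–10 and 10–12 Hz.
* SWI (3) — slow-wave indices: power ratios delta/theta, delta/alpha
  and delta/(theta+alpha) with delta 0.5–4, theta 4–8, alpha 8–12 Hz.
* Hjorth (3) — activity, mobility, complexity.
* Skewness (1), Kurtosis (1) — standardized 3rd/4th central moments.
* Bi-Spectrum (20) — direct bispectrum estimate on the principal
  domain below 12 Hz: 7 global descriptors (mean magnitude, normalized
  bispectral entropy and squared entropy, log-magnitude sums over the
  domain and its diagonal, 1st/2nd spectral moments of the diagonal)
  plus mean magnitude over a 13-strip coarse partition of the domain.
* Wavelet relative power (8) — relative energies of the 7 detail
  levels and the approximation of a 7-level Daubechies-4 DWT.

Epochs are demeaned before extraction, so a DC offset (removed anyway
by the band-pass upstream) changes no feature. Features are min–max
scaled to [0, 1] on the training fold only and classified with a
bootstrap-aggregated decision-tree ensemble.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import signal as sps
from scipy import stats

from .constants import EPOCH_SAMPLES, TARGET_RATE

__all__ = [
    "FEATURE_GROUPS",
    "feature_names",
    "extract_features",
    "epoch_features",
    "minmax_scale",
    "train_bagged_trees",
]

FEATURE_GROUPS: dict[str, int] = {
    "rsp": 11,
    "hp": 15,
    "swi": 3,
    "hjorth": 3,
    "skewness": 1,
    "kurtosis": 1,
    "bispectrum": 20,
    "wavelet": 8,
}

_HP_BANDS = [(0.5, 4.0), (4.0, 6.0), (6.0, 8.0), (8.0, 10.0), (10.0, 12.0)]
_RSP_EDGES = np.linspace(0.5, 12.0, 12)
_NPERSEG = 4 * TARGET_RATE  # 4-s windows
_BISPEC_FMAX_BIN = 48  # 12 Hz at 0.25 Hz resolution
_N_BISPEC_STRIPS = 13


def feature_names() -> list[str]:
    names = [f"rsp_{i:02d}" for i in range(11)]
    for b, (lo, hi) in enumerate(_HP_BANDS):
        names += [f"hp_cf_{lo:g}-{hi:g}", f"hp_bw_{lo:g}-{hi:g}", f"hp_sv_{lo:g}-{hi:g}"]
    names += ["swi_delta_theta", "swi_delta_alpha", "swi_delta_thetaalpha"]
    names += ["hjorth_activity", "hjorth_mobility", "hjorth_complexity"]
    names += ["skewness", "kurtosis"]
    names += [
        "bis_mean_mag", "bis_entropy", "bis_sq_entropy", "bis_sum_log",
        "bis_diag_sum_log", "bis_diag_m1", "bis_diag_m2",
    ]
    names += [f"bis_strip_{i:02d}" for i in range(_N_BISPEC_STRIPS)]
    names += [f"wav_d{i}" for i in range(1, 8)] + ["wav_a7"]
    assert len(names) == sum(FEATURE_GROUPS.values()) == 62
    return names


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else 0.0


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    mask = (freqs >= lo) & (freqs < hi)
    return float(psd[mask].sum())


def _bispectrum_features(x: np.ndarray) -> list[float]:
    n = _NPERSEG
    starts = range(0, len(x) - n + 1, n // 2)
    win = np.hamming(n)
    specs = np.stack([np.fft.fft(win * x[s : s + n]) for s in starts])
    kmax = _BISPEC_FMAX_BIN
    k1g, k2g = np.meshgrid(np.arange(1, kmax + 1), np.arange(1, kmax + 1), indexing="ij")
    dom = (k2g <= k1g) & (k1g + k2g <= kmax)
    B = np.mean(
        specs[:, k1g[dom]] * specs[:, k2g[dom]] * np.conj(specs[:, (k1g + k2g)[dom]]),
        axis=0,
    )
    mag = np.abs(B)
    total = mag.sum()
    eps = 1e-20
    p = mag / total if total > 0 else np.zeros_like(mag)
    q = mag**2 / (mag**2).sum() if total > 0 else np.zeros_like(mag)
    logN = np.log(mag.size)

    def entropy(v: np.ndarray) -> float:
        nz = v[v > 0]
        return float(-(nz * np.log(nz)).sum() / logN) if nz.size else 0.0

    diag_k = np.arange(1, kmax // 2 + 1)
    diag_mag = np.abs(
        np.mean(specs[:, diag_k] ** 2 * np.conj(specs[:, 2 * diag_k]), axis=0)
    )
    dtot = diag_mag.sum()
    m1 = _safe_div(float((diag_k * diag_mag).sum()), dtot)
    m2 = _safe_div(float(((diag_k - m1) ** 2 * diag_mag).sum()), dtot)

    feats = [
        float(mag.mean()),
        entropy(p),
        entropy(q),
        float(np.log(mag + eps).sum()),
        float(np.log(diag_mag + eps).sum()),
        m1,
        m2,
    ]
    k1_dom = k1g[dom]
    for strip in np.array_split(np.arange(1, kmax), _N_BISPEC_STRIPS):
        sel = np.isin(k1_dom, strip)
        feats.append(float(mag[sel].mean()) if sel.any() else 0.0)
    return feats


def extract_features(epoch_channel: np.ndarray, sample_rate: float = TARGET_RATE) -> np.ndarray:
    """62 deterministic features from one 750-sample channel (µV)."""
    x = np.asarray(epoch_channel, dtype=np.float64)
    if x.shape != (EPOCH_SAMPLES,):
        raise ValueError(f"expected a single channel of {EPOCH_SAMPLES} samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("epoch contains non-finite values")
    x = x - x.mean()

    freqs, psd = sps.welch(
        x, fs=sample_rate, window="hamming", nperseg=_NPERSEG, noverlap=_NPERSEG // 2
    )
    total = _band_power(freqs, psd, 0.5, 12.0 + 1e-9)

    feats: list[float] = []
    # RSP
    for i in range(11):
        hi = _RSP_EDGES[i + 1] + (1e-9 if i == 10 else 0.0)
        feats.append(_safe_div(_band_power(freqs, psd, _RSP_EDGES[i], hi), total))
    # HP
    for lo, hi in _HP_BANDS:
        mask = (freqs >= lo) & (freqs < hi + (1e-9 if hi == 12.0 else 0.0))
        bp = psd[mask].sum()
        if bp > 0:
            cf = float((freqs[mask] * psd[mask]).sum() / bp)
            bw = float(np.sqrt((((freqs[mask] - cf) ** 2) * psd[mask]).sum() / bp))
            sv = float(np.interp(cf, freqs, psd))
        else:
            cf, bw, sv = (lo + hi) / 2, 0.0, 0.0
        feats += [cf, bw, sv]
    # SWI
    delta = _band_power(freqs, psd, 0.5, 4.0)
    theta = _band_power(freqs, psd, 4.0, 8.0)
    alpha = _band_power(freqs, psd, 8.0, 12.0 + 1e-9)
    feats += [
        _safe_div(delta, theta),
        _safe_div(delta, alpha),
        _safe_div(delta, theta + alpha),
    ]
    # Hjorth
    var0 = float(np.var(x))
    d1 = np.diff(x) * sample_rate
    d2 = np.diff(d1) * sample_rate
    var1, var2 = float(np.var(d1)), float(np.var(d2))
    mobility = np.sqrt(_safe_div(var1, var0))
    mobility_d = np.sqrt(_safe_div(var2, var1))
    feats += [var0, mobility, _safe_div(mobility_d, mobility)]
    # moments
    feats.append(float(stats.skew(x)) if var0 > 0 else 0.0)
    feats.append(float(stats.kurtosis(x, fisher=False)) if var0 > 0 else 0.0)
    # bispectrum
    feats += _bispectrum_features(x)
    # wavelet relative power (D1..D7, A7); level 7 exceeds pywt's advisory
    # maximum for 750 samples — boundary effects are part of the definition
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(x, "db4", level=7)  # [A7, D7, ..., D1]
    energies = np.array([float(np.sum(c**2)) for c in coeffs])
    etot = energies.sum()
    rel = energies / etot if etot > 0 else energies
    feats += list(rel[:0:-1])  # D1..D7
    feats.append(float(rel[0]))  # A7

    out = np.array(feats, dtype=np.float64)
    assert out.shape == (62,)
    return out


def epoch_features(epoch: np.ndarray, sample_rate: float = TARGET_RATE) -> np.ndarray:
    """124-vector for one (750, 2) epoch: channel 1 block then channel 2."""
    return np.concatenate(
        [extract_features(epoch[:, c], sample_rate) for c in range(2)]
    )


def epoch_feature_names() -> list[str]:
    return [f"ch{c}_{n}" for c in (1, 2) for n in feature_names()]


def minmax_scale(train_features: np.ndarray, apply_features: np.ndarray) -> np.ndarray:
    """Min–max scale ``apply_features`` with ranges fitted on the train set.

    Constant training features map to 0; apply-set values outside the
    training range are clipped into [0, 1], so validation data can
    never widen the fitted range.
    """
    train_features = np.asarray(train_features, dtype=float)
    if train_features.size == 0:
        raise ValueError("train_features is empty")
    lo = train_features.min(axis=0)
    hi = train_features.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    scaled = (np.asarray(apply_features, dtype=float) - lo) / safe
    scaled[:, span == 0] = 0.0
    return np.clip(scaled, 0.0, 1.0)


def train_bagged_trees(features: np.ndarray, labels: np.ndarray, n_trees: int = 100, seed: int = 0):
    """Bootstrap-aggregated decision trees (majority vote) on scaled features."""
    from sklearn.ensemble import BaggingClassifier
    from sklearn.tree import DecisionTreeClassifier

    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training set contains a single class")
    bootstrap = n_trees > 1
    clf = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=0),
        n_estimators=n_trees,
        bootstrap=bootstrap,
        random_state=seed,
        n_jobs=1,
    )
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf
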