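"""The CNN+LSTM per-epoch sleep-stage classifier.

Architecture: three temporal convolution blocks (8/16/32 filters,
kernel 7, ReLU, max-pool 4) turn a 750-sample, 2-channel epoch into a
short feature *sequence* (~11 steps x 32 features) which is passed —
never flattened — to two 64-unit LSTM layers (first returns sequences,
second its last state) and a 5-unit softmax head. LSTM outputs get
dropout 0.2 during training and all weight matrices carry an L2 penalty
of 0.001.

Training minimizes class-weighted categorical cross-entropy
``L = -w_c log p_c`` with Adam (lr 5e-5, beta1 0.99, beta2 0.999),
batch size 64, no early stopping. Two weighting modes are provided:
``relative_frequency`` (w_c = n_c / N, the literal textbook-unfriendly
reading that *amplifies* majority bias) and ``inverse_frequency``
(w_c proportional to N / n_c, normalized to mean 1), the default, which
actually counteracts class imbalance. See docs/methods.md for the
discussion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _nn
from .constants import EPOCH_SAMPLES, STAGE_INDEX, STAGES
from .preprocess import EpochArray

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "SleepModel",
    "build_model",
    "class_weights",
    "weighted_cross_entropy",
    "train_fold",
    "predict",
]


@dataclass(frozen=True)
class ModelConfig:
    conv_filters: tuple[int, int, int] = (8, 16, 32)
    conv_kernel: int = 7
    pool_size: int = 4
    lstm_units: int = 64
    lstm_dropout: float = 0.2
    l2_weight: float = 0.001
    n_classes: int = 5
    input_samples: int = EPOCH_SAMPLES
    input_channels: int = 2
    #: fixed amplitude normalization (µV) applied to inputs; preserves
    #: relative amplitude differences between stages, unlike per-epoch
    #: standardization
    input_scale_uv: float = 20.0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        f = self.conv_filters
        if len(f) != 3 or not (f[1] == 2 * f[0] and f[2] == 2 * f[1]):
            raise ValueError("conv_filters must double layer-to-layer, e.g. (8,16,32)")
        if self.n_classes != len(STAGES):
            raise ValueError("n_classes must be 5")
        if not 0.0 <= self.lstm_dropout < 1.0:
            raise ValueError("lstm_dropout must be in [0,1)")
        if (self.input_samples, self.input_channels) != (EPOCH_SAMPLES, 2):
            raise ValueError(f"input shape must be {EPOCH_SAMPLES}x2")

    @property
    def lstm_steps(self) -> int:
        t = self.input_samples
        for _ in self.conv_filters:
            t = t // self.pool_size
        return t


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 5e-5
    beta1: float = 0.99
    beta2: float = 0.999
    batch_size: int = 64
    n_train_epochs: int = 200
    seed: int = 0
    weight_mode: str = "inverse_frequency"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        for b in (self.beta1, self.beta2):
            if not 0.0 < b < 1.0:
                raise ValueError("Adam betas must be in (0,1)")


#: reduced-budget settings for desk-scale runs on the synthetic cohort
DESK_SCALE_TRAIN = TrainConfig(learning_rate=1e-3, n_train_epochs=30)


class SleepModel:
    """CNN+LSTM classifier with explicit forward/backward passes."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        k = cfg.conv_kernel
        p: dict[str, np.ndarray] = {}
        c_in = cfg.input_channels
        for li, f in enumerate(cfg.conv_filters):
            p[f"conv{li}_W"] = _nn.glorot(rng, (k * c_in, f), dtype)
            p[f"conv{li}_b"] = np.zeros(f, dtype=dtype)
            c_in = f
        H = cfg.lstm_units
        for li, d_in in enumerate((cfg.conv_filters[-1], H)):
            W, U, b = _nn.lstm_init(rng, d_in, H, dtype)
            p[f"lstm{li}_W"], p[f"lstm{li}_U"], p[f"lstm{li}_b"] = W, U, b
        p["dense_W"] = _nn.glorot(rng, (H, cfg.n_classes), dtype)
        p["dense_b"] = np.zeros(cfg.n_classes, dtype=dtype)
        self.params = p

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None):
        """x (B, 750, 2) in µV -> (probs (B,5), cache)."""
        cfg = self.cfg
        if x.shape[1:] != (cfg.input_samples, cfg.input_channels):
            raise ValueError(f"expected input (*, {cfg.input_samples}, {cfg.input_channels})")
        h = (x / cfg.input_scale_uv).astype(self.dtype)
        cache: dict = {"x_shapes": [], "cols": [], "relu": [], "pool": []}
        for li in range(3):
            W, b = self.params[f"conv{li}_W"], self.params[f"conv{li}_b"]
            cache["x_shapes"].append(h.shape)
            y, cols = _nn.conv1d_forward(h, W, b, cfg.conv_kernel)
            cache["cols"].append(cols)
            mask = y > 0
            cache["relu"].append(mask)
            y = y * mask
            h, pc = _nn.maxpool_forward(y, cfg.pool_size)
            cache["pool"].append(pc)
        H = cfg.lstm_units
        drop = cfg.lstm_dropout if train else 0.0
        seq1, c1 = _nn.lstm_forward(
            h, self.params["lstm0_W"], self.params["lstm0_U"], self.params["lstm0_b"], H
        )
        if drop > 0:
            m1 = (rng.random(seq1.shape) >= drop).astype(self.dtype) / (1 - drop)
            seq1 = seq1 * m1
        else:
            m1 = None
        seq2, c2 = _nn.lstm_forward(
            seq1, self.params["lstm1_W"], self.params["lstm1_U"], self.params["lstm1_b"], H
        )
        last = seq2[:, -1]
        if drop > 0:
            m2 = (rng.random(last.shape) >= drop).astype(self.dtype) / (1 - drop)
            last = last * m2
        else:
            m2 = None
        logits = last @ self.params["dense_W"] + self.params["dense_b"]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        cache.update(
            conv_in=h, lstm_caches=(c1, c2), masks=(m1, m2), seq_shapes=(seq1.shape, seq2.shape),
            last=last, probs=probs
        )
        return probs, cache

    # -- backward -----------------------------------------------------------

    def backward(self, cache, y_onehot: np.ndarray, sample_w: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.cfg
        probs = cache["probs"]
        B = probs.shape[0]
        grads: dict[str, np.ndarray] = {}
        dz = ((probs - y_onehot) * sample_w[:, None] / B).astype(self.dtype)
        grads["dense_W"] = cache["last"].T @ dz
        grads["dense_b"] = dz.sum(axis=0)
        dlast = dz @ self.params["dense_W"].T
        m1, m2 = cache["masks"]
        if m2 is not None:
            dlast = dlast * m2
        c1, c2 = cache["lstm_caches"]
        s1_shape, s2_shape = cache["seq_shapes"]
        dh2 = np.zeros(s2_shape, dtype=self.dtype)
        dh2[:, -1] = dlast
        dseq1, dW, dU, db = _nn.lstm_backward(
            dh2, c2, self.params["lstm1_W"], self.params["lstm1_U"], cfg.lstm_units
        )
        grads["lstm1_W"], grads["lstm1_U"], grads["lstm1_b"] = dW, dU, db
        if m1 is not None:
            dseq1 = dseq1 * m1
        dh, dW, dU, db = _nn.lstm_backward(
            dseq1, c1, self.params["lstm0_W"], self.params["lstm0_U"], cfg.lstm_units
        )
        grads["lstm0_W"], grads["lstm0_U"], grads["lstm0_b"] = dW, dU, db
        for li in range(2, -1, -1):
            dh = _nn.maxpool_backward(dh, cache["pool"][li], cfg.pool_size)
            dh = dh * cache["relu"][li]
            dh, dW, db = _nn.conv1d_backward(
                dh, cache["cols"][li], self.params[f"conv{li}_W"],
                cache["x_shapes"][li], cfg.conv_kernel
            )
            grads[f"conv{li}_W"], grads[f"conv{li}_b"] = dW, db
        # L2 weight decay on weight matrices (not biases)
        if cfg.l2_weight:
            for k in grads:
                if k.endswith("_W") or k.endswith("_U"):
                    grads[k] = grads[k] + 2.0 * cfg.l2_weight * self.params[k]
        return grads

    def l2_penalty(self) -> float:
        return self.cfg.l2_weight * sum(
            float(np.sum(v.astype(np.float64) ** 2))
            for k, v in self.params.items()
            if k.endswith("_W") or k.endswith("_U")
        )

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def build_model(cfg: ModelConfig = ModelConfig(), seed: int = 0) -> SleepModel:
    """Instantiate the CNN+LSTM with seeded Glorot/orthodox initialization."""
    if cfg.lstm_steps < 2:
        raise ValueError("configuration collapses the time axis before the LSTM")
    return SleepModel(cfg, seed=seed)


# ---------------------------------------------------------------------------
# loss and class weights
# ---------------------------------------------------------------------------

def class_weights(labels: np.ndarray, mode: str = "inverse_frequency") -> np.ndarray:
    """Per-class weight vector over (W, N1, N2, N3, REM).

    ``relative_frequency``: w_c = n_c / N. ``inverse_frequency``
    (default): w_c proportional to N / n_c, normalized to mean 1.
    Classes absent from ``labels`` receive the minimum observed
    frequency, with a warning.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels is empty")
    counts = np.array([np.sum(labels == s) for s in STAGES], dtype=float)
    if np.any(counts == 0):
        warnings.warn(
            f"stages {[s for s, c in zip(STAGES, counts) if c == 0]} absent from "
            "labels; assigning them the minimum observed frequency",
            stacklevel=2,
        )
        counts[counts == 0] = counts[counts > 0].min()
    freq = counts / labels.size
    if mode == "relative_frequency":
        return freq
    if mode == "inverse_frequency":
        w = 1.0 / freq
        return w / w.mean()
    raise ValueError(f"unknown mode {mode!r}")


def weighted_cross_entropy(
    y: np.ndarray, y_hat: np.ndarray, w: np.ndarray
) -> float:
    """Class-weighted categorical cross-entropy for one prediction.

    ``y`` is one-hot (length 5), ``y_hat`` a probability vector, ``w``
    per-class weights. Reduces to ``-w_c log y_hat_c`` for the true
    class ``c``; probabilities are clipped at 1e-7 before the log.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (np.all((y == 0) | (y == 1)) and y.sum() == 1):
        raise ValueError("y must be one-hot")
    if np.any(y_hat < 0) or abs(y_hat.sum() - 1.0) > 1e-6:
        raise ValueError("y_hat must be a probability vector")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    p = np.clip(y_hat, _nn.EPS_LOG, 1.0)
    return float(-np.sum(w * y * np.log(p)))


# ---------------------------------------------------------------------------
# training and inference
# ---------------------------------------------------------------------------

def _onehot(labels: np.ndarray, dtype) -> np.ndarray:
    idx = np.array([STAGE_INDEX[s] for s in labels])
    out = np.zeros((len(idx), len(STAGES)), dtype=dtype)
    out[np.arange(len(idx)), idx] = 1.0
    return out


def train_fold(
    model: SleepModel,
    train: EpochArray,
    val: EpochArray | None,
    tc: TrainConfig,
) -> tuple[SleepModel, dict[str, list[float]]]:
    """Train on one fold for exactly ``tc.n_train_epochs`` passes.

    Batches of ``tc.batch_size`` are reshuffled every pass from a seeded
    generator; the final partial batch is kept. History records the mean
    weighted training loss per pass and, when ``val`` is given,
    validation accuracy per pass. No early stopping: the final-pass
    weights are returned.
    """
    if val is not None:
        overlap = set(train.subjects) & set(val.subjects)
        if overlap:
            raise ValueError(f"subject leakage between train and val: {sorted(overlap)}")
        if val.n_epochs and not val.is_validation:
            pass  # marking is advisory on entry; augmentation enforces it
    rng = np.random.default_rng(tc.seed)
    w = class_weights(train.labels, tc.weight_mode)
    y = _onehot(train.labels, model.dtype)
    yi = y.argmax(axis=1)
    x = train.data
    n = x.shape[0]
    opt = _nn.Adam(model.params, tc.learning_rate, tc.beta1, tc.beta2)
    history: dict = {"loss": [], "val_accuracy": [], "n_steps": 0}
    for _ in range(tc.n_train_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            sel = order[start : start + tc.batch_size]
            probs, cache = model.forward(x[sel], train=True, rng=rng)
            sw = w[yi[sel]].astype(model.dtype)
            p = np.clip(probs[np.arange(len(sel)), yi[sel]], _nn.EPS_LOG, 1.0)
            losses.append(float(np.mean(-sw * np.log(p))))
            grads = model.backward(cache, y[sel], sw)
            opt.step(model.params, grads)
            history["n_steps"] += 1
        history["loss"].append(float(np.mean(losses)))
        if val is not None and val.n_epochs:
            _, stages = predict(model, val)
            history["val_accuracy"].append(float(np.mean(stages == val.labels)) * 100.0)
    return model, history


def predict(model: SleepModel, epochs: EpochArray | np.ndarray, batch_size: int = 256):
    """Per-epoch stage probabilities and argmax labels.

    Ties in the argmax resolve toward the earlier stage in
    (W, N1, N2, N3, REM). Inference is stateless: identical inputs give
    identical outputs.
    """
    x = epochs.data if isinstance(epochs, EpochArray) else np.asarray(epochs)
    probs = np.empty((x.shape[0], len(STAGES)), dtype=np.float64)
    for start in range(0, x.shape[0], batch_size):
        p, _ = model.forward(x[start : start + batch_size], train=False)
        probs[start : start + batch_size] = p
    stages = np.array(STAGES, dtype="<U3")[probs.argmax(axis=1)]
    return probs, stages
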