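"""NumPy building blocks for the CNN+LSTM sleep stager.

Forward and backward passes are written out explicitly (im2col
convolutions, unrolled LSTM) with an Adam optimizer; the network is
small enough (three conv blocks, two 64-unit LSTMs, a 5-way softmax head)
that CPU NumPy trains it in minutes. Everything is driven by a
``numpy.random.Generator``, so runs are bit-reproducible for a fixed
seed.

Gate layout in LSTM weight matrices is (input, forget, cell, output).
"""

from __future__ import annotations

import numpy as np

EPS_LOG = 1e-7


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


# ---------------------------------------------------------------------------
# convolution block: same-padded conv1d (stride 1) + ReLU + max-pool
# ---------------------------------------------------------------------------

def conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, k: int):
    """x (B,T,C) -> y (B,T,F) with zero 'same' padding; caches im2col."""
    B, T, C = x.shape
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B,T,C,k)
    cols = cols.transpose(0, 1, 3, 2).reshape(B, T, k * C)
    y = cols @ W + b
    return y, cols


def conv1d_backward(dy, cols, W, x_shape, k):
    B, T, C = x_shape
    pad = k // 2
    F = W.shape[1]
    dW = cols.reshape(-1, k * C).T @ dy.reshape(-1, F)
    db = dy.sum(axis=(0, 1))
    dcols = (dy @ W.T).reshape(B, T, k, C)
    dxp = np.zeros((B, T + 2 * pad, C), dtype=dy.dtype)
    for j in range(k):
        dxp[:, j : j + T, :] += dcols[:, :, j, :]
    return dxp[:, pad : pad + T, :], dW, db


def maxpool_forward(x: np.ndarray, p: int):
    """Non-overlapping temporal max-pool; trailing remainder truncated."""
    B, T, F = x.shape
    Tp = T // p
    xt = x[:, : Tp * p].reshape(B, Tp, p, F)
    idx = xt.argmax(axis=2)
    y = np.take_along_axis(xt, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return y, (idx, x.shape)


def maxpool_backward(dy, cache, p: int):
    idx, x_shape = cache
    B, T, F = x_shape
    Tp = T // p
    dxt = np.zeros((B, Tp, p, F), dtype=dy.dtype)
    np.put_along_axis(dxt, idx[:, :, None, :], dy[:, :, None, :], axis=2)
    dx = np.zeros(x_shape, dtype=dy.dtype)
    dx[:, : Tp * p] = dxt.reshape(B, Tp * p, F)
    return dx


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

def lstm_init(rng: np.random.Generator, input_dim: int, units: int, dtype):
    W = glorot(rng, (input_dim, 4 * units), dtype)
    U = glorot(rng, (units, 4 * units), dtype)
    b = np.zeros(4 * units, dtype=dtype)
    b[units : 2 * units] = 1.0  # forget-gate bias
    return W, U, b


def lstm_forward(x: np.ndarray, W, U, b, units: int):
    """x (B,T,D) -> h_seq (B,T,H); returns caches for backprop."""
    B, T, _ = x.shape
    H = units
    h = np.zeros((B, H), dtype=x.dtype)
    c = np.zeros((B, H), dtype=x.dtype)
    h_seq = np.empty((B, T, H), dtype=x.dtype)
    caches = []
    for t in range(T):
        z = x[:, t] @ W + h @ U + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        caches.append((x[:, t], h, c, i, f, g, o, tc))
        h, c = h_new, c_new
        h_seq[:, t] = h
    return h_seq, caches


def lstm_backward(dh_seq: np.ndarray, caches, W, U, units: int):
    """dh_seq (B,T,H): upstream gradient at every time step."""
    B, T, H = dh_seq.shape
    dW = np.zeros_like(W)
    dU = np.zeros_like(U)
    db = np.zeros(4 * H, dtype=W.dtype)
    dx = np.empty((B, T, W.shape[0]), dtype=W.dtype)
    dh_next = np.zeros((B, H), dtype=W.dtype)
    dc_next = np.zeros((B, H), dtype=W.dtype)
    for t in range(T - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, g, o, tc = caches[t]
        dh = dh_seq[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ],
            axis=1,
        )
        dW += x_t.T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ W.T
        dh_next = dz @ U.T
    return dx, dW, dU, db


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the configured (lr, beta1, beta2); eps 1e-8."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, beta1: float, beta2: float):
        self.lr, self.b1, self.b2 = lr, beta1, beta2
        self.eps = 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            params[k] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
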