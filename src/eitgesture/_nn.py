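"""Minimal NumPy neural-network layers with hand-derived gradients.

Only what the CG-SVM architecture needs: valid-mode 1-D convolution,
a single-layer GRU, dense layers, ReLU, dropout, and Adam.  Everything is
float64; forward passes return the caches their backward passes need.
Gradient correctness is asserted against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "glorot",
    "conv1d_forward",
    "conv1d_backward",
    "relu",
    "relu_backward",
    "dense_forward",
    "dense_backward",
    "gru_forward",
    "gru_backward",
    "softmax",
    "Adam",
]


def glorot(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_in, fan_out = shape[0] if len(shape) == 2 else int(np.prod(shape[:-1])), shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


# ---------------------------------------------------------------- conv1d

def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid 1-D convolution (cross-correlation).

    x: (B, L, Cin); w: (k, Cin, Cout); b: (Cout,) -> (B, L-k+1, Cout).
    """
    k = w.shape[0]
    lout = x.shape[1] - k + 1
    y = np.broadcast_to(b, (x.shape[0], lout, w.shape[2])).copy()
    for i in range(k):
        y += x[:, i : i + lout, :] @ w[i]
    return y


def conv1d_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (dx, dw, db)."""
    k = w.shape[0]
    lout = dy.shape[1]
    dx = np.zeros_like(x)
    dw = np.zeros_like(w)
    for i in range(k):
        xs = x[:, i : i + lout, :]
        dw[i] = np.einsum("blc,blo->co", xs, dy)
        dx[:, i : i + lout, :] += dy @ w[i].T
    db = dy.sum(axis=(0, 1))
    return dx, dw, db


# ----------------------------------------------------------------- dense

def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(x: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return dy * (x > 0.0)


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    return x @ w + b


def dense_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return dy @ w.T, x.T @ dy, dy.sum(axis=0)


# ------------------------------------------------------------------- gru

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gru_forward(x: np.ndarray, p: dict[str, np.ndarray]) -> tuple[np.ndarray, list]:
    """Single-layer GRU over the full sequence; returns the final hidden
    state (B, H) plus the step cache for BPTT.

    Gates: z = sig(x Wz + h Uz + bz), r = sig(x Wr + h Ur + br),
    n = tanh(x Wn + r * (h Un) + bn), h' = (1 - z) * n + z * h.
    """
    b, t_len, _ = x.shape
    h = np.zeros((b, p["Uz"].shape[0]))
    cache = []
    for t in range(t_len):
        xt = x[:, t, :]
        z = _sigmoid(xt @ p["Wz"] + h @ p["Uz"] + p["bz"])
        r = _sigmoid(xt @ p["Wr"] + h @ p["Ur"] + p["br"])
        hu = h @ p["Un"]
        n = np.tanh(xt @ p["Wn"] + r * hu + p["bn"])
        h_new = (1.0 - z) * n + z * h
        cache.append((xt, h, z, r, n, hu))
        h = h_new
    return h, cache


def gru_backward(
    dh: np.ndarray, p: dict[str, np.ndarray], cache: list
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """BPTT from the gradient of the final hidden state.

    Returns (dx over the sequence, gradients for every GRU parameter).
    """
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    t_len = len(cache)
    b = dh.shape[0]
    dx = np.zeros((b, t_len, p["Wz"].shape[0]))
    for t in range(t_len - 1, -1, -1):
        xt, h_prev, z, r, n, hu = cache[t]
        dn = dh * (1.0 - z)
        dz = dh * (h_prev - n)
        dh_prev = dh * z
        dpre_n = dn * (1.0 - n**2)
        grads["Wn"] += xt.T @ dpre_n
        grads["bn"] += dpre_n.sum(axis=0)
        dx[:, t, :] += dpre_n @ p["Wn"].T
        dr = dpre_n * hu
        dhu = dpre_n * r
        grads["Un"] += h_prev.T @ dhu
        dh_prev = dh_prev + dhu @ p["Un"].T
        dpre_r = dr * r * (1.0 - r)
        grads["Wr"] += xt.T @ dpre_r
        grads["Ur"] += h_prev.T @ dpre_r
        grads["br"] += dpre_r.sum(axis=0)
        dx[:, t, :] += dpre_r @ p["Wr"].T
        dh_prev = dh_prev + dpre_r @ p["Ur"].T
        dpre_z = dz * z * (1.0 - z)
        grads["Wz"] += xt.T @ dpre_z
        grads["Uz"] += h_prev.T @ dpre_z
        grads["bz"] += dpre_z.sum(axis=0)
        dx[:, t, :] += dpre_z @ p["Wz"].T
        dh_prev = dh_prev + dpre_z @ p["Uz"].T
        dh = dh_prev
    return dx, grads


# --------------------------------------------------------------- softmax

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ------------------------------------------------------------------ adam

class Adam:
    """Adam optimizer over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
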