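"""Minimal NumPy neural-network layers with hand-derived gradients.

Only what the dual-encoder CNN needs: 1-D convolutions with same-length
zero padding, rectifiers, dense layers, and Adam.  Forward passes cache
what the backward pass needs; ``backward`` consumes the upstream gradient
and accumulates parameter gradients in ``.grads``.

All arrays are float64 and all randomness flows through an explicit
``numpy.random.Generator``, so runs are bitwise reproducible per seed.
"""

from __future__ import annotations

from typing import Dict, List

import numpy as np


class Layer:
    params: Dict[str, np.ndarray]
    grads: Dict[str, np.ndarray]

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self):
        for k in self.grads:
            self.grads[k][...] = 0.0


class Conv1d(Layer):
    """Cross-correlation along the sequence axis, same-length zero padding.

    Input ``(B, L, C_in)`` -> output ``(B, L, C_out)``.  Left pad is
    ``(K-1)//2`` so odd kernels are center-aligned.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        self.K = kernel_size
        self.C_in = in_channels
        self.C_out = out_channels
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init (ReLU downstream)
        self.params = {
            "W": rng.normal(0.0, scale, size=(kernel_size, in_channels, out_channels)),
            "b": np.zeros(out_channels),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._windows = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        K = self.K
        pl = (K - 1) // 2
        pr = K - 1 - pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # (B, L, K, C_in), a view — cheap
        return np.lib.stride_tricks.sliding_window_view(xp, K, axis=1).transpose(0, 1, 3, 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        win = self._im2col(x)
        self._windows = win
        self._in_shape = x.shape
        return np.tensordot(win, self.params["W"], axes=([2, 3], [0, 1])) + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win = self._windows
        self.grads["W"] += np.tensordot(win, dout, axes=([0, 1], [0, 1]))
        self.grads["b"] += dout.sum(axis=(0, 1))
        # dx: scatter dout back through each kernel offset
        B, L, _ = self._in_shape
        K = self.K
        pl = (K - 1) // 2
        dxp = np.zeros((B, L + K - 1, self.C_in))
        # d_win[b,l,k,ci] = sum_co dout[b,l,co] W[k,ci,co]
        d_win = np.tensordot(dout, self.params["W"], axes=([2], [2]))  # (B,L,K,C_in)
        for k in range(K):
            dxp[:, k:k + L, :] += d_win[:, :, k, :]
        self._windows = None
        return dxp[:, pl:pl + L, :]


class ReLU(Layer):
    def __init__(self):
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = dout * self._mask
        self._mask = None
        return out


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 relu_gain: bool = True):
        scale = np.sqrt((2.0 if relu_gain else 1.0) / in_dim)
        self.params = {
            "W": rng.normal(0.0, scale, size=(in_dim, out_dim)),
            "b": np.zeros(out_dim),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        dx = dout @ self.params["W"].T
        self._x = None
        return dx


class Adam:
    """Plain Adam over a list of layers."""

    def __init__(self, layers: List[Layer], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
                if self.weight_decay and k == "W":
                    p -= self.lr * self.weight_decay * p

    def zero_grad(self):
        for l in self.layers:
            l.zero_grad()
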