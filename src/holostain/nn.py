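"""Minimal CNN primitives in NumPy: conv layers, pooling, bilinear
upsampling, and Adam, with hand-written backpropagation.

Internal layout is NHWC float32 (channels-last keeps 3x3 convolutions as
nine shifted GEMMs on strided views instead of a large im2col copy; the
network wrapper converts from/to the public NCHW contract at its
boundary).  Layers cache only their padded inputs during training
(``train=True``) and cache nothing in inference mode.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Conv3x3:
    """3x3 same convolution (zero padding), He-initialized.

    Weights are (3, 3, Cin, Cout); the forward pass accumulates
    ``y += x[shifted] @ W[ky, kx]`` over the nine taps, and the data
    gradient is the same loop with the spatially flipped, transposed
    kernel.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (cin * 9))
        self.W = rng.normal(0.0, std, (3, 3, cin, cout)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._xp = xp if train else None
        cout = self.W.shape[3]
        y = np.empty((n, h, w, cout), dtype=DTYPE)
        y[:] = self.b
        for ky in range(3):
            for kx in range(3):
                y += xp[:, ky : ky + h, kx : kx + w, :] @ self.W[ky, kx]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        assert xp is not None, "backward() requires a forward() in train mode"
        n, h, w, cout = dy.shape
        cin = self.W.shape[2]
        # weight gradient: one im2col GEMM against the cached padded input
        v = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N, H, W, C, 3, 3)
        cols = np.ascontiguousarray(
            v.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, 9 * cin)
        )
        dyf = dy.reshape(n * h * w, cout)
        self.dW = (cols.T @ dyf).reshape(3, 3, cin, cout)
        self.db = dyf.sum(axis=0)
        # data gradient: full correlation with the flipped kernel
        Wf = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # (3, 3, Cout, Cin)
        dyp = np.pad(dy, ((0, 0), (1, 1), (1, 1), (0, 0)))
        dx = np.zeros((n, h, w, cin), dtype=DTYPE)
        for ky in range(3):
            for kx in range(3):
                dx += dyp[:, ky : ky + h, kx : kx + w, :] @ np.ascontiguousarray(
                    Wf[ky, kx]
                )
        self._xp = None
        return dx


class Conv1x1:
    """Pointwise convolution (channel projection)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / cin)
        self.W = rng.normal(0.0, std, (cin, cout)).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        cin, cout = self.W.shape
        self.dW = x.reshape(-1, cin).T @ dy.reshape(-1, cout)
        self.db = dy.reshape(-1, cout).sum(axis=0)
        self._x = None
        return dy @ self.W.T


class ReLU:
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        out = dy * self._mask
        self._mask = None
        return out


def avgpool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))


def avgpool2_backward(dy: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) * DTYPE(0.25)


_UP_CACHE: Dict[int, np.ndarray] = {}


def _up_matrix(h: int) -> np.ndarray:
    """1-D factor-2 bilinear interpolation matrix (2h x h), half-pixel
    centres (the align_corners=False convention), edges replicated."""
    A = _UP_CACHE.get(h)
    if A is not None:
        return A
    A = np.zeros((2 * h, h), dtype=DTYPE)
    for i in range(2 * h):
        src = (i + 0.5) / 2.0 - 0.5
        i0 = int(np.floor(src))
        f = src - i0
        A[i, min(max(i0, 0), h - 1)] += 1.0 - f
        A[i, min(max(i0 + 1, 0), h - 1)] += f
    _UP_CACHE[h] = A
    return A


def _apply_rows_cols(x: np.ndarray, Ah: np.ndarray, Aw: np.ndarray) -> np.ndarray:
    """y[n, p, q, c] = sum_{h, w} Ah[p, h] Aw[q, w] x[n, h, w, c]."""
    t = np.tensordot(Ah, x, axes=([1], [1]))  # (P, N, W, C)
    t = np.tensordot(Aw, t, axes=([1], [2]))  # (Q, P, N, C)
    return np.ascontiguousarray(t.transpose(2, 1, 0, 3))


def upsample2(x: np.ndarray) -> np.ndarray:
    h, w = x.shape[1:3]
    return _apply_rows_cols(x, _up_matrix(h), _up_matrix(w))


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    h2, w2 = dy.shape[1:3]
    Ah, Aw = _up_matrix(h2 // 2), _up_matrix(w2 // 2)
    return _apply_rows_cols(dy, np.ascontiguousarray(Ah.T), np.ascontiguousarray(Aw.T))


class DoubleConv:
    """(conv3x3 -> ReLU) x 2: cin -> cout -> cout."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.c1 = Conv3x3(cin, cout, rng)
        self.r1 = ReLU()
        self.c2 = Conv3x3(cout, cout, rng)
        self.r2 = ReLU()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.r1.forward(self.c1.forward(x, train), train)
        return self.r2.forward(self.c2.forward(h, train), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.c2.backward(self.r2.backward(dy))
        return self.c1.backward(self.r1.backward(d))

    def layers(self) -> List:
        return [self.c1, self.c2]


class Adam:
    """Adam with bias correction, operating in place on parameter arrays."""

    def __init__(
        self,
        params: List[np.ndarray],
        lr: float = 1e-3,
        betas: Tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
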