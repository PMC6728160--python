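"""Minimal CPU layers for the 2.5D fully-convolutional network.

Everything operates on single-sample channels-first tensors ``(C, H, W)``;
the slice axis of the input volume is the channel axis of the first layer
(the 2.5D representation).  Each layer caches what its backward pass needs
and accumulates parameter gradients in ``dW``/``db``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ReLU", "AvgPool2", "Upsample"]


class Conv2d:
    """Same-padded 2D convolution (kernel 3 or 1) via im2col + BLAS matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        assert kernel in (1, 3)
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel * kernel
        self.W = (rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        if self.kernel == 1:
            return x.reshape(self.c_in, -1)
        C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
        return win.transpose(0, 3, 4, 1, 2).reshape(C * 9, H * W)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = self._im2col(x)
        y = self.W @ self._cols + self.b[:, None]
        return y.reshape(self.c_out, *x.shape[1:])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        C, H, W = self._shape
        dyf = dy.reshape(self.c_out, -1)
        self.dW += dyf @ self._cols.T
        self.db += dyf.sum(axis=1)
        dcols = self.W.T @ dyf
        if self.kernel == 1:
            return dcols.reshape(self._shape)
        dxp = np.zeros((C, H + 2, W + 2), dtype=dy.dtype)
        dcols = dcols.reshape(C, 3, 3, H, W)
        for di in range(3):
            for dj in range(3):
                dxp[:, di:di + H, dj:dj + W] += dcols[:, di, dj]
        return dxp[:, 1:H + 1, 1:W + 1]


class ReLU:
    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class AvgPool2:
    """2x2 mean pooling; spatial dims must be even."""

    def params(self):
        return []

    def forward(self, x):
        C, H, W = x.shape
        self._shape = x.shape
        return x.reshape(C, H // 2, 2, W // 2, 2).mean(axis=(2, 4))

    def backward(self, dy):
        C, H, W = self._shape
        return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) / 4.0


class Upsample:
    """Nearest-neighbour upsampling by an integer factor."""

    def __init__(self, factor: int):
        self.factor = factor

    def params(self):
        return []

    def forward(self, x):
        f = self.factor
        if f == 1:
            return x
        return np.repeat(np.repeat(x, f, axis=1), f, axis=2)

    def backward(self, dy):
        f = self.factor
        if f == 1:
            return dy
        C, H, W = dy.shape
        return dy.reshape(C, H // f, f, W // f, f).sum(axis=(2, 4))
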