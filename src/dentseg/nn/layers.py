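"""Layer primitives (NHWC, stride-1 'same' convolutions lowered to GEMM)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Extract all k x k patches of a zero-padded NHWC array.

    Returns an array of shape (B*H*W, k*k*C) whose rows are the receptive
    fields of each output pixel, so that convolution is a single matmul.
    """
    b, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    sb, sh, sw, sc = xp.strides
    win = as_strided(
        xp,
        shape=(b, h, w, k, k, c),
        strides=(sb, sh, sw, sh, sw, sc),
        writeable=False,
    )
    return np.ascontiguousarray(win).reshape(b * h * w, k * k * c)


class Conv2D:
    """3x3 (or kxk) stride-1 same-padding convolution with bias.

    Weights use He-normal initialisation. ``backward`` returns the input
    gradient and accumulates dW/db; the input-side gradient is itself a
    same-padding convolution with the spatially flipped, channel-transposed
    kernel, so no scatter ops are needed.
    """

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.k = k
        self.cin, self.cout = cin, cout
        std = np.sqrt(2.0 / (k * k * cin))
        self.W = rng.normal(0.0, std, size=(k * k * cin, cout)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._col: np.ndarray | None = None
        self._shape: tuple | None = None

    @property
    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._col = _im2col(x, self.k)
        y = self._col @ self.W + self.b
        return y.reshape(x.shape[0], x.shape[1], x.shape[2], self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, _ = self._shape
        dy_flat = dy.reshape(b * h * w, self.cout)
        self.dW[...] = self._col.T @ dy_flat
        self.db[...] = dy_flat.sum(axis=0)
        # dx = dy * W_flipped^T, again as an im2col convolution
        k = self.k
        Wk = self.W.reshape(k, k, self.cin, self.cout)
        Wflip = Wk[::-1, ::-1].transpose(0, 1, 3, 2).reshape(k * k * self.cout,
                                                             self.cin)
        col = _im2col(dy, k)
        dx = col @ Wflip
        self._col = None
        return dx.reshape(self._shape)


class ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 stride-2 max pooling; gradient routed to the first argmax."""

    params: list = []

    def __init__(self):
        self._arg = None
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        self._shape = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(b, h // 2, w // 2, 4, c)
        self._arg = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._arg[:, :, :, None, :], axis=3)[
            :, :, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        dr = np.zeros((b, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dr, self._arg[:, :, :, None, :],
                          dy[:, :, :, None, :], axis=3)
        dr = dr.reshape(b, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dr.reshape(b, h, w, c)


class UpsampleZero2:
    """x2 zero-stuffing upsample (even grid positions receive the input).

    Followed by a same-padding convolution this realises a stride-2
    transpose convolution of the same kernel size.
    """

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        y = np.zeros((b, 2 * h, 2 * w, c), dtype=x.dtype)
        y[:, ::2, ::2] = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(dy[:, ::2, ::2])
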