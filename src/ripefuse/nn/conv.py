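"""Convolution and pooling layers (channels-first, im2col-based)."""

from __future__ import annotations

from typing import List, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Layer, Param, he_init

__all__ = ["Conv2d", "Conv1d", "MaxPool2d", "MaxPool1d", "GlobalMaxPool1d"]


class Conv2d(Layer):
    """2-D convolution, stride 1, symmetric zero padding (default 'same' for odd kernels)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        padding: Optional[int] = None,
        dtype=np.float32,
    ):
        k = kernel_size
        self.pad = (k - 1) // 2 if padding is None else padding
        fan_in = in_channels * k * k
        self.w = Param(he_init(rng, (out_channels, in_channels, k, k), fan_in, dtype))
        self.b = Param(np.zeros(out_channels, dtype=dtype))
        self.k = k

    def _cols(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        # (N, C, OH, OW, k, k)
        return sliding_window_view(xp, (self.k, self.k), axis=(2, 3))

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols = self._cols(x)
        out = np.tensordot(cols, self.w.value, axes=([1, 4, 5], [1, 2, 3]))
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + self.b.value[None, :, None, None]
        if self.training:
            self._cols_cache, self._x_shape = cols, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols = self._cols_cache
        self.w.grad += np.tensordot(dout, cols, axes=([0, 2, 3], [0, 2, 3]))
        self.b.grad += dout.sum(axis=(0, 2, 3))
        # (N, OH, OW, C, k, k)
        dcols = np.tensordot(dout.transpose(0, 2, 3, 1), self.w.value, axes=([3], [0]))
        n, c, h, w = self._x_shape
        dxp = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=dout.dtype)
        oh, ow = dout.shape[2], dout.shape[3]
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + oh, j : j + ow] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        if self.pad:
            return dxp[:, :, self.pad : -self.pad, self.pad : -self.pad]
        return dxp

    @property
    def params(self) -> List[Param]:
        return [self.w, self.b]


class Conv1d(Layer):
    """1-D convolution, stride 1, 'same' zero padding for odd kernels."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        padding: Optional[int] = None,
        dtype=np.float32,
    ):
        k = kernel_size
        self.pad = (k - 1) // 2 if padding is None else padding
        self.w = Param(he_init(rng, (out_channels, in_channels, k), in_channels * k, dtype))
        self.b = Param(np.zeros(out_channels, dtype=dtype))
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] + 2 * self.pad < self.k:
            raise ValueError(
                f"input length {x.shape[2]} shorter than the receptive field {self.k}"
            )
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        cols = sliding_window_view(xp, self.k, axis=2)  # (N, C, OL, k)
        out = np.tensordot(cols, self.w.value, axes=([1, 3], [1, 2]))  # (N, OL, F)
        out = np.ascontiguousarray(out.transpose(0, 2, 1)) + self.b.value[None, :, None]
        if self.training:
            self._cols_cache, self._x_shape = cols, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols = self._cols_cache
        self.w.grad += np.tensordot(dout, cols, axes=([0, 2], [0, 2]))
        self.b.grad += dout.sum(axis=(0, 2))
        dcols = np.tensordot(dout.transpose(0, 2, 1), self.w.value, axes=([2], [0]))  # (N, OL, C, k)
        n, c, length = self._x_shape
        dxp = np.zeros((n, c, length + 2 * self.pad), dtype=dout.dtype)
        ol = dout.shape[2]
        for i in range(self.k):
            dxp[:, :, i : i + ol] += dcols[:, :, :, i].transpose(0, 2, 1)
        if self.pad:
            return dxp[:, :, self.pad : -self.pad]
        return dxp

    @property
    def params(self) -> List[Param]:
        return [self.w, self.b]


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped (floor)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xr = x[:, :, : h2 * 2, : w2 * 2].reshape(n, c, h2, 2, w2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if self.training:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dxr = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, : h2 * 2, : w2 * 2] = (
            dxr.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2 * 2, w2 * 2)
        )
        return dx


class MaxPool1d(Layer):
    """Max pooling with kernel = stride = 2 over the length axis (floor)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, length = x.shape
        l2 = length // 2
        xr = x[:, :, : l2 * 2].reshape(n, c, l2, 2)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if self.training:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        l2 = length // 2
        dxr = np.zeros((n, c, l2, 2), dtype=dout.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, length), dtype=dout.dtype)
        dx[:, :, : l2 * 2] = dxr.reshape(n, c, l2 * 2)
        return dx


class GlobalMaxPool1d(Layer):
    """Max over the length axis: (N, C, L) -> (N, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        idx = x.argmax(axis=-1)
        out = np.take_along_axis(x, idx[..., None], axis=-1)[..., 0]
        if self.training:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=dout.dtype)
        np.put_along_axis(dx, self._idx[..., None], dout[..., None], axis=-1)
        return dx
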