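"""Single-layer LSTM with full backpropagation through time."""

from __future__ import annotations

from typing import List

import numpy as np

from .core import Layer, Param

__all__ = ["LSTM"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """LSTM over (N, T, D) inputs; emits the final hidden state (N, H).

    Gates in the order input, forget, cell-candidate, output; the forget-gate
    bias starts at +1 so early training does not erase the cell state.
    States are zero-initialized, so a fixed input gives a deterministic code.
    """

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator, dtype=np.float32):
        h = hidden_dim
        scale_x = np.sqrt(1.0 / max(input_dim, 1))
        scale_h = np.sqrt(1.0 / h)
        self.wx = Param((rng.standard_normal((input_dim, 4 * h)) * scale_x).astype(dtype))
        self.wh = Param((rng.standard_normal((h, 4 * h)) * scale_h).astype(dtype))
        b = np.zeros(4 * h, dtype=dtype)
        b[h : 2 * h] = 1.0
        self.b = Param(b)
        self.hidden_dim = h

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3:
            raise ValueError(f"expected (N, T, D) input, got shape {x.shape}")
        if x.shape[1] == 0:
            raise ValueError("empty sequence")
        n, t_steps, _ = x.shape
        h_dim = self.hidden_dim
        h = np.zeros((n, h_dim), dtype=x.dtype)
        c = np.zeros((n, h_dim), dtype=x.dtype)
        cache = [] if self.training else None
        for t in range(t_steps):
            xt = x[:, t, :]
            a = xt @ self.wx.value + h @ self.wh.value + self.b.value
            i = _sigmoid(a[:, :h_dim])
            f = _sigmoid(a[:, h_dim : 2 * h_dim])
            g = np.tanh(a[:, 2 * h_dim : 3 * h_dim])
            o = _sigmoid(a[:, 3 * h_dim :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            if cache is not None:
                cache.append((xt, h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        if cache is not None:
            self._cache, self._x_shape = cache, x.shape
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h_dim = self.hidden_dim
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        dh = dout
        dc = np.zeros_like(dout)
        for t in range(len(self._cache) - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_prev = dc * f
            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)], axis=1
            )
            self.wx.grad += xt.T @ da
            self.wh.grad += h_prev.T @ da
            self.b.grad += da.sum(axis=0)
            dx[:, t, :] = da @ self.wx.value.T
            dh = da @ self.wh.value.T
            dc = dc_prev
        return dx

    @property
    def params(self) -> List[Param]:
        return [self.wx, self.wh, self.b]
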