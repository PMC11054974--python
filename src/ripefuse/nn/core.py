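"""A minimal feed-forward layer library with explicit backpropagation.

Each layer implements ``forward(x)`` / ``backward(dout)`` and exposes its
:class:`Param` objects; :class:`Sequential` chains layers.  Shapes follow the
channels-first convention: dense inputs are ``(N, D)``, 1-D signals
``(N, C, L)``, images ``(N, C, H, W)``.  All randomness (init, dropout) flows
through numpy Generators, so fixed seeds give bit-stable runs.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Linear",
    "ReLU",
    "Dropout",
    "Flatten",
    "BatchNorm",
    "Sequential",
    "ResidualBlock",
]


class Param:
    """A trainable tensor and its gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    training: bool = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def params(self) -> List[Param]:
        return []

    def set_training(self, flag: bool) -> None:
        self.training = flag

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))

    def children(self) -> List["Layer"]:
        return []


def he_init(rng: np.random.Generator, shape, fan_in: int, dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, dtype=np.float32):
        self.w = Param(he_init(rng, (in_dim, out_dim), in_dim, dtype))
        self.b = Param(np.zeros(out_dim, dtype=dtype))
        self._x: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x if self.training else None
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T

    @property
    def params(self) -> List[Param]:
        return [self.w, self.b]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.maximum(x, 0)
        self._mask = x > 0 if self.training else None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if not self.training or self.rate == 0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class BatchNorm(Layer):
    """Batch normalization over the batch (and any trailing spatial axes).

    Accepts ``(N, C)``, ``(N, C, L)`` or ``(N, C, H, W)`` inputs and
    normalizes per channel.  Running statistics are used in eval mode.
    """

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(n_channels, dtype=dtype))
        self.beta = Param(np.zeros(n_channels, dtype=dtype))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels, dtype=dtype)
        self.running_var = np.ones(n_channels, dtype=dtype)

    def _axes(self, x: np.ndarray):
        return (0,) + tuple(range(2, x.ndim))

    def _expand(self, v: np.ndarray, ndim: int) -> np.ndarray:
        return v.reshape((1, -1) + (1,) * (ndim - 2))

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = self._axes(x)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._expand(mean, x.ndim)) * self._expand(inv_std, x.ndim)
        if self.training:
            self._xhat, self._inv_std = xhat, inv_std
            self._n = int(np.prod([x.shape[a] for a in axes]))
        return self._expand(self.gamma.value, x.ndim) * xhat + self._expand(self.beta.value, x.ndim)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = self._axes(dout)
        xhat, inv_std, n = self._xhat, self._inv_std, self._n
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self._expand(self.gamma.value * inv_std, dout.ndim)
        sum_d = self._expand(dout.sum(axis=axes), dout.ndim)
        sum_dx = self._expand((dout * xhat).sum(axis=axes), dout.ndim)
        return (g / n) * (n * dout - sum_d - xhat * sum_dx)

    @property
    def params(self) -> List[Param]:
        return [self.gamma, self.beta]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def params(self) -> List[Param]:
        return [p for layer in self.layers for p in layer.params]

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for layer in self.layers:
            layer.set_training(flag)

    def children(self) -> List[Layer]:
        return list(self.layers)


class ResidualBlock(Layer):
    """y = post(x + branch(x)) with an identity skip.

    The branch must preserve the input width; mismatched widths are rejected
    at forward time.  ``post`` is typically a ReLU applied after the addition.
    """

    def __init__(self, branch: Layer, post: Optional[Layer] = None):
        self.branch = branch
        self.post = post

    def forward(self, x: np.ndarray) -> np.ndarray:
        bx = self.branch.forward(x)
        if bx.shape != x.shape:
            raise ValueError(
                f"residual branch output {bx.shape} incompatible with identity skip {x.shape}"
            )
        s = x + bx
        return self.post.forward(s) if self.post is not None else s

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.post is not None:
            dout = self.post.backward(dout)
        return dout + self.branch.backward(dout)

    @property
    def params(self) -> List[Param]:
        return self.branch.params + (self.post.params if self.post is not None else [])

    def set_training(self, flag: bool) -> None:
        self.training = flag
        self.branch.set_training(flag)
        if self.post is not None:
            self.post.set_training(flag)

    def children(self) -> List[Layer]:
        return [self.branch] + ([self.post] if self.post is not None else [])


def iter_layers(root: Layer):
    """Depth-first iteration over a layer tree."""
    yield root
    for child in root.children():
        yield from iter_layers(child)


def get_state(root: Layer) -> List[np.ndarray]:
    """All trainable parameters plus batch-norm running statistics, in a
    deterministic order suitable for checkpointing."""
    arrays = [p.value.copy() for p in root.params]
    for layer in iter_layers(root):
        if isinstance(layer, BatchNorm):
            arrays += [layer.running_mean.copy(), layer.running_var.copy()]
    return arrays


def set_state(root: Layer, arrays: Sequence[np.ndarray]) -> None:
    params = root.params
    if len(arrays) < len(params):
        raise ValueError("checkpoint has fewer arrays than the model has parameters")
    i = 0
    for p in params:
        if p.value.shape != arrays[i].shape:
            raise ValueError(
                f"checkpoint array {i} shape {arrays[i].shape} != parameter {p.value.shape}"
            )
        p.value[...] = arrays[i]
        i += 1
    for layer in iter_layers(root):
        if isinstance(layer, BatchNorm):
            layer.running_mean[...] = arrays[i]
            layer.running_var[...] = arrays[i + 1]
            i += 2
    if i != len(arrays):
        raise ValueError("checkpoint array count does not match the model")
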