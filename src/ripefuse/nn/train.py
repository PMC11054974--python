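"""Loss, optimizer and the shared mini-batch training loop."""

from __future__ import annotations

import copy
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import BatchNorm, Dropout, Layer, Param, Sequential, get_state, iter_layers, set_state

__all__ = [
    "softmax",
    "cross_entropy",
    "Adam",
    "TapModel",
    "fit_classifier",
    "predict_logits",
    "refresh_batchnorm",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)


class Adam:
    def __init__(self, params: List[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class TapModel(Layer):
    """A backbone with a designated feature tap plus a classification head.

    ``features`` runs the backbone in eval mode and returns the tap
    activation; ``forward`` chains backbone and head for training.
    """

    def __init__(self, backbone: Layer, head: Layer):
        self.backbone = backbone
        self.head = head

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.backbone.forward(x))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.backbone.backward(self.head.backward(dout))

    def features(self, x: np.ndarray) -> np.ndarray:
        was_training = self.training
        self.set_training(False)
        out = self.backbone.forward(x)
        self.set_training(was_training)
        return out

    @property
    def params(self) -> List[Param]:
        return self.backbone.params + self.head.params

    def set_training(self, flag: bool) -> None:
        self.training = flag
        self.backbone.set_training(flag)
        self.head.set_training(flag)

    def children(self) -> List[Layer]:
        return [self.backbone, self.head]


def refresh_batchnorm(model: Layer, x: np.ndarray, max_samples: int = 1024) -> None:
    """Recalibrate batch-norm running statistics on (a subset of) the data.

    Mini-batch running averages can drift far from the statistics of the
    deterministic eval-mode network, especially with small batches; one
    forward pass with momentum 1 and dropout disabled pins the running
    mean/var to the activation statistics the eval network actually sees.
    """
    bns = [l for l in iter_layers(model) if isinstance(l, BatchNorm)]
    if not bns:
        return
    saved_momenta = [bn.momentum for bn in bns]
    was_training = model.training
    # only the BN layers run in batch-stat mode: dropout stays off and no
    # layer caches activations for backprop
    model.set_training(False)
    try:
        for bn in bns:
            bn.momentum = 1.0
            bn.training = True
        model.forward(x[:max_samples])
    finally:
        for bn, m in zip(bns, saved_momenta):
            bn.momentum = m
        model.set_training(was_training)


def predict_logits(model: Layer, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Batched eval-mode forward pass."""
    was_training = model.training
    model.set_training(False)
    out = [model.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    model.set_training(was_training)
    return np.concatenate(out, axis=0)


def fit_classifier(
    model: Layer,
    x: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int,
    batch_size: int,
    lr: float,
    seed: int,
    x_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    checkpoint_best: bool = False,
    verbose: bool = False,
) -> Dict[str, list]:
    """Mini-batch Adam training with per-epoch loss logging.

    When ``checkpoint_best`` is set and a validation split is given, the
    parameter state of the best-validation-loss epoch is restored at the end.
    Returns a history dict with train (and validation) loss per epoch.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=lr)
    history: Dict[str, list] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state: Optional[list] = None

    for epoch in range(epochs):
        order = rng.permutation(len(x))
        model.set_training(True)
        losses = []
        for start in range(0, len(x), batch_size):
            idx = order[start : start + batch_size]
            opt.zero_grad()
            logits = model.forward(x[idx])
            loss, dlogits = cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        refresh_batchnorm(model, x)
        model.set_training(False)
        history["train_loss"].append(float(np.mean(losses)))
        if x_val is not None and len(x_val):
            val_loss, _ = cross_entropy(predict_logits(model, x_val), y_val)
            history["val_loss"].append(val_loss)
            if checkpoint_best and val_loss < best_val:
                best_val = val_loss
                # full state: parameters plus batch-norm running statistics
                best_state = get_state(model)
        if verbose:  # pragma: no cover - logging only
            msg = f"epoch {epoch + 1}/{epochs} train_loss={history['train_loss'][-1]:.4f}"
            if history["val_loss"]:
                msg += f" val_loss={history['val_loss'][-1]:.4f}"
            print(msg)

    if best_state is not None:
        set_state(model, best_state)
    return history
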