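"""The three unimodal deep feature extractors.

* image: a VGG16-style stack (conv blocks of 2, 2, 3, 3, 3 layers, each
  ending in a /2 max-pool).  A 150x150 input leaves the fifth pool as a
  4x4x512 tensor, so the flattened feature tap is 8192-long.
* spectrum: a 1-D CNN of three conv(+BN+ReLU+maxpool) blocks whose last block
  has 10 channels, globally max-pooled to a 10-long tap.
* haptic: a single-layer LSTM with hidden size 64; the tap is the final
  hidden state.

Each extractor carries a small classification head so it can be trained as a
standalone unimodal classifier; the tap activation is what the fusion stage
consumes.  Reduced-width configurations (for quick CPU runs) are supported
but flagged as non-reference via ``reference_exact``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .datatypes import (
    HAPTIC_FEATURE_DIM,
    IMAGE_FEATURE_DIM,
    SPECTRAL_FEATURE_DIM,
    FeatureVector,
    HapticTrace,
    SegmentedImage,
)

__all__ = [
    "TrainConfig",
    "ImageExtractorConfig",
    "SpectralCNNConfig",
    "HapticLSTMConfig",
    "build_image_extractor",
    "build_spectral_cnn",
    "build_haptic_lstm",
    "extract_image_features",
    "extract_spectral_features",
    "extract_haptic_features",
    "prepare_image_batch",
    "prepare_spectrum_batch",
    "prepare_haptic_batch",
    "train_unimodal",
    "HAPTIC_PRESSURE_SCALE",
]

#: traces are divided by this (kPa) before entering the LSTM so activations
#: stay in a numerically comfortable range
HAPTIC_PRESSURE_SCALE = 50.0


@dataclass
class TrainConfig:
    """Optimization hyperparameters shared by all unimodal heads."""

    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0


@dataclass
class ImageExtractorConfig:
    input_size: int = 150
    width_mult: float = 1.0
    blocks: Tuple[int, ...] = (2, 2, 3, 3, 3)
    base_channels: Tuple[int, ...] = (64, 128, 256, 512, 512)
    head_hidden: Tuple[int, int] = (256, 64)
    dropout: float = 0.5
    n_classes: int = 3
    seed: int = 0

    @property
    def channels(self) -> Tuple[int, ...]:
        return tuple(max(1, round(c * self.width_mult)) for c in self.base_channels)

    @property
    def pooled_size(self) -> int:
        s = self.input_size
        for _ in self.blocks:
            s //= 2
        return s

    @property
    def feature_dim(self) -> int:
        return self.pooled_size**2 * self.channels[-1]

    @property
    def reference_exact(self) -> bool:
        return self.feature_dim == IMAGE_FEATURE_DIM


@dataclass
class SpectralCNNConfig:
    channels: Tuple[int, int, int] = (16, 32, 10)
    kernels: Tuple[int, int, int] = (7, 5, 3)
    head_hidden: int = 16
    dropout: float = 0.0
    n_classes: int = 3
    seed: int = 0

    @property
    def feature_dim(self) -> int:
        return self.channels[-1]

    @property
    def reference_exact(self) -> bool:
        return self.feature_dim == SPECTRAL_FEATURE_DIM


@dataclass
class HapticLSTMConfig:
    hidden_dim: int = 64
    input_stride: int = 1  # subsample factor applied to the trace (CPU budget)
    dropout: float = 0.0
    n_classes: int = 3
    seed: int = 0

    @property
    def feature_dim(self) -> int:
        return self.hidden_dim

    @property
    def reference_exact(self) -> bool:
        return self.feature_dim == HAPTIC_FEATURE_DIM and self.input_stride == 1


# --------------------------------------------------------------------------
# model builders


def build_image_extractor(config: Optional[ImageExtractorConfig] = None) -> nn.TapModel:
    """VGG16-style image extractor with an 8192-long feature tap at default width.

    Raises if a full-width configuration would not produce the 8192-long tap
    (e.g. an incompatible input size), naming the offending length.
    """
    config = config or ImageExtractorConfig()
    if config.width_mult == 1.0 and config.feature_dim != IMAGE_FEATURE_DIM:
        raise ValueError(
            f"full-width extractor with input {config.input_size} yields a "
            f"{config.feature_dim}-length feature tap, expected {IMAGE_FEATURE_DIM}"
        )
    rng = np.random.default_rng(config.seed)
    layers = []
    in_c = 3
    for n_convs, out_c in zip(config.blocks, config.channels):
        for _ in range(n_convs):
            layers += [nn.Conv2d(in_c, out_c, 3, rng), nn.ReLU()]
            in_c = out_c
        layers.append(nn.MaxPool2d())
    backbone = nn.Sequential(*layers, nn.Flatten())
    h1, h2 = config.head_hidden
    head = nn.Sequential(
        nn.Linear(config.feature_dim, h1, rng),
        nn.ReLU(),
        nn.Dropout(config.dropout, rng),
        nn.Linear(h1, h2, rng),
        nn.ReLU(),
        nn.Linear(h2, config.n_classes, rng),
    )
    model = nn.TapModel(backbone, head)
    model.config = config
    return model


def build_spectral_cnn(config: Optional[SpectralCNNConfig] = None) -> nn.TapModel:
    """1-D CNN spectral extractor: three conv+BN+ReLU+maxpool blocks, global
    max pool to a 10-long tap, and a two-linear-layer head."""
    config = config or SpectralCNNConfig()
    rng = np.random.default_rng(config.seed)
    layers = []
    in_c = 1
    for out_c, k in zip(config.channels, config.kernels):
        layers += [
            nn.Conv1d(in_c, out_c, k, rng),
            nn.BatchNorm(out_c),
            nn.ReLU(),
            nn.MaxPool1d(),
        ]
        in_c = out_c
    backbone = nn.Sequential(*layers, nn.GlobalMaxPool1d())
    head = nn.Sequential(
        nn.Linear(config.feature_dim, config.head_hidden, rng),
        nn.ReLU(),
        nn.Linear(config.head_hidden, config.n_classes, rng),
    )
    model = nn.TapModel(backbone, head)
    model.config = config
    return model


def build_haptic_lstm(config: Optional[HapticLSTMConfig] = None) -> nn.TapModel:
    """Single-layer LSTM haptic extractor; the tap is the 64-long final hidden state."""
    config = config or HapticLSTMConfig()
    rng = np.random.default_rng(config.seed)
    backbone = nn.Sequential(_TraceToSequence(config.input_stride), nn.LSTM(1, config.hidden_dim, rng))
    head = nn.Sequential(nn.Linear(config.feature_dim, config.n_classes, rng))
    model = nn.TapModel(backbone, head)
    model.config = config
    return model


class _TraceToSequence(nn.Layer):
    """(N, 1, T) channel-first trace -> (N, T', 1) LSTM input, optional stride."""

    def __init__(self, stride: int = 1):
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, T) trace batch, got {x.shape}")
        if x.shape[2] == 0:
            raise ValueError("empty trace")
        self._shape = x.shape
        return x[:, 0, :: self.stride, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dx[:, 0, :: self.stride] = dout[..., 0]
        return dx


# --------------------------------------------------------------------------
# batch preparation and single-sample extraction


def prepare_image_batch(images: Sequence, input_size: int) -> np.ndarray:
    """Stack segmented images into a (N, 3, S, S) float batch scaled to [0, 1]."""
    arrays = []
    for img in images:
        px = img.pixels if isinstance(img, SegmentedImage) else np.asarray(img)
        if px.shape[:2] != (input_size, input_size):
            raise ValueError(
                f"image size {px.shape[:2]} does not match extractor input "
                f"{(input_size, input_size)}; segment/resize first"
            )
        arrays.append(px)
    batch = np.stack(arrays).astype(np.float32) / 255.0
    return np.ascontiguousarray(batch.transpose(0, 3, 1, 2))


def prepare_spectrum_batch(corrected: Sequence[np.ndarray]) -> np.ndarray:
    """Stack corrected spectra into (N, 1, L); NaN channels are interpolated."""
    out = []
    for spec in corrected:
        arr = np.asarray(spec, dtype=np.float32).copy()
        bad = ~np.isfinite(arr)
        if bad.any():
            idx = np.arange(len(arr))
            arr[bad] = np.interp(idx[bad], idx[~bad], arr[~bad])
        out.append(arr)
    return np.stack(out)[:, None, :]


def prepare_haptic_batch(traces: Sequence) -> np.ndarray:
    """Stack (filtered) traces into (N, 1, T), scaled by the pressure norm."""
    arrays = [
        (t.pressure if isinstance(t, HapticTrace) else np.asarray(t, dtype=float))
        for t in traces
    ]
    return (np.stack(arrays).astype(np.float32) / HAPTIC_PRESSURE_SCALE)[:, None, :]


def _single_feature(
    model: nn.TapModel, batch: np.ndarray, modality: str, fruit_id, rotation_index
) -> FeatureVector:
    values = model.features(batch)[0]
    return FeatureVector(
        modality=modality, values=values, fruit_id=fruit_id, rotation_index=rotation_index
    )


def extract_image_features(
    model: nn.TapModel, image, fruit_id=None, rotation_index=None
) -> FeatureVector:
    """Feature tap of one preprocessed (segmented, resized) image."""
    batch = prepare_image_batch([image], model.config.input_size)
    return _single_feature(model, batch, "image", fruit_id, rotation_index)


def extract_spectral_features(
    model: nn.TapModel, corrected: np.ndarray, fruit_id=None, rotation_index=None
) -> FeatureVector:
    return _single_feature(
        model, prepare_spectrum_batch([corrected]), "spectrum", fruit_id, rotation_index
    )


def extract_haptic_features(
    model: nn.TapModel, trace, fruit_id=None, rotation_index=None
) -> FeatureVector:
    return _single_feature(model, prepare_haptic_batch([trace]), "haptic", fruit_id, rotation_index)


# --------------------------------------------------------------------------
# unimodal training


def train_unimodal(
    model: nn.TapModel,
    x: np.ndarray,
    y: np.ndarray,
    split_indices: Dict[str, np.ndarray],
    train_config: Optional[TrainConfig] = None,
    classes: Optional[Sequence[str]] = None,
):
    """Train an extractor as a standalone classifier and report split metrics.

    ``split_indices`` maps 'train'/'val'/'test' to index arrays.  Returns
    ``(model, history, report)`` where the report carries accuracy, per-class
    and macro precision/recall per split.
    """
    from .evaluation import evaluate_classifier  # local import to avoid a cycle

    train_config = train_config or TrainConfig()
    tr = split_indices["train"]
    if len(np.unique(y[tr])) < 2:
        raise ValueError("training split contains a single class")
    history = nn.fit_classifier(
        model,
        x[tr],
        y[tr],
        epochs=train_config.epochs,
        batch_size=train_config.batch_size,
        lr=train_config.lr,
        seed=train_config.seed,
        x_val=x[split_indices.get("val", np.array([], int))]
        if len(split_indices.get("val", [])) else None,
        y_val=y[split_indices.get("val", np.array([], int))]
        if len(split_indices.get("val", [])) else None,
    )
    report = evaluate_classifier(model, x, y, split_indices, classes=classes)
    report.loss_history = history
    return model, history, report
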