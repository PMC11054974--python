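"""Feature-level fusion and the fused fully connected residual classifier.

The splice [m | n | z] concatenates the image (8192), spectral (10) and
haptic (64) taps into an 8266-long cross-modal vector with no scaling or
reweighting.  The classifier is a four-layer fully connected network
(8266 -> 512 -> 512 -> 256 -> classes), every hidden layer followed by batch
normalization, ReLU and dropout, with an identity-skip residual block of two
512-wide FC layers (each + batch norm + dropout) between the second and third
layers; ReLU is applied after the skip addition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .datatypes import (
    FUSED_FEATURE_DIM,
    HAPTIC_FEATURE_DIM,
    IMAGE_FEATURE_DIM,
    SPECTRAL_FEATURE_DIM,
    FeatureVector,
    FusedFeature,
    Stage,
)

__all__ = [
    "REFERENCE_SEGMENT_DIMS",
    "fuse_features",
    "FusionNetConfig",
    "build_fusion_network",
    "DatasetSplit",
    "make_split",
    "train_fusion",
    "predict_maturity",
]

REFERENCE_SEGMENT_DIMS = (IMAGE_FEATURE_DIM, SPECTRAL_FEATURE_DIM, HAPTIC_FEATURE_DIM)


def fuse_features(
    m: FeatureVector,
    n: FeatureVector,
    z: FeatureVector,
    expected_dims: Optional[Tuple[int, int, int]] = REFERENCE_SEGMENT_DIMS,
) -> FusedFeature:
    """Splice the image, spectral and haptic taps into [m | n | z].

    Dimensions are checked against ``expected_dims`` (pass the actual
    extractor dims for reduced-width configurations, or None to skip);
    provenance (fruit id, rotation) must agree across the three inputs.
    """
    for vec, modality in ((m, "image"), (n, "spectrum"), (z, "haptic")):
        if vec.modality != modality:
            raise ValueError(f"expected a {modality} feature in position, got {vec.modality}")
    if expected_dims is not None:
        for vec, dim, name in ((m, expected_dims[0], "image"), (n, expected_dims[1], "spectrum"), (z, expected_dims[2], "haptic")):
            if vec.dim != dim:
                raise ValueError(f"{name} feature has length {vec.dim}, expected {dim}")
    ids = {v.fruit_id for v in (m, n, z) if v.fruit_id is not None}
    rots = {v.rotation_index for v in (m, n, z) if v.rotation_index is not None}
    if len(ids) > 1 or len(rots) > 1:
        raise ValueError(f"provenance mismatch across modalities: ids={ids}, rotations={rots}")
    return FusedFeature(
        values=np.concatenate([m.values, n.values, z.values]),
        segment_dims=(m.dim, n.dim, z.dim),
        fruit_id=next(iter(ids), None),
        rotation_index=next(iter(rots), None),
    )


@dataclass
class FusionNetConfig:
    """Architecture and training hyperparameters of the fused classifier."""

    input_dim: int = FUSED_FEATURE_DIM
    hidden_widths: Tuple[int, int, int] = (512, 512, 256)
    dropout: float = 0.5
    n_classes: int = 3
    lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0

    @property
    def reference_exact(self) -> bool:
        return self.input_dim == FUSED_FEATURE_DIM and self.hidden_widths == (512, 512, 256)


def build_fusion_network(config: Optional[FusionNetConfig] = None) -> nn.Sequential:
    """Build the fused FCNN; ``n_parameters()`` reports the parameter count."""
    config = config or FusionNetConfig()
    rng = np.random.default_rng(config.seed)
    w1, w2, w3 = config.hidden_widths
    d = config.dropout

    def fc_block(i, o):
        return [nn.Linear(i, o, rng), nn.BatchNorm(o), nn.ReLU(), nn.Dropout(d, rng)]

    residual = nn.ResidualBlock(
        nn.Sequential(
            nn.Linear(w2, w2, rng),
            nn.BatchNorm(w2),
            nn.Dropout(d, rng),
            nn.Linear(w2, w2, rng),
            nn.BatchNorm(w2),
            nn.Dropout(d, rng),
        ),
        post=nn.ReLU(),
    )
    net = nn.Sequential(
        *fc_block(config.input_dim, w1),
        *fc_block(w1, w2),
        residual,
        *fc_block(w2, w3),
        nn.Linear(w3, config.n_classes, rng),
    )
    net.config = config
    return net


# --------------------------------------------------------------------------
# split protocol


@dataclass
class DatasetSplit:
    """Fruit-level train/validation/test assignment (all rotations of a fruit
    share a split, preventing rotation leakage)."""

    train: List[str]
    val: List[str]
    test: List[str]
    fractions: Tuple[float, float, float]
    seed: int

    @property
    def assignment(self) -> Dict[str, str]:
        out = {}
        for name in ("train", "val", "test"):
            for fid in getattr(self, name):
                out[fid] = name
        return out

    def indices(self, fruit_ids: Sequence[str]) -> Dict[str, np.ndarray]:
        """Index arrays into a per-acquisition list ordered like ``fruit_ids``."""
        a = self.assignment
        out = {"train": [], "val": [], "test": []}
        for i, fid in enumerate(fruit_ids):
            out[a[fid]].append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}


def make_split(
    manifest,
    fractions: Tuple[float, float, float] = (0.64, 0.16, 0.20),
    seed: int = 0,
) -> DatasetSplit:
    """Stratified fruit-level 64/16/20 split, deterministic per seed."""
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    by_class: Dict[str, List[str]] = {}
    for fruit in manifest.fruits:
        label = manifest.label_of(fruit["fruit_id"])
        by_class.setdefault(label.category, []).append(fruit["fruit_id"])

    train, val, test = [], [], []
    for category in sorted(by_class):
        ids = sorted(by_class[category])
        if len(ids) < 3:
            raise ValueError(
                f"class {category!r} has {len(ids)} fruits, fewer than the 3 splits"
            )
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n = len(ids)
        n_test = max(1, round(fractions[2] * n))
        n_val = max(1, round(fractions[1] * n))
        test += ids[:n_test]
        val += ids[n_test : n_test + n_val]
        train += ids[n_test + n_val :]
    return DatasetSplit(train=train, val=val, test=test, fractions=fractions, seed=seed)


# --------------------------------------------------------------------------
# training and prediction


def train_fusion(
    x_fused: np.ndarray,
    y: np.ndarray,
    split_indices: Dict[str, np.ndarray],
    config: Optional[FusionNetConfig] = None,
    classes: Optional[Sequence[str]] = None,
):
    """Train the fused classifier on cached features from frozen extractors.

    Uses best-validation-epoch checkpointing.  Returns
    ``(model, history, report)``.
    """
    from .evaluation import evaluate_classifier

    config = config or FusionNetConfig()
    if x_fused.shape[0] != len(y):
        raise ValueError(
            f"feature count {x_fused.shape[0]} does not match label count {len(y)}"
        )
    if x_fused.shape[1] != config.input_dim:
        raise ValueError(
            f"fused feature length {x_fused.shape[1]} does not match configured "
            f"input dim {config.input_dim}"
        )
    model = build_fusion_network(config)
    tr, va = split_indices["train"], split_indices.get("val")
    has_val = va is not None and len(va) > 0
    history = nn.fit_classifier(
        model,
        x_fused[tr],
        y[tr],
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.lr,
        seed=config.seed,
        x_val=x_fused[va] if has_val else None,
        y_val=y[va] if has_val else None,
        checkpoint_best=has_val,
    )
    report = evaluate_classifier(model, x_fused, y, split_indices, classes=classes)
    report.loss_history = history
    return model, history, report


def predict_maturity(
    model: nn.Layer,
    fused: FusedFeature,
    classes: Sequence[str] = tuple(s.value for s in Stage),
):
    """Class probabilities and argmax label for one fused vector.

    Softmax probabilities sum to 1; ties break toward the lowest class index.
    """
    first_linear = next(l for l in model.layers if isinstance(l, nn.Linear))
    expected = first_linear.w.value.shape[0]
    if len(fused.values) != expected:
        raise ValueError(
            f"fused feature length {len(fused.values)} does not match model input {expected}"
        )
    logits = nn.predict_logits(model, fused.values[None, :])[0]
    probs = nn.softmax(logits[None, :])[0].astype(float)
    return classes[int(np.argmax(probs))], dict(zip(classes, probs))
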