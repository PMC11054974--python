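"""Checkpoint I/O: parameter arrays in ``.npz`` plus a JSON sidecar carrying
the builder config, seed and metric history, so a checkpoint is
self-describing and reproducible."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from . import nn
from .features import (
    HapticLSTMConfig,
    ImageExtractorConfig,
    SpectralCNNConfig,
    build_haptic_lstm,
    build_image_extractor,
    build_spectral_cnn,
)
from .fusion import FusionNetConfig, build_fusion_network

__all__ = ["save_model", "load_model"]

_BUILDERS = {
    "image": (ImageExtractorConfig, build_image_extractor),
    "spectrum": (SpectralCNNConfig, build_spectral_cnn),
    "haptic": (HapticLSTMConfig, build_haptic_lstm),
    "fusion": (FusionNetConfig, build_fusion_network),
}


def _config_to_dict(config) -> dict:
    out = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        out[f.name] = list(v) if isinstance(v, tuple) else v
    return out


def _config_from_dict(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def save_model(model: nn.Layer, modality: str, path, history: Optional[dict] = None) -> Path:
    """Write ``<path>.npz`` (arrays) and ``<path>.json`` (config sidecar)."""
    if modality not in _BUILDERS:
        raise ValueError(f"unknown modality {modality!r}")
    path = Path(path)
    arrays = nn.get_state(model)
    np.savez(path.with_suffix(".npz"), *arrays)
    config = getattr(model, "config", None)
    sidecar = {
        "modality": modality,
        "config": _config_to_dict(config) if config is not None else None,
        "history": history,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path.with_suffix(".npz")


def load_model(path) -> Tuple[nn.Layer, dict]:
    """Rebuild a model from a checkpoint pair; returns (model, sidecar)."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cls, builder = _BUILDERS[sidecar["modality"]]
    config = _config_from_dict(cls, sidecar["config"]) if sidecar["config"] else None
    model = builder(config)
    with np.load(path.with_suffix(".npz")) as data:
        arrays = [data[k] for k in data.files]
    nn.set_state(model, arrays)
    return model, sidecar
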