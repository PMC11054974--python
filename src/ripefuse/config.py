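"""Run configuration for the end-to-end experiments.

Two presets:

* ``reference`` — every reference dimension (150x150 images, full-width extractors
  with the 8192/10/64 taps, 8266-input fusion net, 79/60/75 fruits).
* ``desk`` — a reduced-width configuration for CPU-scale seeded runs
  (75x75 images, 1/8-width image extractor, LSTM input stride 10, fewer
  fruits and epochs).  The fused layout [m | n | z] and every preprocessing
  step are identical; only widths and problem sizes shrink, and the
  configuration is flagged non-reference via ``reference_exact``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .features import HapticLSTMConfig, ImageExtractorConfig, SpectralCNNConfig, TrainConfig
from .fusion import FusionNetConfig
from .phantom import PhantomConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    preset: str = "desk"
    seed: int = 0
    n_fruits: Tuple[int, int, int] = (20, 20, 20)  # immature, semi, mature
    n_rotations: int = 4
    fractions: Tuple[float, float, float] = (0.64, 0.16, 0.20)
    het_train_per_category: int = 24
    het_val_per_category: int = 6

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    image: ImageExtractorConfig = field(default_factory=ImageExtractorConfig)
    spectral: SpectralCNNConfig = field(default_factory=SpectralCNNConfig)
    haptic: HapticLSTMConfig = field(default_factory=HapticLSTMConfig)
    fusion: FusionNetConfig = field(default_factory=FusionNetConfig)
    image_train: TrainConfig = field(default_factory=TrainConfig)
    spectral_train: TrainConfig = field(default_factory=TrainConfig)
    haptic_train: TrainConfig = field(default_factory=TrainConfig)

    @property
    def fused_dim(self) -> int:
        return self.image.feature_dim + self.spectral.feature_dim + self.haptic.feature_dim

    @property
    def reference_exact(self) -> bool:
        return (
            self.image.reference_exact
            and self.spectral.reference_exact
            and self.haptic.reference_exact
            and self.fusion.reference_exact
        )

    # ---------------------------------------------------------------- presets

    @staticmethod
    def desk(seed: int = 0) -> "RunConfig":
        """CPU-scale preset: reduced widths, small fruit counts, short training."""
        cfg = RunConfig(preset="desk", seed=seed)
        cfg.image = ImageExtractorConfig(
            input_size=75, width_mult=0.125, head_hidden=(64, 32), seed=seed + 2
        )
        cfg.spectral = SpectralCNNConfig(seed=seed + 3)
        cfg.haptic = HapticLSTMConfig(input_stride=10, seed=seed + 4)
        cfg.image_train = TrainConfig(epochs=8, batch_size=16, seed=seed + 2)
        cfg.spectral_train = TrainConfig(epochs=25, batch_size=32, seed=seed + 3)
        cfg.haptic_train = TrainConfig(epochs=25, batch_size=32, seed=seed + 4)
        cfg.fusion = FusionNetConfig(input_dim=cfg.fused_dim, epochs=40, seed=seed + 5)
        return cfg

    @staticmethod
    def reference(seed: int = 0) -> "RunConfig":
        """Reference preset reproducing all reference dimensions (79/60/75 fruits,
        8192/10/64 taps, 8266-input fusion net)."""
        cfg = RunConfig(preset="reference", seed=seed, n_fruits=(79, 60, 75))
        cfg.image = ImageExtractorConfig(seed=seed + 2)
        cfg.spectral = SpectralCNNConfig(seed=seed + 3)
        cfg.haptic = HapticLSTMConfig(seed=seed + 4)
        cfg.image_train = TrainConfig(seed=seed + 2)
        cfg.spectral_train = TrainConfig(seed=seed + 3)
        cfg.haptic_train = TrainConfig(seed=seed + 4)
        cfg.fusion = FusionNetConfig(epochs=50, seed=seed + 5)
        return cfg

    @staticmethod
    def from_preset(name: str, seed: int = 0) -> "RunConfig":
        if name == "desk":
            return RunConfig.desk(seed)
        if name == "reference":
            return RunConfig.reference(seed)
        raise ValueError(f"unknown preset {name!r} (expected 'desk' or 'reference')")

    # ------------------------------------------------------------ serialization

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {getattr(k, "value", k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            return obj

        return clean(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        """Load a config written by :meth:`to_yaml`, starting from the preset
        named in the file and overriding top-level scalars."""
        data = yaml.safe_load(Path(path).read_text())
        cfg = RunConfig.from_preset(data.get("preset", "desk"), int(data.get("seed", 0)))
        for key in ("n_rotations", "het_train_per_category", "het_val_per_category"):
            if key in data:
                setattr(cfg, key, int(data[key]))
        if "n_fruits" in data:
            cfg.n_fruits = tuple(int(v) for v in data["n_fruits"])
        if "fractions" in data:
            cfg.fractions = tuple(float(v) for v in data["fractions"])
        return cfg
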