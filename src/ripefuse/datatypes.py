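"""Shared domain types for the tri-modal tomato maturity pipeline.

A single acquisition of one fruit consists of a color image of the exocarp,
a Vis/NIR transmission spectrum with its white/dark references, and a 100 Hz
grip-pressure trace from a thin-film tactile sensor.  Fruits carry a maturity
stage (defined by the red fraction of the exocarp and cross-section) and,
optionally, a heterogeneous-ripening category for fruits whose exterior is
fully red but whose interior lags behind.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Feature-tap lengths of the three default (reference) extractors and
#: their splice.  image 4*4*512 = 8192, spectral 10, haptic 64.
IMAGE_FEATURE_DIM = 8192
SPECTRAL_FEATURE_DIM = 10
HAPTIC_FEATURE_DIM = 64
FUSED_FEATURE_DIM = IMAGE_FEATURE_DIM + SPECTRAL_FEATURE_DIM + HAPTIC_FEATURE_DIM

MODALITIES = ("image", "spectrum", "haptic")


class Stage(str, enum.Enum):
    """Maturity stage by red fraction: <10%, 10-90%, >90%."""

    IMMATURE = "immature"
    SEMI_MATURE = "semi_mature"
    MATURE = "mature"


STAGES = (Stage.IMMATURE, Stage.SEMI_MATURE, Stage.MATURE)


class Heterogeneity(str, enum.Enum):
    """Uneven-ripening categories: red exterior, interior differs.

    negative1: light-green cavity and flesh; negative2: white cavity;
    positive: uniformly ripe inside and out.
    """

    NEGATIVE1 = "negative1"
    NEGATIVE2 = "negative2"
    POSITIVE = "positive"


HETEROGENEITY_CATEGORIES = (
    Heterogeneity.NEGATIVE1,
    Heterogeneity.NEGATIVE2,
    Heterogeneity.POSITIVE,
)


@dataclass(frozen=True)
class MaturityLabel:
    """Stage label plus optional heterogeneous-ripening category.

    Heterogeneous fruits always render a fully red exterior (apparent stage
    mature); their true category is carried by ``heterogeneity``.
    """

    stage: Stage
    heterogeneity: Optional[Heterogeneity] = None

    @property
    def category(self) -> str:
        """Classification target: the heterogeneity category if set, else the stage."""
        return (self.heterogeneity or self.stage).value

    @staticmethod
    def from_strings(stage: str, heterogeneity: Optional[str] = None) -> "MaturityLabel":
        return MaturityLabel(
            Stage(stage), Heterogeneity(heterogeneity) if heterogeneity else None
        )


@dataclass(frozen=True)
class QualityAttributes:
    """Destructively measured quality attributes of one fruit."""

    ssc: float  # soluble solids content, degrees Brix
    firmness: float  # penetrometer firmness, MPa

    def __post_init__(self) -> None:
        if not (self.ssc > 0 and self.firmness > 0):
            raise ValueError("ssc and firmness must be positive")


@dataclass
class Spectrum:
    """A raw transmission spectrum with its white/dark references.

    The black-and-white correction R = (R_raw - R_d) / (R_w - R_d) removes
    dark current and the lamp/detector profile; ``r_corrected`` is populated
    by :func:`ripefuse.preprocess.correct_spectrum`.
    """

    wavelengths: np.ndarray  # nm, strictly increasing
    r_raw: np.ndarray
    r_white: np.ndarray
    r_dark: np.ndarray
    r_corrected: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for name in ("r_raw", "r_white", "r_dark"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.wavelengths.shape:
                raise ValueError(f"{name} length does not match wavelength grid")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) < 2:
            raise ValueError("wavelength grid must be a 1-D array of length >= 2")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength grid must be strictly increasing")


@dataclass
class HapticTrace:
    """Uniformly sampled grip-pressure series in kPa."""

    pressure: np.ndarray  # kPa
    sample_rate: float = 100.0  # Hz
    duration: float = 15.0  # s

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure, dtype=float)
        expected = round(self.sample_rate * self.duration)
        if len(self.pressure) != expected:
            raise ValueError(
                f"trace length {len(self.pressure)} != sample_rate*duration = {expected}"
            )
        if not np.all(np.isfinite(self.pressure)):
            raise ValueError("pressure trace contains non-finite values")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.pressure)) / self.sample_rate


@dataclass
class SegmentedImage:
    """A background-removed, resized fruit image.

    ``pixels`` is ``out_size x out_size x 3`` uint8 with background zeroed;
    ``mask`` is the boolean foreground.  ``empty`` flags an all-background
    input (warning status, not an error).
    """

    pixels: np.ndarray
    mask: np.ndarray
    empty: bool = False


@dataclass
class TomatoSample:
    """One acquisition: all three modalities of one fruit at one rotation."""

    fruit_id: str
    rotation_index: int
    image: np.ndarray  # HxWx3 uint8
    spectrum: Spectrum
    haptic: HapticTrace
    label: MaturityLabel
    quality: QualityAttributes


@dataclass
class FeatureVector:
    """A fixed-length unimodal embedding (the extractor's feature tap)."""

    modality: str  # "image" | "spectrum" | "haptic"
    values: np.ndarray
    fruit_id: Optional[str] = None
    rotation_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.values = np.asarray(self.values, dtype=np.float32).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    @property
    def dim(self) -> int:
        return len(self.values)


@dataclass
class FusedFeature:
    """The spliced cross-modal vector [m | n | z] (image, spectral, haptic)."""

    values: np.ndarray
    segment_dims: tuple  # (|m|, |n|, |z|)
    fruit_id: Optional[str] = None
    rotation_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32).ravel()
        if len(self.values) != sum(self.segment_dims):
            raise ValueError("fused length does not equal the sum of segment dims")
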