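"""Synthetic tri-modal tomato phantoms.

Generates datasets of (image, spectrum, haptic) acquisition triplets whose
class-conditional statistics are calibrated to reported measurements on real
greenhouse tomatoes:

* maturity stages defined by exocarp red fraction (<10% / 10-90% / >90%);
* SSC class means 4.15 / 4.85 / 5.5 Brix and firmness means 2.82 / 1.96 /
  1.1 MPa (immature -> mature), negatively correlated across ripening;
* Vis/NIR transmission templates with absorption features at 630 / 730 /
  830 / 1070 nm and band intensity over 600-950 nm ordered
  mature > semi-mature > immature;
* grip-pressure plateaus drawn uniformly from 13-26 / 26-46 / 52-65 kPa for
  mature / semi-mature / immature fruit;
* three heterogeneous-ripening categories (negative1, negative2, positive)
  that all render a fully red exterior but plateau near 29 / 29 / 13 kPa,
  with negative1 spectrally well separated from positive and negative2 only
  slightly offset — the designed blind spots of the image and spectral
  modalities.

Every draw is keyed by (dataset seed, fruit id, rotation, modality), so a
manifest plus its seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from .datatypes import (
    HETEROGENEITY_CATEGORIES,
    MODALITIES,
    STAGES,
    HapticTrace,
    Heterogeneity,
    MaturityLabel,
    QualityAttributes,
    Spectrum,
    Stage,
    TomatoSample,
)

__all__ = [
    "PhantomConfig",
    "AcquisitionRecord",
    "Manifest",
    "generate_manifest",
    "generate_quality_attributes",
    "render_image",
    "synthesize_spectrum",
    "spectral_template",
    "synthesize_haptic",
    "generate_sample",
    "iter_samples",
    "write_dataset",
    "load_manifest",
    "read_sample",
    "red_fraction",
]


# --------------------------------------------------------------------------
# configuration


@dataclass
class PhantomConfig:
    """Distribution parameters of the phantom generator.

    Defaults are the calibrated study conditions; all spreads are artifact
    parameters (the calibration source reports means and ranges only).
    """

    # quality attributes per stage (immature, semi_mature, mature)
    ssc_mean: Dict[Stage, float] = field(
        default_factory=lambda: {
            Stage.IMMATURE: 4.15,
            Stage.SEMI_MATURE: 4.85,
            Stage.MATURE: 5.5,
        }
    )
    ssc_sd: float = 0.35  # Brix
    firmness_mean: Dict[Stage, float] = field(
        default_factory=lambda: {
            Stage.IMMATURE: 2.82,
            Stage.SEMI_MATURE: 1.96,
            Stage.MATURE: 1.1,
        }
    )
    firmness_sd: float = 0.30  # MPa
    # heterogeneous categories: firm unripe interiors for the negatives
    het_firmness_mean: Dict[Heterogeneity, float] = field(
        default_factory=lambda: {
            Heterogeneity.NEGATIVE1: 2.9,
            Heterogeneity.NEGATIVE2: 2.6,
            Heterogeneity.POSITIVE: 1.1,
        }
    )
    het_ssc_mean: Dict[Heterogeneity, float] = field(
        default_factory=lambda: {
            Heterogeneity.NEGATIVE1: 4.4,
            Heterogeneity.NEGATIVE2: 4.6,
            Heterogeneity.POSITIVE: 5.5,
        }
    )

    # image rendering
    render_size: int = 200
    background_gray: float = 15.0
    red_margin: int = 30  # red pixel: R > G + margin
    red_fraction_range: Dict[Stage, Tuple[float, float]] = field(
        default_factory=lambda: {
            Stage.IMMATURE: (0.02, 0.08),
            Stage.SEMI_MATURE: (0.15, 0.85),
            Stage.MATURE: (0.92, 1.0),
        }
    )
    het_red_fraction_range: Tuple[float, float] = (0.96, 1.0)

    # spectral model (corrected-transmittance units)
    wavelength_start: float = 350.0
    wavelength_stop: float = 1100.0
    wavelength_step: float = 1.0
    peak_centers: Tuple[float, ...] = (630.0, 730.0, 830.0, 1070.0)
    peak_sigma: float = 8.5  # nm; ~20 nm FWHM features
    peak_amplitude: float = 0.30
    baseline: float = 0.08
    band_window: Tuple[float, float] = (600.0, 950.0)
    # steep edges keep the band plateau flat at 630 nm so the designed
    # absorption feature, not the window slope, sets the local maximum
    band_edge_width: float = 5.0
    band_gain: Dict[Stage, float] = field(
        default_factory=lambda: {
            Stage.IMMATURE: 0.10,
            Stage.SEMI_MATURE: 0.25,
            Stage.MATURE: 0.40,
        }
    )
    # negative categories sit below the positive template by a multiple of
    # the noise scale: negative1 clearly separated, negative2 only slightly.
    het_band_offset_noise_mult: Dict[Heterogeneity, float] = field(
        default_factory=lambda: {
            Heterogeneity.NEGATIVE1: 5.0,
            Heterogeneity.NEGATIVE2: 1.0,
            Heterogeneity.POSITIVE: 0.0,
        }
    )
    spectral_noise_sd: float = 0.01
    band_gain_jitter_sd: float = 0.03  # relative, per acquisition
    lamp_peak_counts: float = 3200.0
    lamp_center: float = 760.0
    lamp_sigma: float = 240.0
    lamp_floor: float = 400.0
    dark_level: float = 80.0

    # haptic model
    sample_rate: float = 100.0  # Hz
    duration: float = 15.0  # s
    approach_end: float = 3.0  # s of near-zero approach
    ramp_end: float = 5.0  # s; plateau from here on
    plateau_range: Dict[Stage, Tuple[float, float]] = field(
        default_factory=lambda: {
            Stage.MATURE: (13.0, 26.0),
            Stage.SEMI_MATURE: (26.0, 46.0),
            Stage.IMMATURE: (52.0, 65.0),
        }
    )
    het_plateau_mean: Dict[Heterogeneity, float] = field(
        default_factory=lambda: {
            Heterogeneity.NEGATIVE1: 29.0,
            Heterogeneity.NEGATIVE2: 29.0,
            Heterogeneity.POSITIVE: 13.0,
        }
    )
    het_plateau_sd: float = 1.0  # kPa
    vibration_freqs: Tuple[float, ...] = (15.0, 23.0, 37.0)  # Hz, above cutoff
    vibration_amp: float = 0.6  # kPa per component
    haptic_noise_sd: float = 0.1  # kPa, white

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wavelength_stop - self.wavelength_start) / self.wavelength_step)) + 1
        return self.wavelength_start + self.wavelength_step * np.arange(n)

    @property
    def n_samples_per_trace(self) -> int:
        return round(self.sample_rate * self.duration)


DEFAULT_CONFIG = PhantomConfig()


# --------------------------------------------------------------------------
# manifest


@dataclass
class AcquisitionRecord:
    fruit_id: str
    rotation_index: int
    modality: str  # image | spectrum | haptic
    stage: str
    heterogeneity: Optional[str]
    file_path: str

    @property
    def label(self) -> MaturityLabel:
        return MaturityLabel.from_strings(self.stage, self.heterogeneity)


@dataclass
class Manifest:
    """Index of one generated dataset: fruits, per-fruit quality, records."""

    seed: int
    class_counts: Dict[str, int]
    n_rotations: int
    fruits: List[dict]  # {fruit_id, stage, heterogeneity, ssc, firmness}
    records: List[AcquisitionRecord]

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "class_counts": self.class_counts,
            "n_rotations": self.n_rotations,
            "fruits": self.fruits,
            "records": [asdict(r) for r in self.records],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @staticmethod
    def from_json(text: str) -> "Manifest":
        payload = json.loads(text)
        return Manifest(
            seed=payload["seed"],
            class_counts=payload["class_counts"],
            n_rotations=payload["n_rotations"],
            fruits=payload["fruits"],
            records=[AcquisitionRecord(**r) for r in payload["records"]],
        )

    @property
    def fruit_ids(self) -> List[str]:
        return [f["fruit_id"] for f in self.fruits]

    def label_of(self, fruit_id: str) -> MaturityLabel:
        f = self._fruit(fruit_id)
        return MaturityLabel.from_strings(f["stage"], f["heterogeneity"])

    def quality_of(self, fruit_id: str) -> QualityAttributes:
        f = self._fruit(fruit_id)
        return QualityAttributes(ssc=f["ssc"], firmness=f["firmness"])

    def _fruit(self, fruit_id: str) -> dict:
        for f in self.fruits:
            if f["fruit_id"] == fruit_id:
                return f
        raise KeyError(f"unknown fruit id {fruit_id!r}")


def _record_rng(seed: int, fruit_id: str, rotation: int, modality: str) -> np.random.Generator:
    """Deterministic per-(fruit, rotation, modality) random stream."""
    key = [int(seed), zlib.crc32(fruit_id.encode()), int(rotation), MODALITIES.index(modality)]
    return np.random.default_rng(np.random.SeedSequence(key))


def generate_manifest(
    n_immature: int,
    n_semi: int,
    n_mature: int,
    n_rotations: int = 4,
    seed: int = 0,
    het_counts: Optional[Dict[Heterogeneity, int]] = None,
    config: Optional[PhantomConfig] = None,
) -> Manifest:
    """Lay out a dataset: fruits with quality attributes plus one record per
    fruit x rotation x modality.

    The default study layout (79, 60, 75) x 4 rotations gives 214 fruits and
    2568 acquisition records.  Deterministic for a fixed seed.
    """
    config = config or DEFAULT_CONFIG
    counts = {Stage.IMMATURE: n_immature, Stage.SEMI_MATURE: n_semi, Stage.MATURE: n_mature}
    for stage, n in counts.items():
        if n < 0:
            raise ValueError(f"count for {stage.value} must be >= 0, got {n}")
    if n_rotations < 1:
        raise ValueError(f"n_rotations must be >= 1, got {n_rotations}")
    het_counts = het_counts or {}
    for cat, n in het_counts.items():
        if n < 0:
            raise ValueError(f"count for {cat.value} must be >= 0, got {n}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF00D]))
    fruits: List[dict] = []
    records: List[AcquisitionRecord] = []
    class_counts: Dict[str, int] = {}

    def add_fruit(label: MaturityLabel, index: int) -> None:
        fruit_id = f"{label.category}-{index:04d}"
        quality = generate_quality_attributes(label, rng, config)
        fruits.append(
            {
                "fruit_id": fruit_id,
                "stage": label.stage.value,
                "heterogeneity": label.heterogeneity.value if label.heterogeneity else None,
                "ssc": round(quality.ssc, 6),
                "firmness": round(quality.firmness, 6),
            }
        )
        subdir = {"image": "images", "spectrum": "spectra", "haptic": "haptic"}
        ext = {"image": "png", "spectrum": "csv", "haptic": "csv"}
        for rot in range(n_rotations):
            for modality in MODALITIES:
                records.append(
                    AcquisitionRecord(
                        fruit_id=fruit_id,
                        rotation_index=rot,
                        modality=modality,
                        stage=label.stage.value,
                        heterogeneity=label.heterogeneity.value if label.heterogeneity else None,
                        file_path=f"{subdir[modality]}/{fruit_id}_r{rot}.{ext[modality]}",
                    )
                )

    for stage in STAGES:
        class_counts[stage.value] = counts[stage]
        for i in range(counts[stage]):
            add_fruit(MaturityLabel(stage), i)
    for cat in HETEROGENEITY_CATEGORIES:
        n = het_counts.get(cat, 0)
        if n or cat in het_counts:
            class_counts[cat.value] = n
        for i in range(n):
            add_fruit(MaturityLabel(Stage.MATURE, cat), i)

    return Manifest(
        seed=int(seed),
        class_counts=class_counts,
        n_rotations=n_rotations,
        fruits=fruits,
        records=records,
    )


# --------------------------------------------------------------------------
# quality attributes


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, low: float = 0.0) -> float:
    """Normal draw truncated (by rejection) to values > low."""
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return float(x)
    raise RuntimeError("truncated normal rejection failed; check mean/sd")


def generate_quality_attributes(
    label: MaturityLabel,
    rng: np.random.Generator,
    config: Optional[PhantomConfig] = None,
) -> QualityAttributes:
    """Draw SSC (Brix) and firmness (MPa) for one fruit.

    Class means follow the calibrated ripening trend (SSC up, firmness down);
    draws are truncated to positive values.
    """
    config = config or DEFAULT_CONFIG
    if label.heterogeneity is not None:
        ssc_mean = config.het_ssc_mean[label.heterogeneity]
        firm_mean = config.het_firmness_mean[label.heterogeneity]
    else:
        if label.stage not in config.ssc_mean:
            raise ValueError(f"unknown stage {label.stage!r}")
        ssc_mean = config.ssc_mean[label.stage]
        firm_mean = config.firmness_mean[label.stage]
    return QualityAttributes(
        ssc=_truncated_normal(rng, ssc_mean, config.ssc_sd),
        firmness=_truncated_normal(rng, firm_mean, config.firmness_sd),
    )


# --------------------------------------------------------------------------
# image modality


def render_image(
    label: MaturityLabel,
    rotation_index: int = 0,
    rng: Optional[np.random.Generator] = None,
    config: Optional[PhantomConfig] = None,
) -> np.ndarray:
    """Render a tomato-like disc on a dark background as HxWx3 uint8.

    The foreground red-pixel fraction is controlled per class: immature
    < 0.10, semi-mature in [0.10, 0.90], mature > 0.90, and any heterogeneous
    category >= 0.95 so that the exterior is indistinguishable from mature.
    The red region is an organic blotch drawn from a smooth angular random
    field; rotation and rng perturb blotch geometry only.
    """
    config = config or DEFAULT_CONFIG
    rng = rng if rng is not None else np.random.default_rng(0)
    size = config.render_size

    if label.heterogeneity is not None:
        lo, hi = config.het_red_fraction_range
    else:
        lo, hi = config.red_fraction_range[label.stage]
    target = rng.uniform(lo, hi)

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    radius = 0.42 * size * rng.uniform(0.97, 1.03)
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    disc = r <= radius

    # smooth blotch field: low-order angular harmonics + gentle radial drift,
    # phase-shifted by the rotation index
    theta = np.arctan2(dy, dx) + rotation_index * (np.pi / 2.0)
    f = np.zeros_like(r)
    for k in range(1, 5):
        f += (rng.normal(0.0, 1.0) / k) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    f += 0.6 * rng.normal(0.0, 1.0) * (r / radius)

    n_fg = int(disc.sum())
    n_red = int(round(target * n_fg))
    red = np.zeros_like(disc)
    if n_red > 0:
        fg_idx = np.flatnonzero(disc)
        order = np.argsort(f.ravel()[fg_idx], kind="stable")
        red.ravel()[fg_idx[order[-n_red:]]] = True

    img = np.empty((size, size, 3), dtype=float)
    img[..., 0] = config.background_gray
    img[..., 1] = config.background_gray
    img[..., 2] = config.background_gray
    img += rng.normal(0.0, 3.0, img.shape)
    img[~disc] = np.clip(img[~disc], 0.0, 40.0)  # keep background below threshold

    green = np.array([70.0, 145.0, 60.0])
    red_col = np.array([185.0, 42.0, 38.0])
    img[disc] = green + rng.normal(0.0, 5.0, (n_fg, 3))
    img[red] = red_col + rng.normal(0.0, 5.0, (int(red.sum()), 3))
    return np.clip(img, 0, 255).astype(np.uint8)


def red_fraction(image: np.ndarray, threshold: float = 50.0, margin: Optional[int] = None) -> float:
    """Fraction of foreground (luma > threshold) pixels that are red.

    Rule-based: a pixel is red when its red channel exceeds the green channel
    by ``margin`` gray levels.
    """
    margin = DEFAULT_CONFIG.red_margin if margin is None else margin
    img = np.asarray(image, dtype=float)
    luma = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    fg = luma > threshold
    if not fg.any():
        return 0.0
    is_red = img[..., 0] > img[..., 1] + margin
    return float(is_red[fg].mean())


# --------------------------------------------------------------------------
# spectral modality


def _band_window(wl: np.ndarray, config: PhantomConfig) -> np.ndarray:
    lo, hi = config.band_window
    w = config.band_edge_width
    rise = 1.0 / (1.0 + np.exp(-(wl - lo) / w))
    fall = 1.0 / (1.0 + np.exp((wl - hi) / w))
    return rise * fall


def spectral_template(
    label: MaturityLabel, config: Optional[PhantomConfig] = None
) -> np.ndarray:
    """Noise-free corrected-transmittance template for a class.

    baseline + Gaussian features at the four calibrated centers + a
    class-gain band over 600-950 nm (mature > semi > immature; negative
    categories offset below the positive template by a multiple of the
    noise scale).
    """
    config = config or DEFAULT_CONFIG
    wl = config.wavelengths
    peaks = np.zeros_like(wl)
    for c in config.peak_centers:
        peaks += np.exp(-0.5 * ((wl - c) / config.peak_sigma) ** 2)
    if label.heterogeneity is not None:
        gain = config.band_gain[Stage.MATURE] - (
            config.het_band_offset_noise_mult[label.heterogeneity] * config.spectral_noise_sd
        )
    else:
        gain = config.band_gain[label.stage]
    return config.baseline + config.peak_amplitude * peaks + gain * _band_window(wl, config)


def synthesize_spectrum(
    label: MaturityLabel,
    rng: Optional[np.random.Generator] = None,
    config: Optional[PhantomConfig] = None,
) -> Spectrum:
    """Emit the full correction triplet (raw, white, dark) for one acquisition.

    The triplet is constructed so that the black-and-white-corrected spectrum
    equals the class template plus per-wavelength noise and a small relative
    band-gain jitter.
    """
    config = config or DEFAULT_CONFIG
    rng = rng if rng is not None else np.random.default_rng(0)
    wl = config.wavelengths
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be strictly increasing")

    template = spectral_template(label, config)
    jitter = 1.0 + rng.normal(0.0, config.band_gain_jitter_sd) if config.band_gain_jitter_sd else 1.0
    corrected = template * jitter + rng.normal(0.0, config.spectral_noise_sd, wl.shape)

    lamp = config.lamp_peak_counts * np.exp(
        -0.5 * ((wl - config.lamp_center) / config.lamp_sigma) ** 2
    ) + config.lamp_floor
    r_dark = np.full_like(wl, config.dark_level)
    r_white = r_dark + lamp
    r_raw = r_dark + corrected * lamp
    return Spectrum(wavelengths=wl, r_raw=r_raw, r_white=r_white, r_dark=r_dark)


# --------------------------------------------------------------------------
# haptic modality


def synthesize_haptic(
    label: MaturityLabel,
    rng: Optional[np.random.Generator] = None,
    config: Optional[PhantomConfig] = None,
) -> HapticTrace:
    """Simulate one grip-pressure trace (default 100 Hz x 15 s = 1500 samples).

    Approach near zero, a half-cosine grip ramp, then a plateau whose level is
    uniform inside the calibrated class range (or Gaussian around the category
    mean for heterogeneous fruit).  Mechanical vibration is injected above the
    10 Hz cutoff so the low-pass stage is exercised.
    """
    config = config or DEFAULT_CONFIG
    rng = rng if rng is not None else np.random.default_rng(0)
    t = np.arange(config.n_samples_per_trace) / config.sample_rate

    if label.heterogeneity is not None:
        level = _truncated_normal(
            rng, config.het_plateau_mean[label.heterogeneity], config.het_plateau_sd
        )
    else:
        lo, hi = config.plateau_range[label.stage]
        level = rng.uniform(lo, hi)

    envelope = np.zeros_like(t)
    ramp = (t >= config.approach_end) & (t < config.ramp_end)
    envelope[ramp] = 0.5 * (
        1 - np.cos(np.pi * (t[ramp] - config.approach_end) / (config.ramp_end - config.approach_end))
    )
    envelope[t >= config.ramp_end] = 1.0
    pressure = level * envelope

    for f_hz in config.vibration_freqs:
        pressure += config.vibration_amp * np.sin(2 * np.pi * f_hz * t + rng.uniform(0, 2 * np.pi))
    pressure += rng.normal(0.0, config.haptic_noise_sd, t.shape)
    return HapticTrace(pressure=pressure, sample_rate=config.sample_rate, duration=config.duration)


# --------------------------------------------------------------------------
# sample assembly and disk I/O


def generate_sample(
    manifest: Manifest,
    fruit_id: str,
    rotation_index: int,
    config: Optional[PhantomConfig] = None,
) -> TomatoSample:
    """Regenerate one acquisition triplet deterministically from the manifest seed."""
    config = config or DEFAULT_CONFIG
    label = manifest.label_of(fruit_id)
    quality = manifest.quality_of(fruit_id)
    seed = manifest.seed
    image = render_image(
        label, rotation_index, _record_rng(seed, fruit_id, rotation_index, "image"), config
    )
    spectrum = synthesize_spectrum(
        label, _record_rng(seed, fruit_id, rotation_index, "spectrum"), config
    )
    haptic = synthesize_haptic(
        label, _record_rng(seed, fruit_id, rotation_index, "haptic"), config
    )
    return TomatoSample(
        fruit_id=fruit_id,
        rotation_index=rotation_index,
        image=image,
        spectrum=spectrum,
        haptic=haptic,
        label=label,
        quality=quality,
    )


def iter_samples(
    manifest: Manifest, config: Optional[PhantomConfig] = None
) -> Iterator[TomatoSample]:
    for fruit in manifest.fruits:
        for rot in range(manifest.n_rotations):
            yield generate_sample(manifest, fruit["fruit_id"], rot, config)


def write_dataset(
    manifest: Manifest,
    out_dir,
    config: Optional[PhantomConfig] = None,
    overwrite: bool = False,
) -> Path:
    """Materialize a manifest to disk: PNG images, CSV spectra/traces, manifest.json."""
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True to replace it"
        )
    for sub in ("images", "spectra", "haptic"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    for sample in iter_samples(manifest, config):
        stem = f"{sample.fruit_id}_r{sample.rotation_index}"
        Image.fromarray(sample.image).save(out_dir / "images" / f"{stem}.png")
        spec = sample.spectrum
        pd.DataFrame(
            {
                "wavelength_nm": spec.wavelengths,
                "raw": spec.r_raw,
                "white_ref": spec.r_white,
                "dark_ref": spec.r_dark,
            }
        ).to_csv(out_dir / "spectra" / f"{stem}.csv", index=False, float_format="%.6f")
        trace = sample.haptic
        pd.DataFrame(
            {"time_s": trace.times, "pressure_kpa": trace.pressure}
        ).to_csv(out_dir / "haptic" / f"{stem}.csv", index=False, float_format="%.6f")

    manifest_path.write_text(manifest.to_json())
    return out_dir


def load_manifest(path) -> Manifest:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    return Manifest.from_json(path.read_text())


def read_sample(dataset_dir, manifest: Manifest, fruit_id: str, rotation_index: int) -> TomatoSample:
    """Read one acquisition triplet back from a written dataset."""
    dataset_dir = Path(dataset_dir)
    stem = f"{fruit_id}_r{rotation_index}"
    image = np.asarray(Image.open(dataset_dir / "images" / f"{stem}.png").convert("RGB"))
    spec_df = pd.read_csv(dataset_dir / "spectra" / f"{stem}.csv")
    spectrum = Spectrum(
        wavelengths=spec_df["wavelength_nm"].to_numpy(),
        r_raw=spec_df["raw"].to_numpy(),
        r_white=spec_df["white_ref"].to_numpy(),
        r_dark=spec_df["dark_ref"].to_numpy(),
    )
    trace_df = pd.read_csv(dataset_dir / "haptic" / f"{stem}.csv")
    haptic = HapticTrace(pressure=trace_df["pressure_kpa"].to_numpy())
    return TomatoSample(
        fruit_id=fruit_id,
        rotation_index=rotation_index,
        image=image,
        spectrum=spectrum,
        haptic=haptic,
        label=manifest.label_of(fruit_id),
        quality=manifest.quality_of(fruit_id),
    )
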