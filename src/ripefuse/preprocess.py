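"""Modality-specific preprocessing.

Image: gray-threshold background removal (fixed threshold 50) and resize to
150x150.  Spectrum: black-and-white correction R = (R_raw - R_d)/(R_w - R_d).
Haptic: zero-phase order-4 Butterworth low-pass at 10 Hz, plateau summary, and
averaging of the four equatorial readings.  Firmness: P = F/A for an 8 mm
plunger tip.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from scipy import signal

from .datatypes import HapticTrace, SegmentedImage, Spectrum

__all__ = [
    "LUMA_WEIGHTS",
    "segment_image",
    "correct_spectrum",
    "butterworth_lowpass",
    "plateau_level",
    "average_equatorial_readings",
    "firmness_from_force",
    "FirmnessMeasurement",
]

#: standard Rec.601 luma weights for grayscale conversion
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def luma(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    wr, wg, wb = LUMA_WEIGHTS
    return wr * img[..., 0] + wg * img[..., 1] + wb * img[..., 2]


def segment_image(
    image: np.ndarray, threshold: float = 50.0, out_size: int = 150
) -> SegmentedImage:
    """Separate the fruit from the dark background and standardize the size.

    The image is converted to grayscale with standard luma weights; pixels
    strictly above ``threshold`` are foreground.  Background is zeroed and the
    result resized to ``out_size`` x ``out_size`` (bilinear for pixels).  The
    output mask is recomputed on the resized pixels, which makes the operation
    idempotent.  An empty foreground raises a warning, not an exception.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 color image")
    if img.dtype != np.uint8:
        img = np.clip(np.asarray(img, dtype=float), 0, 255).astype(np.uint8)

    mask = luma(img) > threshold
    empty = not mask.any()
    if empty:
        warnings.warn("segment_image: empty foreground (no pixel above threshold)")
        zeros = np.zeros((out_size, out_size, 3), dtype=np.uint8)
        return SegmentedImage(pixels=zeros, mask=np.zeros((out_size, out_size), bool), empty=True)

    masked = img.copy()
    masked[~mask] = 0
    resized = np.asarray(
        Image.fromarray(masked).resize((out_size, out_size), Image.BILINEAR)
    )
    out_mask = luma(resized) > threshold
    out = resized.copy()
    out[~out_mask] = 0
    return SegmentedImage(pixels=out, mask=out_mask, empty=False)


def correct_spectrum(spectrum: Spectrum) -> Spectrum:
    """Black-and-white correction R = (R_raw - R_d) / (R_w - R_d).

    Channels where the white and dark references coincide carry no
    information; they are set to NaN (flagged invalid) rather than silently
    propagated as infinities, and a warning is emitted.

    The correction is invariant to a common positive rescaling of the raw
    signal and both references.
    """
    if spectrum.r_white is None or spectrum.r_dark is None:
        raise ValueError("white and dark references are required")
    denom = spectrum.r_white - spectrum.r_dark
    invalid = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = (spectrum.r_raw - spectrum.r_dark) / denom
    if invalid.any():
        warnings.warn(
            f"correct_spectrum: {int(invalid.sum())} channel(s) with R_w == R_d marked invalid"
        )
        corrected = corrected.copy()
        corrected[invalid] = np.nan
    return Spectrum(
        wavelengths=spectrum.wavelengths,
        r_raw=spectrum.r_raw,
        r_white=spectrum.r_white,
        r_dark=spectrum.r_dark,
        r_corrected=corrected,
    )


def butterworth_lowpass(
    trace: HapticTrace, cutoff: float = 10.0, order: int = 4
) -> HapticTrace:
    """Zero-phase (forward-backward) Butterworth low-pass.

    A single pass has magnitude 1/sqrt(1 + (f/f_c)^(2*order)); the
    forward-backward application squares it, removing phase distortion of the
    plateau onset.  Output length equals input length.
    """
    nyquist = trace.sample_rate / 2.0
    if not 0 < cutoff < nyquist:
        raise ValueError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff}")
    sos = signal.butter(order, cutoff, btype="low", fs=trace.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.pressure)
    return HapticTrace(
        pressure=filtered, sample_rate=trace.sample_rate, duration=trace.duration
    )


def plateau_level(trace: HapticTrace, prefilter: bool = True) -> float:
    """Summarize a grip trace by its plateau pressure (kPa).

    The summary is the mean over the longest contiguous run of samples whose
    level lies in the top quartile of the (filtered) trace values — robust to
    the length of the approach and ramp segments.
    """
    x = butterworth_lowpass(trace).pressure if prefilter else trace.pressure
    thresh = np.quantile(x, 0.75)
    high = x >= thresh
    # longest contiguous run of highs
    best_start = best_len = cur_start = cur_len = 0
    for i, h in enumerate(high):
        if h:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_start, best_len = cur_start, cur_len
        else:
            cur_len = 0
    return float(x[best_start : best_start + best_len].mean())


def average_equatorial_readings(
    traces: Sequence[HapticTrace], expected_count: int = 4, prefilter: bool = True
) -> float:
    """Overall pressure of one fruit: mean plateau over its equatorial readings."""
    if len(traces) != expected_count:
        raise ValueError(f"expected {expected_count} traces, got {len(traces)}")
    lengths = {len(t.pressure) for t in traces}
    if len(lengths) != 1:
        raise ValueError(f"traces have unequal lengths: {sorted(lengths)}")
    return float(np.mean([plateau_level(t, prefilter=prefilter) for t in traces]))


@dataclass(frozen=True)
class FirmnessMeasurement:
    """A penetrometer reading: P = F / A."""

    force: float  # N
    contact_area: float  # m^2

    @property
    def pressure(self) -> float:  # Pa
        return self.force / self.contact_area


def firmness_from_force(force: float, probe_diameter: float = 0.008) -> float:
    """Firmness in Pa from a penetrometer force in N (default 8 mm plunger tip)."""
    if probe_diameter <= 0:
        raise ValueError(f"probe diameter must be positive, got {probe_diameter}")
    if force < 0:
        raise ValueError(f"force must be >= 0, got {force}")
    area = math.pi * (probe_diameter / 2.0) ** 2
    return FirmnessMeasurement(force=force, contact_area=area).pressure
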