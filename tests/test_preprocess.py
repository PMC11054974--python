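"""Preprocessing: reference correction, segmentation, filtering, firmness."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from ripefuse import phantom, preprocess
from ripefuse.datatypes import HapticTrace, MaturityLabel, Spectrum, Stage


def make_spectrum(raw, white, dark, n=16):
    wl = np.linspace(400, 900, n)
    return Spectrum(wl, np.full(n, raw), np.full(n, white), np.full(n, dark))


class TestSpectrumCorrection:
    def test_dark_maps_to_zero(self):
        spec = preprocess.correct_spectrum(make_spectrum(100.0, 4000.0, 100.0))
        assert np.all(spec.r_corrected == 0.0)

    def test_white_maps_to_one(self):
        spec = preprocess.correct_spectrum(make_spectrum(4000.0, 4000.0, 100.0))
        assert np.all(spec.r_corrected == 1.0)

    def test_midpoint_maps_to_half(self):
        spec = preprocess.correct_spectrum(make_spectrum(2050.0, 4000.0, 100.0))
        assert np.allclose(spec.r_corrected, 0.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        raw=st.floats(min_value=0, max_value=5000),
        dark=st.floats(min_value=1, max_value=500),
        span=st.floats(min_value=10, max_value=5000),
    )
    def test_affine_invariance(self, scale, raw, dark, span):
        """A common positive rescaling of raw signal and references leaves the
        corrected spectrum unchanged."""
        a = preprocess.correct_spectrum(make_spectrum(raw, dark + span, dark))
        b = preprocess.correct_spectrum(
            make_spectrum(raw * scale, (dark + span) * scale, dark * scale)
        )
        assert np.allclose(a.r_corrected, b.r_corrected, rtol=1e-9, atol=1e-9)

    def test_equal_references_marked_invalid(self):
        spec = make_spectrum(100.0, 200.0, 200.0)
        with pytest.warns(UserWarning, match="invalid"):
            out = preprocess.correct_spectrum(spec)
        assert np.all(np.isnan(out.r_corrected))

    def test_shape_mismatch_rejected(self):
        wl = np.linspace(400, 900, 8)
        with pytest.raises(ValueError, match="length"):
            Spectrum(wl, np.zeros(8), np.ones(7), np.zeros(8))

    def test_decreasing_grid_rejected(self):
        wl = np.linspace(900, 400, 8)
        with pytest.raises(ValueError, match="increasing"):
            Spectrum(wl, np.zeros(8), np.ones(8), np.zeros(8))


class TestSegmentation:
    def test_all_background_warns_and_flags(self):
        img = np.full((60, 60, 3), 40, dtype=np.uint8)
        with pytest.warns(UserWarning, match="empty foreground"):
            seg = preprocess.segment_image(img)
        assert seg.empty
        assert not seg.mask.any()

    def test_bright_disc_isolated(self):
        img = np.full((120, 120, 3), 10, dtype=np.uint8)
        yy, xx = np.mgrid[0:120, 0:120]
        disc = (yy - 60) ** 2 + (xx - 60) ** 2 < 40**2
        img[disc] = 200
        seg = preprocess.segment_image(img)
        assert seg.pixels.shape == (150, 150, 3)
        assert 0.2 < seg.mask.mean() < 0.5  # disc covers ~35% of the frame
        assert np.all(seg.pixels[~seg.mask] == 0)

    def test_mask_matches_perpixel_oracle(self):
        """At native resolution the mask equals a brute-force scan gray > 50."""
        img = phantom.render_image(
            MaturityLabel(Stage.MATURE), 0, np.random.default_rng(0)
        )
        seg = preprocess.segment_image(img, out_size=img.shape[0])
        oracle = np.zeros(img.shape[:2], dtype=bool)
        for i in range(img.shape[0]):
            for j in range(img.shape[1]):
                r, g, b = (float(v) for v in img[i, j])
                oracle[i, j] = 0.299 * r + 0.587 * g + 0.114 * b > 50
        assert np.array_equal(seg.mask, oracle)

    def test_idempotent(self):
        img = phantom.render_image(
            MaturityLabel(Stage.SEMI_MATURE), 0, np.random.default_rng(1)
        )
        once = preprocess.segment_image(img)
        twice = preprocess.segment_image(once.pixels)
        assert np.array_equal(once.pixels, twice.pixels)
        assert np.array_equal(once.mask, twice.mask)

    def test_rejects_non_color_input(self):
        with pytest.raises(ValueError):
            preprocess.segment_image(np.zeros((50, 50), dtype=np.uint8))


def sinusoid_trace(freq, n=1500, rate=100.0):
    t = np.arange(n) / rate
    return HapticTrace(np.sin(2 * np.pi * freq * t), sample_rate=rate, duration=n / rate)


def steady_amplitude(x):
    """Phase-insensitive amplitude of a steady sinusoid: sqrt(2) * RMS.

    (The sample maximum underestimates the amplitude when the sampling grid
    never lands on a crest, e.g. 10 Hz sampled at 100 Hz.)
    """
    return math.sqrt(2) * float(np.std(x))


class TestButterworth:
    def test_dc_identity(self):
        trace = HapticTrace(np.full(1500, 20.0))
        out = preprocess.butterworth_lowpass(trace)
        assert np.allclose(out.pressure, 20.0, atol=1e-8)
        assert len(out.pressure) == 1500

    def test_gain_at_cutoff(self):
        """Analytic single-pass magnitude at f_c is 1/sqrt(2); the zero-phase
        (forward-backward) filter squares it to 1/2."""
        trace = sinusoid_trace(10.0, n=6000)
        sos = signal.butter(4, 10.0, btype="low", fs=100.0, output="sos")
        single = signal.sosfilt(sos, trace.pressure)
        assert steady_amplitude(single[3000:]) == pytest.approx(1 / math.sqrt(2), rel=0.01)
        double = preprocess.butterworth_lowpass(trace).pressure
        assert steady_amplitude(double[2000:4000]) == pytest.approx(0.5, rel=0.01)

    def test_strong_attenuation_at_40hz(self):
        """Time-domain attenuation at 40 Hz matches the filter's frequency
        response; the digital filter is at least as sharp as the analog
        magnitude 1/sqrt(1 + (f/f_c)^(2n)) (bilinear warping near Nyquist
        only strengthens the stop band)."""
        trace = sinusoid_trace(40.0, n=6000)
        sos = signal.butter(4, 10.0, btype="low", fs=100.0, output="sos")
        single = signal.sosfilt(sos, trace.pressure)
        measured = steady_amplitude(single[3000:])
        _, h = signal.sosfreqz(sos, worN=[40.0], fs=100.0)
        assert measured == pytest.approx(abs(h[0]), rel=0.05)
        assert measured <= 1 / math.sqrt(1 + 4**8)

    def test_cutoff_validation(self):
        trace = HapticTrace(np.zeros(1500))
        with pytest.raises(ValueError, match="cutoff"):
            preprocess.butterworth_lowpass(trace, cutoff=50.0)

    def test_phantom_vibration_suppressed_by_20db(self):
        """Energy above 10 Hz in a generated trace drops by >= 20 dB.

        Measured on the stationary plateau segment: the raw FFT of the whole
        trace is dominated by spectral leakage from the grip step, which
        would mask the vibration band in both numerator and denominator.
        """
        trace = phantom.synthesize_haptic(
            MaturityLabel(Stage.SEMI_MATURE), np.random.default_rng(0)
        )
        filtered = preprocess.butterworth_lowpass(trace)

        def high_energy(x):
            plateau = x[600:]  # past the ramp (t >= 6 s)
            spec = np.abs(np.fft.rfft(plateau - plateau.mean())) ** 2
            freqs = np.fft.rfftfreq(len(plateau), d=0.01)
            return spec[freqs > 10].sum()

        before = high_energy(trace.pressure)
        after = high_energy(filtered.pressure)
        assert 10 * np.log10(before / after) >= 20


class TestPlateauSummaries:
    @staticmethod
    def flat_trace(level, n=1500):
        """Noise-free grip profile: zero approach, linear ramp, plateau."""
        p = np.zeros(n)
        p[300:500] = np.linspace(0, level, 200)
        p[500:] = level
        return HapticTrace(p)

    def test_average_of_known_plateaus(self):
        traces = [self.flat_trace(v) for v in (10, 20, 30, 40)]
        assert preprocess.average_equatorial_readings(traces) == pytest.approx(25.0, abs=0.01)

    def test_permutation_invariant(self):
        traces = [self.flat_trace(v) for v in (10, 20, 30, 40)]
        a = preprocess.average_equatorial_readings(traces)
        b = preprocess.average_equatorial_readings(traces[::-1])
        assert a == pytest.approx(b, rel=1e-12)  # summation order only

    def test_identical_traces_idempotent(self):
        traces = [self.flat_trace(33.0)] * 4
        single = preprocess.plateau_level(traces[0])
        assert preprocess.average_equatorial_readings(traces) == pytest.approx(single)

    def test_count_and_length_validation(self):
        traces = [self.flat_trace(10)] * 3
        with pytest.raises(ValueError, match="expected 4"):
            preprocess.average_equatorial_readings(traces)
        bad = [self.flat_trace(10)] * 3 + [
            HapticTrace(np.zeros(750), sample_rate=100.0, duration=7.5)
        ]
        with pytest.raises(ValueError, match="unequal"):
            preprocess.average_equatorial_readings(bad)


class TestFirmness:
    def test_zero_force(self):
        assert preprocess.firmness_from_force(0.0) == 0.0

    def test_reference_value(self):
        # 1 N over an 8 mm tip: A = 5.0265e-5 m^2, P ~= 1.989e4 Pa
        p = preprocess.firmness_from_force(1.0, probe_diameter=0.008)
        assert p == pytest.approx(1.9894e4, rel=1e-4)

    def test_linearity(self):
        p1 = preprocess.firmness_from_force(2.5)
        p2 = preprocess.firmness_from_force(5.0)
        assert p2 == pytest.approx(2 * p1)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            preprocess.firmness_from_force(1.0, probe_diameter=0.0)
        with pytest.raises(ValueError):
            preprocess.firmness_from_force(-1.0)
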