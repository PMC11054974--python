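"""Phantom generator: dataset layout, calibration statistics, determinism."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from ripefuse import phantom
from ripefuse.datatypes import (
    HETEROGENEITY_CATEGORIES,
    Heterogeneity,
    MaturityLabel,
    Stage,
)
from ripefuse.preprocess import correct_spectrum, plateau_level


def label(stage, het=None):
    return MaturityLabel(stage, het)


class TestManifest:
    @pytest.mark.parametrize(
        "counts,rotations,n_fruits,n_records",
        [
            ((79, 60, 75), 4, 214, 2568),  # the full study layout
            ((1, 0, 0), 1, 1, 3),  # minimal: one fruit, one record per modality
            ((2, 3, 4), 2, 9, 54),
        ],
    )
    def test_layout_counts(self, counts, rotations, n_fruits, n_records):
        m = phantom.generate_manifest(*counts, n_rotations=rotations, seed=0)
        assert len(m.fruits) == n_fruits
        assert len(m.records) == n_records
        # every fruit appears once per rotation and modality
        per_fruit = {}
        for r in m.records:
            per_fruit.setdefault(r.fruit_id, []).append((r.rotation_index, r.modality))
        assert all(len(set(v)) == rotations * 3 for v in per_fruit.values())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="immature"):
            phantom.generate_manifest(-1, 0, 0)
        with pytest.raises(ValueError, match="n_rotations"):
            phantom.generate_manifest(1, 1, 1, n_rotations=0)

    def test_seed_determinism(self):
        a = phantom.generate_manifest(3, 3, 3, seed=7).to_json()
        b = phantom.generate_manifest(3, 3, 3, seed=7).to_json()
        c = phantom.generate_manifest(3, 3, 3, seed=8).to_json()
        assert a == b
        assert a != c

    def test_heterogeneous_counts(self):
        m = phantom.generate_manifest(
            0, 0, 0, n_rotations=1, seed=0,
            het_counts={c: 2 for c in HETEROGENEITY_CATEGORIES},
        )
        assert len(m.fruits) == 6
        assert all(f["heterogeneity"] is not None for f in m.fruits)


class TestQualityAttributes:
    def test_class_means_recovered(self, rng):
        ssc = [
            phantom.generate_quality_attributes(label(Stage.MATURE), rng).ssc
            for _ in range(500)
        ]
        firm = [
            phantom.generate_quality_attributes(label(Stage.IMMATURE), rng).firmness
            for _ in range(500)
        ]
        assert np.mean(ssc) == pytest.approx(5.5, abs=3 * 0.35 / np.sqrt(500))
        assert np.mean(firm) == pytest.approx(2.82, abs=3 * 0.30 / np.sqrt(500))

    def test_zero_variance_degenerates_to_means(self, rng):
        cfg = dataclasses.replace(phantom.PhantomConfig(), ssc_sd=0.0, firmness_sd=0.0)
        q = phantom.generate_quality_attributes(label(Stage.SEMI_MATURE), rng, cfg)
        assert q.ssc == 4.85
        assert q.firmness == 1.96

    def test_monotone_trend_and_negative_correlation(self, rng):
        ssc_means, firm_means, pooled = [], [], []
        for stage in (Stage.IMMATURE, Stage.SEMI_MATURE, Stage.MATURE):
            draws = [
                phantom.generate_quality_attributes(label(stage), rng) for _ in range(300)
            ]
            ssc_means.append(np.mean([q.ssc for q in draws]))
            firm_means.append(np.mean([q.firmness for q in draws]))
            pooled += [(q.ssc, q.firmness) for q in draws]
        assert ssc_means[0] < ssc_means[1] < ssc_means[2]
        assert firm_means[0] > firm_means[1] > firm_means[2]
        ssc, firm = np.array(pooled).T
        assert np.corrcoef(ssc, firm)[0, 1] < -0.5

    def test_draws_positive(self, rng):
        for _ in range(100):
            q = phantom.generate_quality_attributes(label(Stage.MATURE), rng)
            assert q.ssc > 0 and q.firmness > 0


class TestImageRendering:
    @pytest.mark.parametrize(
        "stage,lo,hi",
        [(Stage.IMMATURE, 0.0, 0.10), (Stage.SEMI_MATURE, 0.10, 0.90), (Stage.MATURE, 0.90, 1.0)],
    )
    def test_red_fraction_by_stage(self, stage, lo, hi):
        for seed in range(5):
            img = phantom.render_image(label(stage), 0, np.random.default_rng(seed))
            frac = phantom.red_fraction(img)
            assert lo <= frac <= hi, f"stage {stage}: red fraction {frac}"

    @pytest.mark.parametrize("het", list(Heterogeneity))
    def test_heterogeneous_exteriors_look_mature(self, het):
        """All three uneven-ripening categories render >= 95% red exteriors —
        the image modality cannot separate them by design."""
        for seed in range(3):
            img = phantom.render_image(label(Stage.MATURE, het), 0, np.random.default_rng(seed))
            assert phantom.red_fraction(img) >= 0.95

    def test_background_below_threshold(self):
        img = phantom.render_image(label(Stage.MATURE), 0, np.random.default_rng(0))
        luma = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
        corners = [luma[0, 0], luma[0, -1], luma[-1, 0], luma[-1, -1]]
        assert all(c < 50 for c in corners)

    def test_render_determinism(self):
        a = phantom.render_image(label(Stage.SEMI_MATURE), 1, np.random.default_rng(5))
        b = phantom.render_image(label(Stage.SEMI_MATURE), 1, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestSpectra:
    def test_zero_noise_recovers_template(self, phantom_config):
        cfg = dataclasses.replace(
            phantom_config, spectral_noise_sd=0.0, band_gain_jitter_sd=0.0
        )
        lab = label(Stage.MATURE)
        spec = phantom.synthesize_spectrum(lab, np.random.default_rng(0), cfg)
        corrected = correct_spectrum(spec).r_corrected
        assert np.allclose(corrected, phantom.spectral_template(lab, cfg), atol=1e-9)

    def test_band_intensity_ordering(self, phantom_config):
        """Mean corrected intensity over 600-950 nm: mature > semi > immature."""
        wl = phantom_config.wavelengths
        band = (wl >= 600) & (wl <= 950)
        means = {}
        for stage in (Stage.IMMATURE, Stage.SEMI_MATURE, Stage.MATURE):
            corr = [
                correct_spectrum(
                    phantom.synthesize_spectrum(label(stage), np.random.default_rng(i))
                ).r_corrected[band].mean()
                for i in range(30)
            ]
            means[stage] = np.mean(corr)
        assert means[Stage.MATURE] > means[Stage.SEMI_MATURE] > means[Stage.IMMATURE]

    def test_mature_mean_spectrum_peaks_at_630(self, phantom_config):
        wl = phantom_config.wavelengths
        mean = np.mean(
            [
                correct_spectrum(
                    phantom.synthesize_spectrum(label(Stage.MATURE), np.random.default_rng(i))
                ).r_corrected
                for i in range(50)
            ],
            axis=0,
        )
        window = (wl >= 580) & (wl <= 680)
        assert wl[window][np.argmax(mean[window])] == 630.0

    def test_negative_category_separations(self, phantom_config):
        """negative1 sits well below the positive template in the band;
        negative2 only within about one noise scale of it."""
        wl = phantom_config.wavelengths
        band = (wl >= 650) & (wl <= 900)

        def tmpl(het):
            return phantom.spectral_template(label(Stage.MATURE, het), phantom_config)[band].mean()

        pos, n1, n2 = (tmpl(h) for h in (Heterogeneity.POSITIVE, Heterogeneity.NEGATIVE1, Heterogeneity.NEGATIVE2))
        noise = phantom_config.spectral_noise_sd
        assert pos - n1 > 3 * noise
        assert 0 < pos - n2 <= 1.5 * noise

    def test_correction_triplet_shape(self, phantom_config):
        spec = phantom.synthesize_spectrum(label(Stage.IMMATURE), np.random.default_rng(0))
        assert len(spec.wavelengths) == 751  # 350-1100 nm at 1 nm
        assert np.all(spec.r_white > spec.r_dark)


class TestHaptic:
    def test_trace_length_matches_rate_and_duration(self):
        trace = phantom.synthesize_haptic(label(Stage.MATURE), np.random.default_rng(0))
        assert len(trace.pressure) == 1500  # 100 Hz x 15 s

    @pytest.mark.parametrize(
        "stage,lo,hi",
        [(Stage.MATURE, 13, 26), (Stage.SEMI_MATURE, 26, 46), (Stage.IMMATURE, 52, 65)],
    )
    def test_plateau_ranges(self, stage, lo, hi):
        levels = [
            plateau_level(phantom.synthesize_haptic(label(stage), np.random.default_rng(i)))
            for i in range(40)
        ]
        # estimator noise stays well under the inter-class gaps
        assert min(levels) >= lo - 0.5
        assert max(levels) <= hi + 0.5

    def test_class_ranges_disjoint(self):
        batches = {
            stage: [
                plateau_level(phantom.synthesize_haptic(label(stage), np.random.default_rng(i)))
                for i in range(30)
            ]
            for stage in (Stage.MATURE, Stage.SEMI_MATURE, Stage.IMMATURE)
        }
        assert max(batches[Stage.MATURE]) < min(batches[Stage.SEMI_MATURE])
        assert max(batches[Stage.SEMI_MATURE]) < min(batches[Stage.IMMATURE])

    def test_heterogeneous_plateaus(self):
        neg = [
            plateau_level(
                phantom.synthesize_haptic(
                    label(Stage.MATURE, Heterogeneity.NEGATIVE2), np.random.default_rng(i)
                )
            )
            for i in range(30)
        ]
        pos = [
            plateau_level(
                phantom.synthesize_haptic(
                    label(Stage.MATURE, Heterogeneity.POSITIVE), np.random.default_rng(i)
                )
            )
            for i in range(30)
        ]
        assert np.mean(neg) == pytest.approx(29.0, abs=1.0)
        assert np.mean(pos) == pytest.approx(13.0, abs=1.0)

    def test_vibration_above_cutoff(self):
        """Injected vibration concentrates its energy above 10 Hz."""
        trace = phantom.synthesize_haptic(label(Stage.MATURE), np.random.default_rng(3))
        plateau = trace.pressure[600:]  # past the ramp
        spec = np.abs(np.fft.rfft(plateau - plateau.mean())) ** 2
        freqs = np.fft.rfftfreq(len(plateau), d=1 / 100.0)
        assert spec[freqs > 10].sum() > 5 * spec[(freqs > 0.5) & (freqs <= 10)].sum()


class TestDatasetIO:
    def test_write_read_roundtrip(self, tmp_path):
        m = phantom.generate_manifest(1, 0, 0, n_rotations=1, seed=3)
        out = phantom.write_dataset(m, tmp_path / "ds")
        assert (out / "manifest.json").exists()
        files = list((out / "images").glob("*.png")) + list(
            (out / "spectra").glob("*.csv")
        ) + list((out / "haptic").glob("*.csv"))
        assert len(files) == 3  # one file per modality

        loaded = phantom.load_manifest(out)
        fid = loaded.fruit_ids[0]
        disk = phantom.read_sample(out, loaded, fid, 0)
        mem = phantom.generate_sample(m, fid, 0)
        assert np.array_equal(disk.image, mem.image)  # PNG is lossless
        assert np.allclose(disk.spectrum.r_raw, mem.spectrum.r_raw, atol=1e-5)
        assert np.allclose(disk.haptic.pressure, mem.haptic.pressure, atol=1e-5)

    def test_overwrite_protection(self, tmp_path):
        m = phantom.generate_manifest(1, 0, 0, n_rotations=1, seed=3)
        phantom.write_dataset(m, tmp_path / "ds")
        with pytest.raises(FileExistsError):
            phantom.write_dataset(m, tmp_path / "ds")
        phantom.write_dataset(m, tmp_path / "ds", overwrite=True)
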