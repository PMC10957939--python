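"""Corruption operators: noise calibration, fingerprint-preserving
clipping, noise-only spectra and epoch-set composition."""

import numpy as np
import pytest

import ramanvae as rv
from ramanvae.spectra_io import NULL_LABEL, Spectrum, SpectrumBatch, resample
from ramanvae.augment import (
    AugmentConfig,
    add_intensity_noise,
    build_epoch_set,
    clip_range,
    make_noise_only,
    max_clipped_fraction,
)


def flat_spectrum(n=100_000, value=100.0, lo=300.0, hi=3674.0):
    return Spectrum(np.linspace(lo, hi, n), np.full(n, value))


class TestIntensityNoise:
    def test_noise_disabled_limit(self):
        s = flat_spectrum(64)
        out = add_intensity_noise(s, -np.inf, np.random.default_rng(0))
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_variance_matches_closed_form(self):
        """I = 100, level -5 dB: var = 10^(-0.5) * 100^2 = 3162.3, within 5%."""
        s = flat_spectrum(100_000)
        out = add_intensity_noise(s, -5.0, np.random.default_rng(1))
        var = np.var(out.intensities - s.intensities)
        assert var == pytest.approx(10 ** (-0.5) * 100.0**2, rel=0.05)

    def test_axis_unchanged(self):
        s = flat_spectrum(1000)
        out = add_intensity_noise(s, -5.0, np.random.default_rng(2))
        np.testing.assert_array_equal(out.wavenumbers, s.wavenumbers)

    def test_independent_across_calls(self):
        s = flat_spectrum(10_000)
        n1 = add_intensity_noise(s, -5.0, np.random.default_rng(3)).intensities - s.intensities
        n2 = add_intensity_noise(s, -5.0, np.random.default_rng(4)).intensities - s.intensities
        assert abs(np.corrcoef(n1, n2)[0, 1]) < 0.05


class TestClipRange:
    def test_degenerate_fingerprint_only_span(self):
        s = flat_spectrum(500, lo=800.0, hi=1500.0)
        out = clip_range(s, 800.0, 1500.0, np.random.default_rng(0))
        np.testing.assert_array_equal(out.wavenumbers, s.wavenumbers)

    def test_fingerprint_always_retained_and_bounded(self):
        """Over many draws the retained fraction never drops below 1 - 0.7925."""
        s = flat_spectrum(2048)
        fingerprint = (s.wavenumbers >= 800.0) & (s.wavenumbers <= 1500.0)
        n_fp = int(fingerprint.sum())
        rng = np.random.default_rng(1)
        min_frac = 1.0
        for _ in range(1000):
            out = clip_range(s, 800.0, 1500.0, rng)
            kept = set(out.wavenumbers)
            assert all(w in kept for w in s.wavenumbers[fingerprint])
            min_frac = min(min_frac, len(out) / len(s))
        assert min_frac >= n_fp / len(s)
        assert min_frac >= 1 - 0.7925 - 0.01

    def test_worst_case_arithmetic(self):
        # start=800, stop=1500 on [300, 3674]: (500 + 2174) / 3374 of the span
        assert max_clipped_fraction(300.0, 3674.0, 800.0, 1500.0) == pytest.approx(2674 / 3374)

    def test_uncovered_fingerprint_rejected(self):
        s = flat_spectrum(100, lo=900.0, hi=1400.0)
        with pytest.raises(ValueError, match="fingerprint"):
            clip_range(s, 800.0, 1500.0, np.random.default_rng(0))


class TestNoiseOnly:
    def test_axis_passthrough_and_null_label(self):
        s = flat_spectrum(1000)
        out = make_noise_only(s, np.random.default_rng(0))
        np.testing.assert_array_equal(out.wavenumbers, s.wavenumbers)
        assert out.label == NULL_LABEL

    def test_zero_mean_within_standard_error(self):
        rng = np.random.default_rng(1)
        base = Spectrum(np.linspace(300, 3674, 10_000), 100.0 + 5.0 * rng.standard_normal(10_000))
        out = make_noise_only(base, np.random.default_rng(2))
        se = out.intensities.std() / np.sqrt(len(out))
        assert abs(out.intensities.mean()) < 3 * se

    def test_whiteness_lag_one(self):
        rng = np.random.default_rng(3)
        base = Spectrum(np.linspace(300, 3674, 10_000), 100.0 + 5.0 * rng.standard_normal(10_000))
        x = make_noise_only(base, np.random.default_rng(4)).intensities
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r) < 0.05


class TestEpochSet:
    @pytest.fixture
    def raw(self):
        rng = np.random.default_rng(0)
        specs = rv.make_dataset(5, rng=rng)  # 30 spectra
        return SpectrumBatch([resample(s, 128) for s in specs])

    def test_five_copies(self, raw):
        es = build_epoch_set(raw, AugmentConfig(), np.random.default_rng(1))
        assert len(es) == 5 * len(raw)
        assert all(len(p.noisy) == raw.length and len(p.target) == raw.length for p in es)

    def test_same_seed_identical_including_order(self, raw):
        a = build_epoch_set(raw, AugmentConfig(), np.random.default_rng(2))
        b = build_epoch_set(raw, AugmentConfig(), np.random.default_rng(2))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.noisy.intensities, pb.noisy.intensities)
            np.testing.assert_array_equal(pa.noisy.wavenumbers, pb.noisy.wavenumbers)

    def test_label_multiset(self, raw):
        es = build_epoch_set(raw, AugmentConfig(), np.random.default_rng(3))
        labels = [p.noisy.label for p in es]
        assert labels.count(NULL_LABEL) == len(raw)
        from collections import Counter

        raw_counts = Counter(s.label for s in raw)
        got = Counter(l for l in labels if l != NULL_LABEL)
        assert got == {k: 4 * v for k, v in raw_counts.items()}

    def test_different_epochs_differ(self, raw):
        a = build_epoch_set(raw, AugmentConfig(), np.random.default_rng(4))
        b = build_epoch_set(raw, AugmentConfig(), np.random.default_rng(5))
        assert any(
            not np.array_equal(pa.noisy.intensities, pb.noisy.intensities) for pa, pb in zip(a, b)
        )

    def test_fingerprint_retained_in_targets(self, raw):
        """Every target still spans the fingerprint window up to one grid step."""
        step = np.diff(raw[0].wavenumbers).max()
        es = build_epoch_set(raw, AugmentConfig(), np.random.default_rng(6))
        for p in es:
            lo, hi = p.target.range
            assert lo <= 800.0 + step and hi >= 1500.0 - step

    def test_noise_power_calibration_in_epoch(self, raw):
        """Measured noise variance over corrupted copies within 10% of spec."""
        es = build_epoch_set(raw, AugmentConfig(), np.random.default_rng(7))
        ratios = []
        for p in es:
            if p.noisy.label == NULL_LABEL:
                continue
            resid = p.noisy.intensities - p.target.intensities
            if np.allclose(resid, 0):
                continue  # clean copy
            expected = 10 ** (-0.5) * np.mean(p.target.intensities**2)
            ratios.append(np.var(resid) / expected)
        assert len(ratios) >= 3 * len(raw) - 5
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_empty_raw_rejected(self):
        with pytest.raises(ValueError):
            build_epoch_set(SpectrumBatch([]), AugmentConfig(), np.random.default_rng(0))
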