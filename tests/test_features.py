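"""Feature layer: window geometry and the six features against direct
formula evaluation."""

import math

import numpy as np
import pytest

from semgrip.errors import ConfigError
from semgrip.features import (
    FEATURE_NAMES,
    PowerSpectrum,
    SignalWindow,
    WindowingConfig,
    extract_features,
    iemg,
    mean_power_frequency,
    median_frequency,
    power_spectrum,
    rms,
    shannon_entropy,
    slide_windows,
    wl,
)
from semgrip.preprocess import SignalSegment


def make_segment(n, stage="normalized", rate=1000.0, seed=0, label=60.0):
    rng = np.random.default_rng(seed)
    x = np.abs(rng.standard_normal(n)) if stage == "normalized" else rng.standard_normal(n)
    return SignalSegment(samples=x, rate=rate, stage=stage, force_label=label)


class TestWindowing:
    @pytest.mark.parametrize(
        "length,expected",
        [(2000, 32), (256, 1), (255, 0), (311, 1), (312, 2)],
    )
    def test_window_count_formula(self, length, expected):
        segs = slide_windows(make_segment(length))
        assert len(segs) == expected
        if expected:
            assert [w.start for w in segs] == list(range(0, 56 * expected, 56))
            assert all(len(w) == 256 for w in segs)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigError):
            WindowingConfig(window_ms=56, step_ms=256)


def fsum_oracle(x):
    """Direct, numerically careful evaluation of the printed formulas."""
    n = len(x)
    return {
        "iemg": math.fsum(abs(v) for v in x) / n,
        "rms": math.sqrt(math.fsum(v * v for v in x) / n),
        "wl": math.fsum(abs(x[i + 1] - x[i]) for i in range(n - 1)),
    }


class TestTimeDomain:
    def test_worked_examples(self):
        assert iemg(np.array([1.0, 2.0, 3.0, 4.0])) == pytest.approx(2.5)
        assert rms(np.array([3.0, 4.0])) == pytest.approx(math.sqrt(12.5))
        assert wl(np.array([0.0, 1.0, 0.0, 1.0])) == pytest.approx(3.0)

    def test_constant_window_identities(self):
        c = np.full(77, 3.25)
        assert iemg(c) == pytest.approx(3.25)
        assert rms(c) == pytest.approx(3.25)
        assert wl(c) == 0.0

    def test_monotone_window_waveform_length_telescopes(self):
        x = np.sort(np.random.default_rng(0).standard_normal(50))
        assert wl(x) == pytest.approx(x[-1] - x[0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_formula_to_1e9_relative(self, seed):
        x = np.random.default_rng(seed).standard_normal(256)
        expected = fsum_oracle(list(x))
        assert iemg(x) == pytest.approx(expected["iemg"], rel=1e-9)
        assert rms(x) == pytest.approx(expected["rms"], rel=1e-9)
        assert wl(x) == pytest.approx(expected["wl"], rel=1e-9)

    def test_amplitude_features_are_1_homogeneous(self, rng):
        x = rng.standard_normal(256)
        for f in (iemg, rms, wl):
            assert f(3.0 * x) == pytest.approx(3.0 * f(x), rel=1e-12)


class TestEntropy:
    def test_uniform_over_2k_bins_gives_k_bits(self):
        # 8 equally-populated equal-width bins -> exactly 3 bits
        k = 3
        x = np.repeat(np.arange(2**k, dtype=float), 10) + 0.25
        assert shannon_entropy(x, bins=2**k) == pytest.approx(k)

    def test_constant_window_zero_bits(self):
        assert shannon_entropy(np.full(100, 1.5)) == 0.0

    def test_bounded_by_log2_bins(self, rng):
        x = rng.standard_normal(256)
        for bins in (4, 16, 64):
            assert 0.0 <= shannon_entropy(x, bins=bins) <= np.log2(bins) + 1e-12

    def test_scale_invariant(self, rng):
        x = rng.standard_normal(256)
        assert shannon_entropy(5.0 * x) == pytest.approx(shannon_entropy(x))


class TestSpectrum:
    def make_tone(self, f0, n=256, rate=1000.0):
        t = np.arange(n) / rate
        return SignalWindow(x=np.sin(2 * np.pi * f0 * t), rate=rate, stage="filtered")

    def test_peak_bin_at_tone_frequency(self):
        spec = power_spectrum(self.make_tone(100.0))
        resolution = 1000.0 / 256
        assert abs(spec.freqs[np.argmax(spec.psd)] - 100.0) <= resolution

    def test_broadband_power_close_to_variance(self, rng):
        # Parseval: integrated one-sided PSD ~ signal variance (Hann taper)
        x = rng.standard_normal(4096)
        spec = power_spectrum(SignalWindow(x=x, rate=1000.0, stage="filtered"))
        df = spec.freqs[1] - spec.freqs[0]
        assert np.sum(spec.psd) * df == pytest.approx(x.var(), rel=0.15)

    def test_zero_signal_zero_psd_and_undefined_mf(self):
        spec = power_spectrum(SignalWindow(x=np.zeros(256), rate=1000.0, stage="filtered"))
        assert np.all(spec.psd == 0)
        with pytest.raises(ConfigError):
            median_frequency(spec)
        with pytest.raises(ConfigError):
            mean_power_frequency(spec)

    @pytest.mark.parametrize("f0", [100.0, 250.0, 398.4375])
    def test_mf_mpf_within_one_bin_of_pure_tone(self, f0):
        spec = power_spectrum(self.make_tone(f0))
        resolution = 1000.0 / 256
        assert abs(median_frequency(spec) - f0) <= resolution
        assert abs(mean_power_frequency(spec) - f0) <= resolution

    def test_flat_spectrum_mf_mpf_at_half_band(self):
        freqs = np.linspace(0.0, 200.0, 201)
        flat = PowerSpectrum(freqs=freqs, psd=np.ones_like(freqs))
        assert median_frequency(flat) == pytest.approx(100.0, abs=1.0)
        assert mean_power_frequency(flat) == pytest.approx(100.0, abs=1e-9)

    def test_two_equal_lines_average(self):
        freqs = np.arange(0.0, 500.0, 1.0)
        psd = np.zeros_like(freqs)
        psd[100] = psd[300] = 1.0
        assert mean_power_frequency(PowerSpectrum(freqs=freqs, psd=psd)) == pytest.approx(200.0)

    def test_mf_mpf_scale_invariant_and_below_nyquist(self, rng):
        x = rng.standard_normal(256)
        s1 = power_spectrum(SignalWindow(x=x, rate=1000.0, stage="filtered"))
        s2 = power_spectrum(SignalWindow(x=2 * x, rate=1000.0, stage="filtered"))
        assert median_frequency(s1) == pytest.approx(median_frequency(s2))
        assert mean_power_frequency(s1) == pytest.approx(mean_power_frequency(s2))
        assert 0 <= median_frequency(s1) <= 500.0
        assert 0 <= mean_power_frequency(s1) <= 500.0


class TestExtraction:
    def make_channels(self, n=2000):
        out = {}
        for ch in ("ch1", "ch2"):
            filt = make_segment(n, stage="filtered", seed=hash(ch) % 100)
            norm = SignalSegment(samples=np.abs(filt.samples), rate=1000.0,
                                 stage="normalized", force_label=60.0)
            out[ch] = [(norm, filt)]
        return out

    def test_table_shape_two_channels(self):
        table = extract_features(self.make_channels())
        assert len(table) == 32
        feature_cols = [f"{ch}_{f}" for ch in ("ch1", "ch2") for f in FEATURE_NAMES]
        assert sorted(c for c in table.columns if c not in ("percent_mvc", "window_start")) \
            == sorted(feature_cols)
        assert set(table["percent_mvc"]) == {60.0}

    def test_extraction_deterministic(self):
        a = extract_features(self.make_channels())
        b = extract_features(self.make_channels())
        assert a.equals(b)

    def test_all_features_finite(self):
        table = extract_features(self.make_channels())
        assert np.all(np.isfinite(table.drop(columns=["percent_mvc"]).to_numpy()))
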