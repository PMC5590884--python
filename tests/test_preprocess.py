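"""Filtering, event detection, cycle normalisation and spectral features."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gaitdfa import (
    EventDetectionError,
    ParameterError,
    PreprocessConfig,
    build_feature_matrix,
    butterworth_zero_lag,
    detect_cycle_span,
    detect_gait_events,
    normalize_cycle,
    power_spectrum,
)
from gaitdfa.cohort import Cohort
from gaitdfa.preprocess import normalized_cycles, spectra_from_cycles


class TestButterworth:
    def test_dc_gain_is_unity(self):
        x = np.full(500, 3.7)
        np.testing.assert_allclose(butterworth_zero_lag(x, 100, 6), x, atol=1e-9)

    def test_zero_in_zero_out(self):
        x = np.zeros(300)
        np.testing.assert_array_equal(butterworth_zero_lag(x, 100, 6), x)

    def test_stopband_and_passband_match_squared_analytic_response(self):
        # 1 Hz + 50 Hz sines, fs=1000, cutoff 6 Hz, order 4: forward-backward
        # filtering squares the one-pass |H|, so the 50 Hz line should drop to
        # ~(6/50)^8 while 1 Hz passes within 2 %.
        fs, dur = 1000.0, 4.0
        t = np.arange(int(fs * dur)) / fs
        x = np.sin(2 * np.pi * 1 * t) + np.sin(2 * np.pi * 50 * t)
        y = butterworth_zero_lag(x, fs, 6.0, order=4)
        mid = y[int(fs) : int(3 * fs)]  # avoid edge transients
        tm = t[int(fs) : int(3 * fs)]

        def amplitude(f):
            z = mid @ np.exp(-2j * np.pi * f * tm)
            return 2 * abs(z) / len(mid)

        assert amplitude(50.0) < 1e-3
        assert abs(amplitude(1.0) - 1.0) < 0.02

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ParameterError, match="Nyquist"):
            butterworth_zero_lag(np.zeros(100), 100, 60)

    def test_short_signal_rejected(self):
        with pytest.raises(ParameterError, match="too short"):
            butterworth_zero_lag(np.zeros(10), 100, 6)


class TestGaitEvents:
    def test_rectangular_pulse(self):
        f = np.zeros(600)
        f[100:401] = 0.9
        assert detect_gait_events(f, 1000, 0.02) == (100, 401)

    def test_zero_force_is_an_error(self):
        with pytest.raises(EventDetectionError, match="no stance"):
            detect_gait_events(np.zeros(500), 1000)

    def test_unending_stance_is_an_error(self):
        with pytest.raises(EventDetectionError, match="never ends"):
            detect_gait_events(np.ones(500), 1000)

    def test_double_hump_matches_linear_scan_oracle(self, rng):
        t = np.linspace(0, 1, 800)
        f = 1.5 * np.exp(-(((t - 0.15) / 0.05) ** 2)) + 2.3 * np.exp(
            -(((t - 0.35) / 0.08) ** 2)
        )
        hs, to = detect_gait_events(f, 800, 0.02)
        # brute-force scan
        above = [i for i in range(len(f)) if f[i] > 0.02]
        hs_oracle = above[0]
        to_oracle = next(i for i in range(hs_oracle, len(f)) if f[i] <= 0.02)
        assert (hs, to) == (hs_oracle, to_oracle)

    def test_cycle_span_reaches_second_contact(self):
        f = np.zeros(1000)
        f[100:300] = 1.0
        f[700:900] = 1.0
        assert detect_cycle_span(f, 1000, cycle_mode="full") == (100, 700)
        assert detect_cycle_span(f, 1000, cycle_mode="stance") == (100, 300)
        # auto prefers the full cycle, falls back to stance
        assert detect_cycle_span(f, 1000, cycle_mode="auto") == (100, 700)
        assert detect_cycle_span(f[:500], 1000, cycle_mode="auto") == (100, 300)


class TestNormalizeCycle:
    def test_identity_when_lengths_match(self):
        w = np.sin(np.linspace(0, 3, 40))
        np.testing.assert_allclose(normalize_cycle(w, 5, 25, 20), w[5:25], atol=1e-12)

    def test_lines_are_preserved_exactly(self):
        w = np.linspace(0.0, 10.0, 73)
        out = normalize_cycle(w, 10, 60, 17)
        np.testing.assert_allclose(out, np.linspace(w[10], w[59], 17), atol=1e-12)

    def test_sine_downsample_error_within_analytic_bound(self):
        # resampling one period 100 -> 50 -> 100: each linear interpolation of
        # a curve with |f''| <= M2 errs by at most M2 h^2 / 8; the downsample
        # knots themselves already carry the unit-grid interpolation error, so
        # the round trip is bounded by M2 (h^2 + 1) / 8
        n = 100
        w = np.sin(2 * np.pi * np.arange(n) / (n - 1))
        down = normalize_cycle(w, 0, n, 50)
        back = np.interp(np.linspace(0, 49, n), np.arange(50), down)
        h = (n - 1) / 49
        m2 = (2 * np.pi / (n - 1)) ** 2
        bound = m2 * (h**2 + 1) / 8
        assert np.max(np.abs(back - w)) <= bound

    def test_degenerate_span_rejected(self):
        with pytest.raises(ParameterError, match="span"):
            normalize_cycle(np.arange(10.0), 4, 5, 10)


class TestPowerSpectrum:
    def test_zero_waveform(self):
        np.testing.assert_array_equal(power_spectrum(np.zeros(100)), np.zeros(50))

    def test_single_tone_matches_direct_dft(self):
        n = 100
        w = np.cos(2 * np.pi * 3 * np.arange(n) / n)
        spec = power_spectrum(w, 50)
        # naive DFT summation oracle
        oracle = np.array(
            [
                abs(sum(w[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n)))
                for k in range(50)
            ]
        )
        np.testing.assert_allclose(spec, oracle, atol=1e-9)
        assert spec.argmax() == 3
        others = np.delete(spec, 3)
        assert others.max() < 1e-9 * spec[3]

    @given(st.integers(min_value=1, max_value=99), st.integers(min_value=0, max_value=10))
    def test_circular_shift_invariance(self, shift, seed):
        w = np.random.default_rng(seed).normal(size=100)
        np.testing.assert_allclose(
            power_spectrum(w), power_spectrum(np.roll(w, shift)), atol=1e-12
        )

    def test_too_many_bins_rejected(self):
        with pytest.raises(ParameterError, match="n_bins"):
            power_spectrum(np.zeros(100), 52)


class TestFeatureMatrix:
    def test_shape_and_metadata(self, tiny_cohort):
        fm = build_feature_matrix(tiny_cohort)
        assert fm.features.shape == (16, 1500)
        assert fm.n_bins == 50
        assert set(fm.labels) == {"shod", "barefoot"}
        assert np.all(fm.features >= 0)

    def test_rows_follow_trial_order(self, tiny_cohort):
        fm = build_feature_matrix(tiny_cohort)
        shuffled = Cohort(list(reversed(tiny_cohort.trials)))
        fm2 = build_feature_matrix(shuffled)
        np.testing.assert_array_equal(fm.features, fm2.features[::-1])

    def test_pipeline_is_deterministic(self, tiny_cohort):
        a = build_feature_matrix(tiny_cohort)
        b = build_feature_matrix(tiny_cohort)
        np.testing.assert_array_equal(a.features, b.features)

    def test_flattening_is_variable_major(self, tiny_cohort):
        cfg = PreprocessConfig()
        fm = build_feature_matrix(tiny_cohort, cfg)
        cycles = normalized_cycles(tiny_cohort.trials[0], cfg)
        spectra = spectra_from_cycles(cycles, cfg.n_bins)
        np.testing.assert_allclose(fm.features[0, :50], spectra[0], atol=1e-12)
        np.testing.assert_allclose(fm.features[0, 50:100], spectra[1], atol=1e-12)
        np.testing.assert_array_equal(fm.spectra(0), spectra)

    def test_event_failure_names_the_trial(self, tiny_cohort):
        bad = tiny_cohort.trials[2]
        broken = Cohort(
            [
                t if t is not bad else type(t)(
                    t.subject_id, t.condition, t.repeat_index, t.sampling_rate_hz,
                    np.zeros_like(t.waveforms),
                )
                for t in tiny_cohort.trials
            ]
        )
        with pytest.raises(EventDetectionError, match=str(bad.subject_id)):
            build_feature_matrix(broken)

    def test_save_load_roundtrip(self, tiny_cohort, tmp_path):
        from gaitdfa import FeatureMatrix

        fm = build_feature_matrix(tiny_cohort)
        fm.save(tmp_path / "fm.npz")
        back = FeatureMatrix.load(tmp_path / "fm.npz")
        np.testing.assert_array_equal(fm.features, back.features)
        assert back.config == fm.config
        assert list(back.labels) == list(fm.labels)
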