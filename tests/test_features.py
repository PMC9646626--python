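"""Feature arithmetic: closed-form examples, Monte-Carlo properties and
the discrimination contrasts the classifiers depend on."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from neckppg import Recording, normalize_recording
from neckppg.features import (
    ENVELOPE_FEATURES,
    FEATURE_NAMES,
    Envelope,
    aggregate_time_features,
    approximate_entropy,
    autocorrelation,
    compute_spectrogram,
    correlogram_features,
    envelope_features,
    extract_envelope,
    extract_feature_vector,
    per_pulse_features,
    window_psd_features,
    zero_crossing_rate,
)
from neckppg.pulses import PulseSet

FS = 75.0


def _recording(x, fs=FS, rid="r"):
    return Recording("S", rid, "control", fs, np.asarray(x, dtype=float))


def triangle_train(n_pulses=8, period=0.8, peak_frac=0.25, fs=FS):
    """Identical triangular pulses: onset 0, peak 1, exact anchors known.

    Offsets close each pulse one sample before the next onset so every
    per-pulse segment is one exact, sample-identical period.
    """
    plen = int(period * fs)
    rise = int(peak_frac * plen)
    pulse = np.concatenate(
        [np.linspace(0, 1, rise + 1)[:-1], np.linspace(1, 0, plen - rise + 1)[:-1]]
    )
    x = np.tile(pulse, n_pulses)
    onsets = np.arange(n_pulses) * plen
    peaks = onsets + rise
    offsets = onsets + plen - 1  # segment = one exact period
    return x, PulseSet(onsets, peaks, offsets)


class TestPerPulseFeatures:
    def test_triangle_closed_form(self):
        x, ps = triangle_train()
        rec = _recording(x)
        df = per_pulse_features(rec, ps)
        assert df["Amplitude"].iloc[0] == pytest.approx(1.0)
        assert df["RiseTime"].iloc[0] == pytest.approx(15 / FS)
        assert df["Width"].iloc[0] == pytest.approx(59 / FS)

    def test_two_identical_pulses_pairwise_zero(self):
        x, ps = triangle_train(n_pulses=4)
        rec = _recording(x)
        ppdf = per_pulse_features(rec, ps)
        out = aggregate_time_features(ppdf, 0.0, x.size / FS, rec)
        assert out["PeakHeightDiff"] == pytest.approx(0.0, abs=1e-12)
        assert out["TroughDiff"] == pytest.approx(0.0, abs=1e-12)
        assert out["PeakDistance"] == pytest.approx(0.8, abs=1 / FS)

    def test_symmetric_triangle_zero_skewness(self):
        # symmetric triangle: sample values uniformly distributed, so the
        # value-distribution skewness vanishes
        x, ps = triangle_train(n_pulses=4, peak_frac=0.5)
        df = per_pulse_features(_recording(x), ps)
        assert abs(df["Skewness"].iloc[0]) < 1e-6

    def test_empty_pulse_set_gives_empty_table(self):
        rec = _recording(np.random.default_rng(0).standard_normal(600))
        df = per_pulse_features(rec, PulseSet.empty())
        assert len(df) == 0


class TestAggregates:
    def test_periodic_train_changes_and_stds_vanish(self):
        x, ps = triangle_train(n_pulses=10)
        rec = _recording(x)
        ppdf = per_pulse_features(rec, ps)
        out = aggregate_time_features(ppdf, 0.0, x.size / FS, rec)
        for base in ["Amplitude", "Width", "RiseTime", "Skewness", "Kurtosis"]:
            assert out[f"Change{base}"] == pytest.approx(0.0, abs=1e-9)
            assert out[f"Std{base}"] == pytest.approx(0.0, abs=1e-9)

    def test_zero_crossing_rate_sinusoid(self):
        t = np.arange(int(6 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t + 0.1)  # phase offset: 12 crossings
        assert zero_crossing_rate(x, 6.0) == pytest.approx(2.0)

    def test_alternating_amplitudes(self):
        # pulses with amplitudes 1,2,1,2: Change of amplitude = 1.0,
        # std = sample std of the series
        x, ps = triangle_train(n_pulses=6)
        scale = np.repeat([1.0, 2.0, 1.0, 2.0, 1.0, 2.0], int(0.8 * FS))
        rec = _recording(x * scale)
        ppdf = per_pulse_features(rec, ps)
        out = aggregate_time_features(ppdf, 0.0, x.size / FS, rec)
        assert out["ChangeAmplitude"] == pytest.approx(1.0, abs=1e-9)
        amps = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        assert out["StdAmplitude"] == pytest.approx(np.std(amps, ddof=1), abs=1e-9)

    def test_single_pulse_window_is_nan(self):
        x, ps = triangle_train(n_pulses=8)
        rec = _recording(x)
        ppdf = per_pulse_features(rec, ps)
        out = aggregate_time_features(ppdf, 0.0, 0.9, rec)  # holds 1 peak
        assert np.isnan(out["Amplitude"])


class TestCorrelogram:
    def test_sinusoid_first_peak(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * t / 0.8)
        out = correlogram_features(x, FS, 10.0)
        assert out["CorrelogramLag1"] == pytest.approx(0.8, abs=1.5 / FS)
        assert out["CorrelogramPeak1"] >= 0.9
        assert out["CorrelogramLag2"] == pytest.approx(1.6, abs=2.5 / FS)

    def test_white_noise_first_peak_small(self):
        vals = []
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(int(10 * FS))
            out = correlogram_features(x, FS, 10.0)
            vals.append(out["CorrelogramPeak1"])
        assert np.nanmean(vals) < 0.3

    def test_autocorrelation_bounds(self):
        x = np.random.default_rng(1).standard_normal(500)
        r = autocorrelation(x, 200)
        assert r[0] == pytest.approx(1.0)
        assert np.all(np.abs(r) <= 1.0 + 1e-12)


class TestSpectrogram:
    def test_frame_count_140s(self):
        rec = _recording(np.random.default_rng(0).standard_normal(int(140 * FS)))
        spec = compute_spectrogram(rec)
        assert spec.times.size == 131  # floor((140-10)/1)+1

    def test_sinusoid_peak_bin(self):
        t = np.arange(int(140 * FS)) / FS
        rec = _recording(np.sin(2 * np.pi * 1.0 * t))
        spec = compute_spectrogram(rec)
        P = spec.psd_linear()
        for j in range(P.shape[1]):
            assert spec.freqs[int(np.argmax(P[:, j]))] == pytest.approx(1.0)

    def test_parseval_per_frame(self):
        x = np.random.default_rng(2).standard_normal(int(30 * FS))
        rec = _recording(x)
        spec = compute_spectrogram(rec)
        from scipy.signal import get_window

        win = get_window("hamming", int(10 * FS))
        df = spec.freqs[1] - spec.freqs[0]
        for j in (0, 5, 20):
            s = j * int(FS)
            frame = x[s : s + int(10 * FS)] * win
            time_power = np.sum(frame**2) / np.sum(win**2)
            freq_power = np.sum(spec.psd_linear()[:, j]) * df
            assert freq_power == pytest.approx(time_power, rel=0.02)

    def test_too_short(self):
        from neckppg.features import TooShortError

        with pytest.raises(TooShortError):
            compute_spectrogram(_recording(np.zeros(int(5 * FS))))


class TestPsdFeatures:
    def test_sinusoid_band_concentration(self):
        t = np.arange(int(30 * FS)) / FS
        rec = _recording(np.sin(2 * np.pi * 1.0 * t))
        spec = compute_spectrogram(rec)
        out = window_psd_features(spec, 10.0, 10.0)
        assert out["RelativePower (0.8-1.3Hz)"] >= 0.95
        assert out["RelativePower (0-0.8Hz)"] <= 0.05
        assert out["RelativePower (1.3-1.8Hz)"] <= 0.05

    def test_white_noise_high_entropy(self):
        vals = []
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(int(30 * FS))
            spec = compute_spectrogram(_recording(x))
            out = window_psd_features(spec, 10.0, 10.0)
            vals.append(out["SpectralEntropy (0-1.5Hz)"])
        assert np.mean(vals) >= 0.9

    def test_pure_tone_low_entropy(self):
        # a bin-aligned tone concentrates the band PSD up to taper leakage
        t = np.arange(int(30 * FS)) / FS
        rec = _recording(np.sin(2 * np.pi * 1.0 * t))
        spec = compute_spectrogram(rec)
        out = window_psd_features(spec, 10.0, 10.0)
        assert out["SpectralEntropy (0-1.5Hz)"] < 0.45

    def test_relative_powers_sum_below_one(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(int(20 * FS))
        spec = compute_spectrogram(_recording(x))
        out = window_psd_features(spec, 2.0, 8.0)
        total = (
            out["RelativePower (0-0.8Hz)"]
            + out["RelativePower (0.8-1.3Hz)"]
            + out["RelativePower (1.3-1.8Hz)"]
        )
        assert 0.0 <= total <= 1.0

    def test_no_frame_in_window_warns_nan(self):
        x = np.random.default_rng(0).standard_normal(int(12 * FS))
        spec = compute_spectrogram(_recording(x))
        with pytest.warns(UserWarning):
            out = window_psd_features(spec, 0.0, 2.0)
        assert all(np.isnan(v) for v in out.values())


class TestEnvelope:
    def test_am_train_correlation(self):
        t = np.arange(int(20 * FS)) / FS
        mod = 1 + 0.3 * np.sin(2 * np.pi * 0.25 * t)
        carrier = np.clip(np.sin(2 * np.pi * 1.25 * t), 0, None) ** 2
        x = mod * carrier
        env = extract_envelope(x, FS)
        r = np.corrcoef(env.samples, mod)[0, 1]
        assert r >= 0.9

    def test_constant_amplitude_low_std(self):
        t = np.arange(int(20 * FS)) / FS
        x = np.clip(np.sin(2 * np.pi * 1.25 * t), 0, None) ** 2
        env = extract_envelope(x, FS)
        assert np.std(env.samples) <= 0.05 * np.mean(env.samples)

    def test_envelope_matches_signal_at_knots(self):
        x = np.random.default_rng(5).standard_normal(int(10 * FS))
        env = extract_envelope(x, FS)
        assert not env.flagged
        np.testing.assert_allclose(env.samples[env.knots], x[env.knots], atol=1e-12)

    def test_degenerate_envelope_flagged(self):
        env = extract_envelope(np.linspace(0, 1, 80), FS)
        assert env.flagged
        assert np.all(env.samples == env.samples[0])


class TestApproximateEntropy:
    def test_constant_sequence_zero(self):
        assert approximate_entropy(np.full(200, 3.0)) == 0.0

    def test_noise_exceeds_sinusoid(self):
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(300)
            sine = np.sin(2 * np.pi * 3 * np.arange(300) / 75.0)
            diffs.append(approximate_entropy(noise) - approximate_entropy(sine))
        assert np.mean(diffs) > 0

    def test_brute_force_equivalence(self):
        """Production path equals a direct O(n^2 m) double loop to 1e-10."""
        x = np.random.default_rng(8).standard_normal(200)
        r = 0.2 * np.std(x)

        def phi_brute(m):
            M = x.size - m + 1
            logs = []
            for i in range(M):
                count = 0
                for j in range(M):
                    d = max(abs(x[i + k] - x[j + k]) for k in range(m))
                    if d <= r:
                        count += 1
                logs.append(np.log(count / M))
            return float(np.mean(logs))

        expected = phi_brute(2) - phi_brute(3)
        assert approximate_entropy(x, 2, r) == pytest.approx(expected, abs=1e-10)


class TestEnvelopeFeatures:
    def test_constant_envelope_closed_form(self):
        env = Envelope(np.ones(int(6 * FS) + 1))  # 6 s inclusive of endpoint
        out = envelope_features(env, FS)
        assert out["EnvelopeStd"] == 0.0
        assert out["EnvelopeMax"] == out["EnvelopeMin"] == 1.0
        assert out["EnvelopeRange"] == 0.0
        assert out["EnvelopeArea"] == pytest.approx(6.0)
        assert out["EnvelopeApproxEntropy"] == 0.0

    def test_modulation_band_power_location(self):
        t = np.arange(int(20 * FS)) / FS
        env = Envelope(1 + 0.3 * np.sin(2 * np.pi * 0.25 * t))
        out = envelope_features(env, FS)
        assert out["EnvelopeAvgPower (0.2-0.5Hz)"] > out["EnvelopeAvgPower (0-0.15Hz)"]
        assert out["EnvelopeAvgPower (0.2-0.5Hz)"] > out["EnvelopeAvgPower (0.5-1Hz)"]

    def test_range_identity(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            env = Envelope(rng.standard_normal(300))
            out = envelope_features(env, FS)
            assert out["EnvelopeRange"] == out["EnvelopeMax"] - out["EnvelopeMin"]


@pytest.fixture(scope="module")
def rec_and_parts():
    rng = np.random.default_rng(12)
    t = np.arange(int(30 * FS)) / FS
    x = (1 + 0.3 * np.sin(2 * np.pi * 0.25 * t)) * np.clip(
        np.sin(2 * np.pi * 1.2 * t), 0, None
    ) + 0.02 * rng.standard_normal(t.size)
    rec = normalize_recording(_recording(x))
    from neckppg import detect_pulses

    ps = detect_pulses(rec)
    ppdf = per_pulse_features(rec, ps)
    spec = compute_spectrogram(rec)
    return rec, ppdf, spec


class TestVectorAssembly:
    def test_exactly_51_entries(self, rec_and_parts):
        rec, ppdf, spec = rec_and_parts
        vec = extract_feature_vector(rec, ppdf, 10.0, 6.0, spec)
        assert len(vec) == 51
        assert list(vec.index) == FEATURE_NAMES

    def test_envelope_block_has_10_entries(self):
        assert len(ENVELOPE_FEATURES) == 10
        assert ENVELOPE_FEATURES[0] == "EnvelopeStd"
        assert ENVELOPE_FEATURES[-1] == "EnvelopeAvgPower (0.5-1Hz)"

    def test_determinism(self, rec_and_parts):
        rec, ppdf, spec = rec_and_parts
        v1 = extract_feature_vector(rec, ppdf, 10.0, 6.0, spec)
        v2 = extract_feature_vector(rec, ppdf, 10.0, 6.0, spec)
        pd.testing.assert_series_equal(v1, v2)


class TestDiscrimination:
    """The synthetic classes must separate along the catalogued features."""

    def test_envelope_std_separates_apnea(self, small_cohort, small_features_w6):
        from neckppg.windowing import label_cohort_windows

        rec_ids = [r.recording_id for r in small_cohort.by_scenario("breath_hold")]
        labels = label_cohort_windows(
            small_cohort, "apnea", 6.0, 0.9, recordings=rec_ids
        )
        merged = small_features_w6.merge(
            labels, on=["subject", "recording", "window_start_s"]
        )
        pos = merged[merged["corrupt_fraction"] >= 0.9]["EnvelopeStd"].dropna()
        neg = merged[merged["corrupt_fraction"] == 0.0]["EnvelopeStd"].dropna()
        assert len(pos) >= 30 and len(neg) >= 30
        p = mannwhitneyu(pos, neg).pvalue
        assert p < 0.01

    def test_std_amplitude_separates_artifacts(self, small_cohort, small_features_w6):
        from neckppg.windowing import label_cohort_windows

        labels = label_cohort_windows(small_cohort, "artifacts", 6.0, 0.9)
        merged = small_features_w6.merge(
            labels, on=["subject", "recording", "window_start_s"]
        )
        pos = merged[merged["corrupt_fraction"] >= 0.9]["StdAmplitude"].dropna()
        neg = merged[merged["corrupt_fraction"] == 0.0]["StdAmplitude"].dropna()
        assert len(pos) >= 30 and len(neg) >= 30
        p = mannwhitneyu(pos, neg).pvalue
        assert p < 0.01
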