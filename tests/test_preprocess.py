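"""Spectral estimation, beta-channel selection, causal filtering,
envelope extraction, burst annotation and vigilance labeling."""

import numpy as np
import pytest
import scipy.signal

import betaburst as bb
from betaburst.preprocess import (
    EnvelopeSeries,
    PowerSpectrum,
    bandpass_beta_series,
    stft_frame_count,
)


def _tone(freq, fs, duration, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


def _recording(channels, fs, labels=None):
    arr = np.atleast_2d(np.asarray(channels))
    labels = labels or [f"ch{k}" for k in range(arr.shape[0])]
    return bb.LFPRecording(arr, fs, labels)


class TestPowerSpectrum:
    def test_single_tone_peaks_at_its_frequency(self):
        rec = _recording(_tone(20, 600, 10), 600)
        spec = bb.compute_power_spectrum(rec, "ch0")
        assert spec.frequencies[np.argmax(spec.power)] == 20.0
        assert np.array_equal(spec.frequencies, np.arange(1.0, 101.0))

    def test_window_count_for_long_recording(self):
        # 198 s at 2400 Hz with 1 s windows, 50% overlap -> 395 windows
        assert stft_frame_count(198 * 2400, 2400.0) == 395

    def test_matches_windowwise_dft_oracle(self):
        fs = 600
        x = _tone(18, fs, 6) + 0.5 * _tone(42, fs, 6, phase=1.0)
        rec = _recording(x, fs)
        spec = bb.compute_power_spectrum(rec, "ch0")
        # independent oracle: explicit loop over Hamming windows
        win = scipy.signal.get_window("hamming", fs)
        frames = [x[s : s + fs] for s in range(0, len(x) - fs + 1, fs // 2)]
        powers = np.mean(
            [np.abs(np.fft.rfft(f * win)) ** 2 for f in frames], axis=0
        )
        freqs = np.fft.rfftfreq(fs, 1 / fs)
        for f_hz in (17, 18, 19, 42, 50):
            i = np.flatnonzero(freqs == f_hz)[0]
            np.testing.assert_allclose(
                spec.power[spec.frequencies == f_hz], powers[i], rtol=1e-9
            )

    def test_too_short_recording_errors_with_minimum(self):
        rec = _recording(np.zeros(100), 600)
        with pytest.raises(ValueError, match="1 s"):
            bb.compute_power_spectrum(rec, "ch0")


class TestBetaChannelSelection:
    def test_largest_beta_peak_wins(self):
        fs = 600
        chans = [_tone(18, fs, 10, amplitude=a) + _tone(5, fs, 10) for a in (1, 2, 3)]
        rec = _recording(chans, fs, labels=["a", "b", "c"])
        spectra = {c: bb.compute_power_spectrum(rec, c) for c in rec.channel_labels}
        sel = bb.select_beta_channel(spectra)
        assert sel.channel_label == "c"
        assert sel.beta_peak_frequency == 18.0

    def test_single_channel_with_clear_peak(self):
        rec = _recording(_tone(16, 600, 10), 600)
        sel = bb.select_beta_channel(
            {"ch0": bb.compute_power_spectrum(rec, "ch0")}
        )
        assert sel.channel_label == "ch0"
        assert sel.beta_peak_frequency == 16.0

    def test_no_beta_peak_is_a_distinct_outcome(self):
        grid = np.arange(1.0, 101.0)
        spectra = {
            "a": PowerSpectrum(grid, 1.0 / grid),      # pure 1/f, no local max
            "b": PowerSpectrum(grid, 1.0 / grid**1.5),
        }
        assert bb.select_beta_channel(spectra) is None

    def test_selection_invariant_to_channel_order(self):
        fs = 600
        chans = {f"ch{k}": _tone(20, fs, 8, amplitude=k + 1) for k in range(3)}
        spectra = {
            c: bb.compute_power_spectrum(_recording(x, fs, [c]), c)
            for c, x in chans.items()
        }
        sel1 = bb.select_beta_channel(spectra)
        sel2 = bb.select_beta_channel(dict(reversed(list(spectra.items()))))
        assert sel1 == sel2


class TestBandpass:
    def test_band_edges_follow_the_peak(self):
        # 18 Hz peak -> 15-21 Hz passband; -3 dB at the edges
        sos = scipy.signal.butter(6, [15, 21], btype="bandpass", fs=600,
                                  output="sos")
        w, h = scipy.signal.sosfreqz(sos, worN=[15.0, 18.0, 21.0], fs=600)
        filtered = bandpass_beta_series(_tone(18, 600, 20), 600, 18.0)
        steady = filtered[6000:]
        assert np.abs(h[1]) > 0.99
        np.testing.assert_allclose(steady.max(), np.abs(h[1]), rtol=0.02)

    def test_dc_is_rejected(self):
        out = bandpass_beta_series(np.ones(6000), 600, 18.0)
        assert np.max(np.abs(out[3000:])) < 1e-4

    def test_stopband_attenuation_matches_transfer_function(self):
        fs = 600
        x = _tone(18, fs, 30) + _tone(50, fs, 30)
        out = bandpass_beta_series(x, fs, 18.0)
        sos = scipy.signal.butter(6, [15, 21], btype="bandpass", fs=fs,
                                  output="sos")
        _, h = scipy.signal.sosfreqz(sos, worN=[50.0], fs=fs)
        # measure the residual 50 Hz component in steady state
        steady = out[int(10 * fs):]
        t = np.arange(int(10 * fs), len(x)) / fs
        amp50 = 2 * np.abs(np.mean(steady * np.exp(-2j * np.pi * 50 * t)))
        assert amp50 == pytest.approx(np.abs(h[0]), rel=0.2, abs=1e-6)

    def test_band_outside_nyquist_errors(self):
        with pytest.raises(ValueError):
            bandpass_beta_series(np.zeros(100), 40.0, 18.0)

    def test_causality_truncation_property(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.standard_normal(3000)
            full = bandpass_beta_series(x, 600, 20.0)
            cut = rng.integers(500, 2500)
            trunc = bandpass_beta_series(x[:cut], 600, 20.0)
            np.testing.assert_array_equal(full[:cut], trunc)


class TestDownsample:
    def test_peak_preserved_after_decimation(self):
        x = _tone(18, 2400, 10)
        y = bb.downsample_series(x, 2400, 600)
        assert len(y) == len(x) // 4
        spec = np.abs(np.fft.rfft(y[600:]))
        freqs = np.fft.rfftfreq(len(y) - 600, 1 / 600)
        assert abs(freqs[np.argmax(spec)] - 18.0) < 0.5

    def test_identity_when_rates_match(self):
        x = np.arange(100.0)
        np.testing.assert_array_equal(bb.downsample_series(x, 600, 600), x)

    def test_non_integer_ratio_errors(self):
        with pytest.raises(ValueError):
            bb.downsample_series(np.zeros(100), 600, 250)

    def test_noise_band_limited_like_filter_then_decimate_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(24000)
        y = bb.downsample_series(x, 2400, 600)
        # oracle: explicit anti-alias filter followed by slicing
        sos = scipy.signal.cheby1(8, 0.05, 0.8 / 4, output="sos")
        ref = scipy.signal.sosfiltfilt(sos, x)[::4]
        assert np.corrcoef(y, ref)[0, 1] > 0.99


class TestEnvelope:
    def test_constant_amplitude_tone(self):
        env = bb.compute_envelope(2.0 * np.cos(2 * np.pi * 18 *
                                               np.arange(6000) / 600), 600)
        interior = env.envelope[300:-300]
        assert np.all(np.abs(interior - 2.0) < 0.1)
        assert np.all(env.envelope >= 0)

    def test_tracks_amplitude_ramp_like_hilbert(self):
        fs = 600
        t = np.arange(6 * fs) / fs
        amp = 1.0 + 0.5 * t
        x = amp * np.cos(2 * np.pi * 20 * t)
        env = bb.compute_envelope(x, fs).envelope
        hilb = np.abs(scipy.signal.hilbert(x))
        interior = slice(fs, -fs)
        assert np.max(np.abs(env[interior] - hilb[interior])) < 0.1 * amp.max()

    def test_zero_signal_gives_zero_envelope(self):
        env = bb.compute_envelope(np.zeros(1000), 600)
        np.testing.assert_array_equal(env.envelope, 0.0)


def _burst_oracle(env, threshold):
    """Naive scan for maximal runs strictly above threshold."""
    runs, start = [], None
    for i, v in enumerate(env):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(env)))
    return runs


class TestAnnotateBursts:
    def test_constant_envelope_has_no_bursts(self):
        env = EnvelopeSeries(np.ones(100), np.ones(100), 600.0)
        ann = bb.annotate_bursts(env)
        assert ann.n_bursts == 0

    def test_hand_built_envelope_runs(self):
        vals = np.array([0, 0, 5, 5, 0, 9, 9, 9, 0, 0], dtype=float)
        env = EnvelopeSeries(vals, vals, 1.0)
        ann = bb.annotate_bursts(env, threshold=4.0)
        np.testing.assert_array_equal(ann.onsets, [2, 5])
        np.testing.assert_array_equal(ann.offsets, [4, 8])

    def test_matches_threshold_scan_oracle_on_random_envelopes(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            vals = rng.random(rng.integers(5, 200))
            env = EnvelopeSeries(vals, vals, 100.0)
            pct = rng.uniform(20, 95)
            ann = bb.annotate_bursts(env, percentile=pct)
            runs = _burst_oracle(vals, np.percentile(vals, pct))
            np.testing.assert_array_equal(ann.onsets, [r[0] for r in runs])
            np.testing.assert_array_equal(ann.offsets, [r[1] for r in runs])

    def test_about_one_quarter_of_samples_above_threshold(self, small_pre):
        env = small_pre.envelope.envelope
        frac = np.mean(env > small_pre.bursts.threshold)
        assert abs(frac - 0.25) < 0.02

    def test_detected_count_close_to_ground_truth(self):
        params = bb.SimulationParams(duration=300.0, snr=15.0, seed=3)
        rec, truth = bb.simulate_recording(params)
        pre = bb.preprocess_recording(rec)
        assert abs(pre.bursts.n_bursts - truth.n_bursts) <= 0.15 * truth.n_bursts


class TestBurstStatistics:
    def test_rate_arithmetic(self):
        onsets = np.arange(10) * 1000
        ann = bb.BurstAnnotation(onsets, onsets + 100, np.full(10, 1.0),
                                 2.0, 1.0, 75.0, 100.0)
        stats = bb.burst_statistics(ann, total_duration=300.0)
        assert stats["count"] == 10
        assert stats["rate_per_min"] == 2.0

    def test_empty_annotation_flags_undefined_mean(self):
        ann = bb.BurstAnnotation(np.array([]), np.array([]), np.array([]),
                                 0.0, 1.0, 75.0, 100.0)
        stats = bb.burst_statistics(ann, total_duration=60.0)
        assert stats["count"] == 0
        assert stats["rate_per_min"] == 0.0
        assert not stats["mean_defined"]
        with pytest.raises(ValueError):
            bb.burst_statistics(ann, total_duration=0.0)

    def test_summary_equals_recomputation(self):
        rng = np.random.default_rng(2)
        onsets = np.cumsum(rng.integers(50, 500, size=20))
        lengths = rng.integers(10, 40, size=20)
        fs = 600.0
        ann = bb.BurstAnnotation(onsets, onsets + lengths, lengths / fs,
                                 0.0, 1.0, 75.0, fs)
        stats = bb.burst_statistics(ann, total_duration=120.0)
        assert stats["mean_duration_s"] == pytest.approx(np.mean(lengths / fs))
        assert stats["median_duration_s"] == pytest.approx(np.median(lengths / fs))
        assert stats["rate_per_min"] == pytest.approx(20 / 2.0)


class TestVigilance:
    def test_sleep_window_rule_as_stated(self):
        assert bb.classify_vigilance_state([90, 95, 85, 40, 30]) == ["sleep"]

    def test_all_low_scores_awake(self):
        assert bb.classify_vigilance_state([50, 60, 70, 80, 79]) == ["awake"]

    def test_missing_samples_unknown(self):
        assert bb.classify_vigilance_state([90, np.nan, 85, 90, 90]) == ["unknown"]
        assert bb.classify_vigilance_state([90, 90, 90]) == ["unknown"]

    def test_alternating_scores_match_rule_oracle(self):
        scores = np.array([81.0 if i % 2 == 0 else 79.0 for i in range(50)])
        labels = bb.classify_vigilance_state(scores)
        for w, lab in enumerate(labels):
            chunk = scores[5 * w : 5 * w + 5]
            expected = "sleep" if np.sum(chunk > 80) >= 3 else "awake"
            assert lab == expected
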