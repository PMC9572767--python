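"""ECG conditioning, R-peak detection, RR series and HRV features."""

import numpy as np
import pytest

import mentalload as ml
from mentalload.cardio import (EcgPreprocParams, detect_r_peaks,
                               hrv_freq_features, hrv_time_features,
                               normalize_to_baseline, preprocess_ecg,
                               rr_from_peaks)
from mentalload.signals import RRSeries, TimeSeries
from conftest import short_config


def _sine(freq, fs=256.0, seconds=10.0):
    t = np.arange(0, seconds, 1 / fs)
    return TimeSeries(np.sin(2 * np.pi * freq * t), fs, "BL", "ECG")


class TestPreprocessing:
    def test_mains_frequency_attenuated_20db(self):
        raw = _sine(50.0)
        out = preprocess_ecg(raw)
        # discard filter edges before measuring amplitude
        core = slice(256, -256)
        ratio = np.std(out.values[core]) / np.std(raw.values[core])
        assert ratio < 0.1  # >= 20 dB

    def test_dc_offset_removed(self):
        rng = np.random.default_rng(0)
        raw = TimeSeries(rng.normal(size=2560) + 5.0, 256.0, "BL", "ECG")
        out = preprocess_ecg(raw)
        assert abs(out.values.mean()) < 0.05

    def test_in_band_sine_amplitude_preserved(self):
        raw = _sine(10.0)
        out = preprocess_ecg(raw)
        core = slice(256, -256)
        ratio = np.std(out.values[core]) / np.std(raw.values[core])
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_output_length_equals_input(self):
        raw = _sine(10.0)
        assert preprocess_ecg(raw).n == raw.n

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="100 Hz"):
            preprocess_ecg(TimeSeries(np.zeros(100), 50.0, "BL", "ECG"))


class TestPeakDetection:
    @staticmethod
    def _smooth_noise(rng, n, sd=0.05, rho=0.99):
        from scipy.signal import lfilter

        innov = rng.normal(0, sd * np.sqrt(1 - rho**2), n + 200)
        return lfilter([1.0], [1.0, -rho], innov)[200:]

    def test_three_gaussian_beats_recovered(self):
        fs = 256.0
        t = np.arange(0, 3.6, 1 / fs)
        rng = np.random.default_rng(3)
        x = self._smooth_noise(rng, t.size)
        for beat in (1.0, 1.8, 2.6):
            x += np.exp(-0.5 * ((t - beat) / 0.020) ** 2)
        peaks = detect_r_peaks(TimeSeries(x, fs, "Forward", "ECG"))
        assert peaks.size == 3
        rr = rr_from_peaks(peaks, fs)
        np.testing.assert_allclose(rr.rr, [800.0, 800.0], atol=1000 / fs)

    def test_flat_signal_yields_no_beats(self):
        peaks = detect_r_peaks(TimeSeries(np.zeros(2560), 256.0, "BL", "ECG"))
        assert peaks.size == 0

    def test_amplitude_scaling_invariance(self):
        fs = 256.0
        t = np.arange(0, 10, 1 / fs)
        rng = np.random.default_rng(9)
        x = self._smooth_noise(rng, t.size)
        for beat in np.arange(0.5, 9.5, 0.8):
            x += np.exp(-0.5 * ((t - beat) / 0.020) ** 2)
        base = detect_r_peaks(TimeSeries(x, fs, "BL", "ECG"))
        scaled = detect_r_peaks(TimeSeries(250.0 * x, fs, "BL", "ECG"))
        np.testing.assert_array_equal(base, scaled)

    def test_generator_ground_truth_recovered(self, small_cohort):
        """>= 99% of true beats found within one sample on synthetic ECG."""
        total = found = 0
        for rec in small_cohort:
            for phase, beats in rec.true_beats.items():
                ecg = rec.ecg[phase]
                peaks = detect_r_peaks(preprocess_ecg(ecg))
                true_idx = np.round(beats * ecg.fs).astype(int)
                for ti in true_idx:
                    total += 1
                    if peaks.size and np.abs(peaks - ti).min() <= 1:
                        found += 1
        assert found / total >= 0.99


class TestRRSeries:
    def test_one_second_interval(self):
        rr = rr_from_peaks([256, 512], 256.0)
        np.testing.assert_allclose(rr.rr, [1000.0])

    def test_fractional_sample_intervals(self):
        rr = rr_from_peaks([0, 205, 410], 256.0)
        np.testing.assert_allclose(rr.rr, [800.78125, 800.78125])

    def test_rr_reconstructs_beat_gaps(self, rng):
        idx = np.sort(rng.choice(10000, 40, replace=False))
        rr = rr_from_peaks(idx, 256.0)
        np.testing.assert_allclose(np.diff(rr.beat_times) * 1000, rr.rr)

    def test_fewer_than_two_beats_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            rr_from_peaks([100], 256.0)

    def test_nonincreasing_beats_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            RRSeries(beat_times=np.array([1.0, 1.0, 2.0]))


class TestHrvTimeFeatures:
    def test_hand_computed_example(self):
        rr = RRSeries(beat_times=np.concatenate([[0], np.cumsum([800, 810, 790, 805])]) / 1000)
        rrmean, sdnn, rmssd = hrv_time_features(rr)
        assert rrmean == pytest.approx(801.25, abs=1e-3)
        assert sdnn == pytest.approx(8.5391, abs=1e-3)
        assert rmssd == pytest.approx(15.5456, abs=1e-3)

    def test_constant_rr_has_zero_variability(self):
        rr = RRSeries(beat_times=np.arange(10) * 0.8)
        _, sdnn, rmssd = hrv_time_features(rr)
        assert sdnn == pytest.approx(0.0, abs=1e-9)
        assert rmssd == pytest.approx(0.0, abs=1e-9)

    def test_sdnn_recovers_generative_sd(self):
        rng = np.random.default_rng(8)
        intervals = rng.normal(800, 50, 10_000) / 1000
        rr = RRSeries(beat_times=np.concatenate([[0], np.cumsum(intervals)]))
        _, sdnn, _ = hrv_time_features(rr)
        assert sdnn == pytest.approx(50.0, abs=2.0)

    def test_time_shift_invariance(self, rng):
        intervals = rng.uniform(0.7, 0.9, 50)
        beats = np.concatenate([[0], np.cumsum(intervals)])
        a = hrv_time_features(RRSeries(beat_times=beats))
        b = hrv_time_features(RRSeries(beat_times=beats + 123.4))
        assert a == pytest.approx(b, rel=1e-9)


class TestHrvFreqFeatures:
    @staticmethod
    def _modulated_rr(lf_amp, hf_amp, seconds=300.0):
        beats = [0.0]
        t = 0.0
        while t < seconds:
            rr = 0.85 + lf_amp * np.sin(2 * np.pi * 0.10 * t) \
                 + hf_amp * np.sin(2 * np.pi * 0.25 * t)
            t += rr
            beats.append(t)
        return RRSeries(beat_times=np.array(beats))

    def test_lf_only_modulation(self):
        lf, hf, lfhf = hrv_freq_features(self._modulated_rr(0.05, 0.0))
        assert lfhf > 10

    def test_hf_only_modulation(self):
        lf, hf, lfhf = hrv_freq_features(self._modulated_rr(0.0, 0.05))
        assert lfhf < 0.1

    def test_constant_rr_undefined_ratio(self):
        rr = RRSeries(beat_times=np.arange(400) * 0.8)
        lf, hf, lfhf = hrv_freq_features(rr)
        assert lf == pytest.approx(0.0, abs=1e-9)
        assert hf == pytest.approx(0.0, abs=1e-9)
        assert np.isnan(lfhf)

    def test_too_few_beats_errors(self):
        with pytest.raises(ValueError, match="4 beats"):
            hrv_freq_features(RRSeries(beat_times=np.array([0.0, 0.8, 1.6])))


class TestBaselineNormalization:
    @staticmethod
    def _features(**kw):
        base = dict(RRmean=800.0, SDNN=40.0, RMSSD=30.0, LF=100.0,
                    HF=50.0, LFHF=2.0)
        base.update(kw)
        return ml.HrvFeatures(**base)

    def test_identical_features_ratio_one(self):
        out = normalize_to_baseline(self._features(), self._features())
        assert all(v == pytest.approx(1.0) for v in out.as_dict().values())
        assert out.normalized

    def test_ratio_arithmetic(self):
        out = normalize_to_baseline(self._features(RRmean=900.0),
                                    self._features(RRmean=800.0))
        assert out.RRmean == pytest.approx(1.125)

    def test_zero_baseline_entry_undefined_only_there(self):
        out = normalize_to_baseline(self._features(),
                                    self._features(SDNN=0.0))
        assert np.isnan(out.SDNN)
        defined = [v for k, v in out.as_dict().items() if k != "SDNN"]
        assert all(np.isfinite(defined))

    def test_double_normalization_rejected(self):
        once = normalize_to_baseline(self._features(), self._features())
        with pytest.raises(ValueError, match="unnormalized"):
            normalize_to_baseline(once, self._features())


class TestEndToEnd:
    def test_recovered_rr_mean_tracks_generator(self):
        """Detected RR mean within 1% of the configured per-phase mean."""
        for seed in range(3):
            cfg = short_config(seed=seed, n_subjects=2, rr_subject_sd=0.0)
            for rec in ml.generate_cohort(cfg):
                ecg = rec.ecg["Forward"]
                peaks = detect_r_peaks(preprocess_ecg(ecg))
                rr = rr_from_peaks(peaks, ecg.fs)
                rrmean, _, _ = hrv_time_features(rr)
                assert rrmean == pytest.approx(
                    cfg.rr_mean["Forward"], rel=0.01)
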