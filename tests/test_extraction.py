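"""Filtering, peak detection, segment selection and ectopy correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laborhrv.extraction import (
    NoPeaksError,
    SegmentSelectionError,
    correct_ectopics,
    detect_rpeaks,
    evaluate_detection,
    flag_ectopics,
    highpass_filter,
    normalize_amplitude,
    peaks_to_rri,
    select_segment,
)
from laborhrv.records import LABEL_CORRECTED, RawRecording, RPeakSeries, RRISeries
from laborhrv.synthetic import (
    EhgSynthesisSpec,
    GroundTruth,
    TachogramSpec,
    generate_rri_ipfm,
    inject_ectopics,
    synthesize_ehg,
)


def _rec(x, fs=200.0, modality="EHG"):
    return RawRecording(np.asarray(x, dtype=float), fs, modality=modality)


class TestHighpass:
    def test_dc_removed(self):
        rec = _rec(np.ones(4000))
        out = highpass_filter(rec, cutoff=5.0)
        assert np.max(np.abs(out.samples[500:-500])) < 1e-6

    def test_passband_tone_preserved(self):
        fs, cutoff = 200.0, 5.0
        t = np.arange(int(60 * fs)) / fs
        rec = _rec(np.sin(2 * np.pi * 10 * cutoff * t), fs)
        out = highpass_filter(rec, cutoff=cutoff)
        mid = slice(2000, -2000)
        assert np.max(np.abs(out.samples[mid])) == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_crushed(self):
        fs, cutoff = 200.0, 5.0
        t = np.arange(int(120 * fs)) / fs
        rec = _rec(np.sin(2 * np.pi * (cutoff / 10) * t), fs)
        out = highpass_filter(rec, cutoff=cutoff)
        mid = slice(4000, -4000)
        assert np.max(np.abs(out.samples[mid])) < 0.025  # >= 97.5% attenuation

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            highpass_filter(_rec(np.zeros(100) + 1), cutoff=150.0)

    def test_length_preserved(self):
        rec = _rec(np.random.default_rng(0).normal(size=1234))
        assert len(highpass_filter(rec).samples) == 1234


class TestNormalize:
    def test_example(self):
        out = normalize_amplitude(_rec([0.0, 2.0, -4.0]))
        np.testing.assert_allclose(out.samples, [0.0, 0.5, -1.0])

    def test_idempotent(self):
        out = normalize_amplitude(_rec([0.0, 0.5, -1.0]))
        np.testing.assert_allclose(out.samples, [0.0, 0.5, -1.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_amplitude(_rec(np.zeros(10)))

    @given(st.floats(0.01, 1e6))
    @settings(max_examples=20, deadline=None)
    def test_gain_invariance(self, gain):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        a = normalize_amplitude(highpass_filter(_rec(x)))
        b = normalize_amplitude(highpass_filter(_rec(gain * x)))
        np.testing.assert_allclose(a.samples, b.samples, atol=1e-9)


class TestDetect:
    def test_refractory_keeps_larger_peak(self):
        fs = 1000.0
        x = np.zeros(1000)
        x[400] = 0.9
        x[500] = 0.5  # 100 ms later: violates the 250 ms refractory
        peaks = detect_rpeaks(_rec(x, fs, "ECG"))
        assert list(peaks.indices) == [400]

    def test_flat_signal_raises(self):
        with pytest.raises(NoPeaksError):
            detect_rpeaks(_rec(np.zeros(1000), 1000.0, "ECG"))

    def test_exact_on_noise_free_ecg(self, clean_ecg):
        rec, truth = clean_ecg
        peaks = detect_rpeaks(normalize_amplitude(highpass_filter(rec)))
        sens, ppv = evaluate_detection(peaks, truth, tol=1.0)  # +-1 sample at 1 kHz
        assert (sens, ppv) == (1.0, 1.0)


class TestPeaksToRri:
    def test_sample_example(self):
        peaks = RPeakSeries(np.array([0, 200, 400]), fs=200.0)
        rri = peaks_to_rri(peaks)
        np.testing.assert_allclose(rri.intervals, [1000.0, 1000.0])

    def test_time_example(self):
        peaks = RPeakSeries(np.array([0, 600, 1300]), fs=1000.0)
        np.testing.assert_allclose(peaks_to_rri(peaks).intervals, [600.0, 700.0])

    def test_too_few_peaks(self):
        with pytest.raises(ValueError):
            peaks_to_rri(RPeakSeries(np.array([5]), fs=100.0))


def _series(vals):
    vals = np.asarray(vals, dtype=float)
    return RRISeries(vals, np.concatenate([[0.0], np.cumsum(vals) / 1000.0]))


class TestFlagEctopics:
    def test_short_and_pause_flagged(self):
        flags = flag_ectopics(_series([600, 600, 600, 300, 900, 600, 600, 600]))
        assert list(np.where(flags)[0]) == [3, 4]

    def test_constant_series_unflagged(self):
        assert not flag_ectopics(_series([700.0] * 50)).any()

    def test_out_of_range_always_flagged(self):
        flags = flag_ectopics(_series([600, 600, 600, 600, 600, 600, 2400, 600]))
        assert flags[6]

    def test_short_series_warns(self):
        with pytest.warns(UserWarning):
            flags = flag_ectopics(_series([600.0] * 4))
        assert not flags.any()

    def test_recovers_injected_ectopics(self):
        tp = fn = 0
        for seed in range(5):
            _, rri, _ = generate_rri_ipfm(
                TachogramSpec(800.0, [(0.1, 0.03), (0.25, 0.04)], 310.0, seed=seed)
            )
            mutated, truth_flags = inject_ectopics(rri, 8, prematurity=0.6, seed=seed)
            flags = flag_ectopics(mutated)
            tp += int((flags & truth_flags).sum())
            fn += int((~flags & truth_flags).sum())
        assert tp / (tp + fn) >= 0.95


class TestCorrectEctopics:
    def test_run_mean_example(self):
        rri = _series([600, 300, 900, 600])
        out = correct_ectopics(rri, np.array([False, True, True, False]))
        np.testing.assert_allclose(out.intervals, [600, 600, 600, 600])
        assert list(out.labels[1:3]) == [LABEL_CORRECTED, LABEL_CORRECTED]

    def test_no_flags_is_identity(self):
        rri = _series([600, 650, 700])
        out = correct_ectopics(rri, np.zeros(3, dtype=bool))
        np.testing.assert_array_equal(out.intervals, rri.intervals)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_duration_conserved_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(500, 900, size=40)
        flags = rng.random(40) < 0.3
        if flags.all():
            flags[0] = False
        rri = _series(vals)
        out = correct_ectopics(rri, flags)
        assert out.total_duration_ms == pytest.approx(rri.total_duration_ms, abs=1e-9)
        again = correct_ectopics(out, flags)
        np.testing.assert_allclose(again.intervals, out.intervals, atol=1e-12)

    def test_fully_flagged_rejected(self):
        with pytest.raises(ValueError):
            correct_ectopics(_series([600, 700]), np.array([True, True]))


class TestSelectSegment:
    def test_clean_record_starts_at_zero(self, clean_ecg):
        rec, _ = clean_ecg
        sel = select_segment(rec)
        assert sel.start == 0.0
        assert sel.n_beats >= 150

    def test_noisy_first_window_skipped(self):
        spec = TachogramSpec(800.0, [(0.25, 0.04)], 650.0, seed=5)
        bt, _, _ = generate_rri_ipfm(spec)
        espec = EhgSynthesisSpec(seed=5)
        n = int(np.ceil((bt[-1] + 0.6) * espec.fs))
        profile = np.ones(n)
        profile[: int(300 * espec.fs)] = 60.0  # drown the first 5 minutes
        rec, _ = synthesize_ehg(bt, espec, noise_sd_profile=profile)
        assert select_segment(rec).start == 300.0

    def test_all_noise_record_excluded(self):
        rng = np.random.default_rng(0)
        rec = RawRecording(rng.normal(size=int(400 * 200)), 200.0, modality="EHG")
        with pytest.raises(SegmentSelectionError, match="poorly detectable"):
            select_segment(rec)

    def test_short_record_rejected(self):
        rec = RawRecording(np.zeros(int(200 * 200.0)) + 1.0, 200.0, modality="EHG")
        with pytest.raises(ValueError, match="300"):
            select_segment(rec)


class TestEvaluateDetection:
    def _truth(self, times):
        times = np.asarray(times, dtype=float)
        return GroundTruth(beat_times=times, true_rri=np.diff(times) * 1000.0)

    def test_perfect(self):
        t = np.arange(0.0, 8.0, 0.8)
        det = RPeakSeries((t * 1000).astype(int), fs=1000.0)
        assert evaluate_detection(det, self._truth(t)) == (1.0, 1.0)

    def test_one_missed(self):
        t = np.arange(0.0, 8.0, 0.8)
        det = RPeakSeries((t[1:] * 1000).astype(int), fs=1000.0)
        sens, ppv = evaluate_detection(det, self._truth(t))
        assert sens == pytest.approx((len(t) - 1) / len(t))
        assert ppv == 1.0

    def test_one_spurious(self):
        t = np.arange(0.8, 8.0, 0.8)
        det_times = np.sort(np.concatenate([t, [0.33]]))
        det = RPeakSeries((det_times * 1000).astype(int), fs=1000.0)
        sens, ppv = evaluate_detection(det, self._truth(t))
        assert sens == 1.0
        assert ppv == pytest.approx(len(t) / (len(t) + 1))
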