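"""Raw recording -> corrected RR-interval series.

High-pass filtering removes baseline drift and slow uterine activity so the
maternal R peaks dominate; the filtered trace is amplitude-normalized and
peaks above a relative threshold are kept subject to a refractory period.
A 5-minute analysis window is chosen (start of record preferred, later
windows as fallback), intervals are screened for ectopy with a
running-median rule, and flagged runs are replaced by their duration-
preserving mean.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps

from laborhrv.records import (
    LABEL_CORRECTED,
    LABEL_ECTOPIC,
    RRI_MAX_MS,
    RRI_MIN_MS,
    RawRecording,
    RPeakSeries,
    RRISeries,
    SegmentSelection,
)
from laborhrv.synthetic import GroundTruth

__all__ = [
    "NoPeaksError",
    "SegmentSelectionError",
    "highpass_filter",
    "normalize_amplitude",
    "detect_rpeaks",
    "select_segment",
    "peaks_to_rri",
    "flag_ectopics",
    "correct_ectopics",
    "evaluate_detection",
    "default_cutoff",
]


class NoPeaksError(RuntimeError):
    """No peaks found above threshold."""


class SegmentSelectionError(RuntimeError):
    """No 5-minute window with acceptably detectable R peaks."""


#: Default high-pass cutoffs by modality (Hz).  EHG needs an aggressive
#: cutoff: uterine surface EMG and wander live well below 5 Hz while QRS
#: energy is concentrated at 10–40 Hz.  Clean ECG only needs drift removal.
_DEFAULT_CUTOFF = {"EHG": 5.0, "ECG": 0.5}


def default_cutoff(modality: str) -> float:
    return _DEFAULT_CUTOFF[modality]


def highpass_filter(
    rec: RawRecording, cutoff: Optional[float] = None, order: int = 4
) -> RawRecording:
    """Zero-phase Butterworth high-pass.

    Applied forward–backward (``sosfiltfilt``) so there is no group delay:
    R-peak positions are not shifted.  ``cutoff`` defaults per modality
    (5 Hz for EHG, 0.5 Hz for ECG).
    """
    if cutoff is None:
        cutoff = default_cutoff(rec.modality)
    if not (0 < cutoff < rec.fs / 2):
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, fs/2)")
    sos = sps.butter(order, cutoff, btype="highpass", fs=rec.fs, output="sos")
    return replace(rec, samples=sps.sosfiltfilt(sos, rec.samples))


def normalize_amplitude(rec: RawRecording) -> RawRecording:
    """Scale so the maximum absolute amplitude is exactly 1."""
    peak = float(np.max(np.abs(rec.samples)))
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero signal")
    return replace(rec, samples=rec.samples / peak)


def detect_rpeaks(
    rec: RawRecording, min_height: float = 0.4, refractory: float = 250.0
) -> RPeakSeries:
    """Threshold detector on a filtered, normalized recording.

    Keeps local maxima above ``min_height`` (fraction of the normalized
    maximum) separated by at least ``refractory`` ms; when two candidates
    violate the refractory period the larger is kept.
    """
    dist = max(1, int(round(refractory / 1000.0 * rec.fs)))
    # scipy's distance pruning removes the smaller of two close peaks,
    # which is exactly the required tie-break
    idx, _ = sps.find_peaks(rec.samples, height=min_height, distance=dist)
    if len(idx) == 0:
        raise NoPeaksError(
            f"no peaks above {min_height} of normalized max "
            f"(signal max {np.max(rec.samples):.3g}, "
            f"{len(rec.samples)} samples at {rec.fs} Hz)"
        )
    return RPeakSeries(indices=idx, fs=rec.fs)


def peaks_to_rri(peaks: RPeakSeries) -> RRISeries:
    """Successive peak-time differences in ms; labels start as normal."""
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks to form intervals")
    times = peaks.times
    return RRISeries(np.diff(times) * 1000.0, times)


def flag_ectopics(rri: RRISeries, dev_threshold: float = 0.2) -> np.ndarray:
    """Automated ectopy screen.

    An interval is flagged when it deviates by more than ``dev_threshold``
    (relative) from the running median of the 5 preceding unflagged
    intervals; intervals outside the physiologic 250–2000 ms range are
    always flagged.  With fewer than 6 intervals nothing is flagged.
    """
    n = len(rri)
    flags = np.zeros(n, dtype=bool)
    if n < 6:
        import warnings

        warnings.warn("series too short for ectopy screening; no flags set",
                      stacklevel=2)
        return flags

    x = rri.intervals
    flags |= (x < RRI_MIN_MS) | (x > RRI_MAX_MS)

    # reference for the first intervals (running median not yet primed):
    # median of the leading in-range intervals
    in_range = x[(x >= RRI_MIN_MS) & (x <= RRI_MAX_MS)]
    bootstrap_med = float(np.median(in_range[:11])) if len(in_range) else float(np.median(x))

    history: list = []
    for k in range(n):
        med = float(np.median(history[-5:])) if len(history) >= 5 else bootstrap_med
        if abs(x[k] - med) > dev_threshold * med:
            flags[k] = True
        if not flags[k]:
            history.append(x[k])
    return flags


def correct_ectopics(rri: RRISeries, flags: np.ndarray) -> RRISeries:
    """Replace each maximal run of flagged intervals by its mean.

    A run of length m and total duration D becomes m equal intervals of
    D/m each, so the total series duration is preserved exactly; replaced
    intervals are labeled ``corrected``.
    """
    flags = np.asarray(flags, dtype=bool)
    if len(flags) != len(rri):
        raise ValueError("flags must align with intervals")
    if flags.all() and len(rri) > 0:
        raise ValueError("every interval flagged: series unusable")

    out = rri.copy()
    k = 0
    n = len(out)
    while k < n:
        if flags[k]:
            j = k
            while j < n and flags[j]:
                j += 1
            run = out.intervals[k:j]
            out.intervals[k:j] = np.sum(run) / len(run)
            out.labels[k:j] = LABEL_CORRECTED
            k = j
        else:
            k += 1
    # beat times interior to corrected runs move to the equalized positions
    out.beat_times[1:] = out.beat_times[0] + np.cumsum(out.intervals) / 1000.0
    return out


def select_segment(
    rec: RawRecording,
    quality_threshold: float = 0.05,
    min_beats: int = 150,
    duration: float = 300.0,
    cutoff: Optional[float] = None,
    filter_order: int = 4,
    min_height: float = 0.4,
    refractory: float = 250.0,
    dev_threshold: float = 0.2,
) -> SegmentSelection:
    """Choose the first usable 5-minute window of a raw record.

    Non-overlapping windows are evaluated from t = 0 in ``duration`` steps
    (the start of the record is the favored choice; later windows are
    fallbacks).  A window qualifies when its flagged-beat fraction is at
    most ``quality_threshold`` and it contains at least ``min_beats``
    detected beats.  Raises :class:`SegmentSelectionError` when no window
    qualifies — the record is excluded for poorly detectable R peaks.
    """
    if rec.duration < duration:
        raise ValueError(
            f"record is {rec.duration:.0f} s; at least {duration:.0f} s needed"
        )
    n_windows = int(rec.duration // duration)
    for w in range(n_windows):
        start = w * duration
        try:
            seg = rec.slice_time(start, duration)
            filt = normalize_amplitude(
                highpass_filter(seg, cutoff=cutoff, order=filter_order)
            )
            peaks = detect_rpeaks(filt, min_height=min_height, refractory=refractory)
            rri = peaks_to_rri(peaks)
            flags = flag_ectopics(rri, dev_threshold=dev_threshold)
        except (NoPeaksError, ValueError):
            continue
        frac = float(np.mean(flags)) if len(flags) else 1.0
        if frac <= quality_threshold and len(peaks) >= min_beats:
            return SegmentSelection(
                start=start, duration=duration,
                fraction_corrected=frac, n_beats=len(peaks),
            )
    raise SegmentSelectionError("poorly detectable R peaks")


def evaluate_detection(
    detected: RPeakSeries, truth: GroundTruth, tol: float = 10.0
) -> Tuple[float, float]:
    """Greedy one-to-one matching of detected to true beats within ``tol`` ms.

    Returns ``(sensitivity, ppv)``: matched / true and matched / detected.
    """
    true_t = np.asarray(truth.beat_times, dtype=float)
    det_t = np.asarray(detected.times, dtype=float)
    tol_s = tol / 1000.0
    matched = 0
    j = 0
    for t in true_t:
        while j < len(det_t) and det_t[j] < t - tol_s:
            j += 1
        if j < len(det_t) and abs(det_t[j] - t) <= tol_s:
            matched += 1
            j += 1
    sens = matched / len(true_t) if len(true_t) else 0.0
    ppv = matched / len(det_t) if len(det_t) else 0.0
    return sens, ppv
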