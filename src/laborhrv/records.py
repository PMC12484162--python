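"""Core in-memory containers for recordings, R peaks and RR-interval series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: Hard physiologic screen on RR intervals (ms).  Intervals outside this
#: range cannot be sinus beats at term and are always treated as artifacts.
RRI_MIN_MS = 250.0
RRI_MAX_MS = 2000.0

#: Interval labels.
LABEL_NORMAL = "normal"
LABEL_ECTOPIC = "ectopic"
LABEL_CORRECTED = "corrected"

DELIVERY_MODES = ("spontaneous", "induced", "cesarean")


@dataclass
class SubjectMeta:
    """Per-subject clinical metadata.

    Gestational ages are decimal weeks ("W weeks + D days" is W + D/7).
    """

    subject_id: str = ""
    age: Optional[float] = None            # years
    bmi: Optional[float] = None            # kg/m^2
    ga_recording: Optional[float] = None   # weeks
    ga_delivery: Optional[float] = None    # weeks
    delivery_mode: Optional[str] = None    # spontaneous | induced | cesarean

    def __post_init__(self) -> None:
        if self.delivery_mode is not None and self.delivery_mode not in DELIVERY_MODES:
            raise ValueError(f"unknown delivery mode {self.delivery_mode!r}")
        if (
            self.ga_recording is not None
            and self.ga_delivery is not None
            and self.ga_delivery < self.ga_recording
        ):
            raise ValueError("ga_delivery must be >= ga_recording")


@dataclass
class RawRecording:
    """A uniformly sampled single-channel physiological signal.

    Parameters
    ----------
    samples : array of amplitudes, arbitrary units.
    fs : sampling rate in Hz (200 Hz typical for EHG, 1000 Hz for ECG).
    modality : ``"EHG"`` or ``"ECG"``.
    subject : optional clinical metadata.
    """

    samples: np.ndarray
    fs: float
    modality: str = "ECG"
    subject: SubjectMeta = field(default_factory=SubjectMeta)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.modality not in ("EHG", "ECG"):
            raise ValueError(f"modality must be 'EHG' or 'ECG', got {self.modality!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.fs

    def slice_time(self, start_s: float, duration_s: float) -> "RawRecording":
        """Return a copy restricted to ``[start_s, start_s + duration_s)``."""
        i0 = int(round(start_s * self.fs))
        i1 = i0 + int(round(duration_s * self.fs))
        if i0 < 0 or i1 > len(self.samples):
            raise ValueError("requested slice outside record")
        return replace(self, samples=self.samples[i0:i1].copy())


@dataclass
class RPeakSeries:
    """Detected R-peak positions.

    ``times`` are in seconds from record start; ``indices`` are sample
    positions (``times = indices / fs``).
    """

    indices: np.ndarray
    fs: float
    t_offset: float = 0.0   # record time of sample 0 of the analysed segment

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return self.t_offset + self.indices / self.fs

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class RRISeries:
    """Ordered beat-to-beat intervals in milliseconds.

    ``beat_times`` has one more element than ``intervals``; interval ``k``
    spans ``beat_times[k]`` to ``beat_times[k+1]``.  ``labels`` mark each
    interval as normal, ectopic (flagged, uncorrected) or corrected.
    """

    intervals: np.ndarray
    beat_times: np.ndarray
    labels: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.labels is None:
            self.labels = np.full(len(self.intervals), LABEL_NORMAL, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
        if len(self.beat_times) != len(self.intervals) + 1:
            raise ValueError("need len(beat_times) == len(intervals) + 1")
        if len(self.labels) != len(self.intervals):
            raise ValueError("labels must align with intervals")
        if np.any(self.intervals <= 0):
            raise ValueError("all intervals must be positive")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_duration_ms(self) -> float:
        return float(np.sum(self.intervals))

    def copy(self) -> "RRISeries":
        return RRISeries(
            self.intervals.copy(), self.beat_times.copy(), self.labels.copy()
        )


@dataclass
class SegmentSelection:
    """A 5-minute analysis window chosen from a longer record."""

    start: float                 # s from record start
    duration: float = 300.0     # s; 300 s is the standard short-term HRV length
    fraction_corrected: float = 0.0
    n_beats: int = 0

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("segment start must be >= 0")
        if self.duration <= 0:
            raise ValueError("segment duration must be positive")
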