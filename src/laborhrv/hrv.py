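"""Short-term (5-minute) time- and frequency-domain HRV indices.

Time domain: mean RR, SDNN (sample SD of normal-to-normal intervals) and
RMSSD (root mean square of successive differences).  Frequency domain: the
RR series is resampled to a uniform 4 Hz tachogram by cubic interpolation,
linearly detrended, and its power spectral density estimated by an averaged
modified periodogram (Hann-tapered 150-s segments, 50% overlap).  Band
powers are integrated over

* VLF: 0.0033–0.04 Hz
* LF:  0.04–0.15 Hz
* HF:  0.15–0.4 Hz

and reported as natural logs of absolute power in ms²; the LF/HF ratio is
taken on the raw powers.  At 300 s the VLF band covers roughly one cycle of
its lowest frequency, so VLF values carry a low-reliability flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from laborhrv.records import RRISeries

__all__ = [
    "VLF_BAND", "LF_BAND", "HF_BAND", "BANDS",
    "Tachogram", "SpectralEstimate", "HRVMetrics",
    "time_domain", "resample_tachogram", "estimate_psd", "band_powers",
    "band_fraction", "compute_hrv",
]

VLF_BAND: Tuple[float, float] = (0.0033, 0.04)
LF_BAND: Tuple[float, float] = (0.04, 0.15)
HF_BAND: Tuple[float, float] = (0.15, 0.4)
BANDS: Dict[str, Tuple[float, float]] = {"vlf": VLF_BAND, "lf": LF_BAND, "hf": HF_BAND}


@dataclass
class Tachogram:
    """RR series resampled onto a uniform grid (ms values)."""

    values: np.ndarray
    fs_interp: float = 4.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def duration(self) -> float:
        return len(self.values) / self.fs_interp


@dataclass
class SpectralEstimate:
    """One-sided PSD of the tachogram in ms²/Hz."""

    freqs: np.ndarray
    power_density: np.ndarray
    resolution: float
    method_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power_density = np.asarray(self.power_density, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be ascending")
        if np.any(self.power_density < -1e-12):
            raise ValueError("power density must be non-negative")

    @property
    def total_power(self) -> float:
        return float(np.trapezoid(self.power_density, self.freqs))


@dataclass
class HRVMetrics:
    """HRV indices for one 5-minute segment."""

    mean_rr: float          # ms
    sdnn: float             # ms
    rmssd: float            # ms
    vlf_ln: Optional[float] = None   # ln(ms²)
    lf_ln: Optional[float] = None
    hf_ln: Optional[float] = None
    lf_hf: Optional[float] = None    # ratio of raw powers
    vlf_low_reliability: bool = True
    method_params: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "mean_rr": self.mean_rr, "sdnn": self.sdnn, "rmssd": self.rmssd,
            "vlf_ln": self.vlf_ln, "lf_ln": self.lf_ln, "hf_ln": self.hf_ln,
            "lf_hf": self.lf_hf,
        }


def time_domain(rri: RRISeries | np.ndarray) -> Tuple[float, float, float]:
    """``(mean_rr, sdnn, rmssd)`` in ms.

    SDNN uses the sample standard deviation (n−1 denominator); RMSSD is
    the root mean square of successive interval differences.
    """
    x = rri.intervals if isinstance(rri, RRISeries) else np.asarray(rri, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 intervals")
    d = np.diff(x)
    return (
        float(np.mean(x)),
        float(np.std(x, ddof=1)),
        float(np.sqrt(np.mean(d**2))),
    )


def resample_tachogram(rri: RRISeries, fs_interp: float = 4.0) -> Tachogram:
    """Cubic interpolation of (beat time, interval) onto a uniform grid.

    Each interval is anchored at the beat that ends it.  The grid spans the
    support of the beat times; grid length is ``floor(span * fs) + 1``.
    """
    if len(rri) < 4:
        raise ValueError("need at least 4 beats for cubic interpolation")
    x = rri.beat_times[1:]
    y = rri.intervals
    spline = CubicSpline(x, y)
    span = x[-1] - x[0]
    n = int(np.floor(span * fs_interp)) + 1
    grid = x[0] + np.arange(n) / fs_interp
    return Tachogram(spline(grid), fs_interp=fs_interp, t0=float(x[0]))


def estimate_psd(
    tach: Tachogram,
    segment_s: float = 150.0,
    overlap: float = 0.5,
    detrend: str = "linear",
    min_duration_s: float = 290.0,
) -> SpectralEstimate:
    """Averaged modified periodogram (Hann taper, 50% overlap by default).

    The tachogram is detrended (linear by default, suppressing
    within-segment drift) before tapering; the one-sided density integrates
    back to the series variance up to taper leakage.
    """
    if tach.duration < min_duration_s:
        raise ValueError(
            f"tachogram covers {tach.duration:.0f} s; 300 s (5 min) is the "
            "minimum recommended length for frequency-domain HRV"
        )
    nperseg = int(round(segment_s * tach.fs_interp))
    if nperseg > len(tach.values):
        raise ValueError("analysis window longer than tachogram")
    freqs, pxx = sps.welch(
        tach.values,
        fs=tach.fs_interp,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        detrend=detrend,
        scaling="density",
    )
    return SpectralEstimate(
        freqs=freqs,
        power_density=np.maximum(pxx, 0.0),
        resolution=float(freqs[1] - freqs[0]),
        method_params={
            "estimator": "welch", "window": "hann", "segment_s": segment_s,
            "overlap": overlap, "detrend": detrend, "fs_interp": tach.fs_interp,
            "bands_hz": {k: list(v) for k, v in BANDS.items()},
        },
    )


def _band_power(psd: SpectralEstimate, band: Tuple[float, float]) -> float:
    """Trapezoidal integral of the density over ``band`` (ms²).

    Band edges falling between frequency bins are handled by linear
    interpolation of the density at the exact edges.
    """
    lo, hi = band
    f, p = psd.freqs, psd.power_density
    inside = (f > lo) & (f < hi)
    fi = np.concatenate([[lo], f[inside], [hi]])
    pi = np.concatenate([
        [np.interp(lo, f, p)], p[inside], [np.interp(hi, f, p)]
    ])
    return float(np.trapezoid(pi, fi))


def band_powers(psd: SpectralEstimate) -> Tuple[float, float, float, float]:
    """``(vlf_ln, lf_ln, hf_ln, lf_hf)``.

    Log values are natural logs of the raw band powers in ms²; the LF/HF
    ratio is taken on raw powers (so ``lf_hf == exp(lf_ln - hf_ln)``).
    """
    if psd.freqs[-1] < HF_BAND[1]:
        raise ValueError("spectral estimate must cover up to 0.4 Hz")
    vlf = _band_power(psd, VLF_BAND)
    lf = _band_power(psd, LF_BAND)
    hf = _band_power(psd, HF_BAND)
    if hf <= 0:
        raise ValueError("zero HF power: LF/HF ratio undefined")
    tiny = np.finfo(float).tiny
    return (
        float(np.log(max(vlf, tiny))),
        float(np.log(max(lf, tiny))),
        float(np.log(hf)),
        float(lf / hf),
    )


def band_fraction(psd: SpectralEstimate, band: Tuple[float, float]) -> float:
    """Fraction of total spectral power lying inside ``band``."""
    total = psd.total_power
    if total <= 0:
        return 0.0
    return _band_power(psd, band) / total


def compute_hrv(
    rri: RRISeries,
    fs_interp: float = 4.0,
    segment_s: float = 150.0,
    overlap: float = 0.5,
    detrend: str = "linear",
) -> HRVMetrics:
    """All indices for one corrected 5-minute RR series."""
    mean_rr, sdnn, rmssd = time_domain(rri)
    tach = resample_tachogram(rri, fs_interp=fs_interp)
    psd = estimate_psd(tach, segment_s=segment_s, overlap=overlap, detrend=detrend)
    vlf_ln, lf_ln, hf_ln, lf_hf = band_powers(psd)
    return HRVMetrics(
        mean_rr=mean_rr, sdnn=sdnn, rmssd=rmssd,
        vlf_ln=vlf_ln, lf_ln=lf_ln, hf_ln=hf_ln, lf_hf=lf_hf,
        vlf_low_reliability=True,
        method_params=psd.method_params,
    )
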