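"""Ground-truthed synthetic recordings, RR series and cohorts.

The generators here emulate the inputs of the maternal-HRV pipeline so that
every downstream stage can be validated against known truth:

* :func:`generate_rri_ipfm` — RR series from an integral pulse frequency
  modulation (IPFM) model, giving direct control over the spectral content
  of the tachogram (tones can be placed in the VLF/LF/HF bands).
* :func:`inject_ectopics` — premature beats with compensatory pauses.
* :func:`synthesize_ecg` / :func:`synthesize_ehg` — waveforms with known
  R-peak positions: a clean Gaussian-QRS ECG, or an abdominal EHG in which
  the cardiac train rides on uterine contraction bursts, baseline wander
  and broadband noise.
* :func:`generate_cohort` — whole cohorts with monotone HRV–time-to-delivery
  relations planted at chosen Spearman strengths via a Gaussian copula.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from laborhrv.records import (
    LABEL_NORMAL,
    RawRecording,
    RRISeries,
    SubjectMeta,
)

__all__ = [
    "TachogramSpec",
    "EhgSynthesisSpec",
    "CohortSpec",
    "GroundTruth",
    "generate_rri_ipfm",
    "inject_ectopics",
    "synthesize_ecg",
    "synthesize_ehg",
    "ehg_background_power",
    "ehg_gain_for_ratio_db",
    "generate_cohort",
]


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class TachogramSpec:
    """Parameters of the IPFM beat generator.

    ``modulations`` is a list of ``(freq_hz, rel_amplitude)`` tones applied
    to the instantaneous heart rate; amplitudes are relative to the mean
    rate and must sum to < 1 so the rate stays positive.
    """

    mean_rr: float = 800.0                # ms
    modulations: Sequence[Tuple[float, float]] = ()
    duration: float = 300.0               # s
    seed: int = 0

    def validate(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        total = 0.0
        for f, a in self.modulations:
            if not (0.0 < f <= 0.5):
                raise ValueError(f"modulation frequency {f} Hz outside (0, 0.5]")
            if not (0.0 <= a < 1.0):
                raise ValueError(f"relative amplitude {a} outside [0, 1)")
            total += a
        if total >= 1.0:
            raise ValueError(
                f"modulation amplitudes sum to {total:.3f} >= 1; the "
                "instantaneous rate would go non-positive"
            )


@dataclass
class EhgSynthesisSpec:
    """Parameters of the synthetic abdominal EHG.

    The signal is a scaled cardiac QRS train plus uterine contraction
    bursts (band-limited noise under raised-cosine envelopes), sinusoidal
    baseline wander and white noise.  Defaults place the uterine activity
    in the physiological 0.1–3 Hz surface-EMG band with ~0.02 Hz wander.
    """

    fs: float = 200.0                     # Hz
    ecg_gain: float = 1.0
    contraction_rate: float = 2.0         # bursts per 5 min
    contraction_band: Tuple[float, float] = (0.1, 3.0)   # Hz
    contraction_amp: float = 0.5          # rms of each burst at envelope peak
    wander_freq: float = 0.02             # Hz
    wander_amp: float = 0.3
    noise_sd: float = 0.03
    qrs_width: float = 20.0               # ms, FWHM of the Gaussian R wave
    seed: int = 0

    def validate(self) -> None:
        if self.fs < 100:
            raise ValueError("EHG sampling rate must be >= 100 Hz")
        lo, hi = self.contraction_band
        if not (0 < lo < hi):
            raise ValueError("contraction band must satisfy 0 < low < high")
        if hi >= 5.0:
            raise ValueError("contraction band upper edge must be < 5 Hz")
        if self.wander_freq >= 0.1:
            raise ValueError("baseline wander must be < 0.1 Hz")
        if hi >= self.fs / 2:
            raise ValueError("contraction band exceeds Nyquist")


@dataclass
class CohortSpec:
    """Parameters of a synthetic pregnancy cohort.

    ``effect_map`` plants monotone relations between HRV metrics and time
    to delivery (TTD): it maps a metric name (``"rmssd"``, ``"lf_hf"`` or
    ``"mean_rr"``) to a signed target Spearman rho.  The planting uses a
    Gaussian copula, so with ``subject_noise_sd = 0`` the population rank
    correlation equals the target exactly; extra per-subject dispersion
    attenuates it.
    """

    n_subjects: int = 37
    ttd_range: Tuple[float, float] = (0.0, 9.3)       # weeks
    effect_map: dict = field(default_factory=dict)    # metric -> signed rho
    subject_noise_sd: float = 0.0                     # extra latent noise
    delivery_mode_probs: Tuple[float, float, float] = (35 / 45, 4 / 45, 6 / 45)
    modality: str = "ECG"
    fs: float = 1000.0                                # Hz (200 for EHG)
    duration: float = 310.0                           # s per recording
    synthesize_signals: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        lo, hi = self.ttd_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid ttd_range")
        if abs(sum(self.delivery_mode_probs) - 1.0) > 1e-9:
            raise ValueError("delivery_mode_probs must sum to 1")
        for metric, rho in self.effect_map.items():
            if metric not in ("rmssd", "lf_hf", "mean_rr"):
                raise ValueError(f"cannot plant an effect on {metric!r}")
            if not (-1.0 < rho < 1.0):
                raise ValueError("planted rho must lie in (-1, 1)")


@dataclass
class GroundTruth:
    """What the generator actually produced, for recovery tests."""

    beat_times: np.ndarray                 # s, strictly increasing
    true_rri: np.ndarray                   # ms, len = len(beat_times) - 1
    ectopic_flags: np.ndarray = None       # type: ignore[assignment]
    peak_indices: Optional[np.ndarray] = None   # sample index of each R peak
    true_metrics: Optional[dict] = None
    planted_correlations: Optional[dict] = None
    component_power: Optional[dict] = None  # per-component mean square (EHG)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.true_rri = np.asarray(self.true_rri, dtype=float)
        if self.ectopic_flags is None:
            self.ectopic_flags = np.zeros(len(self.true_rri), dtype=bool)
        if np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        if len(self.true_rri) != len(self.beat_times) - 1:
            raise ValueError("need len(true_rri) == len(beat_times) - 1")


# --------------------------------------------------------------------------
# IPFM tachogram
# --------------------------------------------------------------------------

def generate_rri_ipfm(spec: TachogramSpec) -> Tuple[np.ndarray, RRISeries, GroundTruth]:
    """Generate an RR series from the IPFM model.

    Beats fire whenever the integral of the modulated instantaneous rate

    .. math:: m(t) = \\frac{1}{\\bar T}\\Big(1 + \\sum_i a_i \\sin(2\\pi f_i t + \\phi_i)\\Big)

    crosses an integer.  The integral has closed form, is evaluated on a
    1 ms grid and crossing times are refined by linear interpolation
    (error well below 1 ms).  Phases are drawn from the seeded generator.

    Returns ``(beat_times_s, RRISeries, GroundTruth)``.  The integrator
    reset at ``t = 0`` counts as the first beat.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    tbar = spec.mean_rr / 1000.0          # s
    mods = [(f, a, rng.uniform(0, 2 * np.pi)) for f, a in spec.modulations]

    dt = 1e-3
    t = np.arange(0.0, spec.duration + dt, dt)
    integral = t.copy()
    for f, a, phi in mods:
        integral += (a / (2 * np.pi * f)) * (np.cos(phi) - np.cos(2 * np.pi * f * t + phi))
    m = integral / tbar                   # monotone: sum of amplitudes < 1

    n_beats = int(np.floor(m[-1]))
    ks = np.arange(1, n_beats + 1, dtype=float)
    hi = np.searchsorted(m, ks)
    lo = hi - 1
    frac = (ks - m[lo]) / (m[hi] - m[lo])
    crossings = t[lo] + frac * dt

    beat_times = np.concatenate([[0.0], crossings])
    rri_ms = np.diff(beat_times) * 1000.0
    series = RRISeries(rri_ms, beat_times)
    truth = GroundTruth(
        beat_times=beat_times,
        true_rri=rri_ms,
        true_metrics=_time_domain_truth(rri_ms),
    )
    return beat_times, series, truth


def _time_domain_truth(rri_ms: np.ndarray) -> dict:
    """Plain-formula time-domain metrics of the true RR series."""
    rri_ms = np.asarray(rri_ms, dtype=float)
    d = np.diff(rri_ms)
    return {
        "mean_rr": float(np.mean(rri_ms)),
        "sdnn": float(np.std(rri_ms, ddof=1)) if len(rri_ms) > 1 else 0.0,
        "rmssd": float(np.sqrt(np.mean(d**2))) if len(d) else 0.0,
    }


# --------------------------------------------------------------------------
# ectopic beats
# --------------------------------------------------------------------------

def inject_ectopics(
    rri: RRISeries,
    n_ectopic: int,
    prematurity: float = 0.5,
    seed: int = 0,
    sites: Optional[Sequence[int]] = None,
) -> Tuple[RRISeries, np.ndarray]:
    """Insert premature beats with compensatory pauses.

    At each site ``k`` the interval is shortened to ``prematurity`` times
    its length and interval ``k + 1`` absorbs the remainder, so the total
    series duration is preserved exactly.  Both altered intervals are
    flagged.  Sites are kept >= 3 apart so each ectopic produces its own
    unambiguous two-interval run.
    """
    if not (0.0 < prematurity < 1.0):
        raise ValueError("prematurity must lie in (0, 1)")
    n = len(rri)
    if n_ectopic < 0 or n_ectopic > n / 4:
        raise ValueError(f"{n_ectopic} ectopics is too many for {n} intervals")

    out = rri.copy()
    flags = np.zeros(n, dtype=bool)
    if n_ectopic == 0:
        return out, flags

    if sites is None:
        rng = np.random.default_rng(seed)
        chosen: List[int] = []
        candidates = rng.permutation(n - 1)
        for k in candidates:
            if all(abs(k - c) >= 3 for c in chosen):
                chosen.append(int(k))
            if len(chosen) == n_ectopic:
                break
        if len(chosen) < n_ectopic:
            raise ValueError("could not place non-adjacent ectopic sites")
        sites = sorted(chosen)
    else:
        sites = sorted(int(s) for s in sites)
        if any(s < 0 or s >= n - 1 for s in sites):
            raise ValueError("ectopic site outside series")
        if any(b - a < 3 for a, b in zip(sites, sites[1:])):
            raise ValueError("ectopic sites must be >= 3 intervals apart")

    for k in sites:
        orig = out.intervals[k]
        short = orig * prematurity
        out.intervals[k] = short
        out.intervals[k + 1] += orig - short
        out.beat_times[k + 1] = out.beat_times[k] + short / 1000.0
        flags[k] = flags[k + 1] = True
    return out, flags


# --------------------------------------------------------------------------
# waveform synthesis
# --------------------------------------------------------------------------

#: Lead-in prepended to synthesized waveforms (s) so the first R peak is an
#: interior sample; ground-truth beat times are reported in signal time.
_LEAD_IN_S = 0.3


def _qrs_train(
    beat_times: np.ndarray, fs: float, qrs_width_ms: float, amplitude: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-pulse R-wave train; returns (signal, peak indices, beat times)."""
    beat_times = np.asarray(beat_times, dtype=float) + _LEAD_IN_S
    if np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat_times must be strictly increasing")
    sigma = (qrs_width_ms / 1000.0) / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    n = int(math.ceil((beat_times[-1] + 0.3) * fs))
    x = np.zeros(n)
    half = int(math.ceil(5 * sigma * fs))
    for bt in beat_times:
        c = bt * fs
        i0 = max(0, int(math.floor(c)) - half)
        i1 = min(n, int(math.ceil(c)) + half + 1)
        idx = np.arange(i0, i1)
        x[idx] += amplitude * np.exp(-0.5 * ((idx - c) / (sigma * fs)) ** 2)
    peak_idx = np.clip(np.round(beat_times * fs).astype(np.int64), 0, n - 1)
    return x, peak_idx, beat_times


def synthesize_ecg(
    beat_times: np.ndarray,
    fs: float = 1000.0,
    qrs_width: float = 20.0,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    subject: Optional[SubjectMeta] = None,
) -> Tuple[RawRecording, GroundTruth]:
    """Clean maternal ECG: Gaussian QRS pulses plus white noise.

    ``qrs_width`` is the full width at half maximum in ms.  Requires
    ``fs >= 4 / qrs_width`` so each pulse is well sampled.
    """
    if fs < 4.0 / (qrs_width / 1000.0) / 10.0:
        # 4 samples per pulse width is the bare minimum for peak timing
        raise ValueError("sampling rate too low for the requested QRS width")
    x, peak_idx, bt_sig = _qrs_train(beat_times, fs, qrs_width, amplitude)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + rng.normal(0.0, noise_sd, size=len(x))
    rec = RawRecording(x, fs, modality="ECG", subject=subject or SubjectMeta())
    truth = GroundTruth(
        beat_times=bt_sig,
        true_rri=np.diff(bt_sig) * 1000.0,
        peak_indices=peak_idx,
    )
    return rec, truth


def synthesize_ehg(
    beat_times: np.ndarray,
    spec: EhgSynthesisSpec,
    subject: Optional[SubjectMeta] = None,
    noise_sd_profile: Optional[np.ndarray] = None,
) -> Tuple[RawRecording, GroundTruth]:
    """Abdominal EHG: cardiac train over uterine bursts, wander and noise.

    Contraction bursts are band-limited Gaussian noise shaped by
    raised-cosine (Hann) envelopes of 30–60 s, at ``contraction_rate``
    events per 5 minutes.  ``noise_sd_profile``, if given, is a per-sample
    multiplier on the white-noise standard deviation (used to build records
    whose noise varies over time).

    The returned :class:`GroundTruth` carries the mean-square power of each
    component (``ecg``, ``contraction``, ``wander``, ``noise``) so tests can
    state the cardiac-to-background power ratio exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    ecg, peak_idx, bt_sig = _qrs_train(beat_times, spec.fs, spec.qrs_width, 1.0)
    ecg *= spec.ecg_gain
    n = len(ecg)
    t = np.arange(n) / spec.fs
    duration = n / spec.fs

    contraction = np.zeros(n)
    n_bursts = int(round(spec.contraction_rate * duration / 300.0))
    if n_bursts > 0 and spec.contraction_amp > 0:
        sos = sps.butter(4, spec.contraction_band, btype="bandpass",
                         fs=spec.fs, output="sos")
        for _ in range(n_bursts):
            burst_len = rng.uniform(30.0, 60.0)
            center = rng.uniform(0.0, duration)
            raw = sps.sosfiltfilt(sos, rng.standard_normal(n))
            raw *= spec.contraction_amp / max(np.std(raw), 1e-12)
            env = 0.5 * (1.0 - np.cos(2.0 * np.pi *
                                      np.clip((t - center + burst_len / 2) / burst_len, 0, 1)))
            contraction += raw * env

    phi = rng.uniform(0, 2 * np.pi)
    wander = spec.wander_amp * np.sin(2 * np.pi * spec.wander_freq * t + phi)

    noise = rng.normal(0.0, 1.0, size=n) * spec.noise_sd
    if noise_sd_profile is not None:
        if len(noise_sd_profile) != n:
            raise ValueError("noise_sd_profile must match signal length")
        noise = noise * np.asarray(noise_sd_profile, dtype=float)

    x = ecg + contraction + wander + noise
    rec = RawRecording(x, spec.fs, modality="EHG", subject=subject or SubjectMeta())
    truth = GroundTruth(
        beat_times=bt_sig,
        true_rri=np.diff(bt_sig) * 1000.0,
        peak_indices=peak_idx,
        component_power={
            "ecg": float(np.mean(ecg**2)),
            "contraction": float(np.mean(contraction**2)),
            "wander": float(np.mean(wander**2)),
            "noise": float(np.mean(noise**2)),
        },
    )
    return rec, truth


def ehg_background_power(truth: GroundTruth) -> float:
    """Total mean-square power of the non-cardiac EHG components."""
    cp = truth.component_power or {}
    return cp.get("contraction", 0.0) + cp.get("wander", 0.0) + cp.get("noise", 0.0)


def ehg_gain_for_ratio_db(
    beat_times: np.ndarray, spec: EhgSynthesisSpec, target_db: float
) -> float:
    """ECG gain giving a cardiac-to-background power ratio of ``target_db``.

    Synthesizes the record once at the spec's gain to measure component
    powers, then rescales; powers add independently so the rescaling is
    exact up to the seed-fixed realization.
    """
    _, truth = synthesize_ehg(beat_times, spec)
    p_ecg_unit = truth.component_power["ecg"] / max(spec.ecg_gain, 1e-12) ** 2
    p_bg = ehg_background_power(truth)
    return math.sqrt(10.0 ** (target_db / 10.0) * p_bg / p_ecg_unit)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

#: IPFM tone frequencies used when planting spectral structure (Hz).
_VLF_TONE, _LF_TONE, _HF_TONE = 0.01, 0.1, 0.25


@dataclass
class SyntheticSubject:
    """One generated subject: metadata, truth, and (optionally) a waveform."""

    meta: SubjectMeta
    tachogram_spec: TachogramSpec
    truth: GroundTruth                     # RR-series truth (IPFM timebase)
    recording: Optional[RawRecording] = None
    true_rri: Optional[RRISeries] = None
    waveform_truth: Optional[GroundTruth] = None   # truth in signal time


def generate_cohort(spec: CohortSpec) -> Tuple[List[SyntheticSubject], pd.DataFrame]:
    """Generate a cohort with planted HRV–time-to-delivery rank correlations.

    Per subject: time to delivery (TTD) is drawn uniformly on
    ``ttd_range``; for each planted metric a latent Gaussian correlated
    with the TTD normal score at ``r = 2 sin(pi * rho / 6)`` (the Gaussian
    copula inversion of the target Spearman rho) drives a monotone map onto
    the physical parameter (HF modulation amplitude for RMSSD, LF/HF
    amplitude ratio for LF/HF, mean RR directly).  GA at delivery is drawn
    in 37–41 weeks and GA at recording set so their difference equals TTD.

    Returns the subject list and a ground-truth table (one row per subject)
    with the drawn TTD, GA fields, delivery mode, true tachogram parameters
    and the true time-domain metrics of each generated RR series.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ttd_range
    if hi == lo and spec.n_subjects > 1 and spec.effect_map:
        import warnings

        warnings.warn("degenerate ttd_range: planted correlations are "
                      "undefined against a constant", stacklevel=2)

    u = rng.uniform(0.0, 1.0, size=spec.n_subjects)
    ttd = lo + (hi - lo) * u
    z_ttd = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))

    latents = {}
    for metric, rho in spec.effect_map.items():
        r_p = 2.0 * math.sin(math.pi * rho / 6.0)
        eps = rng.standard_normal(spec.n_subjects)
        g = r_p * z_ttd + math.sqrt(1.0 - r_p**2) * eps
        if spec.subject_noise_sd > 0:
            g = g + spec.subject_noise_sd * rng.standard_normal(spec.n_subjects)
        latents[metric] = g

    # cohort-typical mean RR (ms); modest dispersion so it adds little rank
    # noise to the amplitude-driven metrics
    if "mean_rr" in latents:
        mean_rr = 677.0 + 79.0 * latents["mean_rr"]
    else:
        mean_rr = 677.0 + 25.0 * rng.standard_normal(spec.n_subjects)
    mean_rr = np.clip(mean_rr, 450.0, 1100.0)

    # LF/HF power ratio ~ lognormal around 0.7 (monotone in the LF/HF latent)
    g_ratio = latents.get("lf_hf", rng.standard_normal(spec.n_subjects))
    ratio = np.exp(np.log(0.7) + 0.6 * g_ratio)
    # target RMSSD ~ lognormal around 25 ms (monotone in the RMSSD latent);
    # for sinusoidal rate tones the successive-difference amplitude of tone
    # (f, a) at mean interval T is 2 a T sin(pi f T) ms, so the HF amplitude
    # giving the target RMSSD has closed form given the LF/HF ratio — this
    # keeps the planted RMSSD relation free of LF cross-talk
    g_rmssd = latents.get("rmssd", rng.standard_normal(spec.n_subjects))
    rmssd_target = np.exp(np.log(25.0) + 0.45 * g_rmssd)    # ms
    tbar = mean_rr / 1000.0
    s_hf = np.sin(np.pi * _HF_TONE * tbar)
    s_lf = np.sin(np.pi * _LF_TONE * tbar)
    a_hf = rmssd_target / (
        mean_rr * np.sqrt(2.0 * (s_hf**2 + ratio * s_lf**2))
    )
    a_lf = a_hf * np.sqrt(ratio)
    a_vlf = np.full(spec.n_subjects, 0.01)
    # safety cap keeping the instantaneous rate positive; the amplitude
    # spreads are chosen so it essentially never binds (binding would
    # saturate the planted monotone relations)
    scale = np.minimum(1.0, 0.6 / (a_vlf + a_lf + a_hf))
    a_vlf, a_lf, a_hf = a_vlf * scale, a_lf * scale, a_hf * scale

    ga_delivery = rng.uniform(37.0, 41.0, size=spec.n_subjects)
    modes = rng.choice(
        ["spontaneous", "induced", "cesarean"],
        size=spec.n_subjects, p=spec.delivery_mode_probs,
    )
    ages = rng.normal(29.0, 5.0, size=spec.n_subjects)
    bmis = rng.normal(26.0, 4.0, size=spec.n_subjects)

    subjects: List[SyntheticSubject] = []
    rows = []
    planted = dict(spec.effect_map)
    for i in range(spec.n_subjects):
        meta = SubjectMeta(
            subject_id=f"S{i:04d}",
            age=float(ages[i]),
            bmi=float(bmis[i]),
            ga_recording=float(ga_delivery[i] - ttd[i]),
            ga_delivery=float(ga_delivery[i]),
            delivery_mode=str(modes[i]),
        )
        tspec = TachogramSpec(
            mean_rr=float(mean_rr[i]),
            modulations=[
                (_VLF_TONE, float(a_vlf[i])),
                (_LF_TONE, float(a_lf[i])),
                (_HF_TONE, float(a_hf[i])),
            ],
            duration=spec.duration,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        beat_times, rri, truth = generate_rri_ipfm(tspec)
        truth.planted_correlations = planted
        rec, wt = None, None
        if spec.synthesize_signals:
            if spec.modality == "ECG":
                rec, wt = synthesize_ecg(
                    beat_times, fs=spec.fs, noise_sd=0.0,
                    seed=tspec.seed, subject=meta,
                )
            else:
                espec = EhgSynthesisSpec(fs=spec.fs, seed=tspec.seed)
                rec, wt = synthesize_ehg(beat_times, espec, subject=meta)
        subjects.append(SyntheticSubject(meta, tspec, truth, rec, rri, wt))
        rows.append({
            "subject_id": meta.subject_id,
            "age": meta.age,
            "bmi": meta.bmi,
            "ga_recording": meta.ga_recording,
            "ga_delivery": meta.ga_delivery,
            "ttd": float(ttd[i]),
            "delivery_mode": meta.delivery_mode,
            "true_mean_rr": truth.true_metrics["mean_rr"],
            "true_sdnn": truth.true_metrics["sdnn"],
            "true_rmssd": truth.true_metrics["rmssd"],
            "true_a_lf": float(a_lf[i]),
            "true_a_hf": float(a_hf[i]),
            "true_lf_hf_ratio": float(ratio[i] * 1.0),
        })
    table = pd.DataFrame(rows)
    return subjects, table
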