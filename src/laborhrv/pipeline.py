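"""End-to-end orchestration: recordings -> cohort table -> correlations.

Per subject: read -> high-pass filter -> amplitude normalize -> choose
5-minute segment -> detect R peaks -> RR intervals -> flag and correct
ectopy -> HRV metrics.  Subjects whose R peaks cannot be detected are
excluded with a logged reason rather than aborting the run.  The cohort
then goes through delivery-mode/quality exclusions, time-to-delivery
computation, a Lilliefors normality screen, and the Spearman correlation
table.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from laborhrv import extraction as ex
from laborhrv.cohort import (
    apply_exclusions,
    correlation_table,
    lilliefors_test,
    METRIC_COLUMNS,
    time_to_delivery,
)
from laborhrv.config import PipelineConfig
from laborhrv.hrv import HRVMetrics, compute_hrv
from laborhrv.records import RawRecording, RRISeries, SegmentSelection

logger = logging.getLogger("laborhrv")

__all__ = ["SubjectResult", "process_recording", "run_pipeline"]


@dataclass
class SubjectResult:
    """Outcome of per-subject processing (metrics or a failure reason)."""

    subject_id: str
    metrics: Optional[HRVMetrics] = None
    segment: Optional[SegmentSelection] = None
    rri: Optional[RRISeries] = None
    failure: Optional[str] = None


def process_recording(rec: RawRecording, config: Optional[PipelineConfig] = None
                      ) -> Tuple[HRVMetrics, SegmentSelection, RRISeries]:
    """Run the single-subject chain on one raw recording."""
    cfg = config or PipelineConfig()
    cfg.validate()
    sel = ex.select_segment(
        rec,
        quality_threshold=cfg.segment.quality_threshold,
        min_beats=cfg.segment.min_beats,
        duration=cfg.segment.duration,
        cutoff=cfg.filter.cutoff(rec.modality),
        filter_order=cfg.filter.order,
        min_height=cfg.detection.min_height,
        refractory=cfg.detection.refractory,
        dev_threshold=cfg.ectopic.dev_threshold,
    )
    seg = rec.slice_time(sel.start, sel.duration)
    filt = ex.normalize_amplitude(
        ex.highpass_filter(seg, cutoff=cfg.filter.cutoff(rec.modality),
                           order=cfg.filter.order)
    )
    peaks = ex.detect_rpeaks(filt, min_height=cfg.detection.min_height,
                             refractory=cfg.detection.refractory)
    peaks.t_offset = sel.start
    rri = ex.peaks_to_rri(peaks)
    flags = ex.flag_ectopics(rri, dev_threshold=cfg.ectopic.dev_threshold)
    rri = ex.correct_ectopics(rri, flags)
    metrics = compute_hrv(
        rri,
        fs_interp=cfg.spectral.fs_interp,
        segment_s=cfg.spectral.segment_s,
        overlap=cfg.spectral.overlap,
        detrend=cfg.spectral.detrend,
    )
    return metrics, sel, rri


def run_pipeline(
    recordings: Iterable[RawRecording],
    config: Optional[PipelineConfig] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full cohort analysis.

    Returns ``(cohort_table, correlation_table, report)``.  The report
    carries per-subject failures, the exclusion log, Lilliefors screen
    results and provenance (config hash and seed).
    """
    cfg = config or PipelineConfig()
    cfg.validate()
    results: List[SubjectResult] = []
    rows = []
    for i, rec in enumerate(recordings):
        sid = rec.subject.subject_id or f"subject{i:04d}"
        try:
            metrics, sel, rri = process_recording(rec, cfg)
            res = SubjectResult(sid, metrics, sel, rri)
        except Exception as exc:
            reason = str(exc) or type(exc).__name__
            logger.warning("subject %s excluded: %s", sid, reason)
            res = SubjectResult(sid, failure=reason)
        results.append(res)
        row = {
            "subject_id": sid,
            "age": rec.subject.age,
            "bmi": rec.subject.bmi,
            "ga_recording": rec.subject.ga_recording,
            "ga_delivery": rec.subject.ga_delivery,
            "delivery_mode": rec.subject.delivery_mode or "spontaneous",
            "quality_ok": res.failure is None,
        }
        if res.metrics is not None:
            row.update(res.metrics.as_dict())
        rows.append(row)
    cohort = pd.DataFrame(rows)
    if cohort["ga_delivery"].notna().all() and cohort["ga_recording"].notna().all():
        cohort["ttd"] = time_to_delivery(cohort["ga_delivery"], cohort["ga_recording"])
    else:
        cohort["ttd"] = np.nan

    kept, exclusion_log = apply_exclusions(cohort)
    if len(kept) < 3:
        raise ValueError("fewer than 3 usable subjects; cannot correlate")

    normality = {}
    rng_seed = cfg.seed
    for col in list(METRIC_COLUMNS) + ["ttd"]:
        vals = kept[col].dropna().to_numpy(dtype=float)
        if len(vals) >= 5 and np.std(vals, ddof=1) > 0:
            d, p = lilliefors_test(vals, n_mc=cfg.stats.n_mc, seed=rng_seed)
            normality[col] = {"statistic": d, "p": p, "normal_at_alpha":
                              bool(p > cfg.stats.alpha)}

    corr = correlation_table(kept, alpha=cfg.stats.alpha,
                             bh_correct=cfg.stats.bh_correct)

    cfg_hash = hashlib.sha256(cfg.to_yaml().encode()).hexdigest()[:16]
    report = {
        "n_input": len(rows),
        "n_analyzed": len(kept),
        "exclusions": exclusion_log,
        "failures": {r.subject_id: r.failure for r in results if r.failure},
        "normality": normality,
        "provenance": {"config_sha256": cfg_hash, "seed": cfg.seed},
    }
    return kept, corr, report
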