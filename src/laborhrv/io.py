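"""File formats: signal CSV, RRI CSV, ground-truth sidecars, cohort CSV.

CSV is the canonical interchange format.  A signal file is two columns
``time_s,value`` preceded by ``#``-comment header lines carrying the
sampling rate, modality and subject metadata, e.g.::

    # fs=200.0
    # modality=EHG
    # subject_id=S0001
    time_s,value
    0.000,0.12

A PhysioNet-record adapter is available when the optional ``wfdb`` package
is installed; the core pipeline has no binary-format dependency.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from laborhrv.records import RawRecording, RRISeries, SubjectMeta
from laborhrv.synthetic import GroundTruth

__all__ = [
    "write_signal_csv", "read_signal",
    "write_rri_csv", "read_rri_csv",
    "write_ground_truth", "read_ground_truth",
    "write_cohort_csv", "read_cohort_csv",
]

_META_FIELDS = ("subject_id", "age", "bmi", "ga_recording", "ga_delivery",
                "delivery_mode")


def write_signal_csv(path: str | Path, rec: RawRecording) -> None:
    path = Path(path)
    lines = [f"# fs={rec.fs}", f"# modality={rec.modality}"]
    for f in _META_FIELDS:
        v = getattr(rec.subject, f)
        if v is not None and v != "":
            lines.append(f"# {f}={v}")
    lines.append("time_s,value")
    t = np.arange(len(rec.samples)) / rec.fs
    body = "\n".join(f"{ti:.6f},{vi:.17g}" for ti, vi in zip(t, rec.samples))
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def _parse_header(path: Path) -> Tuple[dict, int]:
    meta = {}
    n_skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_skip += 1
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta, n_skip


def read_signal(
    path: str | Path, format: str = "csv", channel: Optional[int] = None,
    fs: Optional[float] = None,
) -> RawRecording:
    """Load a recording from CSV or (optionally) a PhysioNet record.

    For CSV the sampling rate is taken from the ``# fs=`` header, or from
    the time column spacing, or from the ``fs`` argument.  For multichannel
    PhysioNet records a ``channel`` selector is required.
    """
    if format == "physionet-record":
        return _read_physionet(path, channel)
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    path = Path(path)
    meta, n_skip = _parse_header(path)
    df = pd.read_csv(path, skiprows=n_skip, float_precision="round_trip")
    if "value" in df.columns:
        values = df["value"].to_numpy(dtype=float)
    else:
        values = df.iloc[:, -1].to_numpy(dtype=float)
    if "fs" in meta:
        fs_val = float(meta["fs"])
    elif "time_s" in df.columns and len(df) > 1:
        fs_val = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy(dtype=float))))
    elif fs is not None:
        fs_val = fs
    else:
        raise ValueError(f"{path}: sampling rate missing (no fs header or time column)")

    subject = SubjectMeta(
        subject_id=meta.get("subject_id", ""),
        age=float(meta["age"]) if "age" in meta else None,
        bmi=float(meta["bmi"]) if "bmi" in meta else None,
        ga_recording=float(meta["ga_recording"]) if "ga_recording" in meta else None,
        ga_delivery=float(meta["ga_delivery"]) if "ga_delivery" in meta else None,
        delivery_mode=meta.get("delivery_mode"),
    )
    return RawRecording(values, fs_val, modality=meta.get("modality", "ECG"),
                        subject=subject)


def _read_physionet(path: str | Path, channel: Optional[int]) -> RawRecording:
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - wfdb optional
        raise ImportError(
            "reading PhysioNet records requires the optional 'wfdb' package"
        ) from exc
    record = wfdb.rdrecord(str(path))  # pragma: no cover
    if record.n_sig > 1 and channel is None:  # pragma: no cover
        raise ValueError(
            f"multichannel record: pass channel= (available: {record.sig_name})"
        )
    ch = channel or 0  # pragma: no cover
    return RawRecording(  # pragma: no cover
        record.p_signal[:, ch], float(record.fs), modality="EHG",
        subject=SubjectMeta(subject_id=record.record_name),
    )


def write_rri_csv(path: str | Path, rri: RRISeries) -> None:
    df = pd.DataFrame({
        "beat_time_s": rri.beat_times[1:],
        "rri_ms": rri.intervals,
        "label": rri.labels,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_rri_csv(path: str | Path) -> RRISeries:
    df = pd.read_csv(path)
    ends = df["beat_time_s"].to_numpy(dtype=float)
    intervals = df["rri_ms"].to_numpy(dtype=float)
    t0 = ends[0] - intervals[0] / 1000.0
    return RRISeries(intervals, np.concatenate([[t0], ends]),
                     df["label"].to_numpy(dtype=object))


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    d = {
        "beat_times": truth.beat_times.tolist(),
        "true_rri": truth.true_rri.tolist(),
        "ectopic_flags": truth.ectopic_flags.astype(int).tolist(),
        "peak_indices": (truth.peak_indices.tolist()
                         if truth.peak_indices is not None else None),
        "true_metrics": truth.true_metrics,
        "planted_correlations": truth.planted_correlations,
        "component_power": truth.component_power,
    }
    Path(path).write_text(json.dumps(d))


def read_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        beat_times=np.asarray(d["beat_times"], dtype=float),
        true_rri=np.asarray(d["true_rri"], dtype=float),
        ectopic_flags=np.asarray(d["ectopic_flags"], dtype=bool),
        peak_indices=(np.asarray(d["peak_indices"], dtype=np.int64)
                      if d.get("peak_indices") is not None else None),
        true_metrics=d.get("true_metrics"),
        planted_correlations=d.get("planted_correlations"),
        component_power=d.get("component_power"),
    )


def write_cohort_csv(path: str | Path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
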