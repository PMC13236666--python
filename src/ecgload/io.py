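"""Plain-text readers and writers for the pipeline's session layouts.

Formats: per-session ECG CSV (time_s, ecg_mV, gap), a JSON metadata
sidecar, an annotation-style text layout (a small header file, the signal
CSV and a beat-annotation text file of sample indices), RR CSV
(beat_time_s, rr_ms, quality), the cohort manifest CSV and the features
CSV.  Everything is text so sessions diff and version cleanly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import EcgRecord, RRSeries
from .synthetic import NoiseSpec, SessionSpec


def write_session_csv(record: EcgRecord, path: Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": record.times,
            "ecg_mV": record.samples,
            "gap": record.gap_mask.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_session_csv(path: Path, sampling_rate: Optional[float] = None) -> EcgRecord:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    fs = sampling_rate or (1.0 / float(np.median(np.diff(t))))
    return EcgRecord(
        samples=df["ecg_mV"].to_numpy(dtype=float),
        sampling_rate=round(fs, 6),
        start_time=float(t[0]),
        gap_mask=df["gap"].to_numpy(dtype=bool),
    )


def write_sidecar(spec: SessionSpec, path: Path) -> None:
    payload = dataclasses.asdict(spec)
    payload["noise_profile"] = dataclasses.asdict(spec.noise_profile)
    path.write_text(json.dumps(payload, indent=2))


def read_sidecar(path: Path) -> SessionSpec:
    payload = json.loads(path.read_text())
    payload["noise_profile"] = NoiseSpec(**payload["noise_profile"])
    return SessionSpec(**payload)


def write_annotated_signal(record: EcgRecord, stem: Path) -> None:
    """Annotation-style text layout: <stem>.hea, <stem>.csv, <stem>.ann.

    The header carries record name, sampling rate and length; the
    annotation file lists one beat per line as ``sample_index N`` (ground
    truth for synthetic records, detections otherwise).
    """
    stem = Path(stem)
    stem.with_suffix(".hea").write_text(
        f"{stem.name} 1 {record.sampling_rate:g} {record.samples.size}\n"
        f"{stem.name}.csv mV\n"
    )
    write_session_csv(record, stem.with_suffix(".csv"))
    if record.true_beat_times is not None:
        idx = np.round(
            (record.true_beat_times - record.start_time) * record.sampling_rate
        ).astype(int)
        lines = "\n".join(f"{i} N" for i in idx)
        stem.with_suffix(".ann").write_text(lines + "\n")


def read_annotations(path: Path, sampling_rate: float, start_time: float = 0.0) -> np.ndarray:
    """Beat times (s) from an annotation text file."""
    idx = [int(line.split()[0]) for line in Path(path).read_text().split("\n") if line.strip()]
    return start_time + np.asarray(idx, dtype=float) / sampling_rate


def write_rr_csv(rr: RRSeries, path: Path) -> None:
    df = pd.DataFrame(
        {
            "beat_time_s": rr.beat_times[1:],
            "rr_ms": rr.rr_ms,
            "quality": rr.quality,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_rr_csv(path: Path) -> RRSeries:
    df = pd.read_csv(path)
    end_times = df["beat_time_s"].to_numpy(dtype=float)
    rr_ms = df["rr_ms"].to_numpy(dtype=float)
    first = end_times[0] - rr_ms[0] / 1000.0
    return RRSeries(
        beat_times=np.concatenate(([first], end_times)),
        rr_ms=rr_ms,
        quality=df["quality"].to_numpy(dtype=object),
    )


def write_cohort(
    records: Sequence[EcgRecord], out_dir: Path, manifest_name: str = "manifest.csv"
) -> pd.DataFrame:
    """Write a cohort of sessions (CSV + sidecar + annotations) and its manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        sid = f"session_{i:04d}"
        write_annotated_signal(rec, out_dir / sid)
        if rec.meta is not None:
            write_sidecar(rec.meta, out_dir / f"{sid}.json")
            rows.append(
                {
                    "session_id": sid,
                    "subject_id": rec.meta.subject_id,
                    "sex": rec.meta.sex,
                    "type": rec.meta.session_type,
                    "duration_min": rec.meta.duration_min,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / manifest_name, index=False)
    return manifest
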