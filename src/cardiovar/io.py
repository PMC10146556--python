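"""CSV readers and writers for beat-aligned recordings.

Canonical dialect: header ``beat_index,time_s,rr_ms,sap_mmhg,resp``, one
row per beat, UTF-8, "." decimal separator.  A reduced two-column dialect
``rr_ms,sap_mmhg`` (respiration unavailable) is also accepted; trivariate
indices are then reported missing downstream.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CONDITIONS, ParameterError, SubjectRecording

CANONICAL_COLUMNS = ["beat_index", "time_s", "rr_ms", "sap_mmhg", "resp"]


def write_recording_csv(recording: SubjectRecording, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "beat_index": np.arange(recording.n_beats),
        "time_s": recording.beat_times,
        "rr_ms": recording.rr,
        "sap_mmhg": recording.sap,
        "resp": recording.resp if recording.resp is not None else np.nan,
    })
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_recording_csv(path, condition_label: str | None = None,
                       subject_id: str | None = None) -> SubjectRecording:
    path = Path(path)
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"rr_ms", "sap_mmhg"} - cols:
        raise ParameterError(
            f"{path.name}: expected at least columns rr_ms,sap_mmhg, got {sorted(cols)}")
    rr = df["rr_ms"].to_numpy(dtype=float)
    sap = df["sap_mmhg"].to_numpy(dtype=float)
    resp = None
    if "resp" in cols and df["resp"].notna().all():
        resp = df["resp"].to_numpy(dtype=float)
    if "time_s" in cols:
        times = df["time_s"].to_numpy(dtype=float)
    else:
        times = np.concatenate(([0.0], np.cumsum(rr[:-1]) / 1000.0))
    if condition_label is None or subject_id is None:
        sid, cond = parse_recording_name(path.stem)
        subject_id = subject_id or sid
        condition_label = condition_label or cond
    return SubjectRecording(rr=rr, sap=sap, resp=resp, beat_times=times,
                            condition_label=condition_label,
                            subject_id=subject_id)


def parse_recording_name(stem: str) -> tuple[str | None, str | None]:
    """Infer (subject_id, condition) from ``<subject>_<condition>`` stems."""
    for cond in CONDITIONS:
        if stem.endswith(cond):
            subject = stem[: -len(cond)].rstrip("_") or None
            return subject, cond
    return stem or None, None
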