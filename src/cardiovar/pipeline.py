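"""End-to-end composition: recording -> autonomic profile row -> group table.

``analyze_recording`` chains preprocessing, spectral decomposition and the
baroreflex indices for one recording, producing one row of named autonomic
variables with missing values explicitly encoded as NaN and a structured
log of every gate decision (artefact rejection, respiratory entrainment,
coherence, component classification).  ``run_study`` maps it over a
directory of recordings and feeds the rank-based group comparison.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .baroreflex import BaroreflexAnalyzer, CoherenceError, brs_sequence
from .config import PipelineConfig
from .datatypes import (
    ClassificationError,
    CleanRecording,
    DesignError,
    IdentificationError,
    ParameterError,
    RecordingQualityError,
    SpectralFitError,
    SubjectRecording,
)
from .io import read_recording_csv
from .preprocess import validate_beats
from .spectral import ARSpectrumAnalyzer

log = logging.getLogger(__name__)

#: Output row variables, in report order.
VARIABLES = [
    "HR", "RR Mean", "RR V", "RR LFa", "RR HFa", "RR LFnu", "RR HFnu",
    "RR LF/HF", "RR LFHz", "RR HFHz", "RESP Hz",
    "SAP Mean", "SAP V", "SAP LFa", "SAP HFa",
    "Alpha Index M", "BRS", "A.XAR", "A.XXAR", "Alpha Index CP",
    "n_sequences",
]

#: Variables entering the group comparison (counts and raw means excluded).
GROUP_VARIABLES = [v for v in VARIABLES if v not in ("n_sequences", "RR Mean", "SAP Mean")]


@dataclass
class AnalysisResult:
    subject_id: str | None
    condition_label: str | None
    row: dict
    gate_log: list = field(default_factory=list)
    clean: CleanRecording | None = None


def _empty_row() -> dict:
    return {v: math.nan for v in VARIABLES}


def _resp_proxy_freq(decomp) -> float:
    """Respiration proxy when the respiration trace is absent: the
    largest RR component in the 0.15-0.45 Hz band."""
    cands = [c for c in decomp.components if 0.15 <= c.center_freq_hz <= 0.45]
    if not cands:
        return math.nan
    return max(cands, key=lambda c: c.power_abs).center_freq_hz


def analyze_recording(source, config: PipelineConfig | None = None) -> AnalysisResult:
    """Compute every autonomic variable for one recording.

    ``source`` is a CSV path or a :class:`SubjectRecording`.  Gate failures
    (entrainment, missing LF/HF component, sub-threshold coherence) leave
    the affected fields NaN and are logged; a recording with too many
    artefacts raises :class:`RecordingQualityError`.
    """
    config = config or PipelineConfig()
    rec = source if isinstance(source, SubjectRecording) else read_recording_csv(source)
    gates: list[dict] = []

    clean = validate_beats(rec, entrainment_threshold_hz=config.entrainment_threshold_hz)
    if clean.n_rejected:
        gates.append(dict(gate="artefact", decision="interpolated",
                          detail=f"{clean.n_rejected} beats interpolated"))

    row = _empty_row()
    row["RR Mean"] = clean.rr_mean
    row["HR"] = 60000.0 / clean.rr_mean
    row["SAP Mean"] = clean.sap_mean
    row["RESP Hz"] = clean.resp_freq_hz
    row["RR V"] = float(np.var(clean.rr_centered))
    row["SAP V"] = float(np.var(clean.sap_centered))

    brs, n_seq = brs_sequence(
        clean.rr, clean.sap, min_beats=config.brs_min_beats,
        min_sap_step=config.brs_min_sap_step, min_rr_step=config.brs_min_rr_step,
        min_correlation=config.brs_min_correlation, lag=config.brs_lag)
    row["BRS"] = brs
    row["n_sequences"] = n_seq
    if n_seq < 3:
        gates.append(dict(gate="brs_support", decision="missing",
                          detail=f"only {n_seq} sequences"))

    if clean.entrained:
        gates.append(dict(
            gate="entrainment", decision="withheld",
            detail=f"respiration {clean.resp_freq_hz:.3f} Hz below "
                   f"{config.entrainment_threshold_hz} Hz; LF and HF merge"))
        return AnalysisResult(rec.subject_id, rec.condition_label, row, gates, clean)

    if clean.resp is None and math.isnan(clean.resp_freq_hz):
        dt = clean.mean_interval_s
        probe = ARSpectrumAnalyzer(
            order=config.ar_order, order_range=config.ar_order_range,
            method=config.ar_method).fit(clean.rr_centered, sampling_interval_s=dt)
        clean.resp_freq_hz = _resp_proxy_freq(probe.decomposition_)
        gates.append(dict(gate="respiration", decision="proxy",
                          detail=f"no respiration trace; HF tied to RR band "
                                 f"component at {clean.resp_freq_hz:.3f} Hz"))
        if clean.resp_freq_hz < config.entrainment_threshold_hz:
            gates.append(dict(gate="entrainment", decision="withheld",
                              detail="proxy respiration frequency below threshold"))
            return AnalysisResult(rec.subject_id, rec.condition_label, row, gates, clean)

    try:
        ba = BaroreflexAnalyzer(
            order=config.ar_order, order_range=config.ar_order_range,
            method=config.ar_method,
            coherence_threshold=config.coherence_threshold).fit(clean)
    except (ClassificationError, SpectralFitError, CoherenceError,
            IdentificationError, ParameterError) as exc:
        gates.append(dict(gate="spectral", decision="missing", detail=str(exc)))
        return AnalysisResult(rec.subject_id, rec.condition_label, row, gates, clean)

    rrd = ba.rr_spectrum_.decomposition_
    sapd = ba.sap_spectrum_.decomposition_
    rr_lf, rr_hf = rrd.component("LF"), rrd.component("HF")
    sap_lf, sap_hf = sapd.component("LF"), sapd.component("HF")
    row["RR LFa"] = rr_lf.power_abs
    row["RR HFa"] = rr_hf.power_abs
    row["RR LFnu"] = rr_lf.power_nu
    row["RR HFnu"] = rr_hf.power_nu
    row["RR LF/HF"] = rrd.lf_hf_ratio
    row["RR LFHz"] = rr_lf.center_freq_hz
    row["RR HFHz"] = rr_hf.center_freq_hz
    row["SAP LFa"] = sap_lf.power_abs
    row["SAP HFa"] = sap_hf.power_abs

    noise_frac = rrd.power("NOISE") / rrd.total_power if rrd.total_power else 0.0
    gates.append(dict(gate="noise_components", decision="disregarded",
                      detail=f"{noise_frac:.1%} of RR power in noise components"))

    idx = ba.indices_
    row["Alpha Index M"] = idx.alpha_m
    row["A.XAR"] = idx.a_xar
    row["A.XXAR"] = idx.a_xxar
    row["Alpha Index CP"] = idx.alpha_cp
    k2 = ba.coherence_
    gates.append(dict(
        gate="coherence",
        decision="passed" if not math.isnan(idx.alpha_m) else "alpha_m withheld",
        detail=f"k2_lf={k2.k2_lf:.3f}, k2_hf={k2.k2_hf:.3f} "
               f"(threshold {config.coherence_threshold})"))
    return AnalysisResult(rec.subject_id, rec.condition_label, row, gates, clean)


@dataclass
class StudyReport:
    recordings: pd.DataFrame          # one row per (subject, condition)
    group_table: pd.DataFrame         # descriptives + omnibus p + letters
    gate_log: dict                    # per recording
    config_digest: str


def run_study(directory, config: PipelineConfig | None = None,
              out_dir=None) -> StudyReport:
    """Analyze every recording CSV in ``directory`` and compare conditions.

    Requires at least 3 subjects observed in at least 2 conditions.
    Recordings that fail quality control are excluded and logged.  When
    ``out_dir`` is given, writes ``recordings.csv``, ``group_table.csv``,
    ``group_table.json`` and ``gates.json`` (deterministic byte content
    for a fixed input set and configuration).
    """
    from .stats import descriptive_table

    config = config or PipelineConfig()
    directory = Path(directory)
    files = sorted(directory.glob("*.csv"))
    if not files:
        raise DesignError(f"no recording CSVs found in {directory}")

    results: list[AnalysisResult] = []
    gate_log: dict[str, list] = {}
    for f in files:
        try:
            res = analyze_recording(f, config)
        except (RecordingQualityError, ParameterError) as exc:
            log.warning("recording %s rejected: %s", f.name, exc)
            gate_log[f.stem] = [dict(gate="quality", decision="rejected",
                                     detail=str(exc))]
            continue
        key = f"{res.subject_id}_{res.condition_label}" if res.subject_id else f.stem
        gate_log[key] = res.gate_log
        results.append(res)

    if not results:
        raise DesignError("no analyzable recordings")
    rows = pd.DataFrame(
        [dict(subject=r.subject_id, condition=r.condition_label, **r.row)
         for r in results])
    n_subj = rows["subject"].nunique()
    n_cond = rows.groupby("subject")["condition"].nunique()
    if n_subj < 3 or (n_cond >= 2).sum() < 3:
        raise DesignError(
            f"study design too small ({n_subj} subjects); need >= 3 subjects "
            "in >= 2 conditions")

    long = rows.melt(id_vars=["subject", "condition"],
                     value_vars=GROUP_VARIABLES, var_name="variable")
    table = descriptive_table(long, alpha=config.significance_level,
                              holm=config.holm_adjust)
    table = table.loc[[v for v in GROUP_VARIABLES if v in table.index]]

    report = StudyReport(recordings=rows.set_index(["subject", "condition"]).sort_index(),
                         group_table=table, gate_log=gate_log,
                         config_digest=config.digest())
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: StudyReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"# config_digest={report.config_digest}\n"
    for name, df in (("recordings.csv", report.recordings),
                     ("group_table.csv", report.group_table)):
        with open(out_dir / name, "w", encoding="utf-8", newline="") as fh:
            fh.write(header)
            df.to_csv(fh, float_format="%.6g", lineterminator="\n")
    payload = {
        "config_digest": report.config_digest,
        "group_table": json.loads(
            report.group_table.to_json(orient="index", double_precision=6)),
    }
    (out_dir / "group_table.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n")
    (out_dir / "gates.json").write_text(
        json.dumps({"config_digest": report.config_digest,
                    "gates": report.gate_log}, indent=2, sort_keys=True) + "\n")
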