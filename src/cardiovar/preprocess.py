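"""Beat-series validation, artefact handling, and admissibility gates.

Short-term variability analysis assumes an artefact-free sinus tachogram.
This module flags physiologically implausible beats (outside 300-2000 ms,
or jumping more than 30% from the previous interval), interpolates isolated
artefacts, rejects recordings with more than 5% flagged beats, detrends the
series for autoregressive fitting, and evaluates the respiratory-entrainment
gate: when spontaneous breathing falls below 0.12 Hz the LF and HF
oscillations merge into a single rhythm around 0.1 Hz and the spectral
decomposition is no longer interpretable.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.signal import detrend

from .datatypes import (
    RR_BOUNDS_MS,
    CleanRecording,
    RecordingQualityError,
    SubjectRecording,
)

__all__ = [
    "validate_beats",
    "detect_entrainment",
    "center_series",
    "flag_artefacts",
    "ENTRAINMENT_THRESHOLD_HZ",
]

ENTRAINMENT_THRESHOLD_HZ = 0.12
JUMP_FRACTION = 0.30
MAX_REJECT_FRACTION = 0.05


def flag_artefacts(rr: np.ndarray,
                   rr_bounds: tuple[float, float] = RR_BOUNDS_MS,
                   jump_fraction: float = JUMP_FRACTION) -> np.ndarray:
    """Boolean mask of implausible beats (range rule plus 30% jump rule)."""
    rr = np.asarray(rr, dtype=float)
    bad = (rr < rr_bounds[0]) | (rr > rr_bounds[1])
    jump = np.zeros_like(bad)
    jump[1:] = np.abs(np.diff(rr)) > jump_fraction * rr[:-1]
    # a jump out of an already-flagged beat is attributed to that beat only
    jump[1:] &= ~bad[:-1]
    return bad | jump


def _interpolate(series: np.ndarray, bad: np.ndarray) -> np.ndarray:
    out = np.array(series, dtype=float)
    good = ~bad
    idx = np.arange(len(series))
    out[bad] = np.interp(idx[bad], idx[good], series[good])
    return out


def validate_beats(recording: SubjectRecording,
                   max_reject_fraction: float = MAX_REJECT_FRACTION,
                   entrainment_threshold_hz: float = ENTRAINMENT_THRESHOLD_HZ,
                   ) -> CleanRecording:
    """Validate a recording and interpolate flagged beats.

    Raises
    ------
    RecordingQualityError
        If more than ``max_reject_fraction`` of beats are flagged; such a
        recording is considered uninterpretable and is discarded.
    """
    bad = flag_artefacts(recording.rr)
    n_rejected = int(bad.sum())
    if n_rejected > max_reject_fraction * recording.n_beats:
        raise RecordingQualityError(
            f"{n_rejected}/{recording.n_beats} beats flagged "
            f"(> {max_reject_fraction:.0%}); recording rejected")
    if bad.all() or (~bad).sum() < 2:
        raise RecordingQualityError("not enough valid beats to interpolate")

    rr = _interpolate(recording.rr, bad) if n_rejected else np.array(recording.rr)
    sap = _interpolate(recording.sap, bad) if n_rejected else np.array(recording.sap)
    # onset convention (matching the generator): beat k starts interval rr[k]
    beat_times = recording.beat_times[0] + np.concatenate(
        ([0.0], np.cumsum(rr[:-1]) / 1000.0))

    resp_freq = math.nan
    if recording.resp is not None:
        resp_freq = respiratory_frequency(recording.resp, np.mean(rr) / 1000.0)

    clean = CleanRecording(
        rr=rr, sap=sap,
        resp=None if recording.resp is None else np.array(recording.resp),
        beat_times=beat_times,
        condition_label=recording.condition_label,
        subject_id=recording.subject_id,
        n_rejected=n_rejected,
        entrained=detect_entrainment(resp_freq, entrainment_threshold_hz),
        resp_freq_hz=resp_freq,
        rr_mean=float(np.mean(rr)),
        sap_mean=float(np.mean(sap)),
    )
    return center_series(clean)


def detect_entrainment(resp_freq_hz: float,
                       threshold_hz: float = ENTRAINMENT_THRESHOLD_HZ) -> bool:
    """True iff breathing is slow enough to merge the LF and HF rhythms.

    The threshold is strict: a respiratory rate of exactly 0.12 Hz is not
    entrained.  NaN (respiration unavailable) is treated as non-entrained;
    trivariate indices are withheld separately in that case.
    """
    if math.isnan(resp_freq_hz):
        return False
    return resp_freq_hz < threshold_hz


def center_series(clean: CleanRecording) -> CleanRecording:
    """Remove the linear trend from RR and SAP (and the mean of respiration).

    The reported RR/SAP means are taken from the cleaned, un-detrended
    series; the centered versions exist only for spectral fitting.
    """
    clean.rr_mean = float(np.mean(clean.rr))
    clean.sap_mean = float(np.mean(clean.sap))
    clean.rr_centered = detrend(clean.rr, type="linear")
    clean.sap_centered = detrend(clean.sap, type="linear")
    if clean.resp is not None:
        clean.resp_centered = clean.resp - np.mean(clean.resp)
    return clean


def respiratory_frequency(resp: np.ndarray, dt_s: float) -> float:
    """Center frequency of the dominant respiratory oscillation (Hz).

    Taken from the respiration series' own AR spectrum: the highest-power
    component above 0.03 Hz (excluding the very-low-frequency mass).
    """
    from .spectral import fit_ar, decompose_spectrum  # local: avoids cycle

    resp = np.asarray(resp, dtype=float)
    x = resp - resp.mean()
    if np.allclose(x, 0.0):
        return math.nan
    model = fit_ar(x, dt_s)
    decomp = decompose_spectrum(model, float(np.var(x)))
    cands = [c for c in decomp.components if c.center_freq_hz >= 0.03]
    if not cands:
        return math.nan
    return max(cands, key=lambda c: c.power_abs).center_freq_hz
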