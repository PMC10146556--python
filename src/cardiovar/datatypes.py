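"""Core containers for beat-to-beat cardiovascular variability analysis.

All series are beat-aligned: element *k* of the tachogram (RR, ms), the
systogram (SAP, mmHg) and the respiration trace refer to the same heart
beat.  Frequencies are in Hz on the beat-domain axis obtained by using the
mean RR interval as the sampling step.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

CONDITIONS = (
    "ambulatory_normoxia",
    "ambulatory_hypoxia",
    "bedrest_normoxia",
    "bedrest_hypoxia",
)

#: Table-2-style contrast letters -> (condition A, condition B)
CONTRAST_PAIRS = {
    "a": ("ambulatory_normoxia", "ambulatory_hypoxia"),
    "b": ("ambulatory_normoxia", "bedrest_normoxia"),
    "c": ("ambulatory_normoxia", "bedrest_hypoxia"),
    "d": ("ambulatory_hypoxia", "bedrest_normoxia"),
    "e": ("ambulatory_hypoxia", "bedrest_hypoxia"),
    "f": ("bedrest_normoxia", "bedrest_hypoxia"),
}

MIN_BEATS = 64
RR_BOUNDS_MS = (300.0, 2000.0)


class CardiovarError(Exception):
    """Base class for pipeline errors."""


class ParameterError(CardiovarError, ValueError):
    """Invalid generator or configuration parameters."""


class RecordingQualityError(CardiovarError):
    """Too many artefactual beats: the recording is not analyzable."""


class SpectralFitError(CardiovarError):
    """No stable autoregressive model could be fitted."""


class ClassificationError(CardiovarError):
    """No LF or HF candidate component; spectral indices are missing."""


class IdentificationError(CardiovarError):
    """Collinear regressors in closed-loop model identification."""


class DesignError(CardiovarError):
    """Study design too small for the group model."""


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth parameters of the linear beat-domain generator.

    The generator superposes a Mayer-wave (LF) oscillation and a
    respiratory (HF) oscillation on systolic pressure, and drives RR both
    through an arterial-baroreflex pathway (``gain_arterial``, ms/mmHg,
    acting on SAP delayed by ``delay_beats``) and through a direct
    respiratory pathway (``gain_cp``, ms per unit respiration).
    """

    mean_rr: float = 985.24          # ms
    mean_sap: float = 117.55         # mmHg
    f_lf: float = 0.10               # Hz, Mayer-wave frequency
    f_resp: float = 0.26             # Hz, respiratory frequency
    a_lf_sap: float = 3.0            # mmHg, LF SAP amplitude
    a_hf_sap: float = 1.5            # mmHg, respiratory SAP amplitude
    gain_arterial: float = 14.0      # ms/mmHg, SAP->RR baroreflex gain
    gain_cp: float = 30.0            # ms per unit respiration
    delay_beats: int = 1             # baroreflex latency in beats
    sigma_rr: float = 10.0           # ms, additive white RR noise SD
    sigma_sap: float = 2.0           # mmHg, additive white SAP noise SD
    n_beats: int = 600
    seed: int = 0

    def validate(self) -> "GeneratorParams":
        if not (RR_BOUNDS_MS[0] <= self.mean_rr <= RR_BOUNDS_MS[1]):
            raise ParameterError(f"mean_rr {self.mean_rr} outside {RR_BOUNDS_MS} ms")
        if self.f_lf <= 0 or self.f_resp <= 0:
            raise ParameterError("oscillation frequencies must be positive")
        if not self.f_lf < 0.12:
            raise ParameterError("f_lf must lie below 0.12 Hz")
        if self.f_resp >= 0.5:
            raise ParameterError("f_resp must lie below 0.5 Hz")
        for name in ("a_lf_sap", "a_hf_sap", "sigma_rr", "sigma_sap"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.delay_beats < 0 or int(self.delay_beats) != self.delay_beats:
            raise ParameterError("delay_beats must be a non-negative integer")
        if self.n_beats < MIN_BEATS:
            raise ParameterError(f"n_beats must be >= {MIN_BEATS}")
        return self

    replace = replace


@dataclass
class SubjectRecording:
    """Beat-aligned RR/SAP/respiration series for one subject and condition."""

    rr: np.ndarray                   # ms
    sap: np.ndarray                  # mmHg
    resp: np.ndarray | None          # dimensionless, sampled at beat times
    beat_times: np.ndarray           # cumulative seconds
    condition_label: str | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.rr = np.asarray(self.rr, dtype=float)
        self.sap = np.asarray(self.sap, dtype=float)
        if self.resp is not None:
            self.resp = np.asarray(self.resp, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        n = len(self.rr)
        if n < MIN_BEATS:
            raise ParameterError(f"recording must contain >= {MIN_BEATS} beats")
        if len(self.sap) != n or len(self.beat_times) != n:
            raise ParameterError("rr, sap and beat_times must have equal length")
        if self.resp is not None and len(self.resp) != n:
            raise ParameterError("resp must match rr length")

    @property
    def n_beats(self) -> int:
        return len(self.rr)

    @property
    def mean_interval_s(self) -> float:
        """Mean beat interval in seconds (beat-domain sampling step)."""
        return float(np.mean(self.rr)) / 1000.0


@dataclass
class CleanRecording(SubjectRecording):
    """A validated recording, with artefacts interpolated and gates evaluated."""

    n_rejected: int = 0
    entrained: bool = False
    resp_freq_hz: float = math.nan
    rr_mean: float = math.nan        # mean of the cleaned, un-detrended series
    sap_mean: float = math.nan
    rr_centered: np.ndarray | None = None   # detrended, for spectral analysis
    sap_centered: np.ndarray | None = None
    resp_centered: np.ndarray | None = None


@dataclass
class ARModel:
    """A stable autoregressive model of one beat series."""

    order: int
    coefficients: np.ndarray         # a_1..a_p in x_t = sum a_i x_{t-i} + e_t
    residual_variance: float
    sampling_interval_s: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not (6 <= self.order <= 20):
            raise ParameterError("AR order must lie in [6, 20]")


@dataclass
class SpectralComponent:
    center_freq_hz: float
    power_abs: float                 # ms^2 (RR) or mmHg^2 (SAP)
    power_nu: float = math.nan       # 0-100, defined for LF/HF only
    label: str | None = None         # VLF | LF | HF | NOISE


@dataclass
class SpectrumDecomposition:
    components: list[SpectralComponent]
    total_power: float               # = series sample variance
    lf_hf_ratio: float = math.nan

    def by_label(self, label: str) -> list[SpectralComponent]:
        return [c for c in self.components if c.label == label]

    def power(self, label: str) -> float:
        return float(sum(c.power_abs for c in self.by_label(label)))

    def component(self, label: str) -> SpectralComponent | None:
        cs = self.by_label(label)
        return max(cs, key=lambda c: c.power_abs) if cs else None


@dataclass
class CoherenceProfile:
    freq_grid: np.ndarray
    coherence: np.ndarray            # magnitude-squared coherence, 0..1
    k2_lf: float = math.nan          # coherence at the LF center frequency
    k2_hf: float = math.nan


@dataclass
class BaroreflexIndices:
    """Baroreflex gains for one recording (ms/mmHg; NaN encodes missing)."""

    alpha_m: float = math.nan
    brs: float = math.nan
    a_xar: float = math.nan
    a_xxar: float = math.nan
    alpha_cp: float = math.nan
    n_sequences: int = 0
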