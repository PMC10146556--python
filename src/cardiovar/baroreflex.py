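"""Baroreflex gain indices from coupled RR / SAP / respiration variability.

Five estimators of the ms/mmHg coupling between systolic pressure and RR:

* ``alpha_index_m`` — frequency-domain alpha index: mean of the square-root
  RR/SAP power ratios of the LF and HF components, valid only where the
  RR-SAP magnitude-squared coherence exceeds 0.5 at both frequencies.
* ``brs_sequence`` — time-domain baroreflex slope from spontaneous
  concordant ramps of SAP and (lag-1) RR.
* ``fit_trivariate`` — closed-loop causal identification: RR regressed on
  its own past and on present/past SAP gives the bivariate causal gain
  A.XAR; adding present/past respiration as an exogenous regressor partials
  the respiratory drive out of the SAP->RR transfer (A.XXAR, "avoiding
  respiration bias") and yields the respiration->RR transfer from which the
  cardiopulmonary alpha index (Alpha CP) is scaled to ms/mmHg.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.tsa.api import VAR

from .datatypes import (
    BaroreflexIndices,
    CardiovarError,
    CleanRecording,
    CoherenceProfile,
    IdentificationError,
    ParameterError,
)
from .spectral import ARSpectrumAnalyzer

__all__ = [
    "BaroreflexAnalyzer",
    "cross_coherence",
    "alpha_index_m",
    "brs_sequence",
    "fit_trivariate",
    "CoherenceError",
]

COHERENCE_THRESHOLD = 0.5
BRS_MIN_SEQ_BEATS = 3
BRS_MIN_SAP_STEP = 1.0      # mmHg per beat
BRS_MIN_RR_STEP = 4.0       # ms per beat
BRS_MIN_CORRELATION = 0.85
BRS_RR_LAG = 1
BRS_MIN_SEQUENCES = 3


class CoherenceError(CardiovarError):
    """Singular covariance in the bivariate coherence model."""


def _var_spectral_matrix(coefs: np.ndarray, sigma_u: np.ndarray, dt: float,
                         freqs: np.ndarray) -> np.ndarray:
    """Spectral density matrix of a VAR model at the given frequencies."""
    p, neq, _ = coefs.shape
    out = np.empty((len(freqs), neq, neq), dtype=complex)
    eye = np.eye(neq)
    for i, f in enumerate(freqs):
        a = eye - sum(coefs[m] * np.exp(-2j * np.pi * f * (m + 1) * dt)
                      for m in range(p))
        h = np.linalg.inv(a)
        out[i] = h @ sigma_u @ h.conj().T * dt
    return out


def cross_coherence(rr: np.ndarray, sap: np.ndarray, sampling_interval_s: float,
                    order: int = 8, f_lf: float = math.nan,
                    f_hf: float = math.nan, n_grid: int = 256) -> CoherenceProfile:
    """Magnitude-squared coherence between RR and SAP from a bivariate AR model.

    ``k2_lf`` / ``k2_hf`` are evaluated exactly at the supplied LF/HF center
    frequencies (NaN if not given).
    """
    rr = np.asarray(rr, dtype=float)
    sap = np.asarray(sap, dtype=float)
    if rr.shape != sap.shape:
        raise ParameterError("rr and sap must have equal length")
    data = np.column_stack([rr, sap])
    try:
        res = VAR(data).fit(maxlags=order, ic=None, trend="n")
        sigma_u = np.asarray(res.sigma_u)
        if not np.all(np.isfinite(sigma_u)) or np.linalg.det(sigma_u) <= 0:
            raise CoherenceError("singular residual covariance")
        coefs = np.asarray(res.coefs)
    except np.linalg.LinAlgError as exc:
        raise CoherenceError(f"bivariate model failed: {exc}") from None

    f_nyq = 1.0 / (2.0 * sampling_interval_s)
    grid = np.linspace(0.0, f_nyq, n_grid + 1)[1:]
    extra = [f for f in (f_lf, f_hf) if not math.isnan(f)]
    s = _var_spectral_matrix(coefs, sigma_u, sampling_interval_s,
                             np.concatenate([grid, extra]))
    k2 = np.abs(s[:, 0, 1]) ** 2 / (s[:, 0, 0].real * s[:, 1, 1].real)
    k2 = np.clip(k2.real, 0.0, 1.0)
    prof = CoherenceProfile(freq_grid=grid, coherence=k2[:len(grid)])
    tail = list(k2[len(grid):])
    if not math.isnan(f_lf):
        prof.k2_lf = float(tail.pop(0))
    if not math.isnan(f_hf):
        prof.k2_hf = float(tail.pop(0))
    return prof


def alpha_index_m(lf_rr: float, lf_sap: float, hf_rr: float, hf_sap: float,
                  k2: CoherenceProfile | None = None,
                  coherence_threshold: float = COHERENCE_THRESHOLD) -> float:
    """Frequency-domain alpha index (ms/mmHg), coherence-gated.

    alpha_M = [sqrt(LF_RR / LF_SAP) + sqrt(HF_RR / HF_SAP)] / 2,
    returned only when the RR-SAP coherence exceeds the threshold at both
    the LF and HF center frequencies; NaN (missing) otherwise.
    """
    for name, v in (("lf_rr", lf_rr), ("lf_sap", lf_sap),
                    ("hf_rr", hf_rr), ("hf_sap", hf_sap)):
        if not v > 0:
            raise ParameterError(f"{name} must be positive, got {v}")
    if k2 is not None:
        if not (k2.k2_lf > coherence_threshold and k2.k2_hf > coherence_threshold):
            return math.nan
    return 0.5 * (math.sqrt(lf_rr / lf_sap) + math.sqrt(hf_rr / hf_sap))


def brs_sequence(rr: np.ndarray, sap: np.ndarray,
                 min_beats: int = BRS_MIN_SEQ_BEATS,
                 min_sap_step: float = BRS_MIN_SAP_STEP,
                 min_rr_step: float = BRS_MIN_RR_STEP,
                 min_correlation: float = BRS_MIN_CORRELATION,
                 lag: int = BRS_RR_LAG,
                 min_sequences: int = BRS_MIN_SEQUENCES,
                 ) -> tuple[float, int]:
    """Sequence-method baroreflex slope (ms/mmHg) and its sequence count.

    Scans for spontaneous runs of at least ``min_beats`` beats in which SAP
    changes monotonically by >= ``min_sap_step`` mmHg per beat while RR,
    taken ``lag`` beats later, changes concordantly by >= ``min_rr_step``
    ms per beat.  Each run contributes the least-squares slope of RR on SAP
    provided the correlation is >= ``min_correlation``; the BRS is the mean
    slope, NaN if fewer than ``min_sequences`` runs qualify.
    """
    rr = np.asarray(rr, dtype=float)
    sap = np.asarray(sap, dtype=float)
    if len(rr) < 64:
        raise ParameterError("need at least 64 beats")
    n = len(rr) - lag
    dsap = np.diff(sap[:n])
    drr = np.diff(rr[lag:lag + n])
    up = (dsap >= min_sap_step) & (drr >= min_rr_step)
    down = (dsap <= -min_sap_step) & (drr <= -min_rr_step)

    slopes: list[float] = []
    for mask in (up, down):
        k = 0
        while k < len(mask):
            if not mask[k]:
                k += 1
                continue
            j = k
            while j < len(mask) and mask[j]:
                j += 1
            run_len = j - k + 1          # beats spanned by j-k steps
            if run_len >= min_beats:
                x = sap[k:k + run_len]
                y = rr[k + lag:k + lag + run_len]
                fit = stats.linregress(x, y)
                if abs(fit.rvalue) >= min_correlation and fit.slope > 0:
                    slopes.append(fit.slope)
            k = j + 1
    n_seq = len(slopes)
    brs = float(np.mean(slopes)) if n_seq >= min_sequences else math.nan
    return brs, n_seq


def _lagged_design(series: np.ndarray, order: int, start: int,
                   include_zero: bool) -> np.ndarray:
    first = 0 if include_zero else 1
    cols = [series[start - m: len(series) - m] for m in range(first, order + 1)]
    return np.column_stack(cols)


def _transfer(num: np.ndarray, ar: np.ndarray, dt: float, f: float,
              num_from_zero: bool) -> complex:
    w = 2.0 * np.pi * f * dt
    first = 0 if num_from_zero else 1
    b = sum(num[i] * np.exp(-1j * w * (first + i)) for i in range(len(num)))
    a = 1.0 - sum(ar[i] * np.exp(-1j * w * (i + 1)) for i in range(len(ar)))
    return b / a


def fit_trivariate(rr: np.ndarray, sap: np.ndarray, resp: np.ndarray | None,
                   sampling_interval_s: float, f_lf: float, f_hf: float,
                   order: int = 8,
                   sap_hf_power: float = math.nan,
                   resp_hf_power: float = math.nan,
                   ) -> tuple[float, float, float, dict]:
    """Causal SAP->RR and respiration->RR gains from closed-loop regression.

    Returns ``(a_xar, a_xxar, alpha_cp, detail)``:

    * A.XAR — bivariate model (RR on own past + present/past SAP): SAP->RR
      transfer magnitude averaged at the LF and HF center frequencies.
    * A.XXAR — same transfer from the trivariate model with respiration as
      an exogenous regressor; the respiratory drive common to both signals
      no longer inflates the apparent gain at HF.
    * Alpha CP — |respiration->RR transfer at HF| * sqrt(HF resp power /
      HF SAP power): the respiration-mediated RR fluctuation re-expressed
      per mmHg of respiratory SAP fluctuation.

    ``detail`` carries the per-frequency transfer magnitudes.
    """
    rr = np.asarray(rr, dtype=float)
    sap = np.asarray(sap, dtype=float)
    p = order
    y = rr[p:]
    x_rr = _lagged_design(rr, p, p, include_zero=False)
    x_sap = _lagged_design(sap, p, p, include_zero=True)

    def solve(xmat: np.ndarray) -> np.ndarray:
        coef, _, rank, _ = np.linalg.lstsq(xmat, y, rcond=None)
        if rank < xmat.shape[1]:
            raise IdentificationError(
                "collinear regressors in closed-loop identification")
        return coef

    # bivariate causal model
    c2 = solve(np.hstack([x_rr, x_sap]))
    a2, b2 = c2[:p], c2[p:]
    h_lf_2 = abs(_transfer(b2, a2, sampling_interval_s, f_lf, True))
    h_hf_2 = abs(_transfer(b2, a2, sampling_interval_s, f_hf, True))
    a_xar = 0.5 * (h_lf_2 + h_hf_2)

    detail = {"a_xar_lf": h_lf_2, "a_xar_hf": h_hf_2,
              "a_xxar_lf": math.nan, "a_xxar_hf": math.nan,
              "h_resp_hf": math.nan}
    if resp is None:
        return float(a_xar), math.nan, math.nan, detail

    resp = np.asarray(resp, dtype=float)
    x_resp = _lagged_design(resp, p, p, include_zero=True)
    c3 = solve(np.hstack([x_rr, x_sap, x_resp]))
    a3 = c3[:p]
    b3 = c3[p:2 * p + 1]
    g3 = c3[2 * p + 1:]
    h_lf_3 = abs(_transfer(b3, a3, sampling_interval_s, f_lf, True))
    h_hf_3 = abs(_transfer(b3, a3, sampling_interval_s, f_hf, True))
    a_xxar = 0.5 * (h_lf_3 + h_hf_3)
    h_resp = abs(_transfer(g3, a3, sampling_interval_s, f_hf, True))
    detail.update(a_xxar_lf=h_lf_3, a_xxar_hf=h_hf_3, h_resp_hf=h_resp)

    alpha_cp = math.nan
    if sap_hf_power > 0 and resp_hf_power > 0:
        alpha_cp = h_resp * math.sqrt(resp_hf_power / sap_hf_power)
    return float(a_xar), float(a_xxar), float(alpha_cp), detail


class BaroreflexAnalyzer(BaseEstimator):
    """All baroreflex indices for one cleaned recording.

    Orchestrates the RR and SAP spectral decompositions, the coherence
    gate, the alpha index, the sequence BRS and the closed-loop causal
    models.  Fit on a :class:`~cardiovar.datatypes.CleanRecording`.

    Attributes
    ----------
    rr_spectrum_, sap_spectrum_ : ARSpectrumAnalyzer
        Fitted univariate decompositions (labeled, nu-annotated).
    coherence_ : CoherenceProfile
    indices_ : BaroreflexIndices
        alpha_m, brs, a_xar, a_xxar, alpha_cp, n_sequences (NaN = missing).
    """

    def __init__(self, order: int | None = None,
                 order_range: tuple[int, int] = (8, 16),
                 method: str = "burg",
                 coherence_threshold: float = COHERENCE_THRESHOLD):
        self.order = order
        self.order_range = order_range
        self.method = method
        self.coherence_threshold = coherence_threshold

    def fit(self, X: CleanRecording, y=None) -> "BaroreflexAnalyzer":
        clean = X
        if clean.entrained:
            raise ParameterError("entrained recording; spectral gains undefined")
        dt = clean.mean_interval_s
        spec_kw = dict(order=self.order, order_range=self.order_range,
                       method=self.method)
        self.rr_spectrum_ = ARSpectrumAnalyzer(**spec_kw).fit(
            clean.rr_centered, sampling_interval_s=dt,
            resp_freq_hz=clean.resp_freq_hz)
        self.sap_spectrum_ = ARSpectrumAnalyzer(**spec_kw).fit(
            clean.sap_centered, sampling_interval_s=dt,
            resp_freq_hz=clean.resp_freq_hz)

        rr_lf = self.rr_spectrum_.decomposition_.component("LF")
        rr_hf = self.rr_spectrum_.decomposition_.component("HF")
        sap_lf = self.sap_spectrum_.decomposition_.component("LF")
        sap_hf = self.sap_spectrum_.decomposition_.component("HF")
        f_lf = rr_lf.center_freq_hz
        f_hf = rr_hf.center_freq_hz
        causal_order = self.order or self.rr_spectrum_.model_.order

        self.coherence_ = cross_coherence(
            clean.rr_centered, clean.sap_centered, dt,
            order=causal_order, f_lf=f_lf, f_hf=f_hf)

        alpha_m = alpha_index_m(rr_lf.power_abs, sap_lf.power_abs,
                                rr_hf.power_abs, sap_hf.power_abs,
                                self.coherence_,
                                coherence_threshold=self.coherence_threshold)
        brs, n_seq = brs_sequence(clean.rr, clean.sap)

        resp_hf_power = math.nan
        if clean.resp_centered is not None:
            resp_spec = ARSpectrumAnalyzer(**spec_kw).fit(
                clean.resp_centered, sampling_interval_s=dt)
            cands = [c for c in resp_spec.decomposition_.components
                     if abs(c.center_freq_hz - clean.resp_freq_hz) <= 0.05]
            if cands:
                resp_hf_power = max(c.power_abs for c in cands)
        a_xar, a_xxar, alpha_cp, self.transfer_detail_ = fit_trivariate(
            clean.rr_centered, clean.sap_centered, clean.resp_centered,
            dt, f_lf, f_hf, order=causal_order,
            sap_hf_power=sap_hf.power_abs, resp_hf_power=resp_hf_power)

        self.indices_ = BaroreflexIndices(
            alpha_m=alpha_m, brs=brs, a_xar=a_xar, a_xxar=a_xxar,
            alpha_cp=alpha_cp, n_sequences=n_seq)
        return self
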