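"""Autoregressive spectral decomposition of beat series.

A beat series (tachogram or systogram) is modelled as an AR(p) process on
the beat axis, mapped to Hz through the mean beat interval.  The power
spectral density of a stable AR model factors over its characteristic
roots; each complex-conjugate pole pair contributes one oscillatory
component whose center frequency is the pole angle and whose absolute power
follows from the residues of the autocovariance generating function:

    gamma_k = sigma2 * p_k^(p-1) / ( prod_{j!=k}(p_k - p_j) * prod_j(1 - p_j p_k) )

Real poles carry the very-low-frequency (~0 Hz) mass.  The residue powers
sum to the model variance; they are rescaled to the sample variance so that
the decomposition conserves total power exactly even for near-deterministic
series, and components closer than the merge tolerance (coincident pole
pairs of an undamped oscillation) are combined.

Typical tachogram spectra then show three major components centred near 0,
0.1 and 0.25 Hz; the classifier labels them VLF, LF (Mayer-wave band) and
HF (synchronous with respiration), and small residual components are
labelled NOISE and disregarded in normalized units.
"""
from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator
from statsmodels.regression.linear_model import burg, yule_walker

from .datatypes import (
    ARModel,
    ClassificationError,
    ParameterError,
    SpectralComponent,
    SpectralFitError,
    SpectrumDecomposition,
)

__all__ = [
    "ARSpectrumAnalyzer",
    "fit_ar",
    "decompose_spectrum",
    "classify_components",
    "normalized_units",
    "ar_psd",
]

DEFAULT_ORDER_RANGE = (8, 16)
VLF_EDGE_HZ = 0.003
LF_UPPER_HZ = 0.14
LF_NOMINAL_HZ = 0.10
HF_HALFWIDTH_HZ = 0.05
NOISE_FRACTION = 0.05
_POLE_CLAMP = 1.0 - 1e-8
_MERGE_HZ = 0.01


def fit_ar(series: np.ndarray, sampling_interval_s: float,
           order: int | None = None,
           order_range: tuple[int, int] = DEFAULT_ORDER_RANGE,
           method: str = "burg") -> ARModel:
    """Fit a stable AR model to a centered beat series.

    The order is chosen by Akaike's criterion over ``order_range`` unless a
    fixed ``order`` is given.  Burg's lattice estimator (default) is
    guaranteed stable up to numerics; Yule-Walker is available as an
    alternative.  Marginally unstable roots (deterministic oscillations)
    are tolerated here and clamped during decomposition.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 64:
        raise ParameterError("series must be 1-D with at least 64 beats")
    if sampling_interval_s <= 0:
        raise ParameterError("sampling_interval_s must be positive")
    n = len(x)

    orders = [order] if order is not None else list(range(order_range[0], order_range[1] + 1))
    best: tuple[float, int, np.ndarray, float] | None = None
    for p in orders:
        try:
            if method == "burg":
                rho, sigma2 = burg(x, order=p, demean=False)
            elif method == "yule_walker":
                rho, sigma2 = yule_walker(x, order=p, method="mle")
                sigma2 = float(sigma2) ** 2
            else:
                raise ParameterError(f"unknown AR method {method!r}")
        except (np.linalg.LinAlgError, ZeroDivisionError):
            continue
        rho = np.asarray(rho, dtype=float)
        if not np.all(np.isfinite(rho)):
            continue
        roots = np.roots(np.r_[1.0, -rho])
        # tolerate marginally-unstable roots (deterministic oscillations sit
        # on the unit circle up to rounding); reject genuinely unstable fits
        if np.abs(roots).max() > 1.0 + 1e-4:
            continue
        aic = n * math.log(max(float(sigma2), 1e-300)) + 2.0 * (p + 1)
        if best is None or aic < best[0]:
            best = (aic, p, rho, max(float(sigma2), 0.0))
    if best is None:
        raise SpectralFitError("no stable AR model found at any candidate order")
    _, p, rho, sigma2 = best
    return ARModel(order=p, coefficients=rho, residual_variance=sigma2,
                   sampling_interval_s=float(sampling_interval_s))


def _residue_powers(roots: np.ndarray, sigma2: float) -> np.ndarray:
    """Residues of the autocovariance generating function at each pole."""
    p = len(roots)
    g = np.empty(p, dtype=complex)
    for k in range(p):
        others = np.delete(roots, k)
        den = np.prod(roots[k] - others) * np.prod(1.0 - roots * roots[k])
        g[k] = sigma2 * roots[k] ** (p - 1) / den
    return g


def decompose_spectrum(model: ARModel, total_variance: float) -> SpectrumDecomposition:
    """Factor an AR spectrum into oscillatory components by the residue method.

    ``total_variance`` is the sample variance of the fitted series; residue
    powers are rescaled to sum to it exactly.  Components are returned
    sorted by center frequency; tiny negative residue powers (a known
    artefact of the partial-fraction decomposition) are clipped to zero.
    """
    if total_variance <= 0.0:
        return SpectrumDecomposition(components=[], total_power=0.0)
    dt = model.sampling_interval_s
    roots = np.roots(np.r_[1.0, -model.coefficients]).astype(complex)
    radius = np.abs(roots)
    roots = np.where(radius > _POLE_CLAMP, roots / radius * _POLE_CLAMP, roots)
    g = _residue_powers(roots, max(model.residual_variance, 1e-300))

    raw: list[tuple[float, float]] = []
    used = np.zeros(len(roots), dtype=bool)
    f_nyquist = 1.0 / (2.0 * dt)
    for k in range(len(roots)):
        if used[k]:
            continue
        if abs(roots[k].imag) < 1e-10:
            used[k] = True
            freq = 0.0 if roots[k].real >= 0 else f_nyquist
            raw.append((freq, float(g[k].real)))
        else:
            dist = np.abs(roots - np.conj(roots[k]))
            dist[used] = np.inf
            dist[k] = np.inf
            j = int(np.argmin(dist))
            used[k] = used[j] = True
            freq = abs(np.angle(roots[k])) / (2.0 * np.pi * dt)
            raw.append((freq, 2.0 * float(g[k].real)))

    total_raw = sum(p for _, p in raw)
    scale = total_variance / total_raw if total_raw > 0 else 0.0
    raw = [(f, max(p * scale, 0.0)) for f, p in raw]
    raw.sort(key=lambda fp: fp[0])

    merged: list[list[float]] = []
    for f, p in raw:
        if merged and f - merged[-1][0] < _MERGE_HZ:
            f0, p0 = merged[-1]
            tot = p0 + p
            merged[-1] = [(f0 * p0 + f * p) / tot if tot > 0 else f0, tot]
        else:
            merged.append([f, p])

    # renormalize after clipping so power is conserved exactly
    tot = sum(p for _, p in merged)
    if tot > 0:
        merged = [[f, p * total_variance / tot] for f, p in merged]

    comps = [SpectralComponent(center_freq_hz=float(f), power_abs=float(p))
             for f, p in merged]
    return SpectrumDecomposition(components=comps, total_power=float(total_variance))


def classify_components(decomp: SpectrumDecomposition, resp_freq_hz: float,
                        noise_fraction: float = NOISE_FRACTION,
                        ) -> SpectrumDecomposition:
    """Label components as VLF, LF, HF or NOISE.

    LF is the largest-power component in [0.003, 0.14) Hz (ties broken by
    proximity to 0.10 Hz); HF the largest-power component within +-0.05 Hz
    of the respiratory frequency and at or above 0.12 Hz (ties broken by
    proximity to respiration); sub-0.003 Hz mass is VLF; everything else is
    NOISE and excluded from normalized units.  Requires a non-entrained
    recording (respiration at or above 0.12 Hz).
    """
    if not (resp_freq_hz >= 0.12):
        raise ParameterError(
            "classification requires a non-entrained recording (resp >= 0.12 Hz)")
    comps = [replace(c, label=None) for c in decomp.components]

    for c in comps:
        if c.center_freq_hz < VLF_EDGE_HZ:
            c.label = "VLF"

    lf_cands = [c for c in comps
                if c.label is None and VLF_EDGE_HZ <= c.center_freq_hz < LF_UPPER_HZ]
    if lf_cands:
        best = max(lf_cands,
                   key=lambda c: (c.power_abs, -abs(c.center_freq_hz - LF_NOMINAL_HZ)))
        best.label = "LF"

    hf_cands = [c for c in comps
                if c.label is None and c.center_freq_hz >= 0.12
                and abs(c.center_freq_hz - resp_freq_hz) <= HF_HALFWIDTH_HZ]
    if hf_cands:
        best = max(hf_cands,
                   key=lambda c: (c.power_abs, -abs(c.center_freq_hz - resp_freq_hz)))
        best.label = "HF"

    for c in comps:
        if c.label is None:
            c.label = "NOISE"

    out = SpectrumDecomposition(components=comps, total_power=decomp.total_power,
                                lf_hf_ratio=decomp.lf_hf_ratio)
    if out.component("LF") is None or out.component("HF") is None:
        raise ClassificationError(
            "no LF or HF candidate component; spectral indices missing")
    return out


def normalized_units(decomp: SpectrumDecomposition) -> SpectrumDecomposition:
    """Attach normalized (nu) powers and the LF/HF ratio.

    nu = 100 * power / (total - VLF - NOISE): component power as a
    percentage of the oscillatory power, excluding very-low-frequency and
    noise mass — the convention under which LFnu + HFnu ~= 100.
    """
    lf = decomp.component("LF")
    hf = decomp.component("HF")
    if lf is None or hf is None:
        raise ClassificationError("LF and HF must be labeled before nu computation")
    denom = decomp.total_power - decomp.power("VLF") - decomp.power("NOISE")
    if denom <= 0:
        raise ParameterError("zero oscillatory power; normalized units undefined")
    comps = []
    for c in decomp.components:
        nu = 100.0 * c.power_abs / denom if c.label in ("LF", "HF") else math.nan
        comps.append(replace(c, power_nu=nu))
    ratio = lf.power_abs / hf.power_abs if hf.power_abs > 0 else math.nan
    if hf.power_abs == 0:
        raise ParameterError("zero HF power; LF/HF ratio undefined")
    return SpectrumDecomposition(components=comps, total_power=decomp.total_power,
                                 lf_hf_ratio=float(ratio))


def ar_psd(model: ARModel, freqs: np.ndarray) -> np.ndarray:
    """AR power spectral density (units^2 per Hz) at the given frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    dt = model.sampling_interval_s
    z = np.exp(-2j * np.pi * freqs[:, None] * dt * np.arange(1, model.order + 1))
    a = 1.0 - z @ model.coefficients
    return model.residual_variance * dt / np.abs(a) ** 2


class ARSpectrumAnalyzer(BaseEstimator):
    """Autoregressive spectral decomposition of one beat series.

    Parameters
    ----------
    order : int or None
        Fixed AR order in [6, 20]; None selects by AIC over ``order_range``.
    order_range : tuple of int
        Candidate orders for AIC selection.
    method : {"burg", "yule_walker"}
        AR coefficient estimator.
    noise_fraction : float
        Components below this fraction of total power are NOISE regardless
        of band (classification also labels off-band mass NOISE).

    Attributes
    ----------
    model_ : ARModel
        The selected stable AR model.
    decomposition_ : SpectrumDecomposition
        Components with absolute powers; labeled and nu-annotated when a
        respiratory frequency was supplied to :meth:`fit`.
    total_power_ : float
        Sample variance of the fitted series.
    """

    def __init__(self, order: int | None = None,
                 order_range: tuple[int, int] = DEFAULT_ORDER_RANGE,
                 method: str = "burg",
                 noise_fraction: float = NOISE_FRACTION):
        self.order = order
        self.order_range = order_range
        self.method = method
        self.noise_fraction = noise_fraction

    def fit(self, X, y=None, *, sampling_interval_s: float,
            resp_freq_hz: float | None = None) -> "ARSpectrumAnalyzer":
        x = np.asarray(X, dtype=float).ravel()
        self.total_power_ = float(np.var(x))
        self.model_ = fit_ar(x, sampling_interval_s, order=self.order,
                             order_range=self.order_range, method=self.method)
        decomp = decompose_spectrum(self.model_, self.total_power_)
        if resp_freq_hz is not None and not math.isnan(resp_freq_hz):
            decomp = normalized_units(
                classify_components(decomp, resp_freq_hz,
                                    noise_fraction=self.noise_fraction))
        self.decomposition_ = decomp
        return self

    def band_power(self, label: str) -> float:
        return self.decomposition_.power(label)
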