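"""Alpha index, coherence gate, sequence BRS, causal closed-loop gains."""
import math

import numpy as np
import pytest

from cardiovar.baroreflex import (
    BaroreflexAnalyzer,
    alpha_index_m,
    brs_sequence,
    cross_coherence,
    fit_trivariate,
)
from cardiovar.datatypes import CoherenceProfile, IdentificationError, ParameterError
from cardiovar.preprocess import validate_beats
from cardiovar.simulate import generate_recording, recovery_preset


def test_alpha_formula_perfect_square_ratios():
    # sqrt(100/4)=5, sqrt(225/9)=5 -> mean 5
    assert alpha_index_m(100.0, 4.0, 225.0, 9.0) == pytest.approx(5.0)


def test_alpha_identity_under_pure_gain():
    g = 17.3
    assert alpha_index_m(g * g * 4.0, 4.0, g * g * 9.0, 9.0) == pytest.approx(g)


def test_alpha_gated_by_coherence():
    low = CoherenceProfile(freq_grid=np.array([0.1]), coherence=np.array([0.2]),
                           k2_lf=0.4, k2_hf=0.9)
    assert math.isnan(alpha_index_m(100.0, 4.0, 225.0, 9.0, low))
    high = CoherenceProfile(freq_grid=np.array([0.1]), coherence=np.array([0.9]),
                            k2_lf=0.8, k2_hf=0.9)
    assert alpha_index_m(100.0, 4.0, 225.0, 9.0, high) == pytest.approx(5.0)


def test_alpha_rejects_nonpositive_power():
    with pytest.raises(ParameterError):
        alpha_index_m(0.0, 4.0, 225.0, 9.0)


def test_coherence_near_one_for_deterministic_coupling(rng):
    x = np.sin(2 * np.pi * 0.1 * np.arange(512)) + 0.05 * rng.standard_normal(512)
    prof = cross_coherence(10.0 * x, x, 1.0, f_lf=0.1, f_hf=0.25)
    assert prof.k2_lf > 0.95
    assert np.all((prof.coherence >= 0) & (prof.coherence <= 1))


def test_coherence_low_for_independent_noise():
    rng = np.random.default_rng(77)
    prof = cross_coherence(rng.standard_normal(512), rng.standard_normal(512),
                           1.0, f_lf=0.1, f_hf=0.26)
    assert prof.k2_lf < 0.5 and prof.k2_hf < 0.5


def test_coherence_high_at_lf_with_arterial_coupling(recovery_recording):
    clean = validate_beats(recovery_recording)
    ba = BaroreflexAnalyzer().fit(clean)
    assert ba.coherence_.k2_lf > 0.5
    assert ba.coherence_.k2_hf > 0.5


def test_brs_exact_linear_coupling():
    rng = np.random.default_rng(3)
    n = 512
    # SAP with pronounced slow ramps; RR = 10*SAP(lag 1) + const
    t = np.arange(n)
    sap = 120 + 8 * np.sin(2 * np.pi * t / 25) + 0.1 * rng.standard_normal(n)
    rr = np.empty(n)
    rr[1:] = 10.0 * sap[:-1] + 100.0
    rr[0] = rr[1]
    brs, n_seq = brs_sequence(rr, sap)
    assert n_seq >= 3
    assert brs == pytest.approx(10.0, abs=0.01)


def test_brs_missing_without_ramps():
    brs, n_seq = brs_sequence(np.full(128, 900.0), np.full(128, 120.0))
    assert n_seq == 0
    assert math.isnan(brs)


def test_brs_recovers_generator_gain():
    vals = []
    for seed in range(10):
        rec = generate_recording(recovery_preset(20.0, seed=seed))
        brs, n_seq = brs_sequence(rec.rr, rec.sap)
        assert n_seq >= 3
        vals.append(brs)
    assert np.median(vals) == pytest.approx(20.0, rel=0.25)


def test_trivariate_pathway_isolation():
    """gain_cp = 0: both causal gains equal the arterial gain; Alpha CP ~ 0.
    (Near-noiseless: a token 0.01 ms noise keeps the regression full rank.)"""
    p = recovery_preset(15.0, n_beats=1024, seed=4, sigma_rr=0.01, sigma_sap=0.01)
    rec = generate_recording(p)
    clean = validate_beats(rec)
    a_xar, a_xxar, alpha_cp, _ = fit_trivariate(
        clean.rr_centered, clean.sap_centered, clean.resp_centered,
        clean.mean_interval_s, 0.10, 0.26, order=8,
        sap_hf_power=p.a_hf_sap ** 2 / 2, resp_hf_power=0.5)
    assert a_xar == pytest.approx(15.0, rel=0.05)
    assert a_xxar == pytest.approx(15.0, rel=0.05)
    assert alpha_cp < 1.0


def test_trivariate_removes_respiration_bias():
    """With no arterial gain but a strong respiratory pathway, the bivariate
    HF transfer is inflated while the trivariate one stays near zero."""
    p = recovery_preset(0.0, n_beats=1024, seed=6, gain_cp=30.0)
    rec = generate_recording(p)
    clean = validate_beats(rec)
    _, a_xxar, _, detail = fit_trivariate(
        clean.rr_centered, clean.sap_centered, clean.resp_centered,
        clean.mean_interval_s, 0.10, 0.26, order=8)
    assert detail["a_xar_hf"] > 5.0          # respiration bias in bivariate
    assert a_xxar < 1.5                      # partialled out in trivariate


def test_trivariate_recovers_gain_with_both_pathways():
    vals = []
    for seed in range(10):
        p = recovery_preset(12.0, n_beats=700, seed=seed, gain_cp=25.0)
        clean = validate_beats(generate_recording(p))
        _, a_xxar, _, _ = fit_trivariate(
            clean.rr_centered, clean.sap_centered, clean.resp_centered,
            clean.mean_interval_s, 0.10, 0.26, order=8)
        vals.append(a_xxar)
    assert np.median(vals) == pytest.approx(12.0, rel=0.15)


def test_collinear_regressors_raise():
    rng = np.random.default_rng(0)
    resp = np.sin(2 * np.pi * 0.25 * np.arange(256))
    rr = rng.standard_normal(256)
    with pytest.raises(IdentificationError):
        fit_trivariate(rr, 2.0 * resp, resp, 1.0, 0.10, 0.25, order=8)


def test_alpha_cp_scales_respiratory_pathway(recovery_recording):
    """Generator truth: alpha_cp ~ gain_cp / a_hf_sap (respiration-driven RR
    per mmHg of respiration-driven SAP)."""
    p = recovery_preset(10.0, n_beats=1024, seed=8, gain_cp=30.0)
    clean = validate_beats(generate_recording(p))
    ba = BaroreflexAnalyzer().fit(clean)
    truth = 30.0 / p.a_hf_sap
    assert ba.indices_.alpha_cp == pytest.approx(truth, rel=0.25)


def test_analyzer_produces_all_indices(clean_preset):
    ba = BaroreflexAnalyzer().fit(clean_preset)
    idx = ba.indices_
    for name in ("alpha_m", "brs", "a_xar", "a_xxar", "alpha_cp"):
        assert getattr(idx, name) >= 0 or math.isnan(getattr(idx, name))
    assert idx.n_sequences > 0
    assert not math.isnan(idx.alpha_m)
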