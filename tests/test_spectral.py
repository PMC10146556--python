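"""AR fitting and pole-residue spectral decomposition."""
import math

import numpy as np
import pytest
from scipy.signal import periodogram

from cardiovar.datatypes import ClassificationError, ParameterError, SpectralComponent, SpectrumDecomposition
from cardiovar.preprocess import validate_beats
from cardiovar.simulate import condition_preset, generate_recording
from cardiovar.spectral import (
    ARSpectrumAnalyzer,
    ar_psd,
    classify_components,
    decompose_spectrum,
    fit_ar,
    normalized_units,
)


def test_white_noise_total_power_matches_variance(rng):
    x = rng.standard_normal(2048)
    x -= x.mean()
    spec = ARSpectrumAnalyzer().fit(x, sampling_interval_s=1.0)
    total = sum(c.power_abs for c in spec.decomposition_.components)
    assert total == pytest.approx(np.var(x), rel=1e-9)
    # theoretical AR variance close to the sample variance (rescale is small)
    assert spec.model_.residual_variance == pytest.approx(np.var(x), rel=0.1)


def test_white_noise_has_no_spurious_dominant_component():
    hits = 0
    for seed in range(100):
        x = np.random.default_rng(seed).standard_normal(512)
        spec = ARSpectrumAnalyzer().fit(x - x.mean(), sampling_interval_s=1.0)
        top = max(c.power_abs for c in spec.decomposition_.components)
        hits += top > 0.5 * spec.total_power_
    assert hits == 0


def test_ar2_center_frequency_matches_transfer_function_peak(rng):
    """Truth by construction: simulate a known AR(2); the oracle frequency is
    the peak of the directly evaluated true AR transfer function."""
    from cardiovar.datatypes import ARModel

    r, f0, dt = 0.95, 0.10, 1.0
    theta = 2 * np.pi * f0 * dt
    a1, a2 = 2 * r * np.cos(theta), -r * r
    n = 8192
    e = rng.standard_normal(n + 200)
    x = np.zeros(n + 200)
    for k in range(2, n + 200):
        x[k] = a1 * x[k - 1] + a2 * x[k - 2] + e[k]
    x = x[200:] - x[200:].mean()

    grid = np.linspace(0.001, 0.5 / dt - 0.001, 4000)
    truth_model = ARModel(order=8, coefficients=[a1, a2, 0, 0, 0, 0, 0, 0],
                          residual_variance=1.0, sampling_interval_s=dt)
    f_truth = grid[np.argmax(ar_psd(truth_model, grid))]

    spec = ARSpectrumAnalyzer().fit(x, sampling_interval_s=dt)
    dom = max(spec.decomposition_.components, key=lambda c: c.power_abs)
    assert dom.center_freq_hz == pytest.approx(f_truth, abs=0.01)


def test_single_sinusoid_power_matches_periodogram_integral():
    n, dt, amp, f0 = 4096, 1.0, 3.0, 0.1
    t = np.arange(n) * dt
    x = amp * np.sin(2 * np.pi * f0 * t)
    x -= x.mean()
    spec = ARSpectrumAnalyzer().fit(x, sampling_interval_s=dt)
    dom = max(spec.decomposition_.components, key=lambda c: c.power_abs)

    f, p = periodogram(x, fs=1 / dt)
    band = (f > f0 - 0.02) & (f < f0 + 0.02)
    oracle = np.trapezoid(p[band], f[band])
    assert dom.power_abs == pytest.approx(amp ** 2 / 2, rel=0.05)
    assert dom.power_abs == pytest.approx(oracle, rel=0.05)


def test_three_oscillations_resolved(rng):
    n, dt = 4096, 1.0
    t = np.arange(n) * dt
    x = (2.0 * np.sin(2 * np.pi * 0.01 * t)
         + 3.0 * np.sin(2 * np.pi * 0.10 * t)
         + 1.5 * np.sin(2 * np.pi * 0.25 * t)
         + 0.3 * rng.standard_normal(n))
    spec = ARSpectrumAnalyzer().fit(x - x.mean(), sampling_interval_s=dt)
    major = sorted(c.center_freq_hz for c in spec.decomposition_.components
                   if c.power_abs > 0.05 * spec.total_power_)
    assert len(major) == 3
    for got, want in zip(major, (0.01, 0.10, 0.25)):
        assert got == pytest.approx(want, abs=0.01)


def test_injected_frequencies_recovered_within_001hz(rng):
    """Frequency accuracy at SNR >= 3."""
    n, dt = 2048, 1.0
    t = np.arange(n) * dt
    x = (4.0 * np.sin(2 * np.pi * 0.095 * t)
         + 3.0 * np.sin(2 * np.pi * 0.27 * t)
         + 1.0 * rng.standard_normal(n))
    spec = ARSpectrumAnalyzer().fit(x - x.mean(), sampling_interval_s=dt)
    comps = sorted(spec.decomposition_.components,
                   key=lambda c: -c.power_abs)[:2]
    freqs = sorted(c.center_freq_hz for c in comps)
    assert freqs[0] == pytest.approx(0.095, abs=0.01)
    assert freqs[1] == pytest.approx(0.27, abs=0.01)


def _decomp(freq_power_pairs, total=None):
    comps = [SpectralComponent(center_freq_hz=f, power_abs=p)
             for f, p in freq_power_pairs]
    total = total if total is not None else sum(p for _, p in freq_power_pairs)
    return SpectrumDecomposition(components=comps, total_power=total)


def test_classification_three_major_components():
    d = classify_components(_decomp([(0.0005, 30.0), (0.10, 50.0), (0.26, 40.0)]),
                            resp_freq_hz=0.26)
    assert [c.label for c in d.components] == ["VLF", "LF", "HF"]


def test_small_offband_component_is_noise():
    d = classify_components(
        _decomp([(0.10, 58.0), (0.26, 40.0), (0.35, 2.0)]), resp_freq_hz=0.26)
    labels = {round(c.center_freq_hz, 2): c.label for c in d.components}
    assert labels[0.35] == "NOISE"


def test_classification_requires_non_entrained():
    with pytest.raises(ParameterError):
        classify_components(_decomp([(0.10, 100.0)]), resp_freq_hz=0.10)


def test_missing_hf_candidate_raises():
    with pytest.raises(ClassificationError):
        classify_components(_decomp([(0.10, 100.0)]), resp_freq_hz=0.26)


def test_normalized_units_symmetric_case():
    d = classify_components(_decomp([(0.10, 50.0), (0.26, 50.0)]),
                            resp_freq_hz=0.26)
    d = normalized_units(d)
    lf, hf = d.component("LF"), d.component("HF")
    assert lf.power_nu == pytest.approx(50.0)
    assert hf.power_nu == pytest.approx(50.0)
    assert d.lf_hf_ratio == pytest.approx(1.0)
    assert lf.power_nu + hf.power_nu <= 100.0 + 1e-6


def test_normalized_units_zero_hf_power_errors():
    d = classify_components(_decomp([(0.10, 100.0), (0.26, 0.0)], total=100.0),
                            resp_freq_hz=0.26)
    with pytest.raises(ParameterError):
        normalized_units(d)


def test_preset_recording_has_hf_near_respiration(clean_preset):
    spec = ARSpectrumAnalyzer().fit(
        clean_preset.rr_centered,
        sampling_interval_s=clean_preset.mean_interval_s,
        resp_freq_hz=clean_preset.resp_freq_hz)
    hf = spec.decomposition_.component("HF")
    assert hf.center_freq_hz == pytest.approx(0.26, abs=0.03)


def test_power_conservation_on_preset_recordings():
    for seed in range(5):
        rec = generate_recording(condition_preset("bedrest_normoxia", seed=seed))
        clean = validate_beats(rec)
        spec = ARSpectrumAnalyzer().fit(
            clean.rr_centered, sampling_interval_s=clean.mean_interval_s)
        total = sum(c.power_abs for c in spec.decomposition_.components)
        assert total == pytest.approx(np.var(clean.rr_centered), rel=0.02)
        assert all(c.power_abs >= 0 for c in spec.decomposition_.components)


def test_fixed_order_override_and_bounds():
    x = np.random.default_rng(0).standard_normal(256)
    m = fit_ar(x - x.mean(), 1.0, order=10)
    assert m.order == 10
    with pytest.raises(ParameterError):
        fit_ar(x, 1.0, order=4)


def test_short_series_rejected():
    with pytest.raises(ParameterError):
        fit_ar(np.zeros(32), 1.0)
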