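# Methods

## Scope and model

`cardiovar` analyzes beat-aligned series — RR intervals (ms), systolic
arterial pressure (mmHg) and a respiration trace sampled at beat times —
from ~10-minute resting recordings. The analysis is linear and spectral
throughout: autoregressive (AR) decomposition of each series, a bivariate
AR model for RR–SAP coherence, and closed-loop regression models for
causal gains. Beat-domain spectra are mapped to Hz using the mean RR
interval as the sampling step; no resampling to an evenly spaced time grid
is performed, matching the tachogram-based tradition this pipeline
follows.

## Synthetic generator

The generator is a linear beat-domain model, deliberately matched to the
linear analysis chain so that every index has a closed-form truth:

```
resp[k] = sin(2π f_resp t_k)
sap[k]  = μ_SAP + A_LF sin(2π f_LF t_k) + A_HF resp[k] + ε_SAP[k]
rr[k]   = μ_RR + G_a (sap[k−d] − μ_SAP) + G_cp resp[k] + ε_RR[k]
t_{k+1} = t_k + rr[k]/1000
```

with white Gaussian noises and a baroreflex latency `d` of one beat.
Ground truths: the LF SAP power is A_LF²/2; the arterial baroreflex gain
seen by the α index, the sequence method and the causal models is G_a; the
respiration→RR pathway is G_cp, and the cardiopulmonary index's truth is
G_cp/A_HF (respiration-driven RR per mmHg of respiration-driven SAP).
Beat times use the onset convention (beat *k* starts interval `rr[k]`).

**Condition presets.** Four presets represent ambulatory/bedrest ×
normoxia/hypoxia recordings. Their means, oscillation amplitudes and gains
are derived from published condition-level first and second moments: the
oscillation amplitudes from the LF/HF component powers (A = √2P), the
arterial gain from the LF power ratio (√(LFa_RR/LFa_SAP)), the
respiratory-pathway gain from the residual HF RR power (the delayed
baroreflex contribution adds in near-quadrature at one-beat latency), and
the RR/SAP noise SDs from an even split of the RR variance left over after
the LF and HF lines. Simulated recordings land within ~5% of the target
mean RR/SAP and within ~5–25% of the target RR variance. The presets only
constrain first/second moments; higher-order features of real data
(nonstationarity, respiratory amplitude modulation, ectopy, 1/f VLF
structure, nonlinear coupling) are *not* emulated, so passing tests
demonstrate estimator correctness under the stated linear model, not
performance on arbitrary clinical data.

**Recovery preset.** Estimator-validation simulations (gain recovery,
respiration bias) use a dedicated low-noise preset (σ_RR = 2 ms,
σ_SAP = 1 mmHg, SNR > 3 for every oscillation). This choice is
deliberate: broadband RR power not driven by SAP biases any α-style index
upward — in real data the α index exceeds the causal gain severalfold for
exactly this reason — so recovery of a *known* gain is meaningful only
when non-baroreflex RR power is small. The condition presets, which carry
realistic 25–45 ms broadband RR noise, are used for calibration and
group-level simulations instead.

## Preprocessing

Beats are flagged when RR lies outside 300–2000 ms or jumps more than 30%
from the previous interval; flagged beats are replaced by linear
interpolation of valid neighbours, and a recording with more than 5%
flagged beats is rejected. These thresholds follow common HRV practice;
they make the pipeline tolerant of imperfect input even though curated
recordings should arrive artefact-free. Series are linearly detrended
before AR fitting (10-minute segments are treated as trend-stationary);
reported RR/SAP means come from the cleaned, un-detrended series. The
respiratory rate is the dominant component (≥0.03 Hz) of the respiration
series' own AR spectrum; breathing below 0.12 Hz (strict inequality)
declares entrainment and withholds all spectral indices, since LF and HF
merge into a single rhythm near 0.1 Hz.

## AR spectra

Coefficients are estimated with Burg's lattice method (Yule-Walker
optional), order selected by AIC over 8–16 (fixed order override allowed
within 6–20). The spectral density is factored over the characteristic
roots; the component power of pole p_k is the residue

```
γ_k = σ² p_k^{p−1} / ( Π_{j≠k}(p_k − p_j) · Π_j(1 − p_j p_k) )
```

with conjugate pairs combined (2·Re γ) and real roots assigned to the
~0 Hz mass. Numerical choices, all exercised by tests:

* Pole radii are clamped to 1−1e−8 and marginally unstable fits
  (|root| ≤ 1+1e−4) tolerated: a noiseless sinusoid drives Burg to the
  unit circle with σ² at rounding level.
* Residue powers are rescaled to sum to the sample variance, so power
  conservation is exact by construction and degenerate (near-deterministic)
  series still decompose correctly; for stochastic series the rescale is a
  small correction (the model variance matches the sample variance within
  a few percent).
* Components closer than 0.01 Hz are merged (an undamped oscillation can
  split across coincident pole pairs); tiny negative residues are clipped
  and the total renormalized.
* Classification: LF is the largest component in [0.003, 0.14) Hz (ties to
  the one nearer 0.10 Hz), HF the largest within ±0.05 Hz of respiration
  and ≥0.12 Hz, sub-0.003 Hz mass is VLF, all remaining components are
  noise. Normalized units divide by total − VLF − noise, the convention
  under which LFnu + HFnu ≈ 100. Missing LF or HF is an error surfaced as
  missing indices, never silently imputed.

## Baroreflex indices

* **α index M** — mean of the LF and HF square-root power ratios, gated on
  magnitude-squared coherence > 0.5 at both center frequencies. Coherence
  comes from a bivariate AR model of (RR, SAP) evaluated analytically at
  the classified frequencies.
* **Sequence BRS** — runs of ≥3 beats with monotone SAP steps ≥1 mmHg and
  concordant lag-1 RR steps ≥4 ms; per-run RR-on-SAP slope kept when
  r ≥ 0.85; BRS is the mean slope, missing with <3 runs. Thresholds follow
  standard spontaneous-sequence practice.
* **Causal gains** — the bivariate model regresses RR on its own past and
  on present+past SAP (order = the univariate AR order; zero-delay SAP
  term allowed because the baroreflex acts within the beat); A.XAR is the
  SAP→RR transfer magnitude averaged at LF and HF. The trivariate model
  adds present+past respiration as an exogenous regressor; A.XXAR is the
  same transfer with the respiratory drive partialled out. Rank-deficient
  designs (e.g. SAP exactly proportional to respiration) raise an
  identification error rather than returning a minimum-norm artefact.
* **α index CP** — |respiration→RR transfer at HF| · √(HF resp power /
  HF SAP power). This rescaling, which expresses the respiration-mediated
  RR fluctuation in ms/mmHg, is this package's operationalization of the
  cardiopulmonary-baroreflex proxy; it recovers G_cp/A_HF on the
  generator and should be read as a proxy with that convention, not as a
  literal reflex gain.

## Group statistics

Values of one variable are ranked across *all* (subject, condition) cells
(average ranks on ties) — the standard rank-transform procedure — making
every downstream p-value invariant under monotone transforms. The omnibus
condition test uses the random-intercept mixed model; for complete
balanced designs this equals the two-way repeated-measures ANOVA F with
(k−1), (n−1)(k−1) degrees of freedom and is computed in closed form
(compound symmetry; the covariance structure is configurable only through
the MixedLM path). Incomplete designs use REML MixedLM with a Wald-F
approximation (denominator df N − n_subjects − k + 1); on balanced data the
two paths agree to ~0.01 in p. The six paired contrasts use the pooled
residual variance (model-based SE) and are unadjusted by default, matching
the convention of reporting raw paired contrasts; Holm adjustment is
available. Type-I error, simulated under the null at 11 subjects × 4
conditions × 2000 replicates, is ~0.05 for the omnibus test and for each
contrast letter. Subjects observed in fewer than 2 conditions are dropped;
a variable with zero rank variance is skipped with a warning.

## Problem sizes and determinism

Default simulations use 600-beat recordings (~10 min at ~1 s beats);
parameter-recovery studies use 700 beats × 50–100 seeds, the spectral
oracle comparison 10,000 beats, and the null calibration 2000 vectorized
replicates — sizes at which every validation completes in seconds to a
few minutes on one CPU. All randomness flows through explicit integer
seeds (per-recording seeds derived via `SeedSequence`), and study reports
embed a configuration hash; re-running a study on the same inputs
reproduces byte-identical outputs.

## Known limitations

* The generator and analysis are linear; nonlinear and time-varying
  cardiovascular coupling are out of scope, as are waveform-level
  processing (QRS detection, pulse-wave analysis) and nonlinear HRV
  indices.
* The causal-model structure (regression orders, zero-delay SAP term,
  exogenous respiration) is one defensible identification scheme validated
  by parameter recovery, not a bit-match of any proprietary
  implementation.
* HF is tied to the measured respiratory frequency; without a respiration
  trace a proxy (largest RR component in 0.15–0.45 Hz) is used and
  trivariate indices are withheld.
* Contrast letters are attached at p < 0.05 without multiplicity
  correction unless Holm is enabled.
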