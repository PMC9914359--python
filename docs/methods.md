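# Methods

## The measurement chain

The pipeline turns a raw single-lead ECG into one number per patient — the
approximate entropy (ApEn) of the ECG-derived respiration (EDR) signal — and
then asks whether that number improves an ordinal diagnostic model of the
consciousness level (UWS < MCS < EMCS).

1. **Low-pass, 5 Hz.** A zero-phase (forward–backward) second-order
   Butterworth low-pass suppresses muscle noise and mains interference.
   Because the same filtered trace feeds peak detection, the QRS complex is
   heavily smoothed; the detector therefore works on the *derivative energy*
   of the filtered trace rather than raw amplitude. Filtering before
   detection is a configuration switch (`detect_lowpass_hz`, default 5 Hz);
   zero-phase filtering doubles the effective order, which the documented
   magnitude-response tests account for.
2. **R-peak detection.** Squared derivative, smoothed over 80 ms, thresholded
   at 40% of its 99th percentile; candidates are refined to the local maximum
   within ±100 ms and pruned by an adaptive refractory period (40% of the
   running median inter-beat interval, floored at 250 ms). This is a
   deliberately simple detector whose contract is defined operationally: on
   annotated synthetic records ≥ 99% of planted beats must be recovered
   within one sample (the suite checks this, with and without additive
   noise).
3. **Ectopic correction.** An inter-beat interval is abnormal if it deviates
   more than 30% (configurable) from the median of its neighbours (window of
   11 beats, centre excluded — excluding the centre keeps an outlier from
   dragging its own reference). Beats flanked by abnormal intervals are
   removed; gaps are refilled with evenly spaced beats so restored intervals
   match the local median, flagged `interpolated`. The operation is
   idempotent.
4. **Tachogram.** Per-beat rate 60/IBI at interval midpoints,
   cubic-spline-resampled onto a uniform 4 Hz grid. 4 Hz gives a 10×
   Nyquist margin over the 0.4 Hz upper respiratory band edge and is the
   conventional rate in heart-rate-variability work.
5. **EDR.** Zero-phase second-order Butterworth band-pass of the mean-removed
   rate trace, 0.1–0.4 Hz; 10 s trimmed at each end to drop filter
   transients; the trimmed signal is re-centred (the residual mean from edge
   transients is pure DC and invisible to ApEn, which is shift-invariant).
   Records shorter than 60 s after trimming are rejected.
6. **ApEn.** m = 2, r = 0.2 × sd of the analysed series — the canonical
   parameter choice, exposed in config with a sensitivity helper over
   m ∈ {1,2,3}, r ∈ {0.1,…,0.25}. Self-matches are counted (classic ApEn, so
   no log of zero; this is what distinguishes it from sample entropy), the
   distance is Chebyshev, and a constant series gives exactly 0. ApEn is
   computed on the uniformly resampled EDR waveform, not on per-breath
   values: the band-pass that defines the EDR requires a uniform grid, and
   the waveform reading is the natural one for this chain. (Computing it on
   a per-breath rate sequence would be the main alternative; it is not
   implemented.) The full record is used by default; windowed analysis is a
   config option. The vectorised implementation is pinned against a literal
   nested-loop transcription of the definition to 1e-10 on hundreds of
   random series.

## The synthetic generator

No patient recordings ship with the package, so every downstream stage is
exercised on synthetic data built to have the features the analysis relies
on — and only those.

* **Respiratory-rate process.** Instantaneous breathing rate = base rate
  (default 0.25 Hz) + AR(1) fluctuation with stationary sd `modulation_sd`
  and lag-1 coefficient 0.995 at 8 Hz (correlation time ≈ 25 s, i.e. slow
  drift of breathing frequency), clipped to 0.05–0.45 Hz. AR(1) was chosen
  because it provides a single knob (the sd) that maps monotonically to
  downstream ApEn; the suite verifies that monotonicity empirically
  (Spearman ρ = 1.0 across a 5-point grid, 20 seeds per point).
* **Beat generation.** Integral pulse frequency modulation: heart rate =
  mean HR (75 bpm) + RSA depth (5 bpm) × sin(2π ∫ breathing rate dt) + white
  jitter; a beat fires at each integer crossing of ∫ HR/60 dt. IPFM is the
  standard physiologically motivated model and is analytically checkable
  (beat count = ⌊∫rate⌋ ± 1, asserted).
* **ECG rendering.** A fixed sum-of-Gaussians P-QRS-T template stamped at
  each beat time, plus optional white noise and 0.3 Hz baseline wander.
  Defaults: 128 Hz sampling, 20-minute records — the acquisition conditions
  the analysis assumes. Ground-truth beat times are stored as annotations.
* **Ectopic corruption.** Poisson-count premature (interval split at 40%)
  and missed (beat deleted) events with a perturbation log, so the
  correction stage can be tested against known truth.
* **Cohorts.** Defaults reproduce the published cohort: class sizes
  42/61/99; per-class ApEn targets median [IQR] 0.97 [0.22] / 1.11 [0.34] /
  1.10 [0.28]; descriptor prevalences (theta background, antero-posterior
  gradient, reactivity) and etiology mixes from the printed per-class
  counts. In *feature mode* ApEn is drawn from a log-normal matched to the
  class median/IQR in closed form (σ = asinh(IQR/2e^μ)/z₀.₇₅); the
  distribution family is a modelling choice — the source analysis reports
  only median/IQR — implemented as a shifted log-normal whose location
  shift defaults to 0. In *signal mode* each patient's target is inverted
  through a simulated calibration curve (median pipeline ApEn vs
  `modulation_sd`, cached per configuration; no closed form exists) and the
  pipeline ApEn is actually measured on a generated record; targets outside
  the attainable range raise a calibration error.

What the generator does **not** emulate: real QRS morphology variation,
arrhythmias beyond isolated ectopy, non-stationary RSA depth, movement
artefacts, and any EEG waveform structure (descriptors are generated as
Bernoulli bits). Passing tests therefore demonstrate that the *methods* are
correct and calibrated, not that the clinical effect would survive real-world
noise.

## Statistics

* Kruskal–Wallis (tie-corrected, via scipy) with Dunn post hocs implemented
  from the mean-rank formula with tie-corrected variance (ties are expected
  after rounding ApEn); Bonferroni over pairs.
* Chi-square: Pearson and likelihood-ratio (G) variants are always computed
  side by side, because statistical packages differ in which they print; on
  the published reactivity counts the likelihood-ratio variant reproduces
  the printed p = 0.002 (Pearson gives ≈ 0.0025). Pairwise column-proportion
  z-tests use the pooled estimate without continuity correction and
  Bonferroni correction, with homogeneous-subset letters derived from the
  maximal cliques of the non-significance graph. One printed value (the
  antero-posterior-gradient row, p = 0.025) is not reproducible from the
  printed counts under any standard chi-square variant (we obtain
  0.032–0.035); it is documented here as a discrepancy and not asserted.
* Two-factor fixed-effects model (ApEn ~ consciousness × etiology) by OLS
  with sum-to-zero contrasts and Type-III tests; empty cells trigger a
  Type-II fallback with a warning. Post hoc pairwise contrasts use the
  pooled residual variance with Bonferroni adjustment.
* Proportional odds: cumulative-logit — the conventional default for
  ordinal regression, with the sign convention that positive β means higher
  odds of a *higher* consciousness level. Fitting is maximum likelihood via
  statsmodels' ordinal model; the test suite independently minimises a
  hand-written cumulative-logit negative log-likelihood (thresholds
  parameterised as increments to enforce ordering) from multiple starts and
  requires agreement of the optimum to 1e-5 on −2LL. Wald CIs are reported
  (profile likelihood is not); CIs on the odds-ratio scale are deliberately
  not printed because published CIs of this type are often ambiguous about
  exponentiation. The thresholds-only −2LL has the closed form
  −2Σn_k ln(n_k/n) and anchors Nagelkerke R² = R²_CS / (1 − exp(−(−2LL₀)/n)).
  Separation and non-convergence are flagged on the fit, not raised.

## Numerical choices and degenerate inputs

* ApEn memory is bounded by chunking the pairwise Chebyshev distance matrix
  (≈ 300 MB worst case at the default 20-min/4 Hz series length).
* Zero-variance series with a relative tolerance return ApEn = 0 with a
  `degenerate` flag; series with N ≤ m+1 raise.
* Tiny negative Δ(−2LL) from optimizer noise (< 1e-6 relative) is clamped to
  0 in likelihood-ratio tests; a genuinely better-fitting "reduced" model
  raises, because it means the models were not nested on the same data.
* Cubic tachogram interpolation can overshoot on pathological trains; the
  rate is floored at a small positive value rather than allowed negative.

## Problem sizes used in the self-validation

The validation batteries are sized to be decisive yet quick: 50 records of
20 minutes for the EDR rate-error bound; 200 random series (N = 100–500) for
oracle equivalence; a 5-point modulation-sd grid with 20 seeds per point and
10-minute records for the monotonicity check; 200 simulations at the study's
n = 202 for ordinal parameter recovery, LRT power and type-I calibration;
100 seeds for the cohort-level qualitative reproduction. These sizes are the
package's own choices and are asserted at the tolerances stated in the test
suite.

## Known limitations

* The detector is validated on the package's own synthetic morphology, not
  on public arrhythmia databases; clinical-grade benchmarking is out of
  scope.
* Patient-level quantities from the original cohort (−2LL values, β = 1.994,
  Nagelkerke R² 0.321 → 0.393) depend on raw recordings that are not public;
  the package reproduces them qualitatively (direction and significance
  pattern over seeds), not numerically.
* Feature-mode cohorts draw descriptors independently within class; any
  real-world correlation between EEG descriptors beyond that induced by the
  class is not modelled, which tends to make the descriptor models slightly
  optimistic relative to reality.
* EDF export is not provided; all I/O is plain text (CSV/JSON).
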