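# Methods note

This note records the concrete methodological and numerical choices in
`pupilpipe`, the reasoning behind them, and the problem sizes they were
exercised at. It is aimed at a reader who wants to audit or extend the
pipeline.

## 1. Synthetic generator

### Signal composition

Each session is 1000 Hz binocular pupil area (arbitrary units, tonic level
4000) over `n_blocks × pulses_per_block` trials of 26 s (1 s pulse + 25 s
interstimulus interval). Components, per eye:

- **Hippus** — the dominant ongoing oscillation (~0.35 Hz, SD 120 au),
  shared between the eyes (it is centrally driven). It is generated as a
  quasi-sinusoid with *deterministic slow frequency modulation* (±15% at
  0.007 Hz) and mild amplitude modulation, **not** as a random-walk phase.
  A white phase-noise oscillator has unbounded instantaneous-frequency
  variance, which creates spurious large derivatives and made the first
  derivative pass flag up to ~30% of samples; real hippus has a bounded,
  smooth derivative.
- **Slow drift** — integrated white noise (random walk, 2 au/√s), shared
  between eyes.
- **Per-eye fluctuation** — a small independent quasi-sinusoid per eye
  (40 au at ~0.45 Hz) plus white sample noise (5 au). Together with the
  shared components this sets the across-trial left/right correlation of
  the baseline-corrected traces to roughly r ≈ 0.85–0.9 (Fisher z ≈ 1.3),
  a realistic binocular yoking level.
- **Evoked response** — a gamma-like kernel normalized to peak 1 at
  `response_latency` (1.3 s), scaled by a per-participant amplitude and
  per-trial jitter; the taVNS condition adds `stimulation_effect` plus a
  participant random slope.
- **Lateralized component** — on taVNS only, the right eye adds a
  trial-varying extra response with its own slower kernel
  (`lateralization_latency` = 3.0 s). The slower latency matters: it puts
  the decorrelation into the late analysis segment (2–6 s) instead of the
  early one, and it is the *trial-to-trial variability* of this component
  (SD = 0.6 × gain) that lowers the across-trial correlation — a constant
  mean shift would leave the correlation unchanged.
- **Artifacts** — blinks (missing-sample runs, gamma-distributed durations,
  mean 150 ms) and occlusion dips (50 ms negative excursions of ~half the
  tonic level) are placed by a joint Poisson process thinned with a 2 s
  refractory interval: eyelid events do not occur back-to-back, and without
  the refractory spacing adjacent blink windows merge into interpolated runs
  longer than 1 s, inflating trial exclusions far beyond realistic rates.
  Both artifact types hit both eyes simultaneously.

With the default rates (8 blinks/min, 2.5 dips/min), the full pipeline
excludes roughly 0.5–1.5% of trials depending on seed — the intended
magnitude for a cooperative adult sample.

### Coupled metadata

Per-participant sensation-rating differences (taVNS − sham) are negatively
coupled to sham-response amplitude (`rating_coupling`), and the calibrated
amplitude carries a condition shift, so the aggregate ("meta") models have
realistic structure to estimate.

### Three generator tiers

1. `simulate_study` / `simulate_recording` — full 1000 Hz signal path
   (used for pipeline-level tests; ~0.9 s per 20-minute session).
2. `simulate_clean_epochs` — baseline-corrected 100 Hz epochs with the
   binocular correlation structure but no artifact/filtering path (used for
   laterality Monte-Carlo; ~1 s per 20-participant replicate including the
   model fit).
3. `simulate_trial_table` — outcomes drawn directly from the mixed-model
   data-generating process (used for statistical calibration; ~0.6 s per
   20-participant replicate including the fit).

All randomness derives from `numpy.random.SeedSequence(seed, spawn_key=…)`
substreams, so every participant × condition cell is independently
reproducible and the three tiers share participant traits.

## 2. Signal conditioning

Stage order per eye: blink detection → low-pass + decimate → interpolate
blinks → derivative pass 1 (0.75 SD) → interpolate → derivative pass 2
(3.5 SD) → interpolate.

- **Blink windows**: missing-sample runs merged when separated by < 0.25 s,
  padded ±150 ms, clipped to the recording.
- **Filtering**: 4th-order Butterworth at 6 Hz applied forward-backward
  (`sosfiltfilt`, zero phase, squared magnitude response), then decimation
  1000 → 100 Hz. NaNs are passed through and handled by interpolation
  afterwards. The digital (bilinear-transform) response differs slightly
  from the analog prototype: at 10 Hz the two-pass gain is 0.016491 versus
  0.016519 analog; tests oracle against the designed digital filter via
  `sosfreqz` and measure amplitude by demodulation (peak-sampling a 10 Hz
  tone at 100 Hz underestimates amplitude by cos(π/10)).
- **Derivative passes**: the threshold is `multiplier × SD` of the *signed*
  first difference, compared against the *absolute* derivative. Using the
  SD of the absolute derivative instead would be pathological: for a
  sinusoid, std(|cos|) ≈ 0.31 versus RMS 0.71, so a clean sinusoid would
  perpetually exceed 3.5 × std(|d|). Artifact boundaries are located by a
  60 ms quiet-period rule (expand from each super-threshold sample to the
  nearest flanking quiet periods), and windows are padded −150/+250 ms.
  The implementation is vectorized; the test suite checks it against a
  naive O(n²) restatement of the rule on random discontinuous traces.
- **Interpolation**: linear between the nearest retained samples, constant
  extension at the edges; a window set covering the whole trace marks the
  recording unusable. Every applied window lands in a per-eye ledger
  (eye, start_ms, end_ms, source).

## 3. Trials and exclusions

Epochs span −1…+25 s (2600 samples at 100 Hz). Baseline is the mean over
[−1, 0); traces become percent change; non-positive baselines exclude the
trial. Outcomes (max dilation, peak latency, trapezoid AUC over 0–5 s) are
computed on the binocular mean trace. Exclusion rules are strict
inequalities (> 1 s longest interpolated/missing run in either eye, > 50%
bad samples), so boundary cases are retained; the run-length computation
rounds the sample interval to 9 decimals so a run of exactly 100 samples
compares equal to 1.0 s rather than exceeding it through floating-point
noise.

## 4. Mixed models

`fit_mixed_model` wraps statsmodels `MixedLM` (REML) and adds:

- **A convergence fallback ladder** — correlated random effects →
  independent (diagonal) random effects → progressively dropping slopes.
  Within each rung the optimizers lbfgs → bfgs → powell are tried *one at a
  time*; a rung is abandoned only when no optimizer yields finite, positive
  fixed-effect variances. (statsmodels accepts the first optimizer that
  reports convergence even when its Hessian is unusable.)
- **Model-based fixed-effect covariance** — the reported covariance is
  (X′V⁻¹X)⁻¹ at the fitted variance parameters (the quantity lme4 reports),
  not statsmodels' Hessian-based `cov_params()`, which was up to ~35% wider
  for between-participant covariates on a 12-participant fixture.
- **Satterthwaite degrees of freedom** — df = 2f²/(g′Ag) per coefficient,
  with f the coefficient's variance, g its gradient with respect to the
  variance parameters (central differences), and A the inverse observed
  information of the REML criterion (central-difference Hessian, steps
  1e−4·(|θ| + 0.01·scale)). Falls back to residual df with a warning when
  the information matrix is not invertible (boundary fits).

On a 12-participant fixture, estimates, standard errors (within 5%) and
Satterthwaite dfs all match R's `lmerTest` with the same correlated
random-effects structure; the test suite reruns this comparison whenever
`Rscript` + `lmerTest` are available.

Calibration at 20 participants × 90 trials (outcome-level generator):
null rejection of the stimulation term ≈ 5–7%, recovery of an injected
2.0% effect unbiased with ~95% CI coverage.

## 5. Design coding and downstream analyses

- stimulation ±0.5, block 0/1/2, amplitude z-scored (population SD),
  rating difference centered and /100, order ±0.5; participants missing a
  condition are dropped with a warning.
- Time-resolved analysis: 100 ms bins of the binocular trace, the main
  model refitted per bin, Benjamini–Hochberg applied *jointly* across all
  bins × non-intercept terms (statsmodels `multipletests`, oracled in tests
  against a hand-coded step-up).
- Responders: mean taVNS max dilation strictly greater than sham; ties are
  non-responders.
- Marginal means: linear-predictor evaluation at stimulation ∓0.5 with
  other covariates at their frame means; contrast SEs by the delta method
  from the fixed-effect covariance; warns outside the observed
  rating-difference range.
- Steiger's Z for dependent correlations sharing one variable, with domain
  checks (|r| < 1, n > 3).

## 6. Laterality analysis

Across-trial Pearson correlation between left and right percent-change
traces per 10 ms bin, clipped to |r| ≤ 1 − 1e−6, Fisher-z transformed (by
default before averaging), averaged over early (−1…1 s; 0…1 s in the
restricted variant) and late (2…6 s) segments. The mixed model uses
dummy-coded stimulation and segment with the full interaction in fixed and
random parts (with the standard fallback ladder). Monte-Carlo at 20
participants × 30 trials: lateralization gain 3% yields a negative
Stimulation × Time estimate in ~100% of replicates; with gain 0 the
interaction rejects at ~3–5%.

## 7. Known limitations

- The generator's artifact model is phenomenological (Poisson events with
  refractory thinning), not a mechanistic eyelid model.
- Satterthwaite dfs rely on finite-difference derivatives of the REML
  criterion; extremely flat or boundary likelihoods fall back to residual
  dfs rather than Kenward–Roger-style corrections.
- `detect_blinks` assumes blinks are already encoded as missing samples;
  trackers that report blinks as zeros or implausible values need a prior
  recode step.
- The CLI exchanges plain CSV for transparency; very long sessions are
  written uncompressed.
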