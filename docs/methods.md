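# Methods

## Scope and data model

The package analyses muscle co-contraction during treadmill walking from
two synchronized streams per trial: four-channel surface EMG (tibialis
anterior TA, medial gastrocnemius MG, rectus femoris RF, semitendinosus ST;
2000 Hz) and the foot's vertical acceleration (142 Hz). Trials are labelled
by participant, instrumented limb, population (TD = typically developing,
CP = cerebral palsy), treadmill environment (Dry = conventional, Wet =
aquatic) and belt speed (Slow/Normal/Fast). The crossed design gives every
limb one trial per environment × speed cell.

## Synthetic-data generator

No recorded trials ship with the package; the generator produces raw
signals with the structure the analysis assumes.

**Activation profiles.** Each muscle's activation over the gait cycle is a
tonic co-activation baseline plus Gaussian bursts on the stride-phase
circle, wrapped modulo 1 so terminal-swing bursts continue across the
100% → 0% boundary. Default burst placement follows textbook gait phases
(TA around initial contact and through swing; MG through stance; RF at
loading response and early swing; ST terminal swing into initial contact).
Bursts are parameterised by centre (phase fraction), width (Gaussian SD in
phase fraction) and amplitude (arbitrary units ~1); the cycle integral is
baseline + Σ amplitude·width·√(2π), which the tests verify against fine-grid
quadrature.

**Raw EMG.** The sampled signal is the profile (at the sample's
within-stride phase) multiplying zero-mean unit white noise, plus an
additive noise floor (`noise_sd`, default 0.01). Rectifying and low-pass
filtering such a signal recovers √(2/π)·√(profile² + noise_sd²), i.e. the
profile up to a constant wherever activation dominates the floor — so the
published envelope pipeline is exercised on realistic raw signals rather
than on envelopes directly.

**IMU.** A half-sine pulse of 50 ms and 2 g peak is centred on every
initial contact over 0.1 g Gaussian noise. EMG and IMU share one clock and
the trial starts at an initial contact after a 0.1 s lead-in (the streams'
synchronization convention is the package's own choice).

**Condition effects.** Wet trials multiply all activation by
`env_amplitude_factor` (default 0.65, < 1 encodes the reduced activation
observed in water); speeds multiply it by `speed_amplitude_factors`
(defaults 0.85/1.0/1.2) and divide the mean stride time by the same factor
(faster walking, shorter strides). The CP co-activation baseline (0.15) is
three times the TD baseline (0.05), encoding elevated tonic co-activation.
All magnitudes are invented; only their directions follow the emulated
study (CP > TD co-activation, Wet < Dry amplitude, Fast > Slow amplitude).

**Stride times.** Lognormal with configurable mean (default 1.1 s) and CV
(default 0.05); with probability 0.02 a stride is lengthened 1.8× to
emulate outlier strides (stumbles, handrail grabs).

**Participant heterogeneity.** Each participant carries per-muscle
lognormal burst-amplitude multipliers (log-SD 0.1) shared across all their
trials. The multipliers deliberately exclude the baseline: per-muscle
dynamic normalization divides out any pure amplitude scaling, so the
surviving between-participant variation enters through the
baseline-to-burst ratio — this is what makes a participant random intercept
appropriate downstream.

**Defaults.** 15 TD + 10 CP participants, two limbs, 160 strides per trial
(≈ 3 min of walking) — the emulated study's scale. Tests and validation
experiments use smaller cohorts (2–11 participants, 8–20 strides), the
package's chosen experiment sizes.

**What the generator does not emulate:** hydrodynamic drag and buoyancy
mechanics, electrode artefacts and motion noise, crosstalk between
channels, within-trial fatigue drift, sub-phase gait events, and any
physiological model of spasticity. Passing tests therefore demonstrate that
the *pipeline* recovers what was injected under the stated statistical
structure, not that real aquatic-gait effects have these magnitudes.

## Envelope extraction and dynamic normalization

Bias (series mean) is removed, the signal full-wave rectified, and a
zero-phase forward-backward Butterworth low-pass applied at 6 Hz. "2nd
order" is interpreted as 2nd order per pass (effective 4th order after the
dual pass) with no cutoff correction — the common convention; `order` and
`cutoff_hz` are arguments where the alternative is wanted. Edge effects use
reflective (`even`) padding of length 3 × order. Negative undershoot is
clipped to zero because the CCI formulas assume nonnegative activation.

Normalization divides every envelope of a limb, per muscle, by that
muscle's envelope maximum during the limb's single Dry Fast trial (the
dynamic task expected to elicit maximal activity). The reference maximum is
taken from the *filtered envelope* (not the raw rectified signal), per limb
(not per participant) — both choices are the ones that feed envelope-domain
CCI most directly, and both ambiguities are handled by normalizing
whatever trial set the caller groups together. Values above 1 in other
trials are preserved; a zero reference maximum raises a dead-channel error.
Normalizing already-normalized trials is a no-op (recomputed factors = 1).

## Segmentation and time normalization

Initial contacts are local acceleration maxima with prominence at least
twice the robust noise scale (MAD × 1.4826) and separation at least half
the expected stride time. Because initial contacts are the *greatest*
peaks, candidates below half the tallest candidate's height (above the
signal median) are additionally discarded: Gaussian noise bumps midway
between contacts can clear a pure prominence floor, and the relative-height
rule rejects them without any absolute threshold. Both fractions are
arguments. When no expected stride time is supplied, it is estimated as
the median interval between dominant peaks (prominence ≥ half the signal
range above the median).

Stride-time outliers use a single, non-iterative pass: flag strides with
|duration − mean| > 3 × SD (sample SD, n−1). The rule is applied per trial.
Strides are left-closed right-open in sample indexing; each retained
stride's envelope segment is linearly interpolated onto 101 equally spaced
points from 0 to 100% of stride (both endpoints included). Strides whose
window extends past the recording are dropped, never padded.

## Co-contraction indices

All three formulas act on the 101-point stride-normalized envelopes; the
per-stride values are averaged to one value per trial.

* **Unnithan (common area):** trapezoidal integral of the pointwise minimum
  over the *percent* phase axis (0–100). The percent axis keeps magnitudes
  in the 5–23 range typical for normalized envelopes; a fractional axis
  would divide all values by 100. The trapezoid on 101 points agrees with a
  10⁵-point Riemann sum to ≈ 0.05% on the default waveforms (tested
  tolerance 1%).
* **Rudolph:** mean over the 101 points of (EMGₛ/EMGₗ)·(EMGₛ+EMGₗ).
* **Falconer & Winter:** mean of 2·EMG_ant/EMG_total·100%, the antagonist
  fixed throughout the cycle to RF (RF/ST) or TA (TA/MG).

Phase points with zero larger activation (Rudolph) or zero total activation
(F&W) contribute 0 by default — co-contraction requires activation — with a
`zero_policy="drop"` alternative that excludes them from the mean. Ties
EMGₛ = EMGₗ need no tie-break (the formulas are symmetric at equality).

## Statistics

Condition cells are summarised as mean and sample SD over limb-trials, with
limbs treated as repeated observations of their participant.

Descriptive contrasts are computed from *cell means*: the environment
contrast averages the three speed-level cell means within each environment
and reports 100·(Wet − Dry)/Dry; speed contrasts average cell means over
the marginalized factors (population, and environment when both are
pooled). Computing from cell means rather than per-limb averages is the
convention that exactly reproduces published narrative values from
published tables, and is the only externally verifiable choice.

Model selection fits eight strictly nested linear mixed-effects models with
a participant random intercept — intercept only, then adding Environment,
Population, Speed, Environment:Population, Environment:Speed,
Population:Speed, and the three-way interaction — by maximum likelihood
(ML, not REML: information criteria are only comparable across
fixed-effect structures under ML). Each addition is tested by a
likelihood-ratio chi-square against the previous rung; the selected model
is the most complex whose own addition has p < α. Boundary fits (random-
intercept variance → 0) are reported in a `singular` column, not fatal;
the fitter falls back across optimizers (Powell first, then L-BFGS, CG,
Nelder-Mead) and keeps the first finite-likelihood fit, since boundary
cases can make a single optimizer fail or report an infinite likelihood.
A limb-within-participant nested random effect is deliberately not the
default; participant-only intercepts match the repeated-measures treatment
of limbs above.

## Validation experiments

`ccigait.experiments` packages the simulation studies the acceptance
script reports:

* **Recovery:** a Wet amplitude factor of 0.6 must emerge from the full
  chain as a ≈ 40% Unnithan reduction (tolerance ±10 percentage points;
  the additive noise floor biases the recovered value slightly toward
  zero, ≈ 1 point at default noise).
* **Segmentation fidelity:** ≥ 95% of ground-truth initial contacts
  matched within ±30 ms over 50 trials at default noise.
* **Calibration:** the environment likelihood-ratio test rejects at
  ≈ 0.05 on 200 effect-free cohorts (no environment/speed/population
  effects, participant offsets retained) and detects the 0.6 factor with
  power > 0.9 over 60 replicates.
* **Quadrature:** worst-case trapezoid-vs-Riemann disagreement across all
  condition waveforms.

## Known limitations

* The three-SD stride-outlier rule is applied per trial; a per-participant
  variant is not implemented.
* Initial-contact detection is tuned to signals with a single dominant peak
  per stride; double-peaked heel-strike transients would need the
  separation and relative-height fractions adjusted.
* Gait sub-phases (loading response, midstance, …) are out of scope; CCIs
  integrate the whole cycle.
* Tukey-adjusted post-hoc pairwise p-values and effect sizes are out of
  scope; the percent-change contrasts are descriptive.
* The mixed-model p-values rely on chi-square asymptotics; with very few
  participants they are only approximately calibrated (the type-I
  experiment quantifies this at the sizes used).
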