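# Methods

This note documents the models, numerical choices, and limitations behind
`scallop-pd`. It is the design record: nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Vibration metrics

All scalar levels are computed on the vector magnitude
m(t) = √(x² + y² + z²) of the triaxial acceleration. Field reports often
leave the axis-combination rule unstated; the magnitude is
orientation-invariant and upper-bounds any single axis, which makes it the
conservative default for exposure metrics. Per-axis spectra remain
available through `psd`.

The "90% energy window" of a pulse is the interval between the 5% and 95%
points of cumulative energy — the standard integration window in
impulsive-noise metrology. Cumulative energy uses the trapezoidal rule
(second-order accurate, shape-agnostic), and the 5%/95% times are linearly
interpolated between samples, so the window contains 90.0% of pulse energy
by construction and SEL_ss = 10 log₁₀(0.9 E_total). Pulse duration is the
literal first-crossing interval from 5% to 90% of the maximum magnitude;
rise time runs from the 5% cumulative-energy time to the magnitude peak.
Ties in threshold crossings resolve to the earliest sample. No frequency
weighting or pre-filtering is applied.

**Strike detection** thresholds the 50-ms moving-RMS envelope of m(t) at a
configurable margin (default 12 dB) above the ambient level, estimated from
the quietest 10% of 1-s frames; local maxima separated by at least the
minimum inter-pulse interval (default 1 s) are strikes, and each onset is
refined back from the envelope maximum to the threshold crossing, which
tracks the pulse front to about one sample. The detector therefore needs
some quiet time in the analyzed window to estimate its floor; an
all-vibration segment has no ambient reference.

## Synthetic data

The generator is the package's study-conditions definition, with defaults
drawn from the field measurements it emulates: ambient floor 53.86 dB re
1 µm s⁻², impact-hammer peaks 109.95 dB (per-strike SD 1.25 dB, normal in
dB — a modeling choice, since only per-day means and SDs are reported)
centered at 10 Hz, truncated-normal inter-pulse intervals 6.63 ± 0.61 s
with a 0.5-s physical floor (a hammer cannot double-strike), vibratory
levels 86.00 dB in the 10–100 Hz band, and daytime/exposure valve-angle
means of 7.34°/5.52°.

Design choices:

- **Pulse shape**: exponentially decaying sinusoid (τ = 0.15 s), which
  reproduces a 10-Hz-centered spectrum; onsets are snapped to the sample
  grid so the drawn peak is realized exactly at a sample and ground truth
  is exact.
- **Axis partitioning**: fixed unit-norm direction cosines (default
  1/√3 each), making per-axis and magnitude metrics deterministically
  related.
- **Vibratory noise** is synthesized in the frequency domain (masked
  complex spectrum, inverse rFFT) rather than with an IIR filter, because
  the default band edge (100 Hz) coincides with the geophone Nyquist
  frequency where filter design is ill-posed. The three-axis field is then
  rescaled so its magnitude RMS equals the requested level exactly.
- **Diel cycle**: day level by day, night level at night (nocturnal
  maximum; night default 9.5°, ~30% above the 7.34° daytime mean, mirroring
  the ~30% exposure reduction — the nocturnal mean itself is not reported),
  with 1-h half-cosine transitions at fixed sunset/sunrise times (19:00 /
  06:30, configurable). The period is exactly 24 h and records start at
  local midnight, so a whole-day record places 24.0 h on the Fourier grid.
- **Exposure windows**: the angle declines over a 60-s half-cosine onset
  ramp (the decrease observed in the field occupies roughly the first
  minute of exposure) and reopens instantly at offset (recovery is fast).
  `exposure_angle_mean` parameterizes the *observable* — the mean angle
  over exposure windows including ramp and strike-triggered transients —
  so each window's plateau is offset by the realized in-window depression
  and the noiseless window mean equals the configured value exactly.
- **Closures**: each impact strike triggers a Bernoulli(0.51) partial
  closure (the >50% response rate), dropping the angle by 2.2° (≈30% of
  the 7.34° baseline) with exponential recovery (τ = 5 s, consistent with
  between-strike recovery visible at a 6.6-s strike spacing).
- **Magnetometer forward model**: linear, 400 mV closed + 20 mV/degree,
  with 2 mV sensor noise; angle-domain noise SD 0.5°. The linear form is a
  package decision; published tag calibrations are instrument-specific.
- **Tag accelerometer**: scaled copies of the strike pulses plus band
  noise during vibratory phases, at high SNR, so strike synchronization is
  testable at 25 Hz.

What the generator does **not** emulate: acoustic propagation (distance
attenuation is parameterized, not modeled), tidal or temperature
modulation of gape, sensor drift and dropouts, inter-individual response
heterogeneity beyond random intercepts, and non-stationary ambient noise.
Passing closed-loop tests therefore demonstrates correctness of the
estimators under the stated statistical structure, not robustness to every
field artifact.

## Closure detection

A partial closure is modeled as an abrupt drop with exponential recovery.
Two naive detectors fail under the default conditions (51% of strikes
answered, 6.6-s spacing, τ = 5 s, 0.5° sensor noise at 2 Hz): a running
median of the preceding 30 s collapses onto the dips (they occupy most of
any trailing window during dense trains), and threshold-dwell runs merge
consecutive closures that never recover above threshold. The implemented
detector is a sparse matched deconvolution, alternating matching-pursuit
style:

1. the smooth open-state level is estimated as a centered 60-s running
   mean of the angle *plus the depression explained by events found so
   far* — unbiased regardless of dip duty cycle;
2. new events are peaks of the residual depression correlated with the
   causal exponential-recovery kernel, and all event amplitudes are refit
   leave-one-out (clearly spurious entries are dropped).

After convergence (6 iterations), events are kept if the fitted drop is at
least `partial_drop_deg` (default 1.0°, sized to the ~30% drop on 5–8°
baselines) and the smoothed angle actually reaches baseline − drop within
`sync_window_s` (default 2 s, strike synchronization at 2 Hz) of onset;
consecutive events with no intervening recovery of half the drop merge
into one (a sustained total closure is one event). Totals are events whose
minimum angle is at or below `total_threshold_deg` (default 1°). Reported
depths are measured from the open-state level with a 3-sample median
filter; latency is the gap to the nearest earlier strike within the sync
window.

## Circadian analysis

Angles are binned to 10-min means before the periodogram: periods of
interest are hours, and this keeps a 15-day record at 2160 points. The
record is trimmed to whole days so the Fourier grid contains 24.0 h
exactly. Ordinates use the one-sided normalization Σ Iₖ = n·var (Parseval)
and are restricted to periods in [2·bin, T/2]; the Fourier grid is not
oversampled, so Fisher's exact null applies. Detrending is mean removal
only. Missing bins under 5% are mean-imputed, otherwise the analysis
refuses.

Fisher's exact tail probability is evaluated with log-binomial terms and
compensated summation. The alternating series is numerically unusable only
when g is within a hair of its minimum 1/m; there, negative association of
the normalized ordinates bounds p above 1 − 1e-13, and p = 1 is returned.
The Nyquist ordinate is χ²₁- rather than exponentially-distributed under
the null; it is one ordinate among ~1000 at the default resolution and its
effect on the test level is negligible (the measured type-I error is part
of the acceptance suite).

## Mixed models

The valve-angle ladder fits five nested linear mixed models on
log(angle + 0.1°) (the offset admits zero angles) with crossed random
intercepts for individual and date, via maximum likelihood so
likelihood-ratio tests are valid. Adding the categorical terms verbatim
(phase, then hammer type, then sequence) would be rank-deficient — the
type dummies sum to the exposure-phase dummy — so the ladder adds nested
dummies instead: exposure/post phase (2 df), impact-vs-vibratory within
exposure (1 df), second-repetition within exposure (1 df), and numeric day
of exposure (1 df). Selection is forward stepwise at α = 0.05, stopping at
the first non-significant addition. Crossed random effects use the
variance-components formulation of statsmodels' MixedLM in a single group;
several optimizers are tried and nested log-likelihoods are monotone up to
optimizer tolerance (enforced).

Behavioral rates (events/min per individual × treatment, after removing
fish-related partial closures) are compared with a mixed model (random
intercept per individual). Per-factor F statistics are Wald chi-squares
divided by numerator df with residual denominator df — the backend
provides no Satterthwaite approximation, so denominator df will not match
software chains that do. Pairwise treatment contrasts use the
studentized-range (Tukey) distribution on the fixed-effect contrasts,
emmeans-style; adjusted p-values never fall below the raw t-based ones.

## Problem sizes and determinism

Closed-loop statistical checks use 15-day single-tag records for the
circadian analysis (100 seeds), 500-strike trains for interval recovery,
9-day × 4-individual tag sets for the exposure-window comparison, 10⁵-draw
Monte-Carlo nulls for the g-test, and 100-replicate simulation studies for
the model ladder — sizes at which the targeted effects are decisively
resolvable on a single CPU in minutes. Every stochastic element flows from
an explicit seed; the pipeline's stage seeds derive from one global seed
through `SeedSequence` combined with a CRC-32 stage tag, so stages are
independently reproducible and identical configuration + seed yields
byte-identical reports.

## Known limitations

- Real-data ingest expects calibrated µm s⁻²; the instrument conversion
  chain (preamplifier gain, counts-to-velocity/acceleration) must be
  applied upstream, and no instrument-response deconvolution is performed.
- The closure detector assumes the exponential-recovery closure profile;
  strongly different response shapes (slow adductions, flapping/swimming)
  would need a different kernel.
- The exact 24.0-h grid point requires whole-day records; arbitrary-length
  records resolve the diel peak only to the Fourier spacing.
- Mixed-model denominator df are residual-based (see above); reported
  F/p values are asymptotically, not small-sample, calibrated.
- Timezone handling is by convention (records start at local midnight);
  daylight-saving shifts inside a deployment are not modeled.
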