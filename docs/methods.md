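# Methods

This note documents the models behind `wormrhythm`, the parameters that
matter, the numerical choices, and what the synthetic-data generator does
and does not emulate.

## Conventions

* Body coordinate *c* ∈ [0, 1]: 0 at the head tip, 1 at the tail tip.
* Curvature sign: positive for bends toward the left of the local
  head→tail direction.  The choice is arbitrary but fixed; mirror-imaging a
  midline negates curvature exactly.
* Velocity sign: motion of the body mid-point toward the head is positive.
* Wave-speed sign: head→tail bend propagation (forward locomotion) is
  positive.
* Currents: inward is negative; a "−50 pA gate" admits events with
  amplitude ≤ −50 pA.  Discharge (charge transfer) is reported as a
  positive magnitude in pC.

## Synthetic-data generator

### Midlines

A worm is a tangent-angle field integrated along arc length at uniform
spacing, so arc length equals `body_length` exactly (before coordinate
noise):

    θ(c, t) = A·sin(2π(c/λ − s·t/T)) + head term (anterior 20 % only)

with s = +1 (forward), −1 (backward), and a temporally phase-static
spatial sinusoid with a slow random phase drift for the kinker mode
(deep bends, no propagation, near-zero displacement).  `pause` sets A = 0.
Rigid translation moves the body along its axis toward the head (forward)
or tail (backward).  The true wave speed is s·λ/T in body coordinate/s;
per-frame ground-truth state labels follow the ±1 px/s rule applied to the
signed translation speed.

Defaults: 10 frames/s (plate-tracking rate), 33 points, body length
320 px, A = 0.5 rad, λ = 0.6 body lengths, T = 2 s, translation
30 px/s — a crawling adult covers roughly a tenth of its body length per
second, and one undulation spans a bit over half the body.  Coordinate
noise defaults to 0; analyses that must tolerate noise are tested with it
explicitly (1 % of body length in the wave-speed sweep).

The kinker phase drift is deliberately slow (random-walk increments of
4 mrad/frame, smoothed): a stalled worm's mid-point must stay inside the
±1 px/s pause band, and the measured drift-induced velocity stays below
~0.5 px/s over hundreds of frames.

### Calcium

GCaMP carries a half-rectified sinusoid (the indicator reports calcium
rises; between pulses the trace sits at baseline):

    GCaMP(t) = G₀·(1 + a·max(0, sin(2πt/P + φ)))·bleach(t)·motion(t) + shot noise
    RFP(t)   = R₀·bleach(t)·motion(t) + shot noise

`bleach(t) = exp(−t/τ_b)` and the motion process (a smoothed, positive,
low-frequency multiplicative factor) are applied **bit-identically** to
both channels of a neuron, so the ratio cancels them exactly when shot
noise is zero.  Ground-truth events are the oscillation peaks; per-neuron
phase offsets φ are free parameters (an anti-phasic pair is φ = π apart).
Defaults: P = 50 s, a = 0.5, τ_b = 600 s, 10 samples/s (100 ms frames),
5 % motion amplitude.  The amplitude of real somatic transients varies
strongly from cycle to cycle; the generator keeps a fixed amplitude and
leaves variance to the noise terms, so tests say nothing about
amplitude-variability robustness.

### Current traces

Baseline Gaussian noise (1.5 pA) plus Poisson-timed miniature-PSC kernels
(instant rise, single-exponential decay, τ = 3 ms — an event-detection
stand-in, not a biophysical claim) at 25 Hz with amplitudes jittered
around −10 pA.  Rhythmic bursts start at (k + ½)·interval and are regular
trains at `burst_event_rate` for `burst_duration` with amplitudes drawn
from `burst_amplitude_range`; defaults: 90 s interval, 2.5 s duration,
5 Hz, −50 to −300 pA.  A sampling rate below 10 samples per decay tau is
rejected.

## Posture analysis

Resampling is linear interpolation at equal arc-length targets; degenerate
frames (zero arc length) are flagged invalid and propagate as missing
data — never silently interpolated.  Per-joint curvature is the turning
angle between adjacent segments divided by the joint spacing (1/32 body
coordinate for 33 points): for 33 points on a circular arc subtending Θ
this yields exactly Θ at every joint.

Mid-point velocity projects the mid-point displacement onto the average
tail→head axis of the two frames involved, so the sign is well defined
even for curled postures; a 5-frame boxcar (0.5 s at 10 fps) smooths the
result by default (the original analyses do not state their smoothing; the
window is logged and configurable).  Both mid-point and centroid reference
points are available behind one flag, since published velocity panels mix
the two without stating whether they differ.

Threshold tie-break: velocities of exactly ±1 px/s are "pause" — the
literal reading of "between −1 and +1 px/s".  The ±1 px/s values are
magnification-bound (10× objective) and are kept in px/s; physical-unit
conversion is available when a pixel scale is provided.

The curvature-distribution window defaults to 33–96 % of body length,
excluding the head (foraging swings) and tail tip.

## Wave speed

The estimator is the pointwise gradient ratio −(∂κ/∂t)/(∂κ/∂C); for any
field κ(c − vt) it returns exactly v.  Numerics:

* Gradients are derivative-of-Gaussian filters sharing one 2-D smoothing
  kernel, so the kernel's band attenuation cancels exactly in the ratio
  (separate smoothing followed by central differences would bias the ratio
  by the axis-dependent sinc factor — up to ~6 % at 10 fps with fast
  waves).  The sampled DoG kernel's gain is calibrated on a unit ramp so
  linear fields differentiate exactly.
* Division control: entries where |∂κ/∂C| falls below a quantile (default
  10th percentile) are masked, not regularised — masking keeps the
  estimator unbiased where defined.  Filter borders (2σ) are masked too.
* `compute_gradients` defaults to σ_t = 0.3 s and σ_c = 1.5 joint
  spacings.  The scalar `estimate_wave_speed` instead adapts both sigmas
  to 1/6 of the dominant period and wavelength read from the peak of the
  kymogram's 2-D power spectrum: a travelling wave occupies one spectral
  cell while broadband coordinate noise spreads over all of them, so the
  peak stays findable well below per-pixel SNR of 1, and matched
  band-limiting suppresses the noise without touching the ratio.  The
  spectrum is used only to choose smoothing scales — the speed itself is
  always the gradient ratio.
* The summary statistic over a map is the median of defined entries
  (robust to residual ratio outliers); within reversal bouts the regional
  values are means of defined entries, as the original definition
  prescribes, reported as magnitudes with the signed mean alongside.

Reversal bouts are maximal runs of backward frames with duration ≥ 3 s
(closed boundary; a 30-frame run at 10 fps counts) and no gap tolerance —
strictness is the reproducible choice when no gap rule is published.

Measured recovery (the acceptance suite re-measures this on every run):
over a 20-configuration sweep λ ∈ [0.3, 1.0], T ∈ [1, 10] s, the
noise-free worst-case error is ~1.5 % with 20/20 correct signs; with
coordinate noise of 1 % of body length, ~5–8 %.

## Calcium analysis

R₀ is the 10th percentile of the ratio (global by default; a
running-quantile variant with a configurable window is available for
recordings with residual drift — the ratio already cancels common-mode
drift, so the deterministic global quantile is the default).  ΔR/R₀ =
(R − R₀)/R₀.

Event detection smooths ΔR/R₀ with a 2 s Gaussian (an order of magnitude
below the slowest relevant period; necessary because dividing by a bleached
RFP amplifies shot noise late in long recordings), then takes peaks with

* prominence ≥ 0.2 × (95th − 5th percentile range),
* height ≥ 5th percentile + 0.4 × range (rejects noise bumps on the
  quiescent half-cycle; disable with `height_frac=None`),
* separation ≥ 5 s.

All thresholds are percentile-derived, so detection is invariant to affine
rescaling of the trace.  "Mean activity" is the time-average of
max(ΔR/R₀, 0); the alternative integral-of-ratio measure is available and
labeled.

Phase analysis finds the dominant shared frequency at the cross-spectrum
peak (restricted to frequencies with ≥ 3 cycles in the record), builds
band-limited analytic signals with a one-sided Gaussian filter (relative
bandwidth 0.5), and reports the circular mean of the instantaneous phase
difference with the mean resultant length as coherence; pairs below
coherence 0.2 are flagged unreliable.  The offset is antisymmetric under
pair swap to machine precision by construction.  Offsets are reported in
radians and cycle fractions (published phase panels do not state their
units).  Analytic-signal phase was preferred over peak-time matching
because it tolerates the asymmetric waveforms of rectified calcium
transients; peak-lag remains available as a cross-check via event times.

## Electrophysiology

The detection baseline is a binned running median (1 s bins,
interpolated) — robust to PSCs, which occupy a few percent of samples.
PSCs are runs of baseline-subtracted samples below the −5 pA floor, merged
within a 2 ms refractory window; the event amplitude is the trough.
Template matching is deliberately not the default: no published detector
description exists to match against, and threshold crossing is
transparent.

Bursts cluster events with amplitude ≤ −50 pA (what separates burst
currents from the ~−10 pA mPSC background) at inter-event gaps ≤ 0.5 s,
keeping clusters spanning ≥ 1 s at ≥ 3 Hz.  Boundary comparisons carry a
1 % tolerance so a burst sitting exactly on a criterion (a 3 Hz train
against the 3 Hz floor) is not rejected by sampling quantization.  When
the generator places burst amplitudes at exactly −50 pA, recovery tests
gate at −40 pA instead — the midpoint between the mPSC scale and the
smallest burst events — because measurement noise makes a closed boundary
at the generative value a coin flip.  All four thresholds are exposed on
the CLI.

Discharge integrates max(0, baseline − I(t)) over the burst window (padded
50 ms for the final decay) against a baseline estimated from the samples
*outside* all burst windows: a running median would sag during a
multi-second burst and corrupt the integral, whereas the outside-window
median leaves a rectangular −100 pA, 2 s deviation at exactly 200 pC.

Spectra are Welch periodograms of the baseline-subtracted segment (4 s
windows by default, 0.25 Hz resolution), with the peak reported in a
configurable band defaulting to 1–20 Hz (covering the 3–10 Hz intra-burst
band).

## Statistics

* KS test: two-sided, asymptotic (classical Smirnov) p-values.  The exact
  small-sample null is so discrete that rejecting at α = 0.05 fires at
  ~1 % for n = 10 per group; the asymptotic formula stays near nominal
  (the calibration suite measures ~5 % over 1000 null replicates) and
  matches what the usual desktop analysis packages compute.
* Mann–Whitney U: two-sided, exact for n ≤ 20 per group, normal
  approximation beyond; all-tied input is flagged degenerate with p = 1.
* ANOVA: one-way, with pairwise two-sided t tests Bonferroni-adjusted
  (p × number of pairs, capped at 1).  No correction is applied across
  separate analyses, matching common reporting practice.
* SEM uses the n − 1 standard deviation.  Stars: * 0.01<p<0.05,
  ** 0.001<p<0.01, *** p<0.001.

## What passing tests do and do not show

The generator produces idealized records: sinusoidal bends on a rigid
translation (no viscoelastic body mechanics, no omega turns), fixed-
amplitude rectified calcium oscillations, and instant-rise exponential
PSCs with regular intra-burst trains.  Parameter recovery on these records
validates the estimators' correctness and calibration — it does not
demonstrate robustness to segmentation failures, neuron misidentification,
amplitude drift within a recording, overlapping burst/mPSC kinetics, or
non-stationary rhythms.  Frames that fail midline extraction propagate as
missing data throughout, but no attempt is made to recover them.

Problem sizes used by the test and acceptance suites: 200–600-frame
midline movies (20–60 s at 10 fps), 300–600 s calcium records at 10
samples/s, 60–360 s current traces at 5–10 kHz, and 1000-replicate null
calibrations at n = 10 per group — sizes chosen to match the scale of the
corresponding real recordings while keeping a full run in seconds.
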