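# wormrhythm

Quantitative analysis of *C. elegans* locomotor and motor-neuron rhythms:
posture kymography, bending-wave speed, behavioral state classification,
ratiometric calcium-oscillation analysis, and rhythmic postsynaptic-current
(PSC) burst quantification — plus a synthetic-data generator with known
ground truth so that every stage of the pipeline can be verified by
parameter recovery.

## Who this is for

Labs studying the ventral-cord motor circuit ask whether A-class motor
neurons act as intrinsic oscillators: do bending waves still propagate when
premotor input is removed, do the neurons' calcium levels oscillate on
their own, and do muscles receive rhythmic synaptic drive?  Answering those
questions takes the same small set of measurements over and over — on
crawling movies, fluorescence traces and voltage-clamp recordings.  This
package implements that measurement set as a tested, reusable library.

## The analyses

**Posture and states.** A worm midline (ordered head-to-tail points per
frame) is resampled to 33 points equally spaced in arc length (32 body
segments).  At each interior joint the signed curvature is the turning
angle between adjacent segments divided by the joint spacing in body
coordinate *c* ∈ [0, 1] (head = 0), giving κ(c, t) in rad per unit body
length; stacked over time this is the curvature kymogram, in which a
traveling bend is a diagonal stripe.  The body mid-point's displacement per
frame, projected on the tail→head axis, gives a signed velocity v (px/s,
positive toward the head); frames are classified as

* forward: v > +1 px/s
* backward: v < −1 px/s
* pause: −1 ≤ v ≤ +1 px/s (boundaries inclusive)

and state propensities are the per-state fractions of labeled frames.

**Wave speed.** The bending-wave propagation speed is the gradient ratio

    speed(c, t) = −(∂κ/∂t) / (∂κ/∂C)    [body coordinate / s]

positive for head→tail propagation.  Gradients are derivative-of-Gaussian
filtered; entries with |∂κ/∂C| below a quantile are masked rather than
regularised.  Reversal bouts (maximal backward runs ≥ 3 s) are averaged
within anterior (5–25 %), mid-body (40–60 %) and posterior (75–95 %)
regions of the body.

**Calcium.** GCaMP and RFP are acquired simultaneously; the ratio
GCaMP/RFP cancels motion artifacts and photobleaching (any multiplicative
process common to both channels).  ΔR/R₀ uses a low-quantile baseline R₀.
Oscillation events are prominence-gated peaks of ΔR/R₀; frequency is
reported in events/min.  Pairwise phase offsets come from the analytic
signal of traces band-passed at their dominant shared period, with the
mean resultant length as a coherence score — anti-phasic neuron pairs show
offsets of ≈ π.

**Electrophysiology.** Miniature PSCs (~−10 pA) are detected as
negative-going threshold crossings against a running-median baseline.
Rhythmic PSC bursts — seconds-long clusters of large (−50 to −300 pA)
events at 3–10 Hz recurring at ~90 s intervals — are segmented by
amplitude-gated event clustering; each burst reports duration, intra-burst
rate, peak amplitude and discharge (charge transfer, pC).  Welch spectra
localise the intra-burst rhythm.

**Statistics.** Two-sided Kolmogorov–Smirnov (distributions),
Mann–Whitney U (two groups), and one-way ANOVA with Bonferroni-corrected
pairwise t tests (many groups), with mean ± SEM summaries and the usual
star convention (* 0.01<p<0.05, ** 0.001<p<0.01, *** p<0.001).

## Worked example

```bash
python examples/ephys_bursts.py
```

prints (seed 4):

```
PSC events: 8751 in 360 s (24.3 Hz; median amplitude -10.6 pA)
rPSC bursts: 4 (0.67/min, mean inter-burst interval 90.0 s)
  burst at   45.0 s: 2.20 s, 5.0 Hz, discharge 9 pC
  burst at  135.0 s: 2.20 s, 5.0 Hz, discharge 9 pC
  burst at  225.0 s: 2.20 s, 5.0 Hz, discharge 8 pC
  burst at  315.0 s: 2.20 s, 5.0 Hz, discharge 9 pC
spectral peak inside first burst: 5.00 Hz (intra-burst rhythm, expected in the 3-10 Hz band)
```

The detector recovers the generator's ground truth: a ~25 Hz / −10 pA
miniature-PSC background, four bursts 90 s apart, each ~2 s of 5 Hz
large-amplitude events.  The other example scripts cover behavioral state
classification (`simulate_and_classify.py`), wave-speed estimation
(`wave_speed_demo.py`), multi-neuron phase analysis (`calcium_phases.py`)
and cohort statistics with report rendering (`group_comparison.py`).

A thin CLI wraps the same library:

```bash
wormrhythm simulate worm --seed 1 --out sim/
wormrhythm kymo sim/midline.wcon --out kymo.tsv
wormrhythm states sim/midline.csv --out states.csv
wormrhythm ephys current.csv --min-amp -40 --out summary.json
```

## Layout

```
src/wormrhythm/   synthetic, posture, wavespeed, calcium, ephys, stats, io,
                  report, cli
examples/         one narrative script per capability
tests/            pytest suite (unit + property + acceptance)
docs/methods.md   models, parameter choices, numerical details, limitations
```
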