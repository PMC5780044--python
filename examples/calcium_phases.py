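"""Ratiometric calcium analysis of three rhythmically active motor neurons.

Simulates dual-channel (GCaMP/RFP) traces for three neurons sharing a ~50 s
oscillatory cycle: a dorsal-innervating neuron anti-phasic (pi) to two
ventral-innervating ones, with a small lead between the latter pair.
Detects oscillation events on each GCaMP/RFP ratio and quantifies the
pairwise phase offsets from the analytic signal.
"""

import numpy as np

from wormrhythm.calcium import (compute_ratio, detect_oscillation_events,
                                phase_relationship)
from wormrhythm.synthetic import CalciumSimConfig, simulate_calcium

cfg = CalciumSimConfig(duration=500.0, period=50.0, n_neurons=3,
                       phase_offsets=(np.pi, 0.0, 0.5),  # DA-like, VA-like x2
                       motion_artifact_sd=0.05, shot_noise_sd=5.0, seed=3)
traces, truth = simulate_calcium(cfg)
names = ("dorsal_A", "ventral_A1", "ventral_A2")
ratios = []
for tr, name in zip(traces, names):
    tr.neuron = name
    r = compute_ratio(tr)
    ratios.append(r)
    ev = detect_oscillation_events(r)
    print(f"{name:11s}: {ev.n_events} oscillation events, "
          f"{ev.frequency:.2f} events/min, "
          f"median period {ev.median_period():.1f} s")

print()
for i, j in ((0, 1), (0, 2), (1, 2)):
    rel = phase_relationship(ratios[i], ratios[j])
    true = np.angle(np.exp(1j * (truth.phase_offsets[i]
                                 - truth.phase_offsets[j])))
    print(f"{names[i]} vs {names[j]}: offset {rel.offset:+.2f} rad "
          f"(true {true:+.2f}), coherence {rel.coherence:.2f}")
# An offset of ~+-3.14 rad is anti-phasic activity (dorsal vs ventral);
# ~0.5 rad is a consistent lead of one ventral neuron over the other.
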