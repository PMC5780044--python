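"""Compare synthetic cohorts the way ablation experiments are analysed.

Builds a 'control' cohort of forward crawlers and an 'ablated' cohort of
kinkers (deep standing bends, no propagation), compares their per-animal
curvature with the Kolmogorov-Smirnov test and their pause propensity with
the Mann-Whitney U test, and renders the figure-style report.
"""

import numpy as np

from wormrhythm.posture import (build_kymogram, classify_states,
                                curvature_distribution, midpoint_velocity,
                                propensity, resample_midline)
from wormrhythm.report import render_report
from wormrhythm.stats import compare_distributions, compare_groups_rank
from wormrhythm.synthetic import WormSimConfig, simulate_midline


def cohort(mode, seed0, **kw):
    return [simulate_midline(WormSimConfig(mode=mode, n_frames=400,
                                           seed=seed0 + i, **kw))[0]
            for i in range(10)]


control = cohort("forward", 100, wave_amplitude=0.5)
ablated = cohort("kinker", 200, wave_amplitude=0.8, translation_speed=0.0)


def curv_mean(w):
    return float(np.mean(curvature_distribution(
        build_kymogram(resample_midline(w)))))


def pause_frac(w):
    return propensity(classify_states(midpoint_velocity(w)))["pause"]


curv = {g: np.array([curv_mean(w) for w in ws])
        for g, ws in (("control", control), ("ablated", ablated))}
pause = {g: np.array([pause_frac(w) for w in ws])
         for g, ws in (("control", control), ("ablated", ablated))}

ks = compare_distributions(curv["control"], curv["ablated"],
                           labels=("control", "ablated"))
mwu = compare_groups_rank(pause["control"], pause["ablated"],
                          labels=("control", "ablated"))
print(f"per-animal |curvature|: control {curv['control'].mean():.2f} vs "
      f"ablated {curv['ablated'].mean():.2f} rad/bodycoord; "
      f"KS D={ks.statistic:.2f}, p={ks.p_value:.2g} ({ks.stars})")
print(f"pause propensity: control {pause['control'].mean():.2f} vs "
      f"ablated {pause['ablated'].mean():.2f}; "
      f"Mann-Whitney U={mwu.statistic:.0f}, p={mwu.p_value:.2g} ({mwu.stars})")

k = build_kymogram(resample_midline(ablated[0]))
files = render_report("scratch_report",
                      kymogram=k,
                      propensities={"control": {"forward": 1 - pause["control"].mean(),
                                                "backward": 0.0,
                                                "pause": pause["control"].mean()},
                                    "ablated": {"forward": 0.0, "backward": 0.0,
                                                "pause": pause["ablated"].mean()}},
                      comparisons=[ks, mwu],
                      parameters={"n_points": 33, "thresholds_px_per_s": (-1, 1)})
print("report written:", files)
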