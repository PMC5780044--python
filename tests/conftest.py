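import numpy as np
import pytest

from wormrhythm.synthetic import (CalciumSimConfig, EphysSimConfig,
                                  WormSimConfig, simulate_calcium,
                                  simulate_current_trace, simulate_midline)


@pytest.fixture(scope="session")
def forward_worm():
    cfg = WormSimConfig(mode="forward", n_frames=400, noise_sd=0.0, seed=11)
    return cfg, *simulate_midline(cfg)


@pytest.fixture(scope="session")
def backward_worm():
    cfg = WormSimConfig(mode="backward", n_frames=400, noise_sd=0.0, seed=12)
    return cfg, *simulate_midline(cfg)


@pytest.fixture(scope="session")
def calcium_pair():
    """Two neurons, 0.5 rad apart, moderate noise."""
    cfg = CalciumSimConfig(duration=500.0, period=50.0, n_neurons=2,
                           phase_offsets=(0.5, 0.0), shot_noise_sd=5.0,
                           motion_artifact_sd=0.05, seed=21)
    return cfg, *simulate_calcium(cfg)


@pytest.fixture(scope="session")
def burst_trace():
    cfg = EphysSimConfig(duration=270.0, sample_rate=5000.0,
                         burst_interval=90.0, burst_event_rate=5.0,
                         burst_amplitude_range=(-150.0, -150.0), seed=31)
    return cfg, *simulate_current_trace(cfg)


def circle_arc(n_points: int, radius: float, total_angle: float,
               start_angle: float = 0.0) -> np.ndarray:
    """n_points equally spaced along a circular arc (independent geometry oracle)."""
    t = start_angle + np.linspace(0.0, total_angle, n_points)
    return radius * np.stack([np.cos(t), np.sin(t)], axis=1)
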