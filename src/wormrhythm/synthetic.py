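"""Synthetic worm behavior and physiology generator.

Produces midline movies, dual-channel (GCaMP/RFP) fluorescence traces and
voltage-clamp current traces with known ground truth, emulating the kinds of
recordings used to characterise C. elegans A-class motor neuron rhythms:

* sinusoidal bending waves travelling head->tail (forward crawling) or
  tail->head (backward crawling), standing "kinker" bends, and decoupled
  head oscillation;
* slow (~50 s period) somatic calcium oscillations with channel-common
  photobleaching and motion artifacts;
* ~25 Hz, ~-10 pA miniature postsynaptic currents plus periodic rhythmic
  PSC bursts (~90 s apart, seconds long, 3-10 Hz, -50 to -300 pA events).

Every simulator returns the generated record together with a
:class:`GroundTruth` carrying the parameters an analysis should recover,
so each downstream stage can be verified by parameter recovery.

Conventions shared with the analysis modules: body coordinate c in [0, 1]
runs from head tip (0) to tail tip (1); inward currents are negative;
bending-wave speed is positive for head->tail propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .posture import MidlineSeries
from .calcium import DualChannelTrace
from .ephys import CurrentTrace

__all__ = [
    "WormSimConfig",
    "CalciumSimConfig",
    "EphysSimConfig",
    "GroundTruth",
    "simulate_midline",
    "simulate_calcium",
    "simulate_current_trace",
]

WormMode = Literal["forward", "backward", "kinker", "pause"]

#: fraction of the body (from the head tip) that carries the decoupled
#: head oscillation
HEAD_REGION = 0.2


@dataclass
class WormSimConfig:
    """Parameters of a simulated crawling (or stalled) worm.

    The bending wave is specified as a travelling tangent-angle sinusoid
    theta(c, t) = A sin(2 pi (c / wavelength - s t / wave_period)) with
    s = +1 (forward, bends propagate head->tail), -1 (backward), or a
    standing spatial sinusoid for ``kinker``.  ``pause`` sets A = 0.
    """

    n_frames: int = 200
    frame_rate: float = 10.0  # frames/s; plate recordings are at 10 fps
    n_points: int = 33
    body_length: float = 320.0  # px
    mode: WormMode = "forward"
    wave_amplitude: float = 0.5  # rad, peak tangent-angle bend
    wavelength: float = 0.6  # fraction of body length
    wave_period: float = 2.0  # s
    head_osc_amplitude: float = 0.0  # rad
    head_osc_period: float = 1.0  # s
    translation_speed: float = 30.0  # px/s, along the body axis
    noise_sd: float = 0.0  # px, additive coordinate noise
    seed: int = 0

    def validate(self) -> None:
        for name in ("frame_rate", "body_length", "wavelength", "wave_period",
                     "head_osc_period", "wave_amplitude", "head_osc_amplitude",
                     "translation_speed", "noise_sd"):
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_points < 5:
            raise ValueError("n_points must be >= 5")
        if self.wavelength <= 0 or self.wave_period <= 0 or self.frame_rate <= 0:
            raise ValueError("wavelength, wave_period and frame_rate must be > 0")
        if self.mode not in ("forward", "backward", "kinker", "pause"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class CalciumSimConfig:
    """Parameters of simulated dual-channel somatic calcium recordings.

    The GCaMP channel carries a half-rectified sinusoidal oscillation (the
    indicator reports calcium rises, not dips); both channels share an
    exponential bleach and a bit-identical multiplicative low-frequency
    motion process, so their ratio cancels both.
    """

    duration: float = 500.0  # s
    sample_rate: float = 10.0  # samples/s (100 ms per frame)
    n_neurons: int = 1
    period: float = 50.0  # s, the slow oscillatory cycle
    phase_offsets: Sequence[float] = (0.0,)  # rad, one per neuron
    osc_amplitude: float = 0.5  # peak dR/R0 of the oscillation
    baseline_gcamp: float = 100.0  # a.u.
    baseline_rfp: float = 200.0  # a.u.
    bleach_tau: float = 600.0  # s
    motion_artifact_sd: float = 0.05  # fractional, common to both channels
    shot_noise_sd: float = 0.0  # a.u., per channel
    seed: int = 0

    def validate(self) -> None:
        if self.period <= 0 or self.bleach_tau <= 0:
            raise ValueError("period and bleach_tau must be > 0")
        if self.osc_amplitude < 0 or self.motion_artifact_sd < 0 or self.shot_noise_sd < 0:
            raise ValueError("amplitudes and noise levels must be >= 0")
        if self.period >= self.duration:
            raise ValueError("period must be < duration (need at least one full cycle)")
        if len(self.phase_offsets) != self.n_neurons:
            raise ValueError("phase_offsets must have one entry per neuron")
        if self.baseline_rfp <= 0 or self.baseline_gcamp <= 0:
            raise ValueError("channel baselines must be > 0")


@dataclass
class EphysSimConfig:
    """Parameters of a simulated voltage-clamp current trace (inward < 0)."""

    duration: float = 360.0  # s
    sample_rate: float = 10000.0  # Hz
    mpsc_rate: float = 25.0  # Hz, Poisson miniature PSC rate
    mpsc_amplitude_mean: float = -10.0  # pA
    mpsc_amplitude_sd: float = 2.0  # pA, jitter of mPSC amplitudes
    mpsc_decay_tau: float = 0.003  # s
    burst_interval: float = 90.0  # s, rhythmic burst period
    burst_duration: float = 2.5  # s
    burst_event_rate: float = 5.0  # Hz, intra-burst event rate
    burst_amplitude_range: tuple[float, float] = (-300.0, -50.0)  # pA
    baseline_noise_sd: float = 1.5  # pA
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.burst_duration < self.burst_interval):
            raise ValueError("require 0 < burst_duration < burst_interval")
        if self.mpsc_rate <= 0 or self.burst_event_rate <= 0 or self.sample_rate <= 0:
            raise ValueError("rates must be > 0")
        if self.mpsc_amplitude_mean >= 0:
            raise ValueError("mpsc_amplitude_mean must be negative (inward)")
        lo, hi = self.burst_amplitude_range
        if lo >= 0 or hi >= 0:
            raise ValueError("burst amplitudes must be negative (inward)")
        if self.sample_rate * self.mpsc_decay_tau < 10:
            raise ValueError(
                "sample_rate too low to resolve mpsc_decay_tau "
                "(need >= 10 samples per tau)")


@dataclass
class GroundTruth:
    """What the simulator knows and the analysis should recover."""

    state_labels: np.ndarray | None = None  # per-frame behavioral state
    wave_speed: float | None = None  # body coordinate / s, signed
    event_times: list[np.ndarray] = field(default_factory=list)  # per neuron/trace
    phase_offsets: np.ndarray | None = None  # rad, per neuron
    period: float | None = None  # s
    burst_windows: np.ndarray | None = None  # (n_bursts, 2) start/end in s
    burst_event_times: list[np.ndarray] = field(default_factory=list)
    mpsc_times: np.ndarray | None = None
    mode: str | None = None
    translation_speed: float | None = None  # signed px/s, + toward head


def _state_from_translation(signed_speed: float) -> str:
    """State implied by the signed translation speed under the +-1 px/s rule."""
    if signed_speed > 1.0:
        return "forward"
    if signed_speed < -1.0:
        return "backward"
    return "pause"


def simulate_midline(config: WormSimConfig) -> tuple[MidlineSeries, GroundTruth]:
    """Simulate a worm midline movie.

    The worm is built per frame by integrating the tangent angle along arc
    length at uniform spacing, so the arc length equals ``body_length``
    exactly (before coordinate noise).  The head lies at body coordinate 0;
    the unbent body extends along +x, so translation toward the head is
    along -x.

    Returns the midline series and a :class:`GroundTruth` with per-frame
    state labels, the signed true wave speed (wavelength / period, positive
    head->tail) and the signed translation speed (+ toward head).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n, p = config.n_frames, config.n_points
    ds = config.body_length / (p - 1)
    t = np.arange(n) / config.frame_rate
    # tangent angles are defined on the p-1 segments, at segment midpoints
    c_seg = (np.arange(p - 1) + 0.5) / (p - 1)

    direction = {"forward": 1.0, "backward": -1.0}.get(config.mode, 0.0)
    amp = 0.0 if config.mode == "pause" else config.wave_amplitude

    if config.mode == "kinker":
        # spatial sinusoid, static in time apart from a slow phase jitter:
        # deep local bends that do not propagate and barely move the body
        jitter = rng.standard_normal(n) * 0.004
        jitter = gaussian_filter1d(np.cumsum(jitter), 10.0, mode="nearest")
        phase_t = jitter
    else:
        phase_t = direction * t / config.wave_period

    theta = amp * np.sin(
        2 * np.pi * (c_seg[None, :] / config.wavelength - phase_t[:, None]))

    if config.head_osc_amplitude > 0:
        taper = np.clip(1.0 - c_seg / HEAD_REGION, 0.0, 1.0)
        head = (config.head_osc_amplitude
                * np.sin(2 * np.pi * t / config.head_osc_period))
        theta = theta + head[:, None] * taper[None, :]

    x = np.empty((n, p))
    y = np.empty((n, p))
    x[:, 0] = 0.0
    y[:, 0] = 0.0
    np.cumsum(ds * np.cos(theta), axis=1, out=x[:, 1:])
    np.cumsum(ds * np.sin(theta), axis=1, out=y[:, 1:])

    # rigid translation along the body axis: -x is toward the head
    offset = -direction * config.translation_speed * t
    x += offset[:, None]

    points = np.stack([x, y], axis=-1)
    if config.noise_sd > 0:
        points = points + rng.normal(0.0, config.noise_sd, size=points.shape)

    series = MidlineSeries(points=points, frame_rate=config.frame_rate)

    signed_speed = direction * config.translation_speed
    label = _state_from_translation(signed_speed)
    truth = GroundTruth(
        state_labels=np.full(n, label, dtype=object),
        wave_speed=direction * config.wavelength / config.wave_period,
        mode=config.mode,
        translation_speed=signed_speed,
    )
    return series, truth


def _motion_process(rng: np.random.Generator, n: int, sd: float,
                    sample_rate: float, corr_time: float = 5.0) -> np.ndarray:
    """Positive multiplicative low-frequency motion artifact, mean ~1."""
    if sd == 0:
        return np.ones(n)
    raw = rng.standard_normal(n)
    sigma = corr_time * sample_rate
    smooth = gaussian_filter1d(raw, sigma, mode="nearest")
    s = smooth.std()
    if s > 0:
        smooth = smooth / s
    return np.clip(1.0 + sd * smooth, 0.05, None)


def simulate_calcium(config: CalciumSimConfig) -> tuple[list[DualChannelTrace], GroundTruth]:
    """Simulate dual-channel (GCaMP, RFP) traces for ``n_neurons`` neurons.

    GCaMP carries the half-rectified sinusoidal calcium oscillation; RFP is
    calcium-insensitive.  Bleaching exp(-t/bleach_tau) and one multiplicative
    motion process per neuron are applied bit-identically to both channels,
    so the GCaMP/RFP ratio recovers the oscillation exactly when shot noise
    is zero.  Ground-truth event times are the oscillation peaks
    (sin phase = pi/2) inside the recording.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate

    traces: list[DualChannelTrace] = []
    events: list[np.ndarray] = []
    for i in range(config.n_neurons):
        phi = float(config.phase_offsets[i])
        osc = np.maximum(0.0, np.sin(2 * np.pi * t / config.period + phi))
        gc_clean = config.baseline_gcamp * (1.0 + config.osc_amplitude * osc)
        rfp_clean = np.full(n, config.baseline_rfp)

        bleach = np.exp(-t / config.bleach_tau)
        motion = _motion_process(rng, n, config.motion_artifact_sd,
                                 config.sample_rate)
        common = bleach * motion
        gcamp = gc_clean * common
        rfp = rfp_clean * common
        if config.shot_noise_sd > 0:
            gcamp = gcamp + rng.normal(0, config.shot_noise_sd, n)
            rfp = rfp + rng.normal(0, config.shot_noise_sd, n)

        traces.append(DualChannelTrace(
            time=t.copy(), gcamp=gcamp, rfp=rfp, neuron=f"neuron_{i}"))

        # peaks of sin(2 pi t / period + phi): 2 pi t/P + phi = pi/2 + 2 pi k
        peak = config.period * (0.25 - phi / (2 * np.pi)
                                + np.arange(-2, config.duration / config.period + 2))
        peak = peak[(peak >= 0) & (peak < config.duration)]
        events.append(peak)

    truth = GroundTruth(
        event_times=events,
        phase_offsets=np.asarray(config.phase_offsets, dtype=float),
        period=config.period,
    )
    return traces, truth


def _add_kernels(current: np.ndarray, times: np.ndarray, amps: np.ndarray,
                 tau: float, sample_rate: float) -> None:
    """Add instant-rise, exponential-decay PSC kernels in place."""
    n = current.size
    klen = int(np.ceil(8 * tau * sample_rate))
    kernel = np.exp(-np.arange(klen) / (tau * sample_rate))
    for t0, a in zip(times, amps):
        i0 = int(np.round(t0 * sample_rate))
        if i0 >= n:
            continue
        seg = min(klen, n - i0)
        current[i0:i0 + seg] += a * kernel[:seg]


def simulate_current_trace(config: EphysSimConfig) -> tuple[CurrentTrace, GroundTruth]:
    """Simulate a whole-cell voltage-clamp current trace.

    Baseline Gaussian noise plus Poisson-timed miniature PSCs, plus rhythmic
    PSC bursts: the k-th burst starts at (k + 1/2) * burst_interval and is a
    regular train of large-amplitude events at ``burst_event_rate`` lasting
    ``burst_duration``.  Ground truth stores mPSC times, per-burst event
    times and burst windows.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate

    current = np.zeros(n)
    if config.baseline_noise_sd > 0:
        current += rng.normal(0.0, config.baseline_noise_sd, n)

    # Poisson mPSCs
    n_mpsc = rng.poisson(config.mpsc_rate * config.duration)
    mpsc_times = np.sort(rng.uniform(0, config.duration, n_mpsc))
    mpsc_amps = np.minimum(
        rng.normal(config.mpsc_amplitude_mean, config.mpsc_amplitude_sd, n_mpsc),
        -1.0)
    _add_kernels(current, mpsc_times, mpsc_amps, config.mpsc_decay_tau,
                 config.sample_rate)

    # rhythmic bursts at (k + 1/2) * interval
    starts = []
    s = config.burst_interval / 2
    while s + config.burst_duration <= config.duration:
        starts.append(s)
        s += config.burst_interval
    burst_windows = []
    burst_events = []
    lo, hi = sorted(config.burst_amplitude_range)
    for s0 in starts:
        n_ev = max(2, int(round(config.burst_event_rate * config.burst_duration)))
        ev = s0 + np.arange(n_ev) / config.burst_event_rate
        amps = rng.uniform(lo, hi, n_ev)
        _add_kernels(current, ev, amps, config.mpsc_decay_tau, config.sample_rate)
        burst_events.append(ev)
        burst_windows.append((ev[0], ev[-1]))

    trace = CurrentTrace(time=t, current=current, sample_rate=config.sample_rate)
    truth = GroundTruth(
        mpsc_times=mpsc_times,
        burst_windows=np.array(burst_windows).reshape(-1, 2),
        burst_event_times=burst_events,
        event_times=[mpsc_times],
    )
    return trace, truth
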