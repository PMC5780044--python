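"""Ratiometric calcium-trace analysis.

GCaMP (calcium-sensitive) and RFP (calcium-insensitive) channels are
acquired simultaneously; dividing them cancels any multiplicative process
common to both — photobleaching and motion artifacts — leaving the
calcium-driven signal.  From the ratio trace the module detects slow
oscillation events (prominence-gated peaks of dR/R0), reports their
frequency in events/min and a mean-activity measure, and quantifies
pairwise phase relationships between simultaneously recorded neurons via
the analytic signal of band-passed traces (e.g. the anti-phasic dorsal vs
ventral motor-neuron pattern appears as an offset of ~pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import csd, find_peaks

__all__ = [
    "DualChannelTrace",
    "RatioTrace",
    "OscillationEvents",
    "PhaseRelation",
    "compute_ratio",
    "detect_oscillation_events",
    "phase_relationship",
    "group_summary",
]


@dataclass
class DualChannelTrace:
    """Simultaneously acquired GCaMP and RFP fluorescence of one neuron."""

    time: np.ndarray  # s, strictly increasing
    gcamp: np.ndarray  # a.u.
    rfp: np.ndarray  # a.u.
    neuron: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.gcamp = np.asarray(self.gcamp, dtype=float)
        self.rfp = np.asarray(self.rfp, dtype=float)
        if not (self.time.size == self.gcamp.size == self.rfp.size):
            raise ValueError("time, gcamp and rfp must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class RatioTrace:
    """GCaMP/RFP ratio with baseline R0 and normalised dR/R0."""

    time: np.ndarray
    ratio: np.ndarray
    baseline: float | np.ndarray  # R0 (scalar, or per-sample if running)
    drr: np.ndarray  # (ratio - R0) / R0
    valid: np.ndarray  # per-sample validity (rfp above floor)
    neuron: str = ""

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class OscillationEvents:
    """Detected calcium-oscillation events of one recording."""

    peak_times: np.ndarray  # s
    peak_amplitudes: np.ndarray  # dR/R0 at the peaks
    frequency: float  # events per minute
    mean_activity: float  # time-average of max(dR/R0, 0)
    duration: float  # s of valid trace analysed
    neuron: str = ""

    @property
    def n_events(self) -> int:
        return self.peak_times.size

    def median_period(self) -> float:
        """Median inter-peak interval (s); NaN with < 2 events."""
        if self.peak_times.size < 2:
            return float("nan")
        return float(np.median(np.diff(self.peak_times)))


@dataclass
class PhaseRelation:
    """Phase offset (a minus b) between two neurons at their shared period."""

    pair: tuple[str, str]
    offset: float  # rad in (-pi, pi]
    period: float  # s, dominant shared period
    coherence: float  # mean resultant length in [0, 1]
    reliable: bool  # coherence above the floor

    @property
    def offset_cycles(self) -> float:
        """Offset as a fraction of a cycle in (-0.5, 0.5]."""
        return self.offset / (2 * np.pi)


def compute_ratio(t: DualChannelTrace, baseline_quantile: float = 0.10,
                  rfp_floor: float = 1e-6,
                  baseline_window: float | None = None) -> RatioTrace:
    """GCaMP/RFP ratio with a low-quantile baseline R0.

    R0 defaults to the global ``baseline_quantile`` (10th percentile) of the
    ratio over valid samples; pass ``baseline_window`` (seconds, typically
    twice the dominant period) for a running-quantile baseline robust to
    residual drift.  Samples where RFP falls below ``rfp_floor`` are flagged
    invalid and excluded.
    """
    valid = t.rfp > rfp_floor
    if not np.any(valid):
        raise ValueError("no samples with rfp above floor")
    ratio = np.full(t.time.size, np.nan)
    ratio[valid] = t.gcamp[valid] / t.rfp[valid]
    if baseline_window is None:
        r0: float | np.ndarray = float(np.quantile(ratio[valid], baseline_quantile))
    else:
        dt = float(np.median(np.diff(t.time)))
        half = max(1, int(round(baseline_window / dt / 2)))
        r0 = np.array([
            np.nanquantile(ratio[max(0, i - half):i + half + 1], baseline_quantile)
            for i in range(ratio.size)])
    if np.any(np.asarray(r0) <= 0):
        raise ValueError("baseline R0 must be positive; check the input channels")
    drr = (ratio - r0) / r0
    return RatioTrace(time=t.time, ratio=ratio, baseline=r0, drr=drr,
                      valid=valid, neuron=t.neuron)


def detect_oscillation_events(r: RatioTrace, prominence_frac: float = 0.2,
                              min_separation: float = 5.0,
                              smooth_sigma: float = 2.0,
                              height_frac: float | None = 0.4,
                              min_duration: float = 30.0) -> OscillationEvents:
    """Detect oscillation events as prominent peaks of dR/R0.

    The trace is Gaussian-smoothed (``smooth_sigma`` seconds, an order of
    magnitude below the tens-of-seconds oscillations of interest but enough
    to suppress shot noise, which the ratio amplifies late in bleached
    recordings), then peaks with prominence >= ``prominence_frac`` times the
    5th-95th percentile range and pairwise separation >= ``min_separation``
    are kept.  ``height_frac`` additionally requires peaks to rise to that
    fraction of the percentile range above the 5th percentile, rejecting
    noise bumps on the quiescent half of the cycle (set None to disable);
    both thresholds are percentile-derived, so detection is invariant to
    affine rescaling of the trace.  Frequency is events per minute of valid trace; mean activity
    is the time-average of dR/R0 clipped below at zero.
    """
    good = r.valid & np.isfinite(r.drr)
    duration = r.duration
    if duration < min_duration:
        raise ValueError(f"trace shorter than {min_duration} s of valid data")
    dt = float(np.median(np.diff(r.time)))
    x = r.drr.copy()
    if np.any(~good):
        x[~good] = np.interp(r.time[~good], r.time[good], r.drr[good])
    if smooth_sigma > 0:
        x = gaussian_filter1d(x, smooth_sigma / dt, mode="nearest")
    lo, hi = np.percentile(x, [5, 95])
    rng = hi - lo
    if rng <= 0:
        peaks = np.array([], dtype=int)
    else:
        height = lo + height_frac * rng if height_frac is not None else None
        peaks, _ = find_peaks(x, prominence=prominence_frac * rng,
                              height=height,
                              distance=max(1, int(round(min_separation / dt))))
    times = r.time[peaks]
    amps = x[peaks]
    freq = times.size / duration * 60.0
    activity = float(np.mean(np.clip(r.drr[good], 0, None)))
    return OscillationEvents(peak_times=times, peak_amplitudes=amps,
                             frequency=freq, mean_activity=activity,
                             duration=duration, neuron=r.neuron)


def _analytic_band(x: np.ndarray, fs: float, f0: float,
                   rel_bandwidth: float = 0.5) -> np.ndarray:
    """Band-limited analytic signal: one-sided Gaussian band-pass around f0."""
    n = x.size
    X = np.fft.fft(x - x.mean())
    f = np.fft.fftfreq(n, d=1.0 / fs)
    sigma_f = rel_bandwidth * f0 / 2
    H = np.zeros(n)
    pos = f > 0
    H[pos] = 2.0 * np.exp(-0.5 * ((f[pos] - f0) / sigma_f) ** 2)
    return np.fft.ifft(X * H)


def phase_relationship(a: RatioTrace, b: RatioTrace,
                       coherence_floor: float = 0.2,
                       min_cycles: float = 3.0) -> PhaseRelation:
    """Phase offset (a minus b) at the dominant shared period.

    The dominant shared frequency is the peak of the cross-spectral density
    magnitude; both traces are band-passed there with a one-sided Gaussian
    filter giving the analytic signal directly, and the offset is the
    circular mean of the instantaneous phase difference, with the mean
    resultant length as coherence.  Offsets are antisymmetric under pair
    swap by construction.
    """
    if a.time.size != b.time.size or not np.allclose(a.time, b.time):
        raise ValueError("traces must share the same time base")
    fs = a.sample_rate
    duration = a.duration
    xa = np.where(np.isfinite(a.drr), a.drr, 0.0)
    xb = np.where(np.isfinite(b.drr), b.drr, 0.0)

    nper = min(xa.size, max(256, int(duration * fs / 2)))
    f, pxy = csd(xa, xb, fs=fs, nperseg=nper)
    # frequencies resolvable with >= min_cycles full cycles in the record
    ok = f >= min_cycles / duration
    if not np.any(ok):
        raise ValueError("record too short: no frequency with enough cycles")
    f0 = float(f[ok][np.argmax(np.abs(pxy[ok]))])

    za = _analytic_band(xa, fs, f0)
    zb = _analytic_band(xb, fs, f0)
    good = (np.abs(za) > 0) & (np.abs(zb) > 0)
    phasor = (za[good] / np.abs(za[good])) * np.conj(zb[good] / np.abs(zb[good]))
    mean_phasor = phasor.mean()
    offset = float(np.angle(mean_phasor))
    coherence = float(np.abs(mean_phasor))
    return PhaseRelation(pair=(a.neuron, b.neuron), offset=offset,
                         period=1.0 / f0, coherence=coherence,
                         reliable=coherence >= coherence_floor)


@dataclass
class GroupSummary:
    """Per-group oscillation summary with raster rows (one per animal)."""

    raster: list[np.ndarray]
    frequencies: np.ndarray
    activities: np.ndarray
    mean_frequency: float
    sem_frequency: float
    mean_activity: float
    sem_activity: float
    n: int


def group_summary(events: list[OscillationEvents]) -> GroupSummary:
    """Summarise recordings: raster of event times, mean +- SEM statistics.

    SEM uses the n-1 denominator and is NaN for a single recording.
    """
    if not events:
        raise ValueError("need at least one recording")
    freqs = np.array([e.frequency for e in events])
    acts = np.array([e.mean_activity for e in events])
    n = len(events)

    def sem(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    return GroupSummary(
        raster=[e.peak_times for e in events],
        frequencies=freqs, activities=acts,
        mean_frequency=float(freqs.mean()), sem_frequency=sem(freqs),
        mean_activity=float(acts.mean()), sem_activity=sem(acts),
        n=n)
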