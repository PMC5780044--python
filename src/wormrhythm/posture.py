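"""Posture kinematics: midlines -> curvature kymograms, velocity, states.

The raw record is a time series of ordered 2-D midline points (head first).
This module resamples midlines to a fixed number of points equally spaced in
arc length (33 by convention, i.e. 32 body segments), computes the signed
curvature at every interior joint from the turning angle between adjacent
segments, tracks the body mid-point to obtain a signed crawling velocity
(+ toward the head), classifies frames into forward / backward / pause using
the +-1 px/s rule, and summarises state propensities and body-curvature
distributions.

Body coordinate c runs from 0 at the head tip to 1 at the tail tip.
Curvature sign is positive for bends toward the left of the local
head-to-tail direction (the convention is arbitrary but fixed; mirror
imaging the midline negates it exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "MidlineSeries",
    "CurvatureKymogram",
    "VelocityTrace",
    "StateSequence",
    "resample_midline",
    "compute_curvature",
    "build_kymogram",
    "midpoint_velocity",
    "classify_states",
    "propensity",
    "curvature_distribution",
]

STATES = ("forward", "backward", "pause")


@dataclass
class MidlineSeries:
    """Ordered midline points per frame, head first.

    points has shape (n_frames, n_points, 2) in px; ``valid`` flags frames
    that survived extraction (invalid frames propagate as missing data).
    """

    points: np.ndarray
    frame_rate: float
    pixel_scale: float | None = None  # um/px, optional
    valid: np.ndarray | None = None  # (n_frames,) bool

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[-1] != 2:
            raise ValueError("points must have shape (n_frames, n_points, 2)")
        if self.points.shape[1] < 5:
            raise ValueError("need at least 5 midline points per frame")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.valid is None:
            self.valid = np.ones(self.points.shape[0], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (self.points.shape[0],):
                raise ValueError("valid mask must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def n_points(self) -> int:
        return self.points.shape[1]

    def arc_lengths(self) -> np.ndarray:
        """Total arc length per frame (px)."""
        seg = np.diff(self.points, axis=1)
        return np.linalg.norm(seg, axis=2).sum(axis=1)


@dataclass
class CurvatureKymogram:
    """frames x joints matrix of signed curvature (rad per unit body coord).

    Invalid frames are stored as NaN rows and excluded from statistics.
    """

    values: np.ndarray
    body_coords: np.ndarray  # joint positions in [0, 1], strictly increasing
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.body_coords = np.asarray(self.body_coords, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x joints)")
        if self.values.shape[1] != self.body_coords.size:
            raise ValueError("one body coordinate per joint required")
        if np.any(np.diff(self.body_coords) <= 0):
            raise ValueError("body_coords must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) / self.frame_rate


@dataclass
class VelocityTrace:
    """Signed mid-point speed per frame step (+ toward head), px/s.

    Entry i is the velocity between frames i and i+1; NaN marks steps
    involving an invalid frame.
    """

    values: np.ndarray
    frame_rate: float
    smooth_window: int = 1
    reference: str = "midpoint"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class StateSequence:
    """Per-step behavioral labels with the thresholds that produced them."""

    labels: np.ndarray  # object array of "forward"/"backward"/"pause"/None
    frame_rate: float
    lo: float = -1.0
    hi: float = 1.0

    def __len__(self) -> int:
        return len(self.labels)


def resample_midline(raw: MidlineSeries, n_points: int = 33) -> MidlineSeries:
    """Re-parameterise every frame to ``n_points`` equally spaced in arc length.

    Head/tail order is preserved.  Frames with (near) zero arc length are
    flagged invalid rather than raising; they propagate as missing data.
    """
    if n_points < 5:
        raise ValueError("n_points must be >= 5")
    out = np.empty((raw.n_frames, n_points, 2))
    valid = raw.valid.copy()
    targets = np.linspace(0.0, 1.0, n_points)
    for f in range(raw.n_frames):
        if not valid[f]:
            out[f] = np.nan
            continue
        pts = raw.points[f]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] <= 0 or not np.isfinite(s[-1]):
            valid[f] = False
            out[f] = np.nan
            continue
        s /= s[-1]
        # collapse coincident input points so interpolation is well defined
        keep = np.concatenate([[True], np.diff(s) > 0])
        out[f, :, 0] = np.interp(targets, s[keep], pts[keep, 0])
        out[f, :, 1] = np.interp(targets, s[keep], pts[keep, 1])
    return MidlineSeries(points=out, frame_rate=raw.frame_rate,
                         pixel_scale=raw.pixel_scale, valid=valid)


def compute_curvature(points: np.ndarray) -> np.ndarray:
    """Signed curvature at each interior joint of one resampled frame.

    The turning angle between segments (i-1 -> i) and (i -> i+1), signed by
    the cross product (positive = leftward bend), divided by the joint
    spacing in body coordinate (1 / (n_points - 1)); units are rad per unit
    body length.  For 33 points on a circular arc subtending a total angle
    Theta this yields the constant Theta.
    """
    pts = np.asarray(points, dtype=float)
    d = np.diff(pts, axis=0)
    norms = np.linalg.norm(d, axis=1)
    if np.any(norms == 0):
        raise ValueError("coincident neighboring points")
    a, b = d[:-1], d[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = (a * b).sum(axis=1)
    angle = np.arctan2(cross, dot)
    n = pts.shape[0]
    return angle * (n - 1)


def build_kymogram(m: MidlineSeries) -> CurvatureKymogram:
    """Stack per-frame curvature into a frames x joints kymogram.

    Invalid frames become NaN rows.  Raises if every frame is invalid.
    """
    if not np.any(m.valid):
        raise ValueError("all frames invalid; nothing to analyse")
    n_joints = m.n_points - 2
    values = np.full((m.n_frames, n_joints), np.nan)
    for f in range(m.n_frames):
        if m.valid[f]:
            values[f] = compute_curvature(m.points[f])
    body_coords = np.arange(1, m.n_points - 1) / (m.n_points - 1)
    return CurvatureKymogram(values=values, body_coords=body_coords,
                             frame_rate=m.frame_rate)


def _body_axis(points: np.ndarray) -> np.ndarray:
    """Unit vector from tail to head (motion along it is 'toward the head')."""
    axis = points[0] - points[-1]
    n = np.linalg.norm(axis)
    if n == 0:
        return np.array([np.nan, np.nan])
    return axis / n


def midpoint_velocity(m: MidlineSeries, smooth_window: int = 5,
                      reference: Literal["midpoint", "centroid"] = "midpoint",
                      ) -> VelocityTrace:
    """Signed crawling velocity from the body mid-point (or centroid).

    The displacement of the reference point between consecutive frames is
    projected onto the local tail->head axis (averaged over the two frames),
    so motion toward the head is positive, and multiplied by the frame rate.
    An optional boxcar (default 5 frames) smooths the result; NaN steps from
    invalid frames stay NaN.
    """
    if m.n_frames < 2:
        raise ValueError("need at least 2 frames")
    pts = m.points
    if reference == "midpoint":
        ref = pts[:, pts.shape[1] // 2, :]
    elif reference == "centroid":
        ref = pts.mean(axis=1)
    else:
        raise ValueError("reference must be 'midpoint' or 'centroid'")

    axes = np.array([_body_axis(pts[f]) for f in range(m.n_frames)])
    disp = np.diff(ref, axis=0)
    pair_axis = axes[:-1] + axes[1:]
    norms = np.linalg.norm(pair_axis, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pair_axis = pair_axis / norms
    v = (disp * pair_axis).sum(axis=1) * m.frame_rate

    bad = ~(m.valid[:-1] & m.valid[1:])
    v[bad] = np.nan

    if smooth_window > 1:
        v = _nan_boxcar(v, smooth_window)
        v[bad] = np.nan
    return VelocityTrace(values=v, frame_rate=m.frame_rate,
                         smooth_window=smooth_window, reference=reference)


def _nan_boxcar(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average ignoring NaNs (shrinking at the edges)."""
    n = x.size
    out = np.empty(n)
    half = window // 2
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        seg = x[lo:hi]
        good = np.isfinite(seg)
        out[i] = seg[good].mean() if good.any() else np.nan
    return out


def classify_states(v: VelocityTrace, lo: float = -1.0, hi: float = 1.0,
                    ) -> StateSequence:
    """Classify each step as forward / backward / pause.

    Velocities in [lo, hi] (boundaries inclusive) are pause; above hi is
    forward (toward the head), below lo is backward.  Non-finite entries
    become missing labels (None) and are excluded from propensities.
    """
    if lo >= hi:
        raise ValueError("require lo < hi")
    vals = v.values
    labels = np.empty(vals.size, dtype=object)
    labels[:] = None
    finite = np.isfinite(vals)
    labels[finite & (vals > hi)] = "forward"
    labels[finite & (vals < lo)] = "backward"
    labels[finite & (vals >= lo) & (vals <= hi)] = "pause"
    return StateSequence(labels=labels, frame_rate=v.frame_rate, lo=lo, hi=hi)


def propensity(s: StateSequence) -> dict[str, float]:
    """Fraction of labeled frames in each state; fractions sum to 1."""
    labels = [x for x in s.labels if x is not None]
    if not labels:
        raise ValueError("no labeled frames")
    n = len(labels)
    return {state: labels.count(state) / n for state in STATES}


def curvature_distribution(k: CurvatureKymogram, c_min: float = 0.33,
                           c_max: float = 0.96) -> np.ndarray:
    """Pooled |curvature| sample from joints with body coordinate in range.

    The default 0.33-0.96 window excludes the head (dominated by foraging
    head swings) and the very tail tip.  Returns the sorted sample over all
    valid frames; histogram the result as needed.
    """
    sel = (k.body_coords >= c_min) & (k.body_coords <= c_max)
    if not np.any(sel):
        raise ValueError(f"no joints with body coordinate in [{c_min}, {c_max}]")
    vals = np.abs(k.values[:, sel]).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no valid curvature values in range")
    return np.sort(vals)
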