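"""Midline resampling, curvature, velocity and state classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormrhythm.posture import (MidlineSeries, VelocityTrace, build_kymogram,
                                classify_states, compute_curvature,
                                curvature_distribution, midpoint_velocity,
                                propensity, resample_midline)
from wormrhythm.synthetic import WormSimConfig, simulate_midline
from wormrhythm.stats import compare_distributions

from conftest import circle_arc


def _series(frames: np.ndarray, fps: float = 10.0) -> MidlineSeries:
    return MidlineSeries(points=np.asarray(frames, dtype=float), frame_rate=fps)


class TestResample:
    def test_straight_line_uniform_spacing(self):
        pts = np.stack([np.linspace(0, 32, 9), np.zeros(9)], axis=1)
        m = _series(pts[None])
        out = resample_midline(m, 33)
        spacing = np.diff(out.points[0, :, 0])
        assert np.allclose(spacing, 1.0)
        assert np.allclose(out.points[0, :, 1], 0.0)

    def test_semicircle_keeps_radius(self):
        pts = circle_arc(200, radius=50.0, total_angle=np.pi)
        out = resample_midline(_series(pts[None]), 33)
        radii = np.linalg.norm(out.points[0], axis=1)
        assert np.max(np.abs(radii - 50.0)) < 0.001 * 50.0

    def test_idempotent_on_equally_spaced_input(self):
        pts = circle_arc(33, radius=40.0, total_angle=1.2)
        out = resample_midline(_series(pts[None]), 33)
        # equal chords on a circle are equal arc steps of the polyline
        assert np.max(np.abs(out.points[0] - pts)) < 1e-9

    def test_degenerate_frame_flagged_invalid(self):
        good = np.stack([np.linspace(0, 10, 7), np.zeros(7)], axis=1)
        bad = np.zeros((7, 2))
        m = _series(np.stack([good, bad]))
        out = resample_midline(m, 33)
        assert out.valid.tolist() == [True, False]
        assert np.all(np.isnan(out.points[1]))


class TestCurvature:
    def test_collinear_is_zero(self):
        pts = np.stack([np.linspace(0, 5, 11), np.zeros(11)], axis=1)
        assert np.allclose(compute_curvature(pts), 0.0)

    def test_circle_arc_constant_curvature(self):
        # 33 points subtending total angle Theta: every joint angle Theta/32,
        # so curvature (angle / body-coord spacing) is the constant Theta
        theta = 1.6
        pts = circle_arc(33, radius=100.0, total_angle=theta)
        k = compute_curvature(pts)
        assert np.allclose(k, -theta, rtol=1e-6) or np.allclose(k, theta, rtol=1e-6)
        assert np.std(k) < 1e-6 * abs(theta)

    def test_mirror_negates_exactly(self):
        pts = circle_arc(33, radius=30.0, total_angle=2.0, start_angle=0.4)
        mirrored = pts * np.array([1.0, -1.0])
        np.testing.assert_array_equal(compute_curvature(mirrored),
                                      -compute_curvature(pts))

    def test_coincident_points_rejected(self):
        pts = np.zeros((6, 2))
        pts[:, 0] = [0, 1, 1, 2, 3, 4]
        with pytest.raises(ValueError):
            compute_curvature(pts)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(angle=st.floats(-np.pi, np.pi),
           dx=st.floats(-1e3, 1e3), dy=st.floats(-1e3, 1e3))
    def test_rigid_motion_invariance(self, angle, dx, dy):
        pts = circle_arc(20, radius=25.0, total_angle=1.1)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        moved = pts @ rot.T + np.array([dx, dy])
        assert np.max(np.abs(compute_curvature(moved)
                             - compute_curvature(pts))) < 1e-9


class TestKymogram:
    def test_pause_worm_constant_in_time(self):
        cfg = WormSimConfig(mode="pause", n_frames=40, translation_speed=0.0,
                            noise_sd=0.0, seed=0)
        m, _ = simulate_midline(cfg)
        k = build_kymogram(m)
        assert np.allclose(k.values, k.values[0])

    def test_shape_and_coords(self, forward_worm):
        _, m, _ = forward_worm
        k = build_kymogram(m)
        assert k.values.shape == (m.n_frames, m.n_points - 2)
        assert np.all(np.diff(k.body_coords) > 0)

    def test_all_invalid_raises(self):
        pts = np.zeros((3, 7, 2))
        m = MidlineSeries(points=pts, frame_rate=10.0,
                          valid=np.zeros(3, dtype=bool))
        with pytest.raises(ValueError):
            build_kymogram(m)


class TestVelocityAndStates:
    def test_static_worm_zero_velocity(self):
        pts = np.stack([np.linspace(0, 100, 33), np.zeros(33)], axis=1)
        m = _series(np.repeat(pts[None], 10, axis=0))
        v = midpoint_velocity(m)
        assert np.allclose(v.values, 0.0)

    @pytest.mark.parametrize("direction,expected", [(-1.0, 30.0), (1.0, -30.0)])
    def test_rigid_translation_sign_and_magnitude(self, direction, expected):
        # head at x=0, tail at x=100: moving along -x is toward the head
        base = np.stack([np.linspace(0, 100, 33), np.zeros(33)], axis=1)
        frames = [base + np.array([direction * 3.0 * i, 0.0]) for i in range(12)]
        v = midpoint_velocity(_series(np.stack(frames)))
        assert np.allclose(v.values, expected)

    def test_invalid_frames_propagate_as_nan(self):
        base = np.stack([np.linspace(0, 100, 33), np.zeros(33)], axis=1)
        m = MidlineSeries(points=np.repeat(base[None], 6, axis=0),
                          frame_rate=10.0,
                          valid=np.array([True, True, False, True, True, True]))
        v = midpoint_velocity(m)
        assert np.isnan(v.values[1]) and np.isnan(v.values[2])

    @pytest.mark.parametrize("value,expected", [
        (5.0, "forward"), (-1.0, "pause"), (1.0, "pause"),
        (-1.5, "backward"), (0.0, "pause"), (1.01, "forward"),
    ])
    def test_threshold_rule(self, value, expected):
        v = VelocityTrace(values=np.array([value]), frame_rate=10.0)
        assert classify_states(v).labels[0] == expected

    def test_nan_velocity_label_missing(self):
        v = VelocityTrace(values=np.array([np.nan, 2.0]), frame_rate=10.0)
        s = classify_states(v)
        assert s.labels[0] is None and s.labels[1] == "forward"

    def test_state_recovery_on_clean_simulations(self):
        """classify(midpoint_velocity) matches ground truth exactly when the
        true speed is well away from the +-1 px/s thresholds."""
        cases = [("forward", 30.0, 0.5), ("backward", 30.0, 0.5),
                 ("forward", 3.0, 0.15), ("pause", 0.0, 0.5),
                 ("kinker", 0.0, 0.5)]
        for mode, speed, amp in cases:
            cfg = WormSimConfig(mode=mode, translation_speed=speed,
                                wave_amplitude=amp, n_frames=300,
                                noise_sd=0.0, seed=17)
            m, truth = simulate_midline(cfg)
            s = classify_states(midpoint_velocity(m))
            assert list(s.labels) == list(truth.state_labels[:-1]), mode


class TestPropensityAndDistribution:
    def test_all_forward(self):
        v = VelocityTrace(values=np.full(10, 5.0), frame_rate=10.0)
        p = propensity(classify_states(v))
        assert p == {"forward": 1.0, "backward": 0.0, "pause": 0.0}

    def test_counting(self):
        vals = np.concatenate([np.full(120, 5.0), np.full(60, -5.0),
                               np.zeros(20)])
        p = propensity(classify_states(VelocityTrace(values=vals, frame_rate=10.0)))
        assert p == {"forward": 0.6, "backward": 0.3, "pause": 0.1}
        assert sum(p.values()) == pytest.approx(1.0)

    def test_no_labels_raises(self):
        v = VelocityTrace(values=np.array([np.nan]), frame_rate=10.0)
        with pytest.raises(ValueError):
            propensity(classify_states(v))

    def test_zero_kymogram_point_mass(self, forward_worm):
        _, m, _ = forward_worm
        k = build_kymogram(m)
        zero = type(k)(values=np.zeros_like(k.values),
                       body_coords=k.body_coords, frame_rate=k.frame_rate)
        assert np.all(curvature_distribution(zero) == 0.0)

    def test_range_selects_joints(self, forward_worm):
        _, m, _ = forward_worm
        k = build_kymogram(m)
        n_sel = np.sum((k.body_coords >= 0.33) & (k.body_coords <= 0.96))
        vals = curvature_distribution(k, 0.33, 0.96)
        assert vals.size == n_sel * m.n_frames
        with pytest.raises(ValueError):
            curvature_distribution(k, 0.401, 0.402)

    def test_amplitude_doubling_shifts_distribution_up(self):
        samples = {}
        for amp in (0.3, 0.6):
            cfg = WormSimConfig(mode="forward", wave_amplitude=amp,
                                n_frames=200, noise_sd=0.0, seed=4)
            m, _ = simulate_midline(cfg)
            samples[amp] = curvature_distribution(build_kymogram(m))
        res = compare_distributions(samples[0.3], samples[0.6])
        assert res.statistic > 0.3
        assert np.median(samples[0.6]) > np.median(samples[0.3])
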