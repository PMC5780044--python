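"""Generator contracts: determinism, geometry, ground-truth bookkeeping."""

import numpy as np
import pytest

from wormrhythm.calcium import compute_ratio
from wormrhythm.posture import build_kymogram, midpoint_velocity, resample_midline
from wormrhythm.synthetic import (CalciumSimConfig, EphysSimConfig,
                                  WormSimConfig, simulate_calcium,
                                  simulate_current_trace, simulate_midline)


class TestSimulateMidline:
    def test_pause_mode_is_static_straight_line(self):
        cfg = WormSimConfig(mode="pause", n_frames=50, translation_speed=0.0,
                            noise_sd=0.0, seed=0)
        m, truth = simulate_midline(cfg)
        assert np.allclose(m.points, m.points[0])
        assert np.allclose(m.points[0, :, 1], 0.0)
        assert all(lab == "pause" for lab in truth.state_labels)

    def test_forward_wave_speed_ground_truth(self):
        cfg = WormSimConfig(mode="forward", wavelength=0.6, wave_period=2.0)
        _, truth = simulate_midline(cfg)
        assert truth.wave_speed == pytest.approx(0.3)
        cfg_b = WormSimConfig(mode="backward", wavelength=0.6, wave_period=2.0)
        _, truth_b = simulate_midline(cfg_b)
        assert truth_b.wave_speed == pytest.approx(-0.3)

    def test_backward_translation_displaces_midpoint_toward_tail(self):
        cfg = WormSimConfig(mode="backward", translation_speed=30.0,
                            n_frames=200, noise_sd=0.0, seed=1)
        m, _ = simulate_midline(cfg)
        v = midpoint_velocity(m, smooth_window=1).values
        # -3 px per frame at 10 fps, averaged over whole record
        disp_per_frame = np.nanmean(v) / cfg.frame_rate
        assert disp_per_frame == pytest.approx(-3.0, rel=0.1)

    def test_arc_length_equals_body_length(self):
        cfg = WormSimConfig(mode="forward", n_frames=30, noise_sd=0.0, seed=2)
        m, _ = simulate_midline(cfg)
        assert np.allclose(m.arc_lengths(), cfg.body_length, rtol=1e-6)

    def test_same_seed_bit_identical_different_seed_not(self):
        cfg = WormSimConfig(mode="forward", noise_sd=0.5, seed=3)
        m1, _ = simulate_midline(cfg)
        m2, _ = simulate_midline(WormSimConfig(mode="forward", noise_sd=0.5, seed=3))
        m3, _ = simulate_midline(WormSimConfig(mode="forward", noise_sd=0.5, seed=4))
        np.testing.assert_array_equal(m1.points, m2.points)
        assert not np.array_equal(m1.points, m3.points)

    def test_kymogram_matches_generative_curvature_field(self):
        """Sampled curvature equals the analytic field within discretization."""
        cfg = WormSimConfig(mode="forward", wave_amplitude=0.5, wavelength=0.6,
                            wave_period=2.0, n_frames=60, translation_speed=0.0,
                            noise_sd=0.0, seed=5)
        m, _ = simulate_midline(cfg)
        k = build_kymogram(m)
        t = np.arange(cfg.n_frames) / cfg.frame_rate
        c = k.body_coords
        kappa_true = (cfg.wave_amplitude * 2 * np.pi / cfg.wavelength
                      * np.cos(2 * np.pi * (c[None, :] / cfg.wavelength
                                            - t[:, None] / cfg.wave_period)))
        amp = np.max(np.abs(kappa_true))
        assert np.max(np.abs(k.values - kappa_true)) < 0.01 * amp

    def test_head_oscillation_confined_to_anterior(self):
        cfg = WormSimConfig(mode="pause", head_osc_amplitude=0.4,
                            head_osc_period=1.0, n_frames=80,
                            translation_speed=0.0, noise_sd=0.0, seed=6)
        m, _ = simulate_midline(cfg)
        k = build_kymogram(m)
        anterior = k.values[:, k.body_coords < 0.2]
        posterior = k.values[:, k.body_coords > 0.25]
        assert anterior.std() > 10 * max(posterior.std(), 1e-12)

    def test_rejects_bad_configs(self):
        with pytest.raises(ValueError):
            simulate_midline(WormSimConfig(n_frames=1))
        with pytest.raises(ValueError):
            simulate_midline(WormSimConfig(wavelength=0.0))
        with pytest.raises(ValueError):
            simulate_midline(WormSimConfig(wave_amplitude=float("nan")))


class TestSimulateCalcium:
    def test_ratio_constant_without_oscillation_or_noise(self):
        cfg = CalciumSimConfig(osc_amplitude=0.0, motion_artifact_sd=0.0,
                               shot_noise_sd=0.0, seed=0)
        traces, _ = simulate_calcium(cfg)
        r = traces[0].gcamp / traces[0].rfp
        assert np.allclose(r, r[0])

    def test_ten_peaks_in_ten_cycles(self):
        cfg = CalciumSimConfig(duration=500.0, period=50.0, phase_offsets=(0.0,))
        _, truth = simulate_calcium(cfg)
        assert truth.event_times[0].size == 10
        # sin peaks at P(1/4 + k)
        assert truth.event_times[0][0] == pytest.approx(12.5)

    def test_antiphasic_pair_by_construction(self):
        cfg = CalciumSimConfig(n_neurons=2, phase_offsets=(np.pi, 0.0),
                               motion_artifact_sd=0.0, shot_noise_sd=0.0,
                               seed=1)
        traces, truth = simulate_calcium(cfg)
        assert truth.phase_offsets[0] - truth.phase_offsets[1] == pytest.approx(np.pi)
        # the two rectified oscillations never overlap
        da = compute_ratio(traces[0]).drr
        db = compute_ratio(traces[1]).drr
        assert np.min(da * db) < 1e-6

    def test_rejects_period_longer_than_duration(self):
        with pytest.raises(ValueError):
            simulate_calcium(CalciumSimConfig(duration=40.0, period=50.0))


class TestSimulateCurrentTrace:
    def test_mpsc_count_near_poisson_expectation(self):
        cfg = EphysSimConfig(duration=100.0, sample_rate=5000.0,
                             mpsc_rate=25.0, burst_interval=1e6,
                             burst_duration=2.5, seed=0)
        _, truth = simulate_current_trace(cfg)
        n = truth.mpsc_times.size
        assert abs(n - 2500) < 4 * np.sqrt(2500)

    def test_burst_placement_rule(self):
        cfg = EphysSimConfig(duration=360.0, sample_rate=5000.0,
                             burst_interval=90.0, seed=1)
        _, truth = simulate_current_trace(cfg)
        assert truth.burst_windows.shape[0] == 4
        assert truth.burst_windows[0, 0] == pytest.approx(45.0)

    def test_zero_noise_no_events_gives_zero_trace(self):
        cfg = EphysSimConfig(duration=5.0, sample_rate=5000.0,
                             baseline_noise_sd=0.0, mpsc_rate=1e-9,
                             burst_interval=1e6, burst_duration=2.5, seed=2)
        trace, truth = simulate_current_trace(cfg)
        if truth.mpsc_times.size == 0:
            assert np.all(trace.current == 0.0)

    def test_rejects_unresolvable_decay_tau(self):
        with pytest.raises(ValueError):
            simulate_current_trace(EphysSimConfig(sample_rate=1000.0,
                                                  mpsc_decay_tau=0.003))
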