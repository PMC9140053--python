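"""Tests of the phantom, hemodynamics, microbubble and rendering simulators."""

import numpy as np
import pytest

from renulm.core import REGION_LABELS, angular_distance_deg
from renulm.synthetic import (
    GroundTruthTrajectory,
    HemodynamicsParams,
    PhantomConfig,
    RenderParams,
    TissueMotion,
    build_renal_phantom,
    map_excursion,
    map_model,
    render_frames,
    simulate_map_trace,
    simulate_microbubbles,
    speed_multiplier,
)

BED_TO_REGION_LABEL = {
    "cortex_art": 1, "cortex_ven": 1, "om_dvr": 2, "om_avr": 2,
    "im_dvr": 3, "im_avr": 3,
}


class TestPhantom:
    def test_six_beds_nonempty_and_opposed(self, phantom):
        for bed in BED_TO_REGION_LABEL:
            assert len(phantom.vessels_in_bed(bed)) > 0
        # arterial vs venous mean directions oppose by 180 +/- 5 degrees
        for art, ven in (("cortex_art", "cortex_ven"), ("om_dvr", "om_avr"),
                         ("im_dvr", "im_avr")):
            a = phantom.mean_bed_direction_deg(art)
            v = phantom.mean_bed_direction_deg(ven)
            assert angular_distance_deg(a, v) > 175.0

    def test_every_vessel_opposes_paired_bed_mean(self, phantom):
        # venous/ascending flow_direction is >90 deg from the paired
        # arterial/descending bed's mean direction
        for art, ven in (("cortex_art", "cortex_ven"), ("om_dvr", "om_avr"),
                         ("im_dvr", "im_avr")):
            mean_art = phantom.mean_bed_direction_deg(art)
            for vessel in phantom.vessels_in_bed(ven):
                assert angular_distance_deg(vessel.direction_deg, mean_art) > 90.0

    def test_centerlines_inside_their_region(self, phantom):
        cfg = phantom.config
        for vessel in phantom.vessels:
            pts = vessel.point_at(np.linspace(0, vessel.length, 25))
            r = (pts[:, 1] / cfg.pixel_pitch).astype(int)
            c = (pts[:, 0] / cfg.pixel_pitch).astype(int)
            labels = phantom.label_map[r, c]
            assert np.all(labels == BED_TO_REGION_LABEL[vessel.bed]), vessel.bed

    def test_configured_base_speed_propagates(self):
        cfg = PhantomConfig()
        cfg.bed_speeds["cortex_art"] = 1.59  # baseline cortical arterial mean
        ph = build_renal_phantom(cfg)
        assert all(v.base_speed == 1.59 for v in ph.vessels_in_bed("cortex_art"))

    def test_zero_vessels_gives_empty_valid_phantom(self):
        cfg = PhantomConfig(n_vessels={})
        ph = build_renal_phantom(cfg)
        assert ph.vessels == []
        assert set(np.unique(ph.label_map)) <= {0, 1, 2, 3}

    def test_overlapping_regions_rejected(self):
        cfg = PhantomConfig(region_radii={
            "inner_medulla": (0.0, 2.0), "outer_medulla": (1.5, 3.0),
            "cortex": (3.0, 4.5)})
        with pytest.raises(ValueError, match="invalid geometry"):
            build_renal_phantom(cfg)

    def test_speed_out_of_span_rejected(self):
        cfg = PhantomConfig()
        cfg.bed_speeds["cortex_art"] = 16.0
        with pytest.raises(ValueError):
            build_renal_phantom(cfg)


class TestMapTrace:
    def test_flat_at_baseline_before_injection(self, hemo):
        t = np.arange(0, 60)
        assert np.all(map_model(t, hemo, t_inj=60.0) == hemo.map_baseline)

    def test_minimum_at_drop_peak(self, hemo):
        t = np.arange(0, 470, 0.25)
        m = map_model(t, hemo, t_inj=60.0)
        t_min = t[np.argmin(m)]
        assert t_min == pytest.approx(60.0 + hemo.t_drop_peak, abs=0.5)
        assert m.min() == pytest.approx(hemo.map_min, abs=1.0)

    def test_relaxes_toward_recovery(self, hemo):
        end = map_model(60.0 + 410.0, hemo, t_inj=60.0)
        assert end == pytest.approx(hemo.map_recovery, abs=1.0)

    def test_baseline_window_mean_over_seeds(self, hemo):
        means = []
        for seed in range(1, 21):
            h = HemodynamicsParams(seed=seed)
            t, v = simulate_map_trace(h, 470.0, 60.0)
            means.append(v[:30].mean())
        assert np.mean(means) == pytest.approx(84.0, abs=3.0)

    def test_minimizing_window_in_reported_interval(self, hemo):
        # noise-free: the minimizing 30-s window must sit at the trough,
        # 52-82 s after injection
        t = np.arange(0, 470.0, 1.0)
        m = map_model(t, hemo, t_inj=60.0)
        means = np.convolve(m, np.ones(30) / 30, mode="valid")
        start = t[np.argmin(means)]
        center = start + 15.0
        assert 60.0 + 52.0 <= center <= 60.0 + 82.0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            HemodynamicsParams(t_drop_onset=50.0, t_drop_peak=40.0).validate()
        with pytest.raises(ValueError):
            simulate_map_trace(HemodynamicsParams(), duration=50.0, t_inj=60.0)

    def test_scan2_multiplier_matches_target_mean(self, hemo):
        tg = np.linspace(60.0, 470.0, 8193)
        m = speed_multiplier(hemo, "cortex_art", tg, scan=2, t_inj=60.0)
        assert np.mean(m) == pytest.approx(1.14 / 1.59, rel=1e-3)

    def test_scan2_multiplier_monotone_during_drop(self, hemo):
        t = np.arange(60.0, 60.0 + hemo.t_drop_peak + 1)
        m = speed_multiplier(hemo, "cortex_art", t, scan=2, t_inj=60.0)
        assert np.all(np.diff(m) <= 1e-12)


class TestMicrobubbles:
    def test_poisson_total_count(self, phantom, hemo):
        lam, T = 4.0, 10.0
        counts = []
        rng = np.random.default_rng(7)
        for _ in range(200):
            trajs = simulate_microbubbles(phantom.vessels, hemo, T, lam, rng,
                                          disruption_prob=0.0)
            counts.append(len(trajs))
        mean = np.mean(counts)
        se = np.sqrt(lam * T / 200)
        # a few arrivals too close to scan end are dropped before first frame
        assert abs(mean - lam * T) < 3 * se + 0.5

    def test_no_disruption_runs_to_exit_or_scan_end(self, phantom, hemo):
        rng = np.random.default_rng(3)
        trajs = simulate_microbubbles(phantom.vessels, hemo, 30.0, 5.0, rng,
                                      disruption_prob=0.0)
        fps = 54.0
        for tr in trajs:
            assert tr.disruption_time is None
            v = next(v for v in phantom.vessels if v.id == tr.vessel_id)
            # last frame is the scan end or the bubble is about to exit
            last_s = np.hypot(*(np.array([tr.x[-1], tr.y[-1]]) - v.centerline[0]))
            at_exit = last_s + tr.speeds[-1] / fps >= v.length - 1e-9
            at_end = tr.frames[-1] == int(30.0 * fps) - 1
            assert at_exit or at_end

    def test_per_frame_displacement_is_speed_over_rate(self, phantom, hemo):
        rng = np.random.default_rng(4)
        trajs = simulate_microbubbles(phantom.vessels, hemo, 10.0, 5.0, rng,
                                      disruption_prob=0.0)
        tr = max(trajs, key=len)
        steps = np.hypot(np.diff(tr.x), np.diff(tr.y))
        np.testing.assert_allclose(steps, tr.speeds[:-1] / 54.0, rtol=1e-9)

    def test_speed_equals_commanded_instantaneous(self, phantom, hemo):
        rng = np.random.default_rng(5)
        trajs = simulate_microbubbles(phantom.vessels, hemo, 40.0, 5.0, rng,
                                      scan=2, t_inj=10.0, analysis_window=30.0,
                                      disruption_prob=0.0)
        fps = 54.0
        for tr in trajs[:20]:
            v = next(v for v in phantom.vessels if v.id == tr.vessel_id)
            cmd = v.base_speed * speed_multiplier(
                hemo, tr.bed, tr.frames / fps, scan=2, t_inj=10.0,
                analysis_window=30.0)
            np.testing.assert_allclose(tr.speeds, cmd, rtol=1e-9)

    def test_bit_reproducible(self, phantom, hemo):
        a = simulate_microbubbles(phantom.vessels, hemo, 10.0, 5.0, 42)
        b = simulate_microbubbles(phantom.vessels, hemo, 10.0, 5.0, 42)
        assert len(a) == len(b)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.x, tb.x)
            np.testing.assert_array_equal(ta.frames, tb.frames)


class TestTissueMotion:
    def test_zero_amplitude_zero_field(self):
        m = TissueMotion(amplitude=0.0)
        f = m.field_on_grid((16, 16), 0.05, t=1.234)
        assert np.all(f == 0)

    def test_periodicity(self):
        m = TissueMotion(amplitude=0.2)
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        d1 = m.displacement(pts, 0.7)
        d2 = m.displacement(pts, 0.7 + m.period)
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_peak_displacement_equals_amplitude(self):
        # analytic peak: x = 0 (weight 1) at sine phase pi/2
        m = TissueMotion(amplitude=0.15, phase=0.0)
        t_peak = m.period / 4
        d = m.displacement(np.array([[0.0, 3.0]]), t_peak)
        assert np.hypot(*d[0]) == pytest.approx(0.15, abs=1e-12)
        f = m.field_on_grid((64, 64), 0.05, t_peak)
        assert np.abs(np.hypot(f[..., 0], f[..., 1])).max() <= 0.15 + 1e-12


class TestRendering:
    def test_empty_scene_zero_frames(self):
        prm = RenderParams(noise_sd=0.0)
        c, b = render_frames([], (32, 32), 0.05, 5, 1, params=prm, bmode=False)
        assert np.all(c.frames == 0)
        assert b is None

    def test_static_blob_argmax_at_pixel(self):
        # one static MB at the center of pixel (10, 20)
        traj = GroundTruthTrajectory(
            id=0, vessel_id=0, bed="cortex_art", entry_time=0.0,
            frames=np.arange(3), times=np.arange(3) / 54.0,
            x=np.full(3, (20 + 0.5) * 0.05), y=np.full(3, (10 + 0.5) * 0.05),
            speeds=np.zeros(3))
        c, _ = render_frames([traj], (32, 32), 0.05, 3, 1,
                             params=RenderParams(noise_sd=0.0), bmode=False)
        for k in range(3):
            assert np.unravel_index(np.argmax(c.frames[k]), (32, 32)) == (10, 20)

    def test_frame_count_follows_duration(self):
        n = int(round(2.0 * 54.0))
        c, b = render_frames([], (16, 16), 0.05, n, 1,
                             params=RenderParams(noise_sd=0.0))
        assert c.n_frames == 108
        assert b.n_frames == 108

    def test_out_of_grid_bubble_is_silently_invisible(self):
        traj = GroundTruthTrajectory(
            id=0, vessel_id=0, bed="cortex_art", entry_time=0.0,
            frames=np.arange(2), times=np.arange(2) / 54.0,
            x=np.array([50.0, 51.0]), y=np.array([50.0, 51.0]),
            speeds=np.zeros(2))
        c, _ = render_frames([traj], (16, 16), 0.05, 2, 1,
                             params=RenderParams(noise_sd=0.0), bmode=False)
        assert np.all(c.frames == 0)
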