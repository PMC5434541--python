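import numpy as np
import pandas as pd
import pytest

import mcttrack as m
from conftest import truth_as_detections


def _tracks(rows):
    """rows: (track_id, frame, x, y)"""
    return pd.DataFrame(rows, columns=["track_id", "frame_index", "x_px", "y_px"])


class TestTrackVelocities:
    def test_fifteen_pixels_up_is_six_mm_min_straight_up(self):
        t = _tracks([(0, 0, 50.0, 100.0), (0, 1, 50.0, 85.0)])
        s = m.track_velocities(t, pixel_size_um=16, frame_interval_s=2.4)
        assert s.vy_mm_min.iloc[0] == pytest.approx(6.0)
        assert s.vx_mm_min.iloc[0] == pytest.approx(0.0)
        assert s.speed_mm_min.iloc[0] == pytest.approx(6.0)
        assert s.angle_deg.iloc[0] == pytest.approx(0.0)

    def test_rightward_motion_is_plus_ninety_degrees(self):
        t = _tracks([(0, 0, 50.0, 50.0), (0, 1, 60.0, 50.0)])
        s = m.track_velocities(t, 16, 2.4)
        assert s.angle_deg.iloc[0] == pytest.approx(90.0)
        assert s.vy_mm_min.iloc[0] == pytest.approx(0.0)

    def test_stationary_pair_flagged_degenerate(self):
        t = _tracks([(0, 0, 50.0, 50.0), (0, 1, 50.0, 50.0)])
        s = m.track_velocities(t, 16, 2.4)
        assert s.speed_mm_min.iloc[0] == 0.0
        assert s.angle_deg.iloc[0] == 0.0
        assert bool(s.degenerate.iloc[0])

    def test_gap_span_averages_and_flags(self):
        t = _tracks([(0, 0, 0.0, 100.0), (0, 3, 0.0, 70.0)])
        s = m.track_velocities(t, 16, 2.4)
        assert bool(s.gap_flag.iloc[0]) and s.frame_step.iloc[0] == 3
        assert s.vy_mm_min.iloc[0] == pytest.approx(10 * 16 * 60 / (2.4 * 1000))
        assert len(m.track_velocities(t, 16, 2.4, include_gap_spans=False)) == 0

    def test_doubling_frame_interval_halves_every_speed(self):
        rng = np.random.default_rng(0)
        rows = [(0, f, x, y) for f, (x, y) in enumerate(rng.uniform(0, 50, (8, 2)))]
        t = _tracks(rows)
        s1 = m.track_velocities(t, 16, 2.4)
        s2 = m.track_velocities(t, 16, 4.8)
        np.testing.assert_allclose(s2.speed_mm_min, s1.speed_mm_min / 2, rtol=1e-12)

    def test_mid_frame_times(self):
        t = _tracks([(0, 2, 0.0, 10.0), (0, 3, 0.0, 5.0)])
        s = m.track_velocities(t, 16, 2.4)
        assert s.time_s.iloc[0] == pytest.approx(2.5 * 2.4)


class TestRunSummary:
    def test_mean_and_sample_sd(self):
        s = pd.DataFrame({
            "time_s": [0.0, 1.0, 2.0],
            "vx_mm_min": [1.0, 2.0, 3.0],
            "vy_mm_min": [0.0, 0.0, 0.0],
            "speed_mm_min": [1.0, 2.0, 3.0],
            "angle_deg": [90.0, 90.0, 90.0],
        })
        out = m.run_summary(s)
        assert out.mean_speed_mm_min == pytest.approx(2.0)
        assert out.sd_speed_mm_min == pytest.approx(1.0)  # ddof=1
        assert out.resultant_angle_deg == pytest.approx(90.0)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            m.run_summary(pd.DataFrame(columns=["speed_mm_min"]))

    def test_phantom_recovery_of_speed_and_heading(self):
        p = m.sheep_preset(shape=(700, 700), n_frames=40, n_particles=30,
                           speed_median_mm_min=1.3, heading_sd_deg=20.0, seed=21)
        res = m.generate_phantom(p)
        det = truth_as_detections(res.truth.positions)
        tracks = m.link_tracks(det, gate_px=15, max_gap_frames=2)
        samples = m.track_velocities(tracks, p.pixel_size_um, p.frame_interval_s)
        out = m.run_summary(samples)
        truth = res.truth.positions
        # pooled mean equals the pooled ground-truth mean almost exactly
        # (positions are continuous), heading within 2 degrees of the truth
        assert out.mean_speed_mm_min == pytest.approx(
            truth.speed_mm_min.mean(), rel=0.02)
        true_parts = res.truth.particles
        assert abs(out.resultant_angle_deg - p.heading_mean_deg) < 3 * (
            p.heading_sd_deg / np.sqrt(len(true_parts)) + 0.5)


class TestHeatmap:
    def test_counts_sum_to_in_range_samples(self):
        rng = np.random.default_rng(1)
        s = pd.DataFrame({
            "vx_mm_min": rng.normal(0, 2, 500),
            "vy_mm_min": rng.normal(1, 2, 500),
        })
        hm = m.velocity_heatmap(s, bin_width_mm_min=0.5, extent_mm_min=4.0)
        assert hm.total_in_range() + hm.n_out_of_range == 500
        assert hm.n_out_of_range > 0

    def test_all_stationary_run_hits_origin_bin(self):
        s = pd.DataFrame({"vx_mm_min": np.zeros(10), "vy_mm_min": np.zeros(10)})
        hm = m.velocity_heatmap(s, bin_width_mm_min=0.5, extent_mm_min=2.0)
        assert hm.total_in_range() == 10
        iy, ix = np.nonzero(hm.counts)
        assert len(iy) == 1
        assert hm.vy_edges[iy[0]] <= 0 < hm.vy_edges[iy[0] + 1]
        assert hm.vx_edges[ix[0]] <= 0 < hm.vx_edges[ix[0] + 1]

    def test_heatmap_resultant_matches_sample_resultant(self):
        rng = np.random.default_rng(2)
        angle = np.radians(-14.3)
        speed = rng.lognormal(0.3, 0.5, 2000)
        jitter = rng.normal(0, 0.2, 2000)
        s = pd.DataFrame({
            "vx_mm_min": speed * np.sin(angle + jitter),
            "vy_mm_min": speed * np.cos(angle + jitter),
        })
        hm = m.velocity_heatmap(s, bin_width_mm_min=0.1, extent_mm_min=10.0)
        direct = m.resultant_angle_deg(s.vx_mm_min.to_numpy(), s.vy_mm_min.to_numpy())
        assert hm.resultant_angle_deg() == pytest.approx(direct, abs=1.0)


class TestTreatmentResponse:
    def test_constant_speed_gives_identical_bins(self):
        t = _tracks([(0, f, 0.0, 100.0 - 5 * f) for f in range(20)])
        s = m.track_velocities(t, 16, 2.4)
        out = m.treatment_response(s, treatment_start_s=24.0, bin_s=12.0)
        assert out.mean_speed_mm_min.nunique() == 1
        assert set(out.label) == {"baseline", "post"}

    def test_first_post_bin_includes_treatment_time(self):
        t = _tracks([(0, f, 0.0, 100.0 - 2 * f) for f in range(20)])
        s = m.track_velocities(t, 16, 2.4)
        out = m.treatment_response(s, treatment_start_s=20.0, bin_s=10.0)
        post = out[out.label == "post"]
        assert post.bin_start_s.iloc[0] == pytest.approx(20.0)

    def test_no_baseline_is_an_error(self):
        t = _tracks([(0, f, 0.0, 100.0 - 2 * f) for f in range(5)])
        s = m.track_velocities(t, 16, 2.4)
        with pytest.raises(ValueError, match="baseline|pre"):
            m.treatment_response(s, treatment_start_s=-10.0, bin_s=10.0)

    def test_boosted_phantom_peaks_in_first_post_bin(self):
        p = m.sheep_preset(shape=(640, 640), n_frames=60, n_particles=25,
                           speed_shape=0.3, seed=23)
        start = 72.0
        res = m.treatment_phantom(p, boost_factor=1.5, boost_start_s=start,
                                  decay_s=25.0)
        det = truth_as_detections(res.truth.positions)
        tracks = m.link_tracks(det, gate_px=15, max_gap_frames=2)
        s = m.track_velocities(tracks, p.pixel_size_um, p.frame_interval_s)
        out = m.treatment_response(s, treatment_start_s=start, bin_s=14.4)
        post = out[out.label == "post"]
        assert post.mean_speed_mm_min.iloc[0] == post.mean_speed_mm_min.max()
        base = out[out.label == "baseline"].mean_speed_mm_min.mean()
        assert post.mean_speed_mm_min.iloc[0] > base


class TestGeometryProperties:
    def test_vertical_flip_negates_vy_keeps_speed(self):
        rng = np.random.default_rng(3)
        rows = []
        y = 200.0
        for f in range(15):
            y -= rng.uniform(0, 5)
            rows.append((0, f, 30.0 + 0.3 * f, y))
        t = _tracks(rows)
        h = 256
        flipped = t.copy()
        flipped["y_px"] = (h - 1) - flipped["y_px"]
        s = m.track_velocities(t, 16, 2.4)
        sf = m.track_velocities(flipped, 16, 2.4)
        np.testing.assert_allclose(sf.vy_mm_min, -s.vy_mm_min, atol=1e-9)
        np.testing.assert_allclose(sf.speed_mm_min, s.speed_mm_min, atol=1e-9)
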