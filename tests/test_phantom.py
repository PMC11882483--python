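"""Phantom generation, Poiseuille bubble flow, movie rendering."""
import numpy as np
import pytest

import ulmtools as u
from ulmtools.phantom import poiseuille_speed


class TestGeneratePhantom:
    def test_deterministic_for_fixed_seed(self):
        a = u.generate_phantom(seed=3)
        b = u.generate_phantom(seed=3)
        assert len(a.segments) == len(b.segments)
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points_um, sb.points_um)
            assert sa.radius_um == sb.radius_um
            assert sa.mean_speed_mm_s == sb.mean_speed_mm_s
        np.testing.assert_array_equal(a.region_label_map, b.region_label_map)

    def test_all_zero_seeds_rejected(self):
        empty = [u.RegionSpec("core", n_seeds=0), u.RegionSpec("inv", n_seeds=0)]
        with pytest.raises(ValueError, match="zero seeds"):
            u.generate_phantom(regions=empty, seed=0)

    def test_segments_satisfy_invariants(self, default_phantom):
        ph = default_phantom
        h, w = ph.shape
        for seg in ph.segments:
            assert seg.radius_um > 0 and seg.mean_speed_mm_s > 0
            assert np.all(seg.points_um >= 0)
            assert np.all(seg.points_um[:, 0] <= (w - 1) * ph.pixel_size_um)
            assert np.all(seg.points_um[:, 1] <= (h - 1) * ph.pixel_size_um)
            # confined to its own region band
            px = np.round(seg.points_um / ph.pixel_size_um).astype(int)
            labels = ph.region_label_map[px[:, 1].clip(0, h - 1),
                                         px[:, 0].clip(0, w - 1)]
            assert np.all(labels == seg.region)

    def test_denser_region_has_higher_vessel_area(self):
        lo = u.RegionSpec("core", n_seeds=2, branch_prob=0.0)
        hi = u.RegionSpec("invasive", n_seeds=6, branch_prob=0.0)
        ph = u.generate_phantom(regions=[lo, hi], seed=5)
        mask = u.true_vessel_mask(ph)
        d_lo = np.sum(mask & ph.region_mask("core")) / ph.region_mask("core").sum()
        d_hi = np.sum(mask & ph.region_mask("invasive")) / ph.region_mask("invasive").sum()
        assert d_hi > d_lo

    def test_truth_metric_region_ordering(self, default_phantom):
        """Invasive-region truth exceeds core and normal for the six
        structural/disorder parameters, by construction of the defaults."""
        tm = {name: u.phantom_truth_metrics(default_phantom, name)
              for name in default_phantom.region_names}
        for p in ("density", "branches", "branch_points", "curvature",
                  "fractal_dimension", "orientation_variance"):
            inv = getattr(tm["invasive"], p)
            assert inv > getattr(tm["core"], p), p
            assert inv > getattr(tm["normal"], p), p


class TestTruthMetrics:
    def test_straight_vessel(self, straight_vessel_phantom):
        roi = np.ones((128, 128), dtype=bool)
        tm = u.phantom_truth_metrics(straight_vessel_phantom, roi)
        assert tm.curvature == pytest.approx(1.0)
        assert tm.branches == 1
        assert tm.branch_points == 0
        assert tm.diameter_um == pytest.approx(40.0)
        assert tm.velocity_mm_s == pytest.approx(5.0)

    def test_semicircular_arc_curvature(self):
        theta = np.linspace(0.0, np.pi, 400)
        r = 300.0
        pts = np.column_stack([640.0 + r * np.cos(theta),
                               400.0 + r * np.sin(theta)])
        seg = u.phantom.VesselSegment(points_um=pts, radius_um=10.0,
                                      mean_speed_mm_s=5.0, region=0)
        ph = u.VascularPhantom(segments=[seg],
                               region_label_map=np.zeros((128, 128), dtype=np.int64),
                               region_names=["core"], pixel_size_um=10.0)
        tm = u.phantom_truth_metrics(ph, np.ones((128, 128), dtype=bool))
        assert tm.curvature == pytest.approx(np.pi / 2, rel=1e-3)

    def test_flow_volume_arithmetic(self, straight_vessel_phantom):
        # r = 20 um, v = 5 mm/s: Q = pi (20 um)^2 x 5000 um/s ~ 6.283 nL/s
        tm = u.phantom_truth_metrics(straight_vessel_phantom,
                                     np.ones((128, 128), dtype=bool))
        assert tm.flow_volume_nl_s == pytest.approx(2e-3 * np.pi * 1e3, rel=1e-9)

    def test_empty_roi_rejected(self, straight_vessel_phantom):
        with pytest.raises(ValueError, match="empty"):
            u.phantom_truth_metrics(straight_vessel_phantom,
                                    np.zeros((128, 128), dtype=bool))


class TestBubbleFlow:
    def test_poiseuille_profile(self):
        assert poiseuille_speed(5.0, 0.0, 20.0) == pytest.approx(10.0)
        assert poiseuille_speed(5.0, 20.0, 20.0) == pytest.approx(0.0)

    def test_centerline_displacement(self, straight_vessel_phantom):
        """A centreline bubble at mean speed 5 mm/s moves 10 um per frame at
        1 kHz (profile maximum is twice the mean)."""
        traj = u.simulate_bubble_flow(straight_vessel_phantom,
                                      bubbles_per_frame=5.0, n_frames=40,
                                      frame_rate_hz=1000.0, seed=2)
        fastest = max(traj.bubbles, key=lambda b: b.speed_mm_s)
        steps = np.hypot(*np.diff(fastest.xy_um, axis=0).T)
        expected = fastest.speed_mm_s  # um per frame at 1 kHz
        np.testing.assert_allclose(steps, expected, rtol=1e-6)
        assert fastest.speed_mm_s <= 10.0

    def test_sampled_speed_mean_near_mean_axial_speed(self, straight_vessel_phantom):
        traj = u.simulate_bubble_flow(straight_vessel_phantom,
                                      bubbles_per_frame=2.0, n_frames=200,
                                      seed=4, min_speed_mm_s=0.0)
        speeds = np.array([b.speed_mm_s for b in traj.bubbles])
        assert len(speeds) > 100
        assert abs(speeds.mean() - 5.0) / 5.0 < 0.2

    def test_step_equals_speed_over_frame_rate(self, default_phantom):
        """Flow consistency: arclength advance per frame is exactly
        speed / frame rate for every bubble."""
        traj = u.simulate_bubble_flow(default_phantom, bubbles_per_frame=0.5,
                                      n_frames=100, seed=6)
        checked = 0
        for b in traj.bubbles:
            if b.n_frames < 2:
                continue
            ds = np.diff(b.arclength_um)
            expected = b.speed_mm_s * 1000.0 / traj.frame_rate_hz
            np.testing.assert_allclose(ds, expected, rtol=1e-6)
            checked += 1
        assert checked > 10

    def test_empty_phantom_rejected(self):
        ph = u.generate_phantom(seed=1)
        ph.segments = []
        with pytest.raises(ValueError, match="no vessel segments"):
            u.simulate_bubble_flow(ph, seed=0)


class TestRenderMovie:
    def test_static_bubble_no_clutter(self):
        b = u.phantom.Bubble(frames=np.arange(5), xy_um=np.tile([300.0, 400.0], (5, 1)),
                             speed_mm_s=1.0, segment=0)
        traj = u.BubbleTrajectorySet(bubbles=[b], frame_rate_hz=1000.0, n_frames=5)
        stack = u.render_movie(traj, shape=(64, 64), pixel_size_um=10.0,
                               psf_sigma_um=10.0, seed=0)
        for f in stack.frames[1:]:
            np.testing.assert_array_equal(f, stack.frames[0])
        assert np.unravel_index(np.argmax(stack.frames[0]), (64, 64)) == (40, 30)

    def test_rank1_clutter_casorati_rank(self):
        traj = u.BubbleTrajectorySet(bubbles=[], frame_rate_hz=1000.0, n_frames=30)
        stack = u.render_movie(traj, shape=(32, 32), clutter_rank=1,
                               clutter_amplitude=50.0, noise_sigma=0.0, seed=3)
        s = np.linalg.svd(u.casorati_matrix(stack), compute_uv=False)
        assert s[0] > 0
        assert s[1] < 1e-9 * s[0]

    def test_spot_integral_conservation(self):
        """Noiseless rendering: each in-frame bubble adds one PSF integral."""
        b = u.phantom.Bubble(frames=np.array([0]), xy_um=np.array([[320.0, 320.0]]),
                             speed_mm_s=1.0, segment=0)
        traj = u.BubbleTrajectorySet(bubbles=[b], frame_rate_hz=1000.0, n_frames=2)
        stack = u.render_movie(traj, shape=(64, 64), pixel_size_um=10.0,
                               psf_sigma_um=15.0, seed=0)
        sigma_px = 1.5
        assert stack.frames[0].sum() == pytest.approx(2 * np.pi * sigma_px ** 2,
                                                      rel=1e-3)

    def test_moving_bubble_argmax_tracks_truth(self, fixture_movie):
        """Single moving bubble, noiseless: per-frame argmax stays within
        one pixel of the true position."""
        src = max(fixture_movie["trajectories"].bubbles, key=lambda b: b.n_frames)
        b = u.phantom.Bubble(frames=np.arange(src.n_frames), xy_um=src.xy_um,
                             speed_mm_s=src.speed_mm_s, segment=src.segment)
        traj = u.BubbleTrajectorySet(bubbles=[b], frame_rate_hz=1000.0,
                                     n_frames=src.n_frames)
        clean = u.render_movie(traj, shape=(128, 128), pixel_size_um=10.0,
                               psf_sigma_um=10.0, seed=0)
        for f, (x, y) in zip(b.frames, b.xy_um):
            r, c = np.unravel_index(np.argmax(clean.frames[f]), (128, 128))
            assert abs(c - x / 10.0) <= 1.0 and abs(r - y / 10.0) <= 1.0

    def test_deterministic(self):
        ph = u.generate_phantom(seed=2)
        traj = u.simulate_bubble_flow(ph, bubbles_per_frame=0.5, n_frames=20, seed=3)
        a = u.render_movie(traj, clutter_rank=2, clutter_amplitude=10.0,
                           noise_sigma=0.05, seed=4)
        b = u.render_movie(traj, clutter_rank=2, clutter_amplitude=10.0,
                           noise_sigma=0.05, seed=4)
        np.testing.assert_array_equal(a.frames, b.frames)
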