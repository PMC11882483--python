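"""Structural and hemodynamic metrics: tortuosity, fractal dimension,
orientation variance, flow volume, densities."""
import numpy as np
import pytest

from ulmtools import metrics as M


def sierpinski(depth=9):
    """Sierpinski triangle on a 2^depth grid: pixel set where row & col == 0."""
    n = 2 ** depth
    i, j = np.mgrid[0:n, 0:n]
    return (i & j) == 0


class TestCurvature:
    def test_straight(self):
        assert M.curvature(10.0, 10.0) == 1.0

    def test_semicircle(self):
        r = 1.0
        assert M.curvature(np.pi * r, 2 * r) == pytest.approx(np.pi / 2, rel=1e-9)

    def test_right_angle_elbow(self):
        assert M.curvature(2.0, np.sqrt(2.0)) == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_zero_chord_rejected(self):
        with pytest.raises(ValueError):
            M.curvature(5.0, 0.0)


class TestFractalDimension:
    def test_filled_square(self):
        fit = M.fractal_dimension(np.ones((512, 512), dtype=bool))
        assert fit.fd == pytest.approx(2.0, abs=0.05)
        assert not fit.flagged

    def test_straight_line(self):
        mask = np.zeros((512, 512), dtype=bool)
        mask[256] = True
        fit = M.fractal_dimension(mask)
        assert fit.fd == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_matches_analytic_dimension(self):
        """Box counting recovers log 3 / log 2 for the Sierpinski triangle,
        with the R^2 > 0.99 scale-selection rule active."""
        fit = M.fractal_dimension(sierpinski(9), r2_min=0.99)
        assert fit.fd == pytest.approx(np.log(3) / np.log(2), abs=0.1)
        assert fit.r2 > 0.99

    def test_monotone_complexity(self):
        line = np.zeros((512, 512), dtype=bool)
        line[256] = True
        fd_line = M.fractal_dimension(line).fd
        fd_sier = M.fractal_dimension(sierpinski(9)).fd
        fd_square = M.fractal_dimension(np.ones((512, 512), dtype=bool)).fd
        assert fd_line < fd_sier < fd_square

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            M.fractal_dimension(np.zeros((64, 64), dtype=bool))


class TestOrientationVariance:
    def test_parallel_directions(self):
        assert M.orientation_variance(np.full(10, 0.7)) == pytest.approx(0.0)

    def test_two_point_spread(self):
        d = np.array([1.0 + 0.2, 1.0 - 0.2] * 5)
        assert M.orientation_variance(d) == pytest.approx(0.04, rel=1e-9)

    def test_wraparound_seam(self):
        """Directions at 179 deg and -179 deg are nearly parallel: variance
        is (pi/180)^2, not about pi^2."""
        d = np.deg2rad([179.0, -179.0])
        v = M.orientation_variance(d)
        assert v == pytest.approx(np.deg2rad(1.0) ** 2, rel=1e-6)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(12)
        d = rng.normal(0.3, 0.4, size=50)
        base = M.orientation_variance(d)
        for shift in (0.5, 2.0, np.pi, -2.8):
            rotated = np.mod(d + shift + np.pi, 2 * np.pi) - np.pi
            assert M.orientation_variance(rotated) == pytest.approx(base, rel=1e-9)

    def test_axial_mode_identifies_opposite_flows(self):
        d = np.array([0.1, 0.1 + np.pi, 0.1, 0.1 - np.pi])
        assert M.orientation_variance(d, axial=True) == pytest.approx(0.0, abs=1e-12)
        assert M.orientation_variance(d) > 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            M.orientation_variance(np.array([]))


class TestFlowVolume:
    def test_zero_diameter(self):
        assert M.flow_volume(0.0, 5.0) == 0.0

    def test_printed_case(self):
        # d = 40 um, V = 5 mm/s: Q = pi * 400 * 5000 um^3/s ~ 6.283 nL/s
        q = M.flow_volume(40.0, 5.0)
        assert q == pytest.approx(np.pi * 400.0 * 5000.0 / 1e6, rel=1e-12)
        assert q == pytest.approx(6.283e6 / 1e6, rel=1e-3)

    def test_doubling_diameter_quadruples_q(self):
        assert M.flow_volume(80.0, 5.0) == pytest.approx(4 * M.flow_volume(40.0, 5.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            M.flow_volume(-1.0, 5.0)


class TestVascularDensity:
    def test_full_and_empty(self):
        roi = np.ones((10, 10), dtype=bool)
        assert M.vascular_density(roi, roi) == 1.0
        assert M.vascular_density(np.zeros_like(roi), roi) == 0.0

    def test_half_covered(self):
        roi = np.ones((10, 10), dtype=bool)
        mask = np.zeros_like(roi)
        mask[:5] = True
        assert M.vascular_density(mask, roi) == 0.5

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            M.vascular_density(np.ones((4, 4), bool), np.zeros((4, 4), bool))


class TestHistologyIndices:
    def test_identical_masks(self):
        m = np.ones((8, 8), dtype=bool)
        h = M.histology_mask_metrics(m, m, m)
        assert h.vd_h == 1.0 and h.vmi_h == 1.0

    def test_no_asma(self):
        m = np.ones((8, 8), dtype=bool)
        h = M.histology_mask_metrics(m, np.zeros_like(m), m)
        assert h.vmi_h == 0.0

    def test_counting_case(self):
        region = np.ones((10, 10), dtype=bool)
        cd31 = np.zeros_like(region)
        cd31[:3] = True                            # 30% of the region
        asma = np.zeros_like(region)
        asma[:3, :5] = True                        # half of the CD31 area
        h = M.histology_mask_metrics(cd31, asma, region)
        assert h.vd_h == pytest.approx(0.30)
        assert h.vmi_h == pytest.approx(0.50)

    def test_no_cd31_gives_nan_vmi(self):
        region = np.ones((8, 8), dtype=bool)
        h = M.histology_mask_metrics(np.zeros_like(region),
                                     np.zeros_like(region), region)
        assert h.vd_h == 0.0
        assert np.isnan(h.vmi_h)


class TestRegionMetrics:
    def test_flow_volume_consistency(self, default_end_to_end):
        """Per-segment Q always equals pi (d/2)^2 V recomputed directly."""
        res = default_end_to_end
        per_seg = M.segment_metrics(res.graph, res.maps)
        checked = 0
        for m in per_seg:
            if np.isfinite(m.flow_volume_nl_s):
                q = np.pi * (m.diameter_um / 2) ** 2 * m.velocity_mm_s * 1000 / 1e6
                assert m.flow_volume_nl_s == pytest.approx(q, rel=1e-9)
                checked += 1
        assert checked > 10

    def test_empty_roi_flagged_not_error(self, default_end_to_end):
        res = default_end_to_end
        roi = np.zeros_like(res.mask)
        roi[:8, :8] = True                         # corner with no vessels
        rm = M.region_metrics(res.maps, res.graph, res.mask & False, roi)
        assert not rm.has_vessels
        assert rm.branches == 0 and rm.density == 0.0

    def test_region_branch_counts_bounded_by_total(self, default_end_to_end):
        res = default_end_to_end
        gf = res.maps.grid_factor
        total = 0
        for name in res.phantom.region_names:
            roi = np.kron(res.phantom.region_mask(name),
                          np.ones((gf, gf), dtype=bool))
            total += M.region_metrics(res.maps, res.graph, res.mask, roi).branches
        assert total <= len(res.graph.segments)
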