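"""Vessel mask binarization, skeletonization and graph extraction."""
import numpy as np
import pytest

import ulmtools as u
from ulmtools.graph import (binarize_density, condition_mask, estimate_diameters,
                            extract_graph, skeletonize_mask)


def graph_of(mask, px=1.0, prune_px=0):
    return extract_graph(skeletonize_mask(np.asarray(mask, bool)), px,
                         prune_px=prune_px)


class TestBinarize:
    def test_single_track_line_single_component(self):
        density = np.zeros((64, 64), dtype=int)
        density[32, 10:50] = 1
        vm = binarize_density(density, k=1, min_size=10)
        from scipy import ndimage
        _, n = ndimage.label(vm.mask, structure=np.ones((3, 3)))
        assert n == 1

    def test_all_zero_density_empty_mask(self):
        vm = binarize_density(np.zeros((32, 32), dtype=int))
        assert not vm.mask.any()

    def test_threshold_rule(self):
        density = np.zeros((64, 64), dtype=int)
        density[10:20, 10:40] = 1
        density[30:40, 10:40] = 2
        vm = binarize_density(density, k=2, min_size=10, closing_radius=0)
        assert vm.mask[35, 20]
        assert not vm.mask[15, 20]

    def test_dice_against_phantom_truth(self, default_end_to_end):
        """Segmentation quality gate: the density-derived mask overlaps the
        phantom's true lumen mask with Dice >= 0.7."""
        res = default_end_to_end
        gf = res.maps.grid_factor
        truth = np.kron(u.true_vessel_mask(res.phantom),
                        np.ones((gf, gf), dtype=bool))
        dice = 2 * np.sum(res.mask & truth) / (res.mask.sum() + truth.sum())
        assert dice >= 0.7, f"Dice {dice:.3f}"


class TestSkeletonize:
    def test_bar_thins_to_line(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[14:19, 4:28] = True
        skel = skeletonize_mask(mask)
        rows = np.nonzero(skel.any(axis=1))[0]
        assert len(rows) == 1                   # single-row line
        assert skel[rows[0]].sum() >= 20
        assert not np.any(skel & ~mask)

    def test_empty_mask(self):
        assert skeletonize_mask(np.zeros((16, 16), dtype=bool)).sum() == 0

    def test_skeleton_subset_of_mask(self, default_end_to_end):
        res = default_end_to_end
        cond = condition_mask(res.mask)
        skel = skeletonize_mask(cond)
        assert not np.any(skel & ~cond)

    def test_plus_sign_has_single_junction_cluster(self):
        """The crossing of a plus sign thins to one junction: all
        high-degree pixels form a single connected cluster at the centre."""
        from scipy import ndimage as ndi

        mask = np.zeros((21, 21), dtype=bool)
        mask[10, 2:19] = True
        mask[2:19, 10] = True
        skel = skeletonize_mask(mask)
        from ulmtools.graph import _neighbor_degree
        deg = _neighbor_degree(skel)
        _, n = ndi.label(skel & (deg >= 3), structure=np.ones((3, 3)))
        assert n == 1


class TestExtractGraph:
    def test_straight_line(self):
        skel = np.zeros((16, 32), dtype=bool)
        skel[8, 4:28] = True
        g = extract_graph(skel, pixel_size_um=2.0)
        assert len(g.endpoints) == 2
        assert len(g.branch_points) == 0
        assert len(g.segments) == 1
        seg = g.segments[0]
        assert seg.lc_um == pytest.approx(seg.l_um)
        assert seg.l_um == pytest.approx(23 * 2.0)

    def test_plus_sign(self):
        skel = np.zeros((21, 21), dtype=bool)
        skel[10, 2:19] = True
        skel[2:19, 10] = True
        g = extract_graph(skel, pixel_size_um=1.0)
        assert len(g.branch_points) == 1
        assert len(g.segments) == 4
        assert len(g.endpoints) == 4

    def test_y_shape(self):
        skel = np.zeros((24, 24), dtype=bool)
        skel[2:12, 12] = True                       # stem
        for i in range(1, 9):                       # two diagonal arms
            skel[11 + i, 12 - i] = True
            skel[11 + i, 12 + i] = True
        g = extract_graph(skel, pixel_size_um=1.0)
        assert len(g.branch_points) == 1
        assert len(g.segments) == 3
        assert len(g.endpoints) == 3

    def test_lc_at_least_l_everywhere(self, default_end_to_end):
        for seg in default_end_to_end.graph.segments:
            assert seg.lc_um >= seg.l_um - 1e-9

    def test_segments_partition_nonnode_skeleton(self):
        skel = np.zeros((40, 40), dtype=bool)
        skel[20, 2:38] = True
        skel[2:38, 20] = True
        skel[5:20, 5] = True
        g = extract_graph(skel, pixel_size_um=1.0)
        node_px = set()
        for n in g.nodes:
            node_px.update(n.pixels)
        counts = {}
        for seg in g.segments:
            for r, c in map(tuple, seg.path_rc[1:-1]):
                counts[(r, c)] = counts.get((r, c), 0) + 1
        assert all(v == 1 for v in counts.values())
        covered = set(counts) | node_px
        for rc in map(tuple, np.argwhere(skel)):
            assert rc in covered

    def test_full_binary_tree_segment_count(self):
        """For a full binary tree with b branch points, segments = 2b + 1."""
        skel = np.zeros((64, 128), dtype=bool)

        def grow(r, c, depth, span):
            skel[r:r + 10, c] = True
            if depth == 0:
                return
            rr = r + 10
            for d in (-span, span):
                steps = abs(span)
                for i in range(1, steps + 1):
                    skel[rr + i - 1, c + int(np.sign(d)) * i] = True
                grow(rr + steps, c + d, depth - 1, span // 2)

        grow(2, 64, 2, 16)
        g = extract_graph(skel, pixel_size_um=1.0)
        b = len(g.branch_points)
        assert b == 3
        assert len(g.segments) == 2 * b + 1


class TestDiameters:
    def test_bar_diameter(self):
        mask = np.zeros((32, 64), dtype=bool)
        mask[14:19, 4:60] = True                   # 5 px wide bar
        g = graph_of(mask, px=10.0)
        estimate_diameters(mask, g)
        assert len(g.segments) == 1
        assert g.segments[0].diameter_um == pytest.approx(50.0, abs=10.0)

    def test_single_pixel_line(self):
        mask = np.zeros((16, 32), dtype=bool)
        mask[8, 4:28] = True
        g = graph_of(mask, px=10.0)
        estimate_diameters(mask, g)
        assert g.segments[0].diameter_um == pytest.approx(10.0)

    def test_skeleton_outside_mask_rejected(self):
        mask = np.zeros((16, 32), dtype=bool)
        mask[8, 4:28] = True
        g = graph_of(mask, px=10.0)
        with pytest.raises(ValueError):
            estimate_diameters(np.zeros_like(mask), g)

    def test_phantom_radius_recovered(self, straight_vessel_phantom):
        """A densely sampled vessel of true radius 20 um recovers a diameter
        within 20% of 40 um through the map, mask and distance-transform
        chain (Poiseuille-sampled bubble tracks)."""
        from ulmtools.containers import Track

        ph = straight_vessel_phantom
        traj = u.simulate_bubble_flow(ph, bubbles_per_frame=0.3, n_frames=3000,
                                      seed=31)
        tracks = [Track(frames=b.frames, xy_um=b.xy_um)
                  for b in traj.bubbles if b.n_frames >= 15]
        maps = u.accumulate_maps(tracks, (128, 128), 10.0, 1000.0)
        cond = condition_mask(binarize_density(maps.density))
        g = extract_graph(skeletonize_mask(cond), maps.superres_pixel_um,
                          prune_px=8)
        estimate_diameters(cond, g)
        main = max(g.segments, key=lambda s: len(s.path_rc))
        assert main.diameter_um == pytest.approx(40.0, rel=0.2)
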