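import numpy as np
import pytest

import microvasc as mv
from microvasc.errors import ParameterError

from conftest import make_cylinder_mask

SP = (5.0, 5.0, 5.0)


def mask_of(data):
    return mv.BinaryMask(np.asarray(data, dtype=bool), SP)


class TestSkeletonize:
    def test_empty_mask_empty_skeleton(self):
        skel = mv.skeletonize_mask(mask_of(np.zeros((4, 4, 4))))
        assert skel.positive_count() == 0

    def test_one_voxel_wide_line_unchanged(self):
        a = np.zeros((3, 3, 12), dtype=bool)
        a[1, 1, 1:11] = True
        skel = mv.skeletonize_mask(mask_of(a))
        np.testing.assert_array_equal(skel.data, a)

    def test_skeleton_subset_and_component_count(self, small_phantom):
        _, truth = small_phantom
        mask = truth.mask
        skel = mv.skeletonize_mask(mask)
        assert not (skel.data & ~mask.data).any()
        _, t_mask = mv.connected_components(mask)
        _, t_skel = mv.connected_components(skel)
        assert len(t_mask) == len(t_skel)

    def test_cylinder_centerline_near_axis(self):
        mask, c = make_cylinder_mask(4, length=40)
        skel = mv.skeletonize_mask(mask)
        coords = np.argwhere(skel.data)
        assert len(coords) > 0
        # every skeleton voxel within 1 voxel of the analytic axis
        assert np.abs(coords[:, 1:] - c).max() <= 1
        _, table = mv.connected_components(skel)
        assert len(table) == 1


def make_y_mask():
    """Three 10-voxel arms meeting at one voxel, arranged so that no two
    arm voxels other than at the centre are 26-adjacent."""
    a = np.zeros((5, 21, 21), dtype=bool)
    c = (2, 10, 10)
    a[c] = True
    for i in range(1, 10):
        a[2, 10, 10 + i] = True  # +x arm
        a[2, 10 + i, 10 - i] = True  # diagonal arm
        a[2, 10 - i, 10 - i] = True  # other diagonal arm
    return mask_of(a)


def make_diamond_loop():
    """A closed diagonal loop where every voxel has exactly two
    26-neighbours (a pure cycle)."""
    ring = [(0, 3), (1, 2), (2, 1), (3, 0), (4, 1), (5, 2),
            (6, 3), (5, 4), (4, 5), (3, 6), (2, 5), (1, 4)]
    a = np.zeros((3, 8, 8), dtype=bool)
    for y, x in ring:
        a[1, y, x] = True
    return mask_of(a), len(ring)


class TestExtractGraph:
    def test_straight_line(self):
        a = np.zeros((3, 3, 12), dtype=bool)
        a[1, 1, 1:11] = True  # 10 voxels
        g = mv.extract_graph(mask_of(a))
        assert len(g.nodes) == 2
        assert sorted(n.degree for n in g.nodes) == [1, 1]
        assert len(g.segments) == 1
        assert g.segments[0].length_um == pytest.approx(9 * 5.0)

    def test_y_junction(self):
        g = mv.extract_graph(make_y_mask())
        assert len(g.nodes) == 4
        assert sorted(n.degree for n in g.nodes) == [1, 1, 1, 3]
        assert len(g.segments) == 3
        # every skeleton voxel appears in exactly one polyline (the branch
        # voxel is shared as an endpoint)
        interiors = [tuple(p) for s in g.segments for p in s.points_um[1:-1]]
        assert len(interiors) == len(set(interiors))

    def test_pure_cycle_gets_anchor(self):
        mask, n_ring = make_diamond_loop()
        g = mv.extract_graph(mask)
        assert len(g.nodes) == 1  # one cycle anchor
        assert len(g.segments) == 1
        seg = g.segments[0]
        assert seg.node_ids[0] == seg.node_ids[1]  # returns to its anchor
        assert len(seg.points_um) == n_ring + 1  # closed polyline
        # Euler: E - V + C = cycle rank 1
        assert len(g.segments) - len(g.nodes) + 1 == 1

    def test_non_thin_input_rejected(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[0:2, 0:2, 0:2] = True  # solid 2x2x2 block
        with pytest.raises(ParameterError):
            mv.extract_graph(mask_of(a))


class TestRadii:
    @pytest.mark.parametrize("r", [3, 4, 6])
    def test_cylinder_radius_recovery(self, r):
        """Interior mean radius of a digital cylinder within +-0.6 voxel."""
        mask, _ = make_cylinder_mask(r, length=40)
        skel = mv.skeletonize_mask(mask)
        g = mv.estimate_radii(mv.extract_graph(skel), mask)
        pts = np.concatenate([s.points_um for s in g.segments])
        radii = np.concatenate([s.radii_um for s in g.segments])
        z = pts[:, 0]
        interior = (z >= z.min() + 2 * SP[0]) & (z <= z.max() - 2 * SP[0])
        mean_vox = radii[interior].mean() / SP[0]
        assert abs(mean_vox - r) <= 0.6

    def test_isolated_voxel_radius_bounded_by_pitch(self):
        a = np.zeros((5, 5, 5), dtype=bool)
        a[2, 2, 2] = True
        mask = mask_of(a)
        skel = mv.skeletonize_mask(mask)
        g = mv.estimate_radii(mv.extract_graph(skel), mask)
        assert len(g.nodes) == 1
        assert 0 < g.nodes[0].radius_um <= SP[0]

    def test_two_cylinders_radii_ordered(self):
        # radii 2 and 6 voxels side by side: per-segment means must order
        a = np.zeros((30, 40, 20), dtype=bool)
        yy, xx = np.mgrid[0:40, 0:20]
        a[:, (yy - 8) ** 2 + (xx - 10) ** 2 <= 2**2] = True
        a[:, (yy - 28) ** 2 + (xx - 10) ** 2 <= 6**2] = True
        mask = mask_of(a)
        g = mv.estimate_radii(mv.extract_graph(mv.skeletonize_mask(mask)), mask)
        means = {}
        for s in g.segments:
            y_mean = s.points_um[:, 1].mean()
            key = "thin" if y_mean < 18 * 5 else "thick"
            means.setdefault(key, []).append(s.radii_um.mean())
        assert np.mean(means["thin"]) < np.mean(means["thick"])

    def test_mean_radius_invariant_under_reversal(self):
        mask, _ = make_cylinder_mask(3, length=20)
        g = mv.estimate_radii(mv.extract_graph(mv.skeletonize_mask(mask)), mask)
        base = mv.graph_summary(g).mean_radius_um
        for s in g.segments:
            s.points_um = s.points_um[::-1].copy()
            s.radii_um = s.radii_um[::-1].copy()
        assert mv.graph_summary(g).mean_radius_um == pytest.approx(base)


class TestClassify:
    @pytest.mark.parametrize(
        "radius,expected",
        [(2.0, "thin"), (2.999, "thin"), (3.0, "intermediate"),
         (7.0, "intermediate"), (11.0, "intermediate"), (12.0, "thick")],
    )
    def test_calibre_classes(self, radius, expected):
        assert mv.classify_radius(radius) == expected

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ParameterError):
            mv.classify_radius(0.0)


class TestSummaryAndExport:
    def test_summary_arithmetic(self):
        mask, _ = make_cylinder_mask(3, length=20)
        g = mv.estimate_radii(mv.extract_graph(mv.skeletonize_mask(mask)), mask)
        s = mv.graph_summary(g)
        assert s.n_segments == len(g.segments)
        assert s.mean_radius_um == pytest.approx(g.all_point_radii().mean())
        assert sum(s.class_length_fractions.values()) == pytest.approx(1.0)

    def test_empty_graph_summary(self):
        g = mv.VascularGraph(nodes=[], segments=[], spacing=SP)
        s = mv.graph_summary(g)
        assert s.n_segments == 0 and s.total_length_um == 0.0
        assert np.isnan(s.mean_radius_um)

    def test_export_import_roundtrip_bit_exact(self, tmp_path):
        g = mv.extract_graph(make_y_mask())
        mask = make_y_mask()
        g = mv.estimate_radii(g, mask)
        base = str(tmp_path / "graph")
        mv.export_spatial_graph(g, base)
        back = mv.import_spatial_graph(base, SP)
        assert len(back.segments) == len(g.segments) == 3
        assert {s.id for s in back.segments} == {s.id for s in g.segments}
        for a, b in zip(g.segments, back.segments):
            np.testing.assert_array_equal(a.points_um, b.points_um)
            np.testing.assert_array_equal(a.radii_um, b.radii_um)

    def test_empty_graph_exports_header_only(self, tmp_path):
        g = mv.VascularGraph(nodes=[], segments=[], spacing=SP)
        p_path, n_path = mv.export_spatial_graph(g, str(tmp_path / "empty"))
        assert open(p_path).read().strip() == (
            "segment_id,point_index,z_um,y_um,x_um,radius_um"
        )
        back = mv.import_spatial_graph(str(tmp_path / "empty"), SP)
        assert back.segments == [] and back.nodes == []
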