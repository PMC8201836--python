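"""Rod geometry: lattice placement, spline tubes, expansion, valley."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

import rodplan as rp
from rodplan.rods import bending_rod_centerline


def rod_planar_centroids(rods, axis, center):
    """Rod centroids relative to ``center``, projected onto the rod-normal plane."""
    u = np.cross([0.0, 1.0, 0.0], axis)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    out = []
    for rod in rods:
        c = rod.centroid_mm() - center
        out.append((c @ u, c @ v))
    return np.asarray(out)


class TestAxisFromAngles:
    def test_zero_angles_map_to_plus_z(self):
        assert np.allclose(rp.axis_from_angles(0.0, 0.0), [0, 0, 1])

    @pytest.mark.parametrize("zx,zy", [(30.0, 0.0), (0.0, -25.0), (20.0, 40.0)])
    def test_matches_independent_rotation_matrices(self, zx, zy):
        """Rotate +z by zx about y then zy about x, via scipy Rotation."""
        expected = (
            Rotation.from_euler("x", zy, degrees=True).as_matrix()
            @ Rotation.from_euler("y", zx, degrees=True).as_matrix()
            @ np.array([0.0, 0.0, 1.0])
        )
        assert np.allclose(rp.axis_from_angles(zx, zy), expected, atol=1e-12)

    def test_near_limit_angle_approaches_axial_plane(self):
        v = rp.axis_from_angles(89.9, 0.0)
        assert abs(v[0]) > 0.999
        assert np.isclose(np.linalg.norm(v), 1.0)

    @pytest.mark.parametrize("zx,zy", [(90.0, 0.0), (0.0, -95.0)])
    def test_right_angle_rejected(self, zx, zy):
        with pytest.raises(ValueError):
            rp.axis_from_angles(zx, zy)


class TestStraightRods:
    def test_pitch_and_edge_gap_on_box(self):
        """Adjacent rods sit 15 mm apart center-to-center, 10 mm edge-to-edge."""
        grid = rp.VoxelGrid(shape=(88, 88, 48), spacing_mm=1.25)
        data = np.zeros(grid.shape, dtype=bool)
        data[4:84, 4:84, 4:44] = True  # 100 mm square cross-section
        target = rp.StructureMask("box", grid, data)
        spec = rp.StraightRodGridSpec(max_rods=None)
        rods = rp.generate_straight_rods(target, spec)
        assert len(rods) == 49  # lattice points at 0, +-15, +-30, +-45 mm
        cent = rod_planar_centroids(rods, rods.axis, target.centroid_mm())
        # nearest-neighbor planar centroid separation
        half_voxel = grid.spacing_mm / 2
        d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nearest = d.min(axis=1)
        assert np.all(np.abs(nearest - 15.0) <= half_voxel)
        # edge-to-edge gap between two adjacent rods' voxel clouds
        i, j = np.unravel_index(np.argmin(d), d.shape)
        sp = grid.spacing_mm
        pts_i = np.argwhere(rods.rods[i].data) * sp
        pts_j = np.argwhere(rods.rods[j].data) * sp
        gap, _ = cKDTree(pts_j).query(pts_i, k=1)
        # voxel-center distance overestimates the surface gap by <= one voxel
        assert gap.min() == pytest.approx(10.0, abs=sp + half_voxel)

    def test_max_rods_kept_central_first(self, box_target):
        rods = rp.generate_straight_rods(box_target, rp.StraightRodGridSpec())
        assert len(rods) == 3
        cent = rod_planar_centroids(rods, rods.axis, box_target.centroid_mm())
        radii = np.linalg.norm(cent, axis=1)
        assert radii[0] == min(radii)  # most central rod first
        assert radii[0] <= box_target.grid.spacing_mm  # anchored at centroid

    def test_voxelized_cylinder_volume_matches_analytic(self):
        """Single unclipped rod volume agrees with pi r^2 L within 3%."""
        grid = rp.VoxelGrid(shape=(60, 60, 80), spacing_mm=0.5)
        data = np.zeros(grid.shape, dtype=bool)
        data[2:58, 2:58, 10:70] = True
        target = rp.StructureMask("box", grid, data)
        spec = rp.StraightRodGridSpec(diameter_mm=5.0, center_to_center_mm=40.0,
                                      max_rods=1)
        rods = rp.generate_straight_rods(target, spec)
        rod = rods.rods[0]
        w = np.argwhere(rod.data)[:, 2]
        length = (w.max() - w.min() + 1) * grid.spacing_mm
        analytic = np.pi * 2.5**2 * length / 1000.0
        assert rod.volume_cm3 == pytest.approx(analytic, rel=0.03)

    def test_single_voxel_target(self):
        grid = rp.VoxelGrid(shape=(16, 16, 16), spacing_mm=1.25)
        data = np.zeros(grid.shape, dtype=bool)
        data[8, 8, 8] = True
        rods = rp.generate_straight_rods(
            rp.StructureMask("dot", grid, data), rp.StraightRodGridSpec()
        )
        assert len(rods) <= 1
        assert rods.volume_cm3 <= grid.voxel_volume_cm3 + 1e-12

    def test_no_intersection_warns_and_returns_empty(self):
        grid = rp.VoxelGrid(shape=(16, 16, 16), spacing_mm=1.25)
        data = np.zeros(grid.shape, dtype=bool)
        data[8, 8, 8] = True
        target = rp.StructureMask("dot", grid, data)
        spec = rp.StraightRodGridSpec(offset_uv_mm=(7.5, 7.5), max_rods=None)
        with pytest.warns(UserWarning, match="empty RodSet"):
            rods = rp.generate_straight_rods(target, spec)
        assert len(rods) == 0

    def test_rods_contained_in_target(self, coarse_phantom, coarse_rods):
        ctv = coarse_phantom["CTV"]
        union = coarse_rods.union_mask(ctv.grid)
        assert not (union.data & ~ctv.data).any()

    def test_translation_equivariance(self):
        """Shifting the target by whole voxels shifts the rods identically."""
        grid = rp.VoxelGrid(shape=(48, 48, 48), spacing_mm=1.25)
        x, y, z = grid.coordinate_grids()
        c = 20 * 1.25
        ell = ((x - c) / 14) ** 2 + ((y - c) / 11) ** 2 + ((z - c) / 20) ** 2 <= 1
        spec = rp.StraightRodGridSpec()
        rods_a = rp.generate_straight_rods(rp.StructureMask("a", grid, ell), spec)
        shifted = np.roll(ell, shift=(3, 2, 1), axis=(0, 1, 2))
        rods_b = rp.generate_straight_rods(rp.StructureMask("b", grid, shifted), spec)
        assert len(rods_a) == len(rods_b)
        for ra, rb in zip(rods_a, rods_b):
            assert np.array_equal(
                np.roll(ra.data, shift=(3, 2, 1), axis=(0, 1, 2)), rb.data
            )

    def test_merging_spacing_rejected(self):
        with pytest.raises(ValueError, match="merge"):
            rp.StraightRodGridSpec(diameter_mm=5.0, center_to_center_mm=5.0)


class TestBendingRod:
    def test_collinear_seeds_give_straight_cylinder(self, box_target):
        c = box_target.centroid_mm()
        seeds = tuple(tuple(c + [0, 0, dz]) for dz in (-20.0, 0.0, 20.0))
        bent = rp.generate_bending_rod(
            box_target, rp.BendingRodSpec(seed_points_mm=seeds, diameter_mm=5.0)
        )
        straight = rp.generate_straight_rods(
            box_target,
            rp.StraightRodGridSpec(diameter_mm=5.0, center_to_center_mm=100.0,
                                   max_rods=1),
        ).rods[0]
        # compare between the seed endpoints, excluding the spherical end
        # caps of the swept tube (the straight rod spans the whole target)
        sp = box_target.grid.spacing_mm
        z0 = int(np.ceil((c[2] - 20.0 + 2.5) / sp)) + 1
        z1 = int(np.floor((c[2] + 20.0 - 2.5) / sp)) - 1
        assert z1 > z0
        assert np.array_equal(bent.data[:, :, z0:z1 + 1], straight.data[:, :, z0:z1 + 1])

    def test_two_seeds_make_a_straight_segment(self, box_target):
        c = box_target.centroid_mm()
        seeds = (tuple(c + [0, 0, -15.0]), tuple(c + [0, 0, 15.0]))
        rod = rp.generate_bending_rod(box_target, rp.BendingRodSpec(seeds, 5.0))
        idx = np.argwhere(rod.data)
        # every occupied voxel lies within the tube radius of the segment line
        xy = idx[:, :2] * box_target.grid.spacing_mm
        center = c[:2]
        assert np.all(np.linalg.norm(xy - center, axis=1) <= 2.5 + 1e-9)
        assert not rod.is_empty()

    def test_quarter_circle_arc_length(self):
        """Spline arc length matches the analytic quarter circle within 2%."""
        radius = 40.0
        angles = np.linspace(0, np.pi / 2, 5)
        seeds = tuple(
            (radius * np.cos(a), radius * np.sin(a), 0.0) for a in angles
        )
        spec = rp.BendingRodSpec(seed_points_mm=seeds, diameter_mm=5.0)
        samples = bending_rod_centerline(spec, spacing_mm=1.25)
        length = np.linalg.norm(np.diff(samples, axis=0), axis=1).sum()
        assert length == pytest.approx(np.pi / 2 * radius, rel=0.02)

    def test_centerline_passes_through_seeds(self, box_target):
        c = box_target.centroid_mm()
        seeds = tuple(
            tuple(c + delta)
            for delta in ([0, 0, -20], [6, -4, -5], [-5, 6, 10], [0, 0, 20])
        )
        spec = rp.BendingRodSpec(seed_points_mm=seeds, diameter_mm=5.0)
        samples = bending_rod_centerline(spec, box_target.grid.spacing_mm)
        dist, _ = cKDTree(samples).query(np.asarray(seeds), k=1)
        assert dist.max() <= box_target.grid.spacing_mm / 2

    def test_seed_outside_target_rejected(self, box_target):
        seeds = ((1.0, 1.0, 1.0), tuple(box_target.centroid_mm()))
        with pytest.raises(ValueError, match="outside the target"):
            rp.generate_bending_rod(box_target, rp.BendingRodSpec(seeds, 5.0))

    def test_tight_curvature_warns(self, box_target):
        c = box_target.centroid_mm()
        seeds = tuple(
            tuple(c + d) for d in ([0, 0, -10], [8, 0, -9.0], [0, 0, -8], [0, 0, 10])
        )
        with pytest.warns(UserWarning, match="curvature"):
            rp.generate_bending_rod(box_target, rp.BendingRodSpec(seeds, 5.0))


class TestExpandAndValley:
    def test_zero_margin_is_identity(self, coarse_phantom):
        ctv = coarse_phantom["CTV"]
        assert np.array_equal(rp.expand(ctv, 0.0).data, ctv.data)

    def test_sphere_expansion_matches_analytic_volume(self):
        grid = rp.VoxelGrid(shape=(88, 88, 88), spacing_mm=0.625)
        x, y, z = grid.coordinate_grids()
        c = 43.5 * 0.625
        sphere = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= 20.0**2
        mask = rp.StructureMask("sphere", grid, sphere)
        grown = rp.expand(mask, 5.0)
        analytic = 4.0 / 3.0 * np.pi * 25.0**3 / 1000.0
        assert grown.volume_cm3 == pytest.approx(analytic, rel=0.03)

    def test_expansion_is_superset(self, coarse_phantom):
        ctv = coarse_phantom["CTV"]
        grown = rp.expand(ctv, 5.0)
        assert (grown.data | ctv.data).sum() == grown.data.sum()
        assert grown.data.sum() > ctv.data.sum()

    def test_negative_margin_rejected(self, coarse_phantom):
        with pytest.raises(ValueError):
            rp.expand(coarse_phantom["CTV"], -1.0)

    def test_valley_zero_margin_is_boolean_difference(self, coarse_phantom, coarse_rods):
        ctv = coarse_phantom["CTV"]
        valley = rp.make_valley(ctv, coarse_rods, 0.0)
        union = coarse_rods.union_mask(ctv.grid)
        assert np.array_equal(valley.data, ctv.data & ~union.data)

    def test_valley_properties_at_default_margin(self, coarse_phantom, coarse_rods,
                                                 coarse_valley):
        ctv = coarse_phantom["CTV"]
        union = coarse_rods.union_mask(ctv.grid)
        grown = rp.expand(union, 3.0)
        # disjoint from expanded rods, contained in target, covers the rest
        assert not (coarse_valley.data & grown.data).any()
        assert not (coarse_valley.data & ~ctv.data).any()
        assert np.array_equal(coarse_valley.data | (grown.data & ctv.data), ctv.data)
        # 5 mm rods at 15 mm pitch leave far more valley than rod
        assert coarse_valley.volume_cm3 > coarse_rods.volume_cm3

    def test_empty_rodset_valley_is_target(self, coarse_phantom):
        ctv = coarse_phantom["CTV"]
        valley = rp.make_valley(ctv, rp.RodSet(), 3.0)
        assert np.array_equal(valley.data, ctv.data)
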