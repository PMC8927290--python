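import numpy as np
import pytest
from scipy.spatial import ConvexHull

from dosekit.beam_mask import (
    bev_aperture,
    combined_beam_mask,
    rasterize_beam,
    source_position,
)
from dosekit.grid import VoxelGrid
from dosekit.plans import PlanSpec


def sphere_mask(grid, center, radius):
    c = grid.voxel_centers()
    return ((c - np.asarray(center)) ** 2).sum(axis=-1) <= radius**2


class TestSourcePosition:
    @pytest.mark.parametrize(
        "angle,expected",
        [
            (0.0, (0.0, -1000.0, 0.0)),  # anterior for a supine patient
            (90.0, (1000.0, 0.0, 0.0)),  # patient left
            (180.0, (0.0, 1000.0, 0.0)),  # posterior
            (270.0, (-1000.0, 0.0, 0.0)),  # patient right
        ],
    )
    def test_cardinal_angles(self, angle, expected):
        np.testing.assert_allclose(
            source_position(angle, (0, 0, 0), 1000.0), expected, atol=1e-9
        )

    def test_distance_is_sad_for_any_angle(self, rng):
        iso = np.array([3.0, -7.0, 12.0])
        for angle in rng.uniform(0, 360, 25):
            src = source_position(angle, iso, 850.0)
            assert np.linalg.norm(src - iso) == pytest.approx(850.0)
            assert src[2] == iso[2]  # coplanar: axial plane through isocenter


class TestBevAperture:
    def test_central_sphere_gives_disc_of_ptv_radius(self, small_grid):
        r = 20.0
        ptv = sphere_mask(small_grid, (0, 0, 0), r)
        ap = bev_aperture(source_position(0.0), (0, 0, 0), ptv, small_grid)
        minx, miny, maxx, maxy = ap.polygon.bounds
        tol = max(small_grid.spacing)  # parallel-projection limit, 1 voxel
        assert abs(maxx - r) < tol and abs(minx + r) < tol
        assert abs(maxy - r) < tol and abs(miny + r) < tol

    def test_off_axis_ptv_shifts_aperture_centroid(self, small_grid):
        dx = 15.0
        ptv = sphere_mask(small_grid, (dx, 0, 0), 15.0)
        ap = bev_aperture(source_position(0.0), (0, 0, 0), ptv, small_grid)
        # the PTV center lies in the isocenter plane: unit magnification
        assert ap.polygon.centroid.x == pytest.approx(dx, abs=max(small_grid.spacing))

    def test_single_voxel_ptv_degenerates_to_voxel_footprint(self, small_grid):
        ptv = np.zeros(small_grid.shape, dtype=bool)
        ptv[16, 16, 8] = True
        ap = bev_aperture(source_position(0.0), (0, 0, 0), ptv, small_grid)
        assert ap.polygon.area > 0
        minx, _, maxx, _ = ap.polygon.bounds
        assert maxx - minx <= 1.5 * max(small_grid.spacing)

    def test_empty_ptv_is_an_error(self, small_grid):
        with pytest.raises(ValueError, match="empty"):
            bev_aperture(
                source_position(0.0), (0, 0, 0), np.zeros(small_grid.shape, bool), small_grid
            )


def oracle_rasterize(angle, iso, ptv_mask, grid, sad=1000.0):
    """Independent per-voxel projection test: convex-hull half-plane
    inequalities on an independently constructed plane basis."""
    iso = np.asarray(iso, float)
    g = np.deg2rad(angle)
    src = iso + sad * np.array([np.sin(g), -np.cos(g), 0.0])
    n = (iso - src) / sad
    u = np.array([n[1], -n[0], 0.0])  # in-plane, perpendicular to the axis
    v = np.array([0.0, 0.0, 1.0])

    def project(points):
        rel = points - src
        t = sad / (rel @ n)
        return np.column_stack([t * (rel @ u), t * (rel @ v)])

    pts = project(grid.index_to_world(np.argwhere(ptv_mask).astype(float)))
    hull = ConvexHull(pts)
    vox2d = project(grid.voxel_centers().reshape(-1, 3))
    # margin <= 0 inside; hull.equations rows are (a, b, c): a*x + b*y + c <= 0
    margins = (vox2d @ hull.equations[:, :2].T + hull.equations[:, 2]).max(axis=1)
    return margins.reshape(grid.shape)


class TestRasterizeBeam:
    @pytest.mark.parametrize("angle", [0.0, 50.0, 137.0, 260.0])
    def test_matches_independent_projection_oracle(self, angle):
        grid = VoxelGrid.centered((24, 24, 12), (6.0, 6.0, 6.0))
        ptv = sphere_mask(grid, (8.0, -5.0, 3.0), 22.0)
        ap = bev_aperture(source_position(angle), (0, 0, 0), ptv, grid)
        got = rasterize_beam(ap, grid).astype(bool)
        margins = oracle_rasterize(angle, (0, 0, 0), ptv, grid)
        decisive = np.abs(margins) > 1e-7  # boundary-exact voxels are a tie-break
        np.testing.assert_array_equal(got[decisive], (margins <= 0)[decisive])

    def test_isocenter_and_ptv_voxels_are_covered_by_every_beam(
        self, small_grid, seven_beam_plan
    ):
        ptv = sphere_mask(small_grid, (0, 0, 0), 20.0)
        iso_idx = tuple(
            np.round(small_grid.world_to_index(np.zeros(3))).astype(int)
        )
        for angle in seven_beam_plan.angles:
            ap = bev_aperture(source_position(angle), (0, 0, 0), ptv, small_grid)
            beam = rasterize_beam(ap, small_grid)
            assert beam[iso_idx] == 1
            assert beam[ptv].all()

    def test_far_lateral_voxel_is_outside(self, small_grid):
        r = 20.0
        ptv = sphere_mask(small_grid, (0, 0, 0), r)
        ap = bev_aperture(source_position(0.0), (0, 0, 0), ptv, small_grid)
        beam = rasterize_beam(ap, small_grid)
        # voxel at lateral distance 3r, at isocenter depth
        idx = tuple(np.round(small_grid.world_to_index((3 * r, 0.0, 0.0))).astype(int))
        assert beam[idx] == 0


class TestCombinedBeamMask:
    def test_max_equals_prescription_and_counts_kept(self, small_grid, seven_beam_plan):
        ptv = sphere_mask(small_grid, (0, 0, 0), 20.0)
        bm = combined_beam_mask(seven_beam_plan, ptv, small_grid)
        assert bm.values.max() == pytest.approx(50.4)
        assert bm.counts.max() == 7
        assert bm.counts[ptv].min() == 7  # PTV voxels see every beam
        np.testing.assert_allclose(bm.values[ptv], 50.4)

    def test_single_beam_mask_is_binary_times_prescription(self, small_grid):
        plan = PlanSpec(angles=(40.0,), prescription_gy=50.4)
        ptv = sphere_mask(small_grid, (0, 0, 0), 15.0)
        bm = combined_beam_mask(plan, ptv, small_grid)
        assert set(np.unique(bm.values)) == {0.0, 50.4}

    def test_opposed_beams_give_180_degree_symmetric_mask(self, small_grid):
        plan = PlanSpec(angles=(0.0, 180.0))
        ptv = sphere_mask(small_grid, (0, 0, 0), 20.0)
        bm = combined_beam_mask(plan, ptv, small_grid)
        np.testing.assert_array_equal(bm.counts, np.rot90(bm.counts, 2, axes=(0, 1)))

    def test_rotation_equivariance_on_symmetric_phantom(self, small_grid):
        """Rotating all gantry angles by 90 deg rotates the mask of a
        rotationally symmetric PTV by 90 deg, voxel for voxel."""
        ptv = sphere_mask(small_grid, (0, 0, 0), 20.0)
        base = combined_beam_mask(PlanSpec(angles=(0.0, 50.0)), ptv, small_grid)
        rot = combined_beam_mask(PlanSpec(angles=(90.0, 140.0)), ptv, small_grid)
        np.testing.assert_array_equal(rot.counts, np.rot90(base.counts, 1, axes=(0, 1)))

    def test_adding_a_beam_never_decreases_coverage(self, small_grid):
        ptv = sphere_mask(small_grid, (5.0, 5.0, 0.0), 18.0)
        two = combined_beam_mask(PlanSpec(angles=(0.0, 120.0)), ptv, small_grid)
        three = combined_beam_mask(PlanSpec(angles=(0.0, 120.0, 240.0)), ptv, small_grid)
        assert (three.counts >= two.counts).all()
        # support is the union of per-beam supports
        single = combined_beam_mask(PlanSpec(angles=(240.0,)), ptv, small_grid)
        np.testing.assert_array_equal(
            three.counts > 0, (two.counts > 0) | (single.counts > 0)
        )

    def test_zero_beams_impossible(self):
        with pytest.raises(ValueError):
            PlanSpec(angles=())
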