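"""STN border lines, hit-map thresholding, contact-to-tract distance."""

import numpy as np
import pytest

from tractprox.geometry import (BorderLines, Electrode, TractMask,
                                contact_reference, perpendicular_distance,
                                standardize_threshold, stn_border_lines)
from tractprox.tracking import HitMap


def _grid_affine(shape, voxel=1.0, origin=None):
    aff = np.diag([voxel, voxel, voxel, 1.0])
    if origin is None:
        origin = -voxel * (np.array(shape) - 1) / 2.0
    aff[:3, 3] = origin
    return aff


def _ellipsoid_mask(shape, affine, center, semi):
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    m = np.sum(((world - center) / semi) ** 2, axis=1) <= 1.0
    return m.reshape(shape)


class TestBorderLines:
    def test_analytic_ellipsoid_extrema(self):
        # STN ellipsoid centered (12, -2, -4), semi-axes (3, 4, 3) on a
        # 1 mm grid: medial border x = 9, posterior border y = -6
        shape = (41, 41, 21)
        aff = _grid_affine(shape, 1.0, origin=(-8.0, -22.0, -14.0))
        stn = _ellipsoid_mask(shape, aff, (12.0, -2.0, -4.0), (3.0, 4.0, 3.0))
        lines = stn_border_lines(stn, aff)
        assert lines.side == "right"
        assert abs(lines.medial_x - 9.0) <= 1.0
        assert abs(lines.posterior_y - (-6.0)) <= 1.0

    def test_single_voxel_mask(self):
        shape = (5, 5, 5)
        aff = _grid_affine(shape, 2.0, origin=(4.0, -8.0, -8.0))
        stn = np.zeros(shape, bool)
        stn[2, 2, 2] = True  # world (8, -4, -4)
        lines = stn_border_lines(stn, aff)
        assert lines.medial_x == 8.0 and lines.posterior_y == -4.0

    def test_left_hemisphere_mirrors_medial_logic(self):
        shape = (41, 41, 21)
        aff = _grid_affine(shape, 1.0, origin=(-32.0, -22.0, -14.0))
        stn = _ellipsoid_mask(shape, aff, (-12.0, -2.0, -4.0), (3.0, 4.0, 3.0))
        lines = stn_border_lines(stn, aff)
        assert lines.side == "left"
        assert abs(lines.medial_x - (-9.0)) <= 1.0
        # STN side of the medial line is more lateral (more negative x)
        assert lines.stn_side(np.array([[-10.0, -10.0]]))[0]
        assert not lines.stn_side(np.array([[-8.0, -10.0]]))[0]

    def test_missing_plane_intersection_raises(self):
        shape = (5, 5, 5)
        aff = _grid_affine(shape, 2.0, origin=(0.0, 0.0, 10.0))
        stn = np.ones(shape, bool)
        with pytest.raises(ValueError, match="plane"):
            stn_border_lines(stn, aff)


class TestStandardizeThreshold:
    def _hitmap(self, counts, affine):
        return HitMap(counts=counts, n_accepted=int(counts.max()), affine=affine)

    def test_clean_map_keeps_tau_one(self):
        shape = (11, 11, 11)
        aff = _grid_affine(shape, 1.0, origin=(-5.0, -15.0, -9.0))
        counts = np.zeros(shape, int)
        counts[2:5, 2:5, :] = 4  # x in [-3,-1], y in [-13,-11]: off the STN side
        lines = BorderLines(plane_z=-4.0, medial_x=3.0, posterior_y=-8.0, side="right")
        tau, mask = standardize_threshold(self._hitmap(counts, aff), lines)
        assert tau == 1
        assert np.array_equal(mask.voxels, counts >= 1)

    def test_tau_found_by_exhaustive_sweep_oracle(self):
        shape = (11, 11, 11)
        aff = _grid_affine(shape, 1.0, origin=(-5.0, -15.0, -9.0))
        counts = np.zeros(shape, int)
        counts[2:5, 2:5, :] = 9          # clean core
        counts[9, 9, 5] = 2              # stray on the STN side at z=-4
        counts[8, 9, 5] = 1
        lines = BorderLines(plane_z=-4.0, medial_x=3.0, posterior_y=-8.0, side="right")
        hm = self._hitmap(counts, aff)
        tau, _ = standardize_threshold(hm, lines)

        def violates(t):
            idx = np.argwhere(counts >= t)
            world = idx @ aff[:3, :3].T + aff[:3, 3]
            on = np.abs(world[:, 2] + 4.0) <= 0.5
            return bool(lines.stn_side(world[on, :2]).any())

        expected = min(t for t in range(1, counts.max() + 1) if not violates(t))
        assert tau == expected == 3

    def test_threshold_monotonicity(self, noisy_phantom, fitted_noisy):
        from tractprox.tracking import TrackingParams, track_drt

        _, rois, _ = noisy_phantom
        _, hit = track_drt(fitted_noisy, rois.seed["right"],
                           rois.filter_masks_for("right"),
                           TrackingParams(starts_per_voxel=10, rng_seed=4))
        prev = hit.counts >= 1
        for tau in range(2, int(hit.counts.max()) + 1):
            cur = hit.counts >= tau
            assert np.all(prev[cur])  # mask(tau) subset of mask(tau-1)
            prev = cur

    def test_inseparable_raises(self):
        shape = (11, 11, 11)
        aff = _grid_affine(shape, 1.0, origin=(-5.0, -15.0, -9.0))
        counts = np.zeros(shape, int)
        counts[9, 9, 5] = 3  # the only signal sits on the STN side
        lines = BorderLines(plane_z=-4.0, medial_x=3.0, posterior_y=-8.0, side="right")
        with pytest.raises(ValueError, match="inseparable"):
            standardize_threshold(self._hitmap(counts, aff), lines)


def _electrode(centers, active, mode):
    centers = np.asarray(centers, float)
    axis = centers[1] - centers[0]
    return Electrode(axis=axis, contact_centers=centers, active=active, mode=mode)


def _lead(p0, axis, spacing=1.5):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    return [np.asarray(p0, float) + i * spacing * axis for i in range(4)]


class TestContactReference:
    def test_monopolar_is_contact_center(self):
        e = _electrode(_lead((10.0, -3.0, -6.0), (0, 0, 1)), (0,), "monopolar")
        ref, flagged = contact_reference(e)
        assert np.allclose(ref, (10.0, -3.0, -6.0))
        assert not flagged

    def test_bipolar_is_midpoint(self):
        e = _electrode(_lead((10.0, -3.0, -6.0), (0, 0, 1)), (0, 1), "bipolar")
        ref, flagged = contact_reference(e)
        assert np.allclose(ref, (10.0, -3.0, -5.25))
        assert not flagged

    def test_double_monopolar_midpoint_is_flagged(self):
        e = _electrode(_lead((0.0, 0.0, 0.0), (0, 0, 1)), (1, 2), "double_monopolar")
        ref, flagged = contact_reference(e)
        assert np.allclose(ref, (0.0, 0.0, 1.5 * 1.5))
        assert flagged

    def test_empty_active_set_raises(self):
        e = _electrode(_lead((0.0, 0.0, 0.0), (0, 0, 1)), (0,), "monopolar")
        e.active = ()
        with pytest.raises(ValueError, match="active"):
            contact_reference(e)

    def test_noncolinear_contacts_rejected(self):
        centers = np.array([[0, 0, 0], [0, 0, 1.5], [0, 1, 3.0], [0, 0, 4.5]], float)
        with pytest.raises(ValueError, match="colinear"):
            Electrode(axis=(0, 0, 1), contact_centers=centers, active=(0,),
                      mode="monopolar")


class TestPerpendicularDistance:
    def _cylinder_mask(self, radius=3.0, half=12, zlen=21):
        shape = (2 * half + 1, 2 * half + 1, zlen)
        aff = _grid_affine(shape, 1.0)
        idx = np.indices(shape).reshape(3, -1).T.astype(float)
        world = idx @ aff[:3, :3].T + aff[:3, 3]
        m = (world[:, 0] ** 2 + world[:, 1] ** 2) <= radius**2
        return TractMask(voxels=m.reshape(shape), threshold=1, affine=aff)

    def test_point_inside_tract_scores_zero(self):
        tract = self._cylinder_mask()
        d, flags = perpendicular_distance(np.zeros(3), (0, 0, 1.0), tract)
        assert d == 0.0 and flags["inside"]

    @pytest.mark.parametrize("offset", [4.0, 5.0, 6.0, 7.0, 8.0])
    def test_cylinder_oracle(self, offset):
        tract = self._cylinder_mask(radius=3.0)
        p = np.array([offset, 0.0, 0.0])
        d, flags = perpendicular_distance(p, (0, 0, 1.0), tract, 0.5)
        assert not flags["missing"]
        assert abs(d - (offset - 3.0)) <= np.sqrt(3) / 2

    def test_three_four_five_single_boundary_voxel(self):
        shape = (11, 11, 11)
        aff = _grid_affine(shape, 1.0)
        m = np.zeros(shape, bool)
        m[8, 9, 5] = True  # world (3, 4, 0)
        tract = TractMask(voxels=m, threshold=1, affine=aff)
        d, _ = perpendicular_distance(np.zeros(3), (0, 0, 1.0), tract, 0.5)
        assert d == pytest.approx(5.0)

    def test_rigid_transform_invariance(self):
        from scipy.spatial.transform import Rotation

        tract = self._cylinder_mask()
        p = np.array([5.0, 1.0, 2.0])
        axis = np.array([0.2, -0.1, 1.0])
        axis /= np.linalg.norm(axis)
        d0, _ = perpendicular_distance(p, axis, tract, 1.0)
        rng = np.random.default_rng(42)
        for _ in range(20):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(-5, 5, 3)
            aff = tract.affine.copy()
            aff[:3, :3] = R @ aff[:3, :3]
            aff[:3, 3] = R @ aff[:3, 3] + t
            rotated = TractMask(voxels=tract.voxels, threshold=1, affine=aff)
            d, _ = perpendicular_distance(R @ p + t, R @ axis, rotated, 1.0)
            assert d == pytest.approx(d0, abs=1e-9)

    def test_slab_widening_flagged(self):
        shape = (11, 11, 11)
        aff = _grid_affine(shape, 1.0)
        m = np.zeros(shape, bool)
        m[5, 5, 9] = True  # 4 mm above the reference plane
        tract = TractMask(voxels=m, threshold=1, affine=aff)
        d, flags = perpendicular_distance(np.zeros(3), (0, 0, 1.0), tract,
                                          0.5, max_slab_half_mm=6.0)
        assert flags["widened"] and not flags["missing"]
        d2, flags2 = perpendicular_distance(np.zeros(3), (0, 0, 1.0), tract,
                                            0.5, max_slab_half_mm=2.0)
        assert flags2["missing"] and np.isnan(d2)

    def test_distance_nonincreasing_with_growing_mask(self):
        # lower threshold -> larger mask -> shorter or equal distance
        shape = (21, 21, 21)
        aff = _grid_affine(shape, 1.0)
        rng = np.random.default_rng(1)
        counts = np.zeros(shape, int)
        core = _ellipsoid_mask(shape, aff, (0, 0, 0), (4, 4, 6))
        counts[core] = rng.integers(1, 6, core.sum())
        p = np.array([8.0, 0.0, 0.0])
        prev = 0.0
        for tau in range(1, 6):
            mask = counts >= tau
            if not mask.any():
                break
            d, flags = perpendicular_distance(
                p, (0, 0, 1.0), TractMask(voxels=mask, threshold=tau, affine=aff),
                0.5, max_slab_half_mm=20.0)
            if np.isnan(d):
                break
            assert d >= prev - 1e-9
            prev = d

    def test_empty_tract_raises(self):
        tract = TractMask(voxels=np.zeros((3, 3, 3), bool), threshold=1,
                          affine=np.eye(4))
        with pytest.raises(ValueError, match="empty"):
            perpendicular_distance(np.zeros(3), (0, 0, 1.0), tract)
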