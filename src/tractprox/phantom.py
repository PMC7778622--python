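"""Synthetic diffusion phantom for the DRT proximity analysis.

The phantom emulates the study conditions the pipeline is designed for: a
single-shell acquisition (30 directions, b = 1000 s/mm^2, one b0 volume,
2 mm isotropic voxels) containing one curved anisotropic bundle per
hemisphere that mimics the dentato-rubro-thalamic tract: it rises from the
contralateral dentate region, decussates at the midline, passes the
ipsilateral red nucleus and ends under the precentral (primary motor)
region.  Around it sit the regions the real analysis needs as inputs: a
precentral seed box, red-nucleus and dentate filter boxes, and an STN
ellipsoid anterolateral to the bundle on the z = -4 mm plane.

World frame: RAS millimetres, AC-PC aligned, intercommissural plane at
z = 0, so "4 mm ventral to the intercommissural line" is z = -4.  The grid
is mirror-symmetric in x; the left-hemisphere bundle is the x-mirror of
the right one except for a localized anterior shift at the decussation
(see :func:`_left_centerline`), which lets the two tubes cross the
midline without occupying the same voxels — a single-tensor voxel cannot
represent a true fiber crossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .gradients import direction_table
from .tensor import DWIDataset, forward_signal

# Default centerline of the right-hemisphere DRT-like bundle (world mm):
# contralateral (left) dentate -> decussation -> red-nucleus level ->
# STN plane (z = -4) -> thalamus -> precentral end.
DEFAULT_CONTROL_POINTS: tuple = (
    (-11.0, -15.0, -30.0),
    (0.0, -13.0, -20.0),
    (3.0, -12.0, -10.0),
    (4.5, -11.5, -4.0),
    (7.0, -8.0, 6.0),
    (12.0, -2.0, 14.0),
)


@dataclass
class PhantomConfig:
    """Geometry, diffusivities, and acquisition of the synthetic phantom.

    ``lambda_bundle`` must be prolate with equal second and third
    diffusivities; voxels whose centers fall inside the tube get the
    tangent-aligned bundle tensor, everything else is isotropic at
    ``lambda_background`` (no partial-volume blending, which keeps the
    tensor-fit oracle exact).  ``snr`` is S0 over the Gaussian channel
    noise sigma; ``None`` or ``inf`` means noiseless.
    """

    grid_shape: tuple = (24, 18, 30)
    voxel_size: float = 2.0
    bundle_control_points: tuple = DEFAULT_CONTROL_POINTS
    bundle_radius: float = 3.5
    lambda_bundle: tuple = (1.7e-3, 0.3e-3, 0.3e-3)
    lambda_background: float = 0.8e-3
    n_directions: int = 30
    b_value: float = 1000.0
    s0: float = 100.0
    snr: float | None = 20.0
    decussation_y_offset: float = 9.5  # mm; AP offset of the left bundle
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be three positive counts")
        if self.bundle_radius <= self.voxel_size / 2:
            raise ValueError("bundle_radius must exceed half a voxel")
        l1, l2, l3 = self.lambda_bundle
        if not (l1 > l2 == l3 > 0):
            raise ValueError("lambda_bundle must satisfy l1 > l2 == l3 > 0")
        if self.lambda_background <= 0:
            raise ValueError("lambda_background must be positive")
        if self.n_directions < 6:
            raise ValueError("need at least 6 diffusion directions")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or None for noiseless)")

    @property
    def affine(self) -> np.ndarray:
        """Voxel->world map placing the grid symmetric in x with the
        intercommissural plane (z = 0) on a voxel-center plane."""
        nx, ny, nz = self.grid_shape
        vs = self.voxel_size
        aff = np.diag([vs, vs, vs, 1.0])
        # x symmetric about 0; y mostly posterior; z spans cerebellum..vertex
        aff[0, 3] = -vs * (nx - 1) / 2.0
        aff[1, 3] = -vs * (ny - 6)
        aff[2, 3] = -vs * (nz - 11)
        return aff


@dataclass
class ROISet:
    """Per-hemisphere masks on the phantom grid (boolean arrays).

    ``seed`` is the precentral box at the superior bundle end, ``red_nucleus``
    sits on the centerline, ``dentate`` at the inferior (contralateral) end,
    ``stn`` is an ellipsoid anterolateral to the bundle at z = -4.  Keys are
    "left"/"right" hemisphere labels; for tracking hemisphere h the filters
    are red_nucleus[h] (ipsilateral) and dentate of the opposite side's
    naming convention — see :func:`filter_masks_for`.
    """

    seed: dict
    red_nucleus: dict
    dentate: dict
    stn: dict
    affine: np.ndarray

    def filter_masks_for(self, side: str) -> list:
        """Waypoint filters for tracking the DRT of hemisphere ``side``:
        ipsilateral red nucleus and contralateral dentate."""
        other = "left" if side == "right" else "right"
        return [self.red_nucleus[side], self.dentate[other]]


@dataclass
class GroundTruth:
    """Phantom ground truth retained for testing.

    ``centerline``/``tube_mask`` describe the right bundle,
    ``centerline_left``/``tube_mask_left`` the left one (its x-mirror with
    the anterior decussation offset).  ``true_distances`` (hemisphere id
    -> mm to the tube surface) and ``effect_params`` are filled by the
    cohort generator.
    """

    centerline: np.ndarray
    tube_mask: np.ndarray
    affine: np.ndarray
    bundle_radius: float
    centerline_left: np.ndarray = None
    tube_mask_left: np.ndarray = None
    decussation_mask: np.ndarray = None  # voxels shared by both bundles
    true_distances: dict = field(default_factory=dict)
    effect_params: dict = field(default_factory=dict)

    def tube_mask_for(self, side: str) -> np.ndarray:
        return self.tube_mask if side == "right" else self.tube_mask_left

    def centerline_for(self, side: str) -> np.ndarray:
        return self.centerline if side == "right" else self.centerline_left

    def distance_to_tube(self, points: np.ndarray, side: str = "right") -> np.ndarray:
        """Analytic distance from world points to the bundle surface
        (distance to centerline minus radius, floored at zero)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = cKDTree(self.centerline_for(side)).query(pts)[0]
        return np.maximum(d - self.bundle_radius, 0.0)


def _dense_centerline(control_points: np.ndarray, spacing: float = 0.25) -> np.ndarray:
    cp = np.asarray(control_points, dtype=float)
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))])
    spline = CubicSpline(chord, cp, axis=0)
    n = max(int(np.ceil(chord[-1] / spacing)), 2)
    t = np.linspace(0.0, chord[-1], n + 1)
    return spline(t)


def _left_centerline(centerline: np.ndarray, y_offset: float,
                     support_mm: float = 4.5) -> np.ndarray:
    """Left-bundle centerline: x-mirror of the right one with a smooth
    anterior shift near the midline so the two tubes pass adjacent to
    each other instead of through each other (a single-tensor voxel
    cannot represent a true crossing).

    The shift follows a parabolic profile of the mirrored |x|,
    ``y_offset * (1 - (|x|/support)^2)`` for |x| < support, so it peaks at
    the decussation and vanishes where the bundle is lateral (STN plane,
    bundle ends), leaving those mirror-symmetric; the red-nucleus level
    keeps a partial shift, so the left red-nucleus ROI is placed on the
    left bundle's own course.
    """
    left = centerline.copy()
    left[:, 0] *= -1
    if y_offset != 0.0:
        x = np.abs(left[:, 0])
        bump = np.clip(1.0 - (x / support_mm) ** 2, 0.0, None)
        left[:, 1] += y_offset * bump
    return left


def voxel_centers(grid_shape, affine) -> np.ndarray:
    """World coordinates of all voxel centers, shape grid_shape + (3,)."""
    nx, ny, nz = grid_shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def _box_mask(centers: np.ndarray, center, half_extents) -> np.ndarray:
    c = np.asarray(center, dtype=float)
    h = np.asarray(half_extents, dtype=float)
    return np.all(np.abs(centers - c) <= h, axis=-1)


def _ellipsoid_mask(centers: np.ndarray, center, semi_axes) -> np.ndarray:
    c = np.asarray(center, dtype=float)
    a = np.asarray(semi_axes, dtype=float)
    return np.sum(((centers - c) / a) ** 2, axis=-1) <= 1.0


def add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude-MRI noise: sqrt((S + e1)^2 + e2^2), e ~ N(0, sigma^2)."""
    e1 = rng.normal(0.0, sigma, size=signal.shape)
    e2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + e1) ** 2 + e2 ** 2)


def generate_phantom(config: PhantomConfig | None = None):
    """Build the synthetic DWI dataset, ROI set, and ground truth.

    Returns ``(DWIDataset, ROISet, GroundTruth)``.  Raises ``ValueError``
    naming the offending control point if the bundle (tube) leaves the
    grid.
    """
    cfg = config or PhantomConfig()
    affine = cfg.affine
    nx, ny, nz = cfg.grid_shape
    centers = voxel_centers(cfg.grid_shape, affine)

    centerline = _dense_centerline(cfg.bundle_control_points)
    centerline_left = _left_centerline(
        centerline, cfg.decussation_y_offset, support_mm=cfg.bundle_radius + 1.0
    )
    lo = centers.reshape(-1, 3).min(axis=0) - cfg.voxel_size / 2
    hi = centers.reshape(-1, 3).max(axis=0) + cfg.voxel_size / 2
    margin = cfg.bundle_radius
    for cl in (centerline, centerline_left):
        for axis in range(3):
            bad = (cl[:, axis] - margin < lo[axis]) | (cl[:, axis] + margin > hi[axis])
            if bad.any():
                cp = np.asarray(cfg.bundle_control_points)
                # both centerlines share the arc-length parametrization, so
                # the offending sample maps to a right-bundle control point
                worst = centerline[np.argmax(bad)]
                offender = int(np.argmin(np.linalg.norm(cp - worst, axis=1)))
                raise ValueError(
                    f"bundle leaves the grid near control point {offender} "
                    f"{tuple(cp[offender])}"
                )

    flat = centers.reshape(-1, 3)
    dist_r, idx_r = cKDTree(centerline).query(flat)
    dist_l, idx_l = cKDTree(centerline_left).query(flat)
    tube_r = (dist_r <= cfg.bundle_radius).reshape(cfg.grid_shape)
    tube_l = (dist_l <= cfg.bundle_radius).reshape(cfg.grid_shape)

    def tangents(cl):
        t = np.gradient(cl, axis=0)
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    l1, l2, _ = cfg.lambda_bundle
    iso = cfg.lambda_background * np.eye(3)
    tensors = np.broadcast_to(iso, cfg.grid_shape + (3, 3)).copy()

    def bundle_tensors(t_vec):
        # axisymmetric prolate tensor: l2*I + (l1-l2) * t t^T
        tt = t_vec[:, :, None] * t_vec[:, None, :]
        return l2 * np.eye(3) + (l1 - l2) * tt

    in_r = tube_r.ravel()
    in_l = tube_l.ravel()
    # the AP offset of the left bundle's decussation keeps the tubes
    # disjoint, so each voxel belongs to at most one bundle; any residual
    # overlap (possible only for non-default geometry) goes to the nearer
    # centerline
    overlap = in_r & in_l
    t_r = tangents(centerline)[idx_r]
    t_l = tangents(centerline_left)[idx_l]
    use_r = in_r & (~in_l | (dist_r <= dist_l))
    use_l = in_l & ~use_r
    flat_tensors = tensors.reshape(-1, 3, 3)
    flat_tensors[use_r] = bundle_tensors(t_r[use_r])
    flat_tensors[use_l] = bundle_tensors(t_l[use_l])
    tensors = flat_tensors.reshape(cfg.grid_shape + (3, 3))

    bvecs_dw = direction_table(cfg.n_directions)
    bvals = np.concatenate([[0.0], np.full(cfg.n_directions, cfg.b_value)])
    bvecs = np.vstack([np.zeros(3), bvecs_dw])

    signal = forward_signal(tensors, bvals, bvecs, np.full(cfg.grid_shape, cfg.s0))
    if cfg.snr is not None and np.isfinite(cfg.snr):
        rng = np.random.default_rng(cfg.rng_seed)
        signal = add_rician_noise(signal, cfg.s0 / cfg.snr, rng)

    dwi = DWIDataset(
        signal=signal,
        bvals=bvals,
        bvecs=bvecs,
        brain_mask=np.ones(cfg.grid_shape, dtype=bool),
        affine=affine,
    )

    cp = np.asarray(cfg.bundle_control_points, dtype=float)
    top, dn_c = cp[-1], cp[0]
    # red-nucleus boxes sit on each bundle's own course at the midbrain
    # level (the left course carries part of the decussation offset)
    rn_r = centerline[np.argmin(np.abs(centerline[:, 2] + 10.0))]
    rn_l = centerline_left[np.argmin(np.abs(centerline_left[:, 2] + 10.0))]

    def both_sides(maker):
        right = maker(centers)
        return {"right": right, "left": np.flip(right, axis=0)}

    # masks are keyed by the physical brain side they occupy; the dentate
    # box built from the right-bundle control points sits in the LEFT half
    # of the brain (the bundle decussates), hence the swapped keys below
    dentate_left = _box_mask(centers, dn_c, (4.0, 4.0, 4.0))
    rois = ROISet(
        seed=both_sides(lambda c: _box_mask(c, top, (2.5, 2.5, 2.5))),
        red_nucleus={
            "right": _box_mask(centers, rn_r, (3.0, 3.0, 3.0)),
            "left": _box_mask(centers, rn_l, (3.0, 3.0, 3.0)),
        },
        dentate={"left": dentate_left, "right": np.flip(dentate_left, axis=0)},
        stn=both_sides(lambda c: _ellipsoid_mask(c, (12.0, -4.0, -4.0), (3.0, 4.0, 3.0))),
        affine=affine,
    )

    truth = GroundTruth(
        centerline=centerline,
        tube_mask=tube_r,
        affine=affine,
        bundle_radius=cfg.bundle_radius,
        centerline_left=centerline_left,
        tube_mask_left=tube_l,
        decussation_mask=overlap.reshape(cfg.grid_shape),
    )
    return dwi, rois, truth
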