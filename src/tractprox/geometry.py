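"""Tract-boundary standardization and contact-to-tract distance.

The study procedure this reproduces is manual: straight lines are drawn
along the medial and posterior borders of the STN on the axial plane 4 mm
below the intercommissural line, the display contrast of the tract-density
image is raised until the tract signal no longer crosses those lines, and
the shortest distance from the active electrode contact to the tract
border is then measured on image planes perpendicular to the electrode
axis.  Here "contrast adjustment" is formalized as integer thresholding of
the hit map — the only monotone, automatable reading of the display
procedure — and the distance is taken to face-connectivity boundary voxel
centers inside a thin slab around the perpendicular plane, which bounds
the discretization error by half a voxel diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tracking import HitMap

STN_PLANE_Z = -4.0  # mm, 4 mm ventral to the intercommissural plane


@dataclass
class BorderLines:
    """STN border lines on the axial z = plane_z plane.

    ``medial_x`` is the x of the anterior-posterior line along the medial
    STN border; ``posterior_y`` the y of the medial-lateral line along the
    posterior border; ``side`` ("left"/"right") fixes which half-plane of
    the medial line contains the STN (x > medial_x on the right,
    x < medial_x on the left; y > posterior_y on both sides).
    """

    plane_z: float
    medial_x: float
    posterior_y: float
    side: str

    def stn_side(self, xy: np.ndarray) -> np.ndarray:
        """True for points strictly inside the STN-side half-plane of
        either border line."""
        xy = np.atleast_2d(xy)
        if self.side == "right":
            beyond_medial = xy[:, 0] > self.medial_x
        else:
            beyond_medial = xy[:, 0] < self.medial_x
        return beyond_medial | (xy[:, 1] > self.posterior_y)


@dataclass
class TractMask:
    """Binarized hit map at an integer threshold."""

    voxels: np.ndarray
    threshold: int
    affine: np.ndarray
    boundary: np.ndarray = field(default=None, repr=False)  # (m, 3) voxel indices

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.boundary is None:
            self.boundary = _boundary_voxels(self.voxels)

    def boundary_centers(self) -> np.ndarray:
        """World coordinates of boundary voxel centers."""
        return self.boundary @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class Electrode:
    """DBS lead: straight axis, four point contacts, active set."""

    axis: np.ndarray
    contact_centers: np.ndarray  # (4, 3) ordered, tip-ward first
    active: tuple
    mode: str  # monopolar | bipolar | double_monopolar

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis /= np.linalg.norm(self.axis)
        self.contact_centers = np.asarray(self.contact_centers, dtype=float)
        self.active = tuple(int(a) for a in self.active)
        offs = self.contact_centers - self.contact_centers[0]
        resid = offs - np.outer(offs @ self.axis, self.axis)
        if np.abs(resid).max() > 1e-6:
            raise ValueError("contact centers must be colinear with the axis")
        spacings = np.diff(offs @ self.axis)
        if len(spacings) and not np.allclose(spacings, spacings[0], atol=1e-6):
            raise ValueError("contact spacing must be uniform along the axis")


def stn_border_lines(stn_mask: np.ndarray, affine: np.ndarray,
                     plane_z: float = STN_PLANE_Z) -> BorderLines:
    """Medial and posterior STN border lines on the z = plane_z plane.

    The medial line passes through the most medial STN voxel center on
    that plane (smallest |x|, i.e. min x on the right / max x on the
    left, laterality from the STN centroid); the posterior line through
    the most posterior (min y) voxel center.
    """
    stn_mask = np.asarray(stn_mask, dtype=bool)
    if not stn_mask.any():
        raise ValueError("STN mask is empty")
    idx = np.argwhere(stn_mask)
    world = idx @ affine[:3, :3].T + affine[:3, 3]
    half_vox = np.abs(affine[2, 2]) / 2.0
    on_plane = np.abs(world[:, 2] - plane_z) <= half_vox + 1e-9
    if not on_plane.any():
        raise ValueError(f"STN mask does not intersect the z = {plane_z} mm plane")
    w = world[on_plane]
    side = "right" if world[:, 0].mean() >= 0 else "left"
    medial_x = w[:, 0].min() if side == "right" else w[:, 0].max()
    posterior_y = w[:, 1].min()
    return BorderLines(plane_z=plane_z, medial_x=float(medial_x),
                       posterior_y=float(posterior_y), side=side)


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with at least one face-neighbor outside the mask
    (grid borders count as outside-neighbors)."""
    if not mask.any():
        return np.empty((0, 3), dtype=int)
    interior = np.ones_like(mask)
    for ax in range(3):
        lo = np.roll(mask, 1, axis=ax)
        hi = np.roll(mask, -1, axis=ax)
        # rolled-in faces are outside the grid
        sl_lo = [slice(None)] * 3
        sl_lo[ax] = 0
        lo[tuple(sl_lo)] = False
        sl_hi = [slice(None)] * 3
        sl_hi[ax] = -1
        hi[tuple(sl_hi)] = False
        interior &= lo & hi
    return np.argwhere(mask & ~interior)


def standardize_threshold(hit_map: HitMap, lines: BorderLines):
    """Smallest integer threshold at which no supra-threshold voxel
    center on the border plane lies strictly on the STN side of either
    line.  Returns ``(tau, TractMask)``.
    """
    counts = np.asarray(hit_map.counts)
    if counts.max(initial=0) < 1:
        raise ValueError("hit map is empty")
    idx = np.argwhere(counts >= 1)
    world = idx @ hit_map.affine[:3, :3].T + hit_map.affine[:3, 3]
    half_vox = np.abs(hit_map.affine[2, 2]) / 2.0
    on_plane = np.abs(world[:, 2] - lines.plane_z) <= half_vox + 1e-9
    violating = np.zeros(len(idx), dtype=bool)
    violating[on_plane] = lines.stn_side(world[on_plane, :2])
    if violating.any():
        # threshold must exceed the largest count among violating voxels
        tau = int(counts[tuple(idx[violating].T)].max()) + 1
        if tau > counts.max():
            raise ValueError("tract inseparable from STN at this resolution")
    else:
        tau = 1
    mask = counts >= tau
    return tau, TractMask(voxels=mask, threshold=tau, affine=hit_map.affine.copy())


def contact_reference(e: Electrode) -> tuple[np.ndarray, bool]:
    """Reference point of the active contact set.

    Monopolar: the active contact center.  Bipolar: the midpoint of the
    two active centers.  Double-monopolar: midpoint of the active centers
    as well — an extension of the bipolar midpoint rule; the returned
    flag is True whenever the midpoint extension (rather than a single
    contact center) was used for a non-bipolar mode.
    """
    if not e.active:
        raise ValueError("active contact set is empty")
    pts = e.contact_centers[list(e.active)]
    if e.mode == "monopolar":
        if len(pts) != 1:
            raise ValueError("monopolar mode requires exactly one active contact")
        return pts[0].copy(), False
    ref = pts.mean(axis=0)
    flagged = e.mode != "bipolar"
    return ref, flagged


def perpendicular_distance(
    p: np.ndarray,
    axis: np.ndarray,
    tract: TractMask,
    slab_half_mm: float = 0.5,
    max_slab_half_mm: float = 3.0,
):
    """Shortest in-plane distance from ``p`` to the tract border on the
    plane through ``p`` perpendicular to the electrode axis.

    Only boundary voxel centers within ``|(x - p) . axis| <= slab`` are
    considered; an empty slab is widened in steps of ``slab_half_mm`` up
    to ``max_slab_half_mm`` (the result is then flagged ``widened``).  A
    reference point inside the tract mask scores 0.  Returns
    ``(distance_mm or nan, flags dict)``.
    """
    if not tract.voxels.any():
        raise ValueError("tract mask is empty")
    p = np.asarray(p, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    inv = np.linalg.inv(tract.affine)
    ijk = np.rint(p @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    if np.all((ijk >= 0) & (ijk < np.array(tract.voxels.shape))) and tract.voxels[tuple(ijk)]:
        return 0.0, {"inside": True, "widened": False, "missing": False}

    centers = tract.boundary_centers()
    rel = centers - p
    along = rel @ axis
    slab = slab_half_mm
    while slab <= max_slab_half_mm + 1e-9:
        sel = np.abs(along) <= slab
        if sel.any():
            inplane = rel[sel] - np.outer(along[sel], axis)
            d = float(np.linalg.norm(inplane, axis=1).min())
            return d, {"inside": False, "widened": slab > slab_half_mm, "missing": False}
        slab += slab_half_mm
    return float("nan"), {"inside": False, "widened": True, "missing": True}
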