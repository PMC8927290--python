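"""Geometry-based beam masks.

Each treatment beam is modeled as a point source at source-axis distance
from the isocenter whose aperture is tangent to the PTV: the aperture is
the convex hull of the perspective projection of all PTV voxel centers
from the source onto the plane through the isocenter perpendicular to the
beam axis.  Every voxel whose source ray crosses that plane inside the
aperture polygon is assigned 1, all others 0 — a divergent 3D cone, not a
per-slice fan.  The per-beam binary masks are summed over the plan's beams
and linearly rescaled so the maximum voxel equals the prescription dose
(50.4 Gy by default), which makes the mask's value range match the dose
distributions a prediction model is trained on.

This is a purely geometric encoding of the beam settings; it involves no
fluence or dose calculation.

Gantry angles follow IEC 61217: 0 deg = source anterior to a supine
patient (the -y direction in LPS), increasing clockwise viewed from the
foot of the couch, so 90 deg places the source at the patient's left (+x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Polygon

from .grid import VoxelGrid
from .plans import PlanSpec

__all__ = [
    "Aperture",
    "BeamMaskVolume",
    "source_position",
    "bev_aperture",
    "rasterize_beam",
    "combined_beam_mask",
]

# slack (mm, in the isocenter plane) for boundary point-in-polygon tests:
# voxels whose ray lands exactly on the aperture edge count as inside
_EDGE_EPS_MM = 1e-9


def source_position(
    angle_deg: float,
    isocenter=(0.0, 0.0, 0.0),
    sad_mm: float = 1000.0,
) -> np.ndarray:
    """Point-source position for a coplanar beam, mm in LPS.

    The source lies in the axial plane through the isocenter at distance
    ``sad_mm``; at 0 deg it sits anterior (-y), at 90 deg at the patient's
    left (+x).
    """
    g = np.deg2rad(angle_deg)
    direction = np.array([np.sin(g), -np.cos(g), 0.0])
    return np.asarray(isocenter, dtype=float) + sad_mm * direction


@dataclass(frozen=True)
class Aperture:
    """BEV aperture polygon in the isocenter plane of one beam.

    ``u``/``v`` are unit vectors spanning the plane (v is the patient
    cranio-caudal axis for coplanar beams), ``axis`` the unit beam
    direction from source to isocenter; ``polygon`` lives in (u, v)
    coordinates centered on the isocenter.
    """

    source: tuple[float, float, float]
    isocenter: tuple[float, float, float]
    u: tuple[float, float, float]
    v: tuple[float, float, float]
    axis: tuple[float, float, float]
    polygon: Polygon

    @property
    def sad_mm(self) -> float:
        return float(
            np.linalg.norm(np.asarray(self.isocenter) - np.asarray(self.source))
        )


def _beam_frame(source: np.ndarray, isocenter: np.ndarray):
    axis = isocenter - source
    sad = np.linalg.norm(axis)
    if sad == 0:
        raise ValueError("source coincides with isocenter")
    axis = axis / sad
    zhat = np.array([0.0, 0.0, 1.0])
    u = np.cross(axis, zhat)
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise ValueError("beam axis parallel to the cranio-caudal axis; only coplanar beams are supported")
    u = u / nu
    v = np.cross(axis, u)  # right-handed (axis, u, v); v = +z for coplanar beams
    return axis, u, v, float(sad)


def _project_points(points: np.ndarray, source: np.ndarray, axis, u, v, sad: float):
    """Perspective-project points onto the isocenter plane; returns (pu, pv, forward)."""
    rel = points - source
    pn = rel @ axis
    forward = pn > 1e-9
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(forward, sad / pn, np.nan)
    return t * (rel @ u), t * (rel @ v), forward


def bev_aperture(
    source,
    isocenter,
    ptv_mask: np.ndarray,
    grid: VoxelGrid,
) -> Aperture:
    """Beam's-eye-view aperture tangent to the PTV.

    The aperture is the convex hull, in the isocenter plane, of the
    perspective projection of every PTV voxel center from the source.  Its
    boundary rays graze the PTV point cloud, which realizes the
    tangent-to-PTV construction.  A degenerate hull (single-voxel or
    collinear PTV) falls back to projecting the voxel corners so the
    aperture is the voxel footprint rather than a zero-area polygon.
    """
    source = np.asarray(source, dtype=float)
    isocenter = np.asarray(isocenter, dtype=float)
    ptv_mask = np.asarray(ptv_mask, dtype=bool)
    if not ptv_mask.any():
        raise ValueError("PTV mask is empty; cannot build a BEV aperture")
    axis, u, v, sad = _beam_frame(source, isocenter)

    idx = np.argwhere(ptv_mask).astype(float)
    centers = grid.index_to_world(idx)
    pu, pv, forward = _project_points(centers, source, axis, u, v, sad)
    if not forward.all():
        raise ValueError("PTV voxels behind the beam source; geometry invalid")
    hull = MultiPoint(np.column_stack([pu, pv])).convex_hull
    if hull.area == 0.0:
        # degenerate PTV: use the projected voxel corner footprint
        offs = np.array(
            [[sx, sy, sz] for sx in (-0.5, 0.5) for sy in (-0.5, 0.5) for sz in (-0.5, 0.5)]
        )
        corners = grid.index_to_world(idx[:, None, :] + offs[None, :, :]).reshape(-1, 3)
        pu, pv, _ = _project_points(corners, source, axis, u, v, sad)
        hull = MultiPoint(np.column_stack([pu, pv])).convex_hull
    if not isinstance(hull, Polygon):
        raise ValueError("aperture construction produced a degenerate polygon")
    return Aperture(
        source=tuple(source),
        isocenter=tuple(isocenter),
        u=tuple(u),
        v=tuple(v),
        axis=tuple(axis),
        polygon=hull,
    )


def project_to_aperture_plane(aperture: Aperture, points: np.ndarray):
    """Project arbitrary mm points through the aperture's source onto its plane.

    Returns ``(pu, pv, forward)``: in-plane coordinates (mm, isocenter
    origin) and a mask of points on the forward side of the source.
    """
    return _project_points(
        np.asarray(points, dtype=float),
        np.asarray(aperture.source),
        np.asarray(aperture.axis),
        np.asarray(aperture.u),
        np.asarray(aperture.v),
        aperture.sad_mm,
    )


def rasterize_beam(aperture: Aperture, grid: VoxelGrid) -> np.ndarray:
    """Binary beam-path volume: 1 where the voxel-center ray crosses the
    isocenter plane inside the aperture polygon (boundary inclusive)."""
    centers = grid.voxel_centers().reshape(-1, 3)
    pu, pv, forward = project_to_aperture_plane(aperture, centers)
    inside = np.zeros(len(centers), dtype=bool)
    fwd = np.flatnonzero(forward)
    poly = aperture.polygon.buffer(_EDGE_EPS_MM) if _EDGE_EPS_MM else aperture.polygon
    inside[fwd] = shapely.intersects_xy(poly, pu[fwd], pv[fwd])
    return inside.reshape(grid.shape).astype(np.uint8)


@dataclass
class BeamMaskVolume:
    """Summed-and-rescaled beam mask on the dose grid.

    ``values`` is the scalar field in Gy after rescaling the per-voxel
    beam-overlap counts so that the maximum equals the prescription;
    ``counts`` retains the pre-rescale integer overlap counts.
    """

    values: np.ndarray
    counts: np.ndarray
    grid: VoxelGrid
    prescription_gy: float

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise ValueError("beam-mask shape does not match its grid")
        if (self.values < 0).any():
            raise ValueError("beam-mask values must be nonnegative")


def combined_beam_mask(
    plan: PlanSpec,
    ptv_mask: np.ndarray,
    grid: VoxelGrid,
    body_mask: np.ndarray | None = None,
) -> BeamMaskVolume:
    """Sum the plan's per-beam binary masks and rescale to the prescription.

    Every PTV voxel lies inside every beam's aperture by construction, so
    the pre-rescale maximum equals the beam count and rescaled PTV voxels
    carry exactly the prescription dose.  ``body_mask`` optionally clips
    the mask to the patient's external contour (off by default; the beam
    path itself is not body-limited).
    """
    if plan.beam_count < 1:
        raise ValueError("plan has no beams")
    counts = np.zeros(grid.shape, dtype=np.int32)
    iso = np.asarray(plan.isocenter, dtype=float)
    for angle in plan.angles:
        src = source_position(angle, iso, plan.sad_mm)
        aperture = bev_aperture(src, iso, ptv_mask, grid)
        counts += rasterize_beam(aperture, grid)
    if body_mask is not None:
        counts = counts * np.asarray(body_mask, dtype=bool)
    peak = int(counts.max())
    if peak == 0:
        values = np.zeros(grid.shape, dtype=float)
    else:
        values = counts * (plan.prescription_gy / peak)
    return BeamMaskVolume(
        values=values, counts=counts, grid=grid, prescription_gy=plan.prescription_gy
    )
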