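"""Preparation of aligned multi-channel training samples.

Raw volumes become model-ready samples in four steps: standardize the CT
to zero mean / unit variance, rasterize contours to binary ROI masks,
resample everything onto the dose grid (trilinear for intensities,
nearest-neighbor for labels), and stack the channels in a fixed order:

    [CT, bladder, body, femoral_head_l, femoral_head_r, ptv, rectum,
     spinal_cord]  (+ beam mask last, when included)

The beam-mask channel is fed in Gy as rescaled, not re-standardized: the
rescale to the prescription already places its values on the scale of the
training dose distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.draw import polygon2mask

from .beam_mask import BeamMaskVolume
from .grid import VoxelGrid
from .plans import PlanSpec
from .structures import REQUIRED_ROIS, ContourSet, StructureSet

#: fixed channel order of assembled samples (beam mask appended last if used)
CHANNEL_ORDER = ("ct",) + REQUIRED_ROIS


def normalize_ct(volume: np.ndarray) -> np.ndarray:
    """Standardize a CT volume to mean 0 and (population) variance 1.

    A zero-variance volume cannot be standardized; it is returned as all
    zeros with a warning.
    """
    volume = np.asarray(volume, dtype=float)
    mean = volume.mean()
    std = volume.std()  # population std, ddof=0
    if std == 0.0:
        warnings.warn("CT volume has zero variance; returning all zeros", stacklevel=2)
        return np.zeros_like(volume)
    return (volume - mean) / std


def rasterize_roi(polygons, grid: VoxelGrid) -> np.ndarray:
    """Rasterize one ROI's planar polygons to a binary mask on ``grid``.

    Each polygon is an ``(n, 3)`` vertex array (mm, constant z) assigned to
    the nearest slice; the fill is a voxel-center-inside scanline with the
    even-odd rule, so nested contours (donuts) punch holes and overlapping
    self-intersections resolve deterministically.  Polygons with fewer than
    three distinct vertices contribute nothing (with a warning), as do
    polygons whose slice lies outside the grid.
    """
    mask = np.zeros(grid.shape, dtype=bool)
    for poly in polygons:
        poly = np.asarray(poly, dtype=float)
        if len(poly) > 1 and np.allclose(poly[0], poly[-1]):
            poly = poly[:-1]
        if len(poly) < 3:
            warnings.warn(
                f"degenerate contour with {len(poly)} vertices ignored", stacklevel=2
            )
            continue
        if not np.allclose(poly[:, 2], poly[0, 2], atol=1e-6):
            raise ValueError("contour is not planar (z varies within polygon)")
        shp = _ShapelyPolygon(poly[:, :2])
        if not shp.is_valid:
            warnings.warn(
                "self-intersecting contour rasterized with the even-odd rule",
                stacklevel=2,
            )
        idx = grid.world_to_index(poly)
        k = int(np.round(idx[0, 2]))
        if k < 0 or k >= grid.shape[2]:
            continue
        # polygon2mask treats dim0 as rows: our slice arrays are (nx, ny)
        slice_mask = polygon2mask(grid.shape[:2], idx[:, :2])
        mask[:, :, k] ^= slice_mask  # even-odd across polygons of one ROI
    return mask


def rasterize_structures(contours: ContourSet, grid: VoxelGrid) -> StructureSet:
    """Rasterize every ROI of a contour set onto ``grid``."""
    masks = {name: rasterize_roi(polys, grid) for name, polys in contours.rois.items()}
    return StructureSet(masks=masks, grid=grid)


def resample_to_dose_grid(
    volume: np.ndarray,
    src: VoxelGrid,
    dst: VoxelGrid,
    kind: str = "intensity",
) -> np.ndarray:
    """Resample ``volume`` from grid ``src`` onto grid ``dst``.

    ``kind="intensity"`` uses trilinear interpolation, ``kind="label"``
    nearest neighbor (labels are never invented).  World coordinates of
    the content are preserved; samples beyond the source extent take the
    nearest edge value.  Grids whose physical bounding boxes do not
    overlap are a hard error.
    """
    if kind not in ("intensity", "label"):
        raise ValueError(f"kind must be intensity|label, got {kind!r}")
    volume = np.asarray(volume)
    if volume.shape != src.shape:
        raise ValueError(f"volume shape {volume.shape} != src grid {src.shape}")
    if src.same_geometry(dst):
        return volume.copy()
    for a in range(3):
        src_lo = src.origin[a] - src.spacing[a] / 2
        src_hi = src.origin[a] + src.spacing[a] * (src.shape[a] - 0.5)
        dst_lo = dst.origin[a] - dst.spacing[a] / 2
        dst_hi = dst.origin[a] + dst.spacing[a] * (dst.shape[a] - 0.5)
        if dst_hi < src_lo or dst_lo > src_hi:
            raise ValueError(f"grids do not overlap on axis {a}")
    coords = src.world_to_index(dst.voxel_centers())  # (nx,ny,nz,3) fractional
    coords = np.moveaxis(coords, -1, 0)
    order = 1 if kind == "intensity" else 0
    out = ndimage.map_coordinates(
        volume.astype(float), coords, order=order, mode="nearest"
    )
    if kind == "label":
        out = out.astype(volume.dtype)
    return out


@dataclass
class TrainingSample:
    """Aligned multi-channel input stack and target dose on one grid.

    ``channels`` has shape ``(C,) + grid.shape`` with ``channel_names``
    recording the fixed order; ``dose_gy`` is the target volume.
    """

    channels: np.ndarray
    channel_names: tuple[str, ...]
    dose_gy: np.ndarray
    grid: VoxelGrid
    plan: PlanSpec | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channels.shape != (len(self.channel_names),) + self.grid.shape:
            raise ValueError("channel stack shape inconsistent with names/grid")
        if self.dose_gy.shape != self.grid.shape:
            raise ValueError("dose shape does not match grid")

    def channel(self, name: str) -> np.ndarray:
        return self.channels[self.channel_names.index(name)]

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


def assemble_sample(
    ct: np.ndarray,
    structures: StructureSet,
    dose_gy: np.ndarray,
    grid: VoxelGrid,
    beam_mask: BeamMaskVolume | None = None,
    include_beam: bool = False,
    plan: PlanSpec | None = None,
    meta: dict | None = None,
) -> TrainingSample:
    """Stack CT, the seven ROI masks and (optionally) the beam mask.

    All inputs must already live on the same (dose) grid; a grid mismatch
    or a missing required ROI is a hard error naming the culprit.
    """
    ct = np.asarray(ct, dtype=float)
    if ct.shape != grid.shape:
        raise ValueError(f"CT shape {ct.shape} != grid shape {grid.shape}")
    if dose_gy.shape != grid.shape:
        raise ValueError(f"dose shape {dose_gy.shape} != grid shape {grid.shape}")
    if not structures.grid.same_geometry(grid):
        raise ValueError("structure-set grid does not match the dose grid")
    structures.require(REQUIRED_ROIS)
    names = list(CHANNEL_ORDER)
    stack = [ct] + [structures[r].astype(float) for r in REQUIRED_ROIS]
    if include_beam:
        if beam_mask is None:
            raise ValueError("include_beam=True but no beam mask supplied")
        if not beam_mask.grid.same_geometry(grid):
            raise ValueError("beam-mask grid does not match the dose grid")
        names.append("beam_mask")
        stack.append(beam_mask.values.astype(float))
    return TrainingSample(
        channels=np.stack(stack).astype(np.float32),
        channel_names=tuple(names),
        dose_gy=np.asarray(dose_gy, dtype=np.float32),
        grid=grid,
        plan=plan,
        meta=dict(meta or {}),
    )
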