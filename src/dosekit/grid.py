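"""Voxel-grid geometry shared by CT, masks, dose and beam masks.

Convention used throughout the package: DICOM patient coordinates (LPS,
millimetres), 0-based voxel indices, axis order ``(x, y, z)`` =
(column, row, slice).  Every volume that crosses a module boundary is a
numpy array of shape ``grid.shape`` accompanied by its :class:`VoxelGrid`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: orientation labels of the +x, +y, +z axes in the LPS patient frame
LPS_AXES = ("L", "P", "S")

# right-handed triples of DICOM orientation labels (axis -> anatomical direction)
_DIRS = {
    "L": np.array([1.0, 0.0, 0.0]),
    "R": np.array([-1.0, 0.0, 0.0]),
    "P": np.array([0.0, 1.0, 0.0]),
    "A": np.array([0.0, -1.0, 0.0]),
    "S": np.array([0.0, 0.0, 1.0]),
    "I": np.array([0.0, 0.0, -1.0]),
}


@dataclass(frozen=True)
class VoxelGrid:
    """Regular axis-aligned voxel lattice in patient coordinates.

    Parameters
    ----------
    origin
        Physical position (mm, LPS) of the *center* of voxel ``(0, 0, 0)``.
    spacing
        Per-axis voxel size in mm; strictly positive.
    shape
        Voxel counts per axis; at least 1 on every axis.
    axes
        Orientation label of each voxel axis (default LPS); must form a
        right-handed frame.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    shape: tuple[int, int, int]
    axes: tuple[str, str, str] = field(default=LPS_AXES)

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "shape", tuple(int(v) for v in self.shape))
        object.__setattr__(self, "axes", tuple(self.axes))
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be >= 1 per axis, got {self.shape}")
        try:
            basis = [_DIRS[a] for a in self.axes]
        except KeyError as exc:
            raise ValueError(f"unknown orientation label {exc}") from exc
        if float(np.linalg.det(np.stack(basis))) <= 0:
            raise ValueError(f"axes {self.axes} are not a right-handed frame")

    # -- coordinate transforms -------------------------------------------------

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices ``(..., 3)`` to mm positions."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map mm positions ``(..., 3)`` to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """All voxel-center positions as an array of shape ``shape + (3,)`` (mm)."""
        axes_mm = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        xx, yy, zz = np.meshgrid(*axes_mm, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size covered by voxel centers plus one spacing, per axis."""
        return tuple(self.spacing[a] * self.shape[a] for a in range(3))

    def center_mm(self) -> np.ndarray:
        """World position of the grid's geometric center."""
        return self.index_to_world((np.asarray(self.shape, dtype=float) - 1) / 2)

    @classmethod
    def centered(
        cls,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float],
        center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "VoxelGrid":
        """Grid of ``shape``/``spacing`` whose geometric center sits at ``center``."""
        shape_arr = np.asarray(shape, dtype=float)
        origin = np.asarray(center) - (shape_arr - 1) / 2 * np.asarray(spacing)
        return cls(tuple(origin), tuple(spacing), tuple(shape))

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def to_dict(self) -> dict:
        return {
            "origin": list(self.origin),
            "spacing": list(self.spacing),
            "shape": list(self.shape),
            "axes": list(self.axes),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGrid":
        return cls(
            tuple(d["origin"]),
            tuple(d["spacing"]),
            tuple(d["shape"]),
            tuple(d.get("axes", LPS_AXES)),
        )
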