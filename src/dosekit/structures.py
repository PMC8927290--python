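"""Named binary ROI masks and raw contour sets.

:class:`StructureSet` holds the seven regions of interest used throughout
the toolkit (PTV plus six normal structures), all as boolean masks on one
shared :class:`~dosekit.grid.VoxelGrid`.  :class:`ContourSet` is the raw
carrier for RTSTRUCT content: per-ROI lists of closed planar polygons in
patient coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid

#: canonical ROI names in the fixed channel order (after the CT channel)
REQUIRED_ROIS = (
    "bladder",
    "body",
    "femoral_head_l",
    "femoral_head_r",
    "ptv",
    "rectum",
    "spinal_cord",
)

_ALIASES = {
    "femoral-head-l": "femoral_head_l",
    "femoral-head-r": "femoral_head_r",
    "femoral head l": "femoral_head_l",
    "femoral head r": "femoral_head_r",
    "spinal-cord": "spinal_cord",
    "spinal cord": "spinal_cord",
}


def canonical_roi_name(name: str) -> str:
    """Normalize an ROI label to the toolkit's canonical snake_case form."""
    key = name.strip().lower()
    return _ALIASES.get(key, key.replace("-", "_").replace(" ", "_"))


@dataclass
class StructureSet:
    """Binary ROI masks sharing one grid.

    ``masks`` values are boolean arrays of shape ``grid.shape``.  The PTV
    must be nonempty; a full seven-ROI set is required only where an
    operation says so (e.g. sample assembly, DVH index computation).
    """

    masks: dict[str, np.ndarray]
    grid: VoxelGrid

    def __post_init__(self) -> None:
        self.masks = {canonical_roi_name(k): np.asarray(v, dtype=bool) for k, v in self.masks.items()}
        for name, m in self.masks.items():
            if m.shape != self.grid.shape:
                raise ValueError(
                    f"mask {name!r} shape {m.shape} != grid shape {self.grid.shape}"
                )
        if "ptv" in self.masks and not self.masks["ptv"].any():
            raise ValueError("PTV mask is empty")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[canonical_roi_name(name)]

    def __contains__(self, name: str) -> bool:
        return canonical_roi_name(name) in self.masks

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.masks)

    def require(self, names=REQUIRED_ROIS) -> None:
        """Raise if any of ``names`` is absent or empty, naming the culprit."""
        for name in names:
            key = canonical_roi_name(name)
            if key not in self.masks:
                raise KeyError(f"required ROI {key!r} is missing")
            if not self.masks[key].any():
                raise ValueError(f"required ROI {key!r} is empty")


@dataclass
class ContourSet:
    """Per-ROI closed planar polygons in patient coordinates (mm).

    ``rois`` maps ROI name to a list of polygons; each polygon is an
    ``(n, 3)`` array of vertices with constant z (slice position).
    Polygons are implicitly closed: the last vertex connects back to the
    first and need not repeat it.
    """

    rois: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[np.ndarray]] = {}
        for name, polys in self.rois.items():
            out = []
            for p in polys:
                p = np.asarray(p, dtype=float)
                if p.ndim != 2 or p.shape[1] != 3:
                    raise ValueError(f"polygon for {name!r} must be (n, 3), got {p.shape}")
                # drop an explicit closing vertex so closure is uniformly implicit
                if len(p) > 1 and np.allclose(p[0], p[-1]):
                    p = p[:-1]
                if len(p) < 3:
                    raise ValueError(
                        f"polygon for {name!r} has {len(p)} distinct vertices; need >= 3"
                    )
                out.append(p)
            clean[canonical_roi_name(name)] = out
        self.rois = clean

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.rois)
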