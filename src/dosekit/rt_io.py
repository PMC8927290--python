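"""DICOM-RT input and the toolkit's on-disk sample format.

Readers return grid-aligned numpy arrays in the package convention (LPS
mm, axis order ``(x, y, z)``) together with their :class:`VoxelGrid`; no
grid-less array crosses a module boundary.  CT, structures, plan and dose
of one case are expected to share a frame of reference, so alignment is
the identity transform on patient coordinates; a frame-of-reference
mismatch is an error rather than a registration problem.

Prepared samples are serialized as plain ``.npy`` arrays plus one JSON
sidecar carrying grid, channel and plan metadata, so the numeric payload
round-trips bit-exactly while the metadata stays auditable.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pydicom

from .data_prep import TrainingSample
from .grid import VoxelGrid
from .plans import DEFAULT_PRESCRIPTION_GY, PlanSpec
from .structures import ContourSet

__all__ = [
    "read_ct_series",
    "read_rtplan",
    "read_rtstruct",
    "read_rtdose",
    "save_sample",
    "load_sample",
]

_AXIAL_ORIENT = (1, 0, 0, 0, 1, 0)


def _require_axial(ds) -> None:
    orient = getattr(ds, "ImageOrientationPatient", list(_AXIAL_ORIENT))
    if not np.allclose([float(v) for v in orient], _AXIAL_ORIENT, atol=1e-4):
        raise ValueError("only identity (axial LPS) image orientation is supported")


def read_ct_series(directory) -> tuple[np.ndarray, VoxelGrid]:
    """Read one coherent axial CT series into an HU volume.

    Slices are sorted by z position; mixed series UIDs, duplicate slice
    positions, or a gap in the slice ladder (a missing slice) are hard
    errors naming the offending position.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        if getattr(ds, "Modality", None) == "CT":
            slices.append(ds)
    if not slices:
        raise ValueError(f"no CT slices found in {directory}")
    uids = {ds.SeriesInstanceUID for ds in slices}
    if len(uids) != 1:
        raise ValueError(f"mixed CT series in {directory}: {sorted(uids)}")
    _require_axial(slices[0])
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        if (np.abs(dz) < 1e-6).any():
            dup = zs[np.flatnonzero(np.abs(dz) < 1e-6)[0]]
            raise ValueError(f"duplicate CT slice position z={dup:g} mm")
        step = np.min(dz)
        bad = np.flatnonzero(dz > step * 1.5 + 1e-6)
        if len(bad):
            lo, hi = zs[bad[0]], zs[bad[0] + 1]
            raise ValueError(
                f"missing CT slice between z={lo:g} mm and z={hi:g} mm"
            )
    else:
        step = float(getattr(slices[0], "SliceThickness", 1.0))

    first = slices[0]
    rows_mm, cols_mm = (float(v) for v in first.PixelSpacing)
    vol = np.stack(
        [
            np.asarray(ds.pixel_array, dtype=float)
            * float(getattr(ds, "RescaleSlope", 1.0))
            + float(getattr(ds, "RescaleIntercept", 0.0))
            for ds in slices
        ],
        axis=-1,
    )  # (rows=y, cols=x, z)
    vol = np.transpose(vol, (1, 0, 2))  # -> (x, y, z)
    grid = VoxelGrid(
        origin=tuple(float(v) for v in first.ImagePositionPatient),
        spacing=(cols_mm, rows_mm, float(step)),
        shape=vol.shape,
    )
    return vol, grid


def read_rtplan(path) -> PlanSpec:
    """Extract beam settings from an RTPLAN file.

    Returns gantry angles (deg), isocenter (mm), prescription dose when
    present (default 50.4 Gy otherwise), and the patient position.  A
    nonzero couch angle raises a warning and sets ``noncoplanar``.
    """
    ds = pydicom.dcmread(path)
    beams = list(getattr(ds, "BeamSequence", []))
    if not beams:
        raise ValueError("RTPLAN contains no beams")
    angles, isocenter, noncoplanar = [], None, False
    for beam in beams:
        cp = beam.ControlPointSequence[0]
        angles.append(float(cp.GantryAngle))
        couch = float(getattr(cp, "PatientSupportAngle", 0.0))
        if couch != 0.0:
            warnings.warn(
                f"non-coplanar beam (couch angle {couch} deg); flagged", stacklevel=2
            )
            noncoplanar = True
        if isocenter is None and hasattr(cp, "IsocenterPosition"):
            isocenter = tuple(float(v) for v in cp.IsocenterPosition)
    prescription = DEFAULT_PRESCRIPTION_GY
    for ref in getattr(ds, "DoseReferenceSequence", []):
        if hasattr(ref, "TargetPrescriptionDose"):
            prescription = float(ref.TargetPrescriptionDose)
            break
    position = "supine"
    for setup in getattr(ds, "PatientSetupSequence", []):
        pp = str(getattr(setup, "PatientPosition", "HFS"))
        if pp.endswith("P"):
            position = "prone"
    return PlanSpec(
        angles=tuple(angles),
        isocenter=isocenter or (0.0, 0.0, 0.0),
        prescription_gy=prescription,
        position=position,
        noncoplanar=noncoplanar,
    )


def read_rtstruct(path) -> ContourSet:
    """Read an RTSTRUCT into per-ROI closed planar polygons (mm)."""
    ds = pydicom.dcmread(path)
    names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    rois: dict[str, list[np.ndarray]] = {}
    for rc in getattr(ds, "ROIContourSequence", []):
        name = names.get(int(rc.ReferencedROINumber), f"roi_{rc.ReferencedROINumber}")
        polys = []
        for contour in getattr(rc, "ContourSequence", []):
            data = np.asarray([float(v) for v in contour.ContourData]).reshape(-1, 3)
            polys.append(data)
        if polys:
            rois[name] = polys
    return ContourSet(rois=rois)


def read_rtdose(path) -> tuple[np.ndarray, VoxelGrid]:
    """Read an RTDOSE volume, scaled to Gy."""
    ds = pydicom.dcmread(path)
    units = str(getattr(ds, "DoseUnits", "GY")).upper()
    if units != "GY":
        raise ValueError(f"dose units {units!r} unsupported; expected GY")
    _require_axial(ds)
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    frames = np.asarray(ds.pixel_array, dtype=float) * scaling  # (z, y, x)
    if frames.ndim == 2:
        frames = frames[None]
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if len(dz) and not np.allclose(dz, dz[0], atol=1e-6):
        raise ValueError("non-uniform dose grid frame offsets")
    rows_mm, cols_mm = (float(v) for v in ds.PixelSpacing)
    vol = np.transpose(frames, (2, 1, 0))  # -> (x, y, z)
    origin = [float(v) for v in ds.ImagePositionPatient]
    origin[2] += float(offsets[0])
    grid = VoxelGrid(
        origin=tuple(origin),
        spacing=(cols_mm, rows_mm, float(dz[0]) if len(dz) else 1.0),
        shape=vol.shape,
    )
    return vol, grid


# ---------------------------------------------------------------------------
# toolkit sample format: npy arrays + JSON sidecar


def save_sample(sample: TrainingSample, directory) -> Path:
    """Serialize a training sample: one ``.npy`` per array + sidecar JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "channels.npy", sample.channels)
    np.save(directory / "dose.npy", sample.dose_gy)
    sidecar = {
        "grid": sample.grid.to_dict(),
        "channel_names": list(sample.channel_names),
        "plan": sample.plan.to_dict() if sample.plan is not None else None,
        "meta": sample.meta,
    }
    (directory / "sample.json").write_text(json.dumps(sidecar, indent=1))
    return directory


def load_sample(directory) -> TrainingSample:
    """Load a sample written by :func:`save_sample` (bit-exact arrays)."""
    directory = Path(directory)
    sidecar = json.loads((directory / "sample.json").read_text())
    return TrainingSample(
        channels=np.load(directory / "channels.npy"),
        channel_names=tuple(sidecar["channel_names"]),
        dose_gy=np.load(directory / "dose.npy"),
        grid=VoxelGrid.from_dict(sidecar["grid"]),
        plan=PlanSpec.from_dict(sidecar["plan"]) if sidecar["plan"] else None,
        meta=sidecar.get("meta", {}),
    )
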