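"""Minimal synthetic DICOM-RT writers used as round-trip oracles.

These build just enough of each IOD for the readers under test; the
values written here are the expected values the reader tests assert
against.
"""

from __future__ import annotations

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
RTPLAN_SOP = "1.2.840.10008.5.1.4.1.1.481.5"
RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"


def _base(sop_class: str) -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientName = "Phantom^Synthetic"
    ds.PatientID = "SYN000"
    return ds


def write_ct_series(
    directory,
    hu: np.ndarray,
    spacing=(1.0, 1.0, 5.0),
    origin=(0.0, 0.0, 0.0),
    series_uid: str | None = None,
    skip_slices=(),
    prefix: str = "ct",
):
    """Write an axial CT series from an (x, y, z) HU volume.

    Returns the per-slice file paths.  ``skip_slices`` omits the given z
    indices to fabricate a gap.
    """
    series_uid = series_uid or generate_uid()
    nx, ny, nz = hu.shape
    paths = []
    for k in range(nz):
        if k in skip_slices:
            continue
        ds = _base(CT_SOP)
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [spacing[1], spacing[0]]  # [row, col] = [y, x]
        ds.SliceThickness = spacing[2]
        ds.ImagePositionPatient = [origin[0], origin[1], origin[2] + k * spacing[2]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        stored = np.round(hu[:, :, k] + 1024.0).astype(np.uint16)
        ds.PixelData = stored.T.tobytes()  # DICOM rows are y
        path = directory / f"{prefix}_{k:03d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths


def write_rtplan(
    path,
    gantry_angles,
    isocenter=(0.0, 0.0, 0.0),
    prescription_gy: float | None = 50.4,
    couch_angles=None,
    patient_position="HFS",
):
    ds = _base(RTPLAN_SOP)
    ds.Modality = "RTPLAN"
    couch_angles = couch_angles or [0.0] * len(gantry_angles)
    beams = []
    for i, (g, c) in enumerate(zip(gantry_angles, couch_angles)):
        beam = Dataset()
        beam.BeamNumber = i + 1
        cp = Dataset()
        cp.GantryAngle = g
        cp.PatientSupportAngle = c
        cp.IsocenterPosition = list(isocenter)
        beam.ControlPointSequence = [cp]
        beams.append(beam)
    ds.BeamSequence = beams
    if prescription_gy is not None:
        ref = Dataset()
        ref.TargetPrescriptionDose = prescription_gy
        ds.DoseReferenceSequence = [ref]
    setup = Dataset()
    setup.PatientPosition = patient_position
    ds.PatientSetupSequence = [setup]
    ds.save_as(path, enforce_file_format=True)
    return path


def write_rtstruct(path, rois: dict):
    """``rois`` maps name -> list of (n, 3) polygon vertex arrays (mm)."""
    ds = _base(RTSTRUCT_SOP)
    ds.Modality = "RTSTRUCT"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for num, (name, polys) in enumerate(rois.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for poly in polys:
            c = Dataset()
            poly = np.asarray(poly, dtype=float)
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(poly)
            c.ContourData = [float(v) for v in poly.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)
    return path


def write_rtdose(
    path,
    stored: np.ndarray,
    scaling: float,
    spacing=(2.5, 2.5, 2.5),
    origin=(0.0, 0.0, 0.0),
    units="GY",
):
    """Write an RTDOSE from an (x, y, z) volume of stored integer values."""
    ds = _base(RTDOSE_SOP)
    ds.Modality = "RTDOSE"
    nx, ny, nz = stored.shape
    ds.Rows, ds.Columns = ny, nx
    ds.NumberOfFrames = nz
    ds.PixelSpacing = [spacing[1], spacing[0]]
    ds.ImagePositionPatient = list(origin)
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [k * spacing[2] for k in range(nz)]
    ds.DoseUnits = units
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    frames = np.transpose(stored.astype(np.uint32), (2, 1, 0))  # (z, y, x)
    ds.PixelData = frames.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path
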