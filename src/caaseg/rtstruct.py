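"""DICOM RT-Structure export: binary masks -> per-slice planar contours.

Each structure is polygonised slice by slice (0.5-level iso-contours of the
mask) and written as CLOSED_PLANAR contours referencing the planning CT
series. Empty structures are skipped with a warning rather than failing the
export. The writer targets interoperability for contour transfer, not full
IOD conformance (no registration objects, no RT-Plan/Dose, no keyhole/hole
encoding).

``rasterize_rtstruct`` inverts the export on a given grid, which lets a
round-trip be validated: export -> rasterise should reproduce a convex
structure with DSC >= 0.99.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage import draw, measure

from .errors import FormatError, GridMismatchError
from .volume_io import Grid, ImageVolume, StructureSet, read_dicom_series

_RTSTRUCT_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"

# ROI display colours (RGB) per structure, loosely following the conventional
# rendering: right atrium red, aortic valve root green, LCA blue, RCA orange.
_COLOURS = {
    "RightAtrium": [255, 0, 0],
    "AorticValveRoot": [0, 255, 0],
    "LCA": [0, 0, 255],
    "RCA": [255, 165, 0],
    "CAA": [255, 255, 0],
}


def _slice_polygons(mask_slice: np.ndarray) -> list[np.ndarray]:
    """Closed 0.5-level contours of a 2D mask, in (x_index, y_index) coords."""
    padded = np.pad(mask_slice.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    return [c - 1.0 for c in contours if len(c) >= 3]


def export_rtstruct(
    structures: StructureSet,
    reference_ct: str | os.PathLike | ImageVolume,
    path: str | os.PathLike,
    series_description: str = "CAA auto-contours",
) -> Path:
    """Write a structure set as DICOM RT-Structure referencing a CT series.

    ``reference_ct`` is the DICOM CT series directory (or an already-loaded
    volume of it, in which case the geometry is trusted but per-slice SOP
    references are synthesised). Masks must live on the CT grid.
    """
    if isinstance(reference_ct, ImageVolume):
        ct = reference_ct
        slice_uids = [generate_uid() for _ in range(ct.shape[2])]
    else:
        ct = read_dicom_series(reference_ct)
        slice_uids = _series_sop_uids(reference_ct)
    if not structures.grid.close_to(ct.grid, tol=1e-3):
        raise GridMismatchError("structure-set grid does not match the reference CT grid")

    ds = Dataset()
    ds.SOPClassUID = _RTSTRUCT_CLASS
    ds.SOPInstanceUID = generate_uid()
    ds.Modality = "RTSTRUCT"
    ds.SeriesDescription = series_description
    ds.StructureSetLabel = "CAA"
    ds.PatientName = "Phantom"
    ds.PatientID = "PHANTOM"
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    frame_uid = generate_uid()

    roi_seq, contour_seq, obs_seq = [], [], []
    number = 0
    sx, sy, sz = ct.spacing
    for name in structures.names:
        mask = structures[name]
        if not mask.any():
            warnings.warn(f"structure {name!r} is empty; omitted from RT-Structure", stacklevel=2)
            continue
        number += 1
        roi = Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ROIDisplayColor = _COLOURS.get(name, [0, 255, 255])
        slices = []
        for k in range(mask.shape[2]):
            for poly in _slice_polygons(mask[:, :, k]):
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = len(poly)
                pts = np.column_stack(
                    [
                        ct.origin[0] + poly[:, 0] * sx,
                        ct.origin[1] + poly[:, 1] * sy,
                        np.full(len(poly), ct.origin[2] + k * sz),
                    ]
                )
                c.ContourData = [float(v) for v in pts.reshape(-1)]
                ref = Dataset()
                ref.ReferencedSOPClassUID = pydicom.uid.CTImageStorage
                ref.ReferencedSOPInstanceUID = slice_uids[k]
                c.ContourImageSequence = [ref]
                slices.append(c)
        rc.ContourSequence = slices
        contour_seq.append(rc)

        ob = Dataset()
        ob.ObservationNumber = number
        ob.ReferencedROINumber = number
        ob.ROIObservationLabel = name
        ob.RTROIInterpretedType = "ORGAN"
        obs_seq.append(ob)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTSTRUCT_CLASS
    meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta = meta
    path = Path(path)
    pydicom.dcmwrite(path, ds, enforce_file_format=True)
    return path


def _series_sop_uids(directory: str | os.PathLike) -> list[str]:
    """SOP instance UIDs of a CT series directory, ordered by slice position."""
    entries = []
    for f in sorted(Path(directory).glob("*.dcm")):
        ds = pydicom.dcmread(f, stop_before_pixels=True)
        entries.append((float(ds.ImagePositionPatient[2]), str(ds.SOPInstanceUID)))
    if not entries:
        raise FormatError(f"no DICOM files found in {directory}")
    return [uid for _, uid in sorted(entries)]


def rasterize_rtstruct(path: str | os.PathLike, grid: Grid, observer: str = "rtstruct") -> StructureSet:
    """Rasterise an RT-Structure file back to masks on an axis-aligned grid."""
    ds = pydicom.dcmread(Path(path))
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    sx, sy, sz = grid.spacing
    out = StructureSet(grid=grid, structures={}, observer=observer)
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        mask = np.zeros(grid.shape, dtype=np.uint8)
        for contour in getattr(rc, "ContourSequence", []):
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            k = int(round((pts[0, 2] - grid.origin[2]) / sz))
            if not 0 <= k < grid.shape[2]:
                continue
            xi = (pts[:, 0] - grid.origin[0]) / sx
            yi = (pts[:, 1] - grid.origin[1]) / sy
            rr, cc = draw.polygon(xi, yi, shape=grid.shape[:2])
            mask[rr, cc, k] = 1
        out.add(name, mask)
    return out
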