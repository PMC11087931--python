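"""Volumes, masks and structure sets: in-memory containers and file round-trips.

Conventions
-----------
* A volume is an axis-aligned 3D scalar grid. ``voxels[i, j, k]`` sits at physical
  position ``origin + (i*sx, j*sy, k*sz)`` mm (voxel-centre convention, 0-based
  indices). Only identity direction cosines are supported; oblique/tilted
  acquisitions are rejected.
* Array axis order is (x, y, z) so that axis 2 is the slice (z) axis.
* Distances are millimetres, volumes cm^3. CT intensities are Hounsfield units,
  dose grids are Gy.
* Binary masks are uint8 arrays with values in {0, 1}.

Files: NIfTI (.nii/.nii.gz) via nibabel for volumes/masks/dose; DICOM CT series
(read, via SimpleITK; write, a minimal series via pydicom, intended as reference
geometry for RT-Structure export and for tests). Structure sets travel as a JSON
manifest naming one NIfTI mask file per structure.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np

from .errors import (
    FormatError,
    GridMismatchError,
    UnsupportedGeometryError,
    ValidationError,
)

MODALITIES = ("CT", "DOSE", "MASK", "LABEL")

#: Fixed label registry for the segmentation classes. The cardiac avoidance area
#: (CAA) is always derived as the union of the four substructures and is never a
#: primary label.
LABEL_REGISTRY: dict[str, int] = {
    "RightAtrium": 1,
    "AorticValveRoot": 2,
    "LCA": 3,
    "RCA": 4,
}
CAA_MEMBERS = tuple(LABEL_REGISTRY)
NUM_CLASSES = len(LABEL_REGISTRY) + 1  # + background


@dataclass(frozen=True)
class Grid:
    """Shared voxel-grid geometry: shape, spacing (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValidationError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.spacing) != 3 or any(float(s) <= 0 for s in self.spacing):
            raise ValidationError(f"grid spacing must be 3 positive floats, got {self.spacing}")

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing
        return float(sx * sy * sz) / 1000.0

    def close_to(self, other: "Grid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Physical mm coordinates of (possibly fractional) voxel indices, shape (..., 3)."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)


@dataclass
class ImageVolume:
    """Axis-aligned 3D scalar grid (HU for CT, Gy for dose, {0,1} for masks)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"volume must be rank 3, got rank {self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing components must be > 0, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}, got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.spacing, self.origin)

    @property
    def voxel_volume_cm3(self) -> float:
        return self.grid.voxel_volume_cm3

    def same_grid(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return self.grid.close_to(other.grid, tol)


def as_mask(arr: np.ndarray) -> np.ndarray:
    """Validate and return a uint8 {0,1} mask."""
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValidationError(f"mask values must be in {{0,1}}, found {vals[:8]}")
    return arr.astype(np.uint8)


@dataclass
class StructureSet:
    """Named binary masks sharing one grid, tagged with an observer id.

    Observer ids follow the commissioning convention: ``"auto"`` for the CNN,
    ``"obs1"``/``"obs2"``/... for human observers, ``"STAPLE"`` for the consensus,
    ``"truth"`` for phantom ground truth.
    """

    grid: Grid
    structures: dict[str, np.ndarray] = field(default_factory=dict)
    observer: str = "auto"

    def __post_init__(self) -> None:
        validated = {}
        for name, mask in self.structures.items():
            validated[name] = self._check(name, mask)
        self.structures = validated

    def _check(self, name: str, mask: np.ndarray) -> np.ndarray:
        mask = as_mask(mask)
        if tuple(mask.shape) != self.grid.shape:
            raise GridMismatchError(
                f"structure {name!r} has shape {mask.shape}, grid is {self.grid.shape}"
            )
        return mask

    def add(self, name: str, mask: np.ndarray) -> None:
        if name in self.structures:
            raise ValidationError(f"duplicate structure name {name!r} for observer {self.observer!r}")
        self.structures[name] = self._check(name, mask)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    @property
    def names(self) -> list[str]:
        return list(self.structures)

    def to_label_map(self, registry: Mapping[str, int] = LABEL_REGISTRY) -> np.ndarray:
        """Collapse registry structures into a single uint8 label map.

        Earlier registry entries take precedence where masks overlap, so the
        result is always a valid mutually-exclusive labelling.
        """
        labels = np.zeros(self.grid.shape, dtype=np.uint8)
        for name, value in registry.items():
            if name in self.structures:
                m = self.structures[name].astype(bool) & (labels == 0)
                labels[m] = value
        return labels

    @classmethod
    def from_label_map(
        cls,
        labels: np.ndarray,
        grid: Grid,
        observer: str = "auto",
        registry: Mapping[str, int] = LABEL_REGISTRY,
    ) -> "StructureSet":
        ss = cls(grid=grid, structures={}, observer=observer)
        for name, value in registry.items():
            ss.add(name, (np.asarray(labels) == value).astype(np.uint8))
        return ss


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------


def _affine(spacing: Iterable[float], origin: Iterable[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(list(spacing))
    aff[:3, 3] = list(origin)
    return aff


def write_volume(volume: ImageVolume, path: str | os.PathLike) -> Path:
    """Write a volume as NIfTI; dtype is preserved (int HU stays int)."""
    path = Path(path)
    img = nib.Nifti1Image(volume.voxels, _affine(volume.spacing, volume.origin))
    img.header.set_data_dtype(volume.voxels.dtype)
    nib.save(img, path)
    return path


def _read_nifti(path: Path, modality: str) -> ImageVolume:
    img = nib.load(path)
    aff = np.asarray(img.affine)
    rot = aff[:3, :3]
    diag = np.diag(np.diag(rot))
    if not np.allclose(rot, diag, atol=1e-6) or np.any(np.diag(rot) <= 0):
        raise UnsupportedGeometryError(
            f"{path}: only axis-aligned volumes with identity direction cosines are supported"
        )
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected rank-3 volume, got rank {data.ndim}")
    return ImageVolume(
        voxels=data,
        spacing=tuple(np.diag(rot)),
        origin=tuple(aff[:3, 3]),
        modality=modality,
    )


def read_volume(path: str | os.PathLike, modality: str = "CT") -> ImageVolume:
    """Read a volume from NIfTI or from a DICOM CT series directory."""
    path = Path(path)
    if path.is_dir():
        return read_dicom_series(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path, modality)
    raise FormatError(f"unrecognised volume format: {path}")


# ---------------------------------------------------------------------------
# DICOM CT series
# ---------------------------------------------------------------------------


def read_dicom_series(directory: str | os.PathLike) -> ImageVolume:
    """Read a DICOM CT series directory into an ImageVolume (HU)."""
    import SimpleITK as sitk

    directory = str(directory)
    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(directory)
    if not files:
        raise FormatError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    image = reader.Execute()
    direction = np.asarray(image.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-4):
        raise UnsupportedGeometryError(
            f"{directory}: oblique/tilted DICOM series not supported (direction {direction.tolist()})"
        )
    # SimpleITK arrays are (z, y, x); transpose to our (x, y, z).
    voxels = sitk.GetArrayFromImage(image).transpose(2, 1, 0)
    return ImageVolume(
        voxels=voxels,
        spacing=tuple(image.GetSpacing()),
        origin=tuple(image.GetOrigin()),
        modality="CT",
    )


def write_dicom_series(volume: ImageVolume, directory: str | os.PathLike) -> list[Path]:
    """Write a minimal axial DICOM CT series (one file per slice).

    Intended for phantom/reference geometry (RT-Structure export needs a
    referenced CT series); not a conformance-complete CT IOD.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vox = np.asarray(np.rint(volume.voxels), dtype=np.int16)
    sx, sy, sz = volume.spacing
    study_uid, series_uid, frame_uid = generate_uid(), generate_uid(), generate_uid()
    paths = []
    for k in range(vox.shape[2]):
        ds = Dataset()
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.PatientName = "Phantom"
        ds.PatientID = "PHANTOM"
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [
            volume.origin[0],
            volume.origin[1],
            volume.origin[2] + k * sz,
        ]
        ds.PixelSpacing = [sy, sx]  # DICOM order: row spacing (y), column spacing (x)
        ds.SliceThickness = sz
        ds.Rows, ds.Columns = vox.shape[1], vox.shape[0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = 0.0
        ds.RescaleSlope = 1.0
        # Pixel rows are y, columns are x -> transpose the (x, y) slice.
        ds.PixelData = np.ascontiguousarray(vox[:, :, k].T).tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        out = directory / f"ct_{k:04d}.dcm"
        pydicom.dcmwrite(out, ds, enforce_file_format=True)
        paths.append(out)
    return paths


# ---------------------------------------------------------------------------
# Structure-set manifest
# ---------------------------------------------------------------------------


def write_structure_set(ss: StructureSet, directory: str | os.PathLike, stem: str = "structures") -> Path:
    """Save masks as NIfTI plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for name in sorted(ss.structures):
        fname = f"{stem}_{ss.observer}_{name}.nii.gz"
        write_volume(
            ImageVolume(ss.structures[name], ss.grid.spacing, ss.grid.origin, modality="MASK"),
            directory / fname,
        )
        entries.append({"name": name, "file": fname})
    manifest = {
        "observer": ss.observer,
        "grid": {"shape": list(ss.grid.shape), "spacing": list(ss.grid.spacing), "origin": list(ss.grid.origin)},
        "structures": entries,
    }
    path = directory / f"{stem}_{ss.observer}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_structure_set(manifest_path: str | os.PathLike, reference: Grid | None = None) -> StructureSet:
    """Load a structure set from its JSON manifest.

    All masks must share one grid; if ``reference`` is given it must match too.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FormatError(f"no such manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    grid = None
    masks: dict[str, np.ndarray] = {}
    for entry in manifest["structures"]:
        fpath = base / entry["file"]
        if not fpath.exists():
            raise FormatError(f"structure {entry['name']!r}: missing file {fpath}")
        vol = read_volume(fpath, modality="MASK")
        if grid is None:
            grid = vol.grid
        elif not grid.close_to(vol.grid):
            raise GridMismatchError(f"structure {entry['name']!r} is on a different grid")
        masks[entry["name"]] = as_mask(vol.voxels)
    if grid is None:
        raise FormatError(f"{manifest_path}: manifest lists no structures")
    if reference is not None and not grid.close_to(reference):
        raise GridMismatchError("structure-set grid does not match the reference grid")
    return StructureSet(grid=grid, structures=masks, observer=manifest.get("observer", "unknown"))
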