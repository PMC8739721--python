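"""Treatment-course I/O: dose grids, anatomy volumes and structures.

Reads and writes DICOM RTDOSE / RTSTRUCT plus a research raster fallback
(any SimpleITK-readable volume format carrying origin/spacing/direction,
e.g. ``.mha``/``.nii``/``.nrrd``), and establishes the common geometric model
(:class:`~rebed.geometry.GridGeometry`) every later stage works on.

Doses are stored as *total physical dose for the course* in Gy; the
per-fraction dose is derived (total / n) at BED-conversion time.
Resampling outside the source grid's support yields 0 Gy (conservative for
dose summation); the number of such voxels is logged for audit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage.draw import polygon2mask

from .errors import DoseFormatError, RasterizationError
from .geometry import GridGeometry, array_to_sitk, geometry_from_sitk, sitk_to_array

logger = logging.getLogger(__name__)

_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"

__all__ = [
    "DoseGrid",
    "ImageVolume",
    "FractionationScheme",
    "TreatmentCourse",
    "StructureMask",
    "read_rtdose",
    "write_rtdose",
    "read_dose",
    "read_volume",
    "write_volume",
    "read_structures",
    "write_rtstruct",
    "mask_to_volume",
    "resample_to_grid",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DoseGrid:
    """A 3-D raster of total physical dose (Gy) with geometry."""

    geometry: GridGeometry
    values: np.ndarray
    frame_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.values.shape) != self.geometry.dims:
            raise ValueError(
                f"values shape {self.values.shape} != geometry dims {self.geometry.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dose values must be finite")
        if self.values.min() < 0:
            raise ValueError("dose values must be >= 0 Gy")


@dataclass
class ImageVolume:
    """A scalar anatomy volume (CT-like intensities) with geometry."""

    geometry: GridGeometry
    values: np.ndarray
    frame_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if tuple(self.values.shape) != self.geometry.dims:
            raise ValueError(
                f"values shape {self.values.shape} != geometry dims {self.geometry.dims}"
            )


@dataclass(frozen=True)
class FractionationScheme:
    """Number of fractions (and optionally the prescription) of one course."""

    n_fractions: int
    prescription_dose: float | None = None

    def __post_init__(self) -> None:
        if int(self.n_fractions) < 1:
            raise ValueError("n_fractions must be >= 1")
        object.__setattr__(self, "n_fractions", int(self.n_fractions))


@dataclass
class TreatmentCourse:
    """One radiotherapy course: dose grid, fractionation and planning anatomy."""

    dose: DoseGrid
    fractionation: FractionationScheme
    anatomy: ImageVolume
    label: str = ""

    def __post_init__(self) -> None:
        if self.dose.frame_label != self.anatomy.frame_label:
            raise ValueError(
                "dose and anatomy must share frame_label (same patient time point): "
                f"{self.dose.frame_label!r} != {self.anatomy.frame_label!r}"
            )


@dataclass
class StructureMask:
    """Binary OAR occupancy on a grid."""

    geometry: GridGeometry
    occupancy: np.ndarray
    name: str

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if tuple(self.occupancy.shape) != self.geometry.dims:
            raise ValueError(
                f"occupancy shape {self.occupancy.shape} != geometry dims "
                f"{self.geometry.dims}"
            )

    @property
    def voxel_volume_cc(self) -> float:
        return self.geometry.voxel_volume_cc

    @property
    def volume_cc(self) -> float:
        return float(self.occupancy.sum()) * self.voxel_volume_cc


# ---------------------------------------------------------------------------
# DICOM RTDOSE
# ---------------------------------------------------------------------------

_REQUIRED_RTDOSE_TAGS = (
    "ImagePositionPatient",
    "ImageOrientationPatient",
    "PixelSpacing",
    "GridFrameOffsetVector",
    "DoseGridScaling",
    "Rows",
    "Columns",
)


def read_rtdose(path: str | Path, scale_to_total: bool = False) -> DoseGrid:
    """Read a DICOM RTDOSE file into a :class:`DoseGrid` of total Gy.

    Raw stored integers are multiplied by DoseGridScaling. Per-fraction dose
    objects (DoseSummationType == FRACTION) are multiplied up to course totals
    only when ``scale_to_total`` is set and fraction metadata is present.
    """
    ds = pydicom.dcmread(str(path))
    missing = [t for t in _REQUIRED_RTDOSE_TAGS if getattr(ds, t, None) is None]
    if missing:
        raise DoseFormatError(f"RTDOSE missing required geometry tags: {missing}")

    summation = str(getattr(ds, "DoseSummationType", "PLAN")).upper()
    factor = 1.0
    if summation == "FRACTION":
        n = getattr(ds, "NumberOfFractionsPlanned", None)
        if scale_to_total:
            if n is None:
                raise DoseFormatError(
                    "DoseSummationType=FRACTION but no fraction metadata "
                    "(NumberOfFractionsPlanned) to scale to a course total"
                )
            factor = float(n)
    elif summation not in ("PLAN", "MULTI_PLAN", "COURSE"):
        raise DoseFormatError(f"unsupported DoseSummationType: {summation!r}")

    gfov = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    if gfov.size > 1:
        steps = np.diff(gfov)
        if not np.allclose(steps, steps[0], atol=1e-4):
            raise DoseFormatError("non-uniform GridFrameOffsetVector not supported")
        dz = float(steps[0])
    else:
        dz = float(getattr(ds, "SliceThickness", 1.0) or 1.0)

    iop = np.asarray(ds.ImageOrientationPatient, dtype=float)
    col_dir, row_dir = iop[:3], iop[3:]
    normal = np.cross(col_dir, row_dir)
    sign = -1.0 if dz < 0 else 1.0
    direction = np.column_stack([col_dir, row_dir, normal * sign])

    origin = np.asarray(ds.ImagePositionPatient, dtype=float) + normal * gfov[0]
    spacing = (float(ds.PixelSpacing[1]), float(ds.PixelSpacing[0]), abs(dz))
    nz = int(getattr(ds, "NumberOfFrames", 1))
    dims = (int(ds.Columns), int(ds.Rows), nz)

    raw = ds.pixel_array.astype(float)  # (frames, rows, cols)
    if raw.ndim == 2:
        raw = raw[None]
    values = raw.transpose(2, 1, 0) * float(ds.DoseGridScaling) * factor

    geom = GridGeometry(origin=tuple(origin), spacing=spacing, dims=dims, direction=direction)
    return DoseGrid(geometry=geom, values=values, frame_label=str(getattr(ds, "FrameOfReferenceUID", "")))


def write_rtdose(dose: DoseGrid, path: str | Path, n_fractions: int | None = None) -> None:
    """Write a :class:`DoseGrid` as a DICOM RTDOSE (32-bit stored values).

    The dose-grid scaling factor is chosen so the full 32-bit range covers
    the maximum dose; quantization error is at most one scaling quantum.
    """
    geom = dose.geometry
    max_dose = float(dose.values.max())
    scaling = max_dose / (2**32 - 1) if max_dose > 0 else 1.0

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = _RTDOSE_SOP_CLASS
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    if n_fractions is not None:
        ds.NumberOfFractionsPlanned = int(n_fractions)
    if dose.frame_label:
        ds.FrameOfReferenceUID = dose.frame_label

    nx, ny, nz = geom.dims
    ds.Columns, ds.Rows, ds.NumberOfFrames = nx, ny, nz
    ds.PixelSpacing = [geom.spacing[1], geom.spacing[0]]
    ds.ImagePositionPatient = list(geom.origin)
    ds.ImageOrientationPatient = list(geom.direction[:, 0]) + list(geom.direction[:, 1])
    ds.GridFrameOffsetVector = [k * geom.spacing[2] for k in range(nz)]
    ds.DoseGridScaling = scaling
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0

    raw = np.round(dose.values / scaling).astype(np.uint32)
    ds.PixelData = np.ascontiguousarray(raw.transpose(2, 1, 0)).tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Research raster fallback (SimpleITK-readable volumes)
# ---------------------------------------------------------------------------


def read_volume(path: str | Path) -> tuple[np.ndarray, GridGeometry]:
    """Read any SimpleITK-supported raster volume (``.mha``/``.nii``/``.nrrd``...)."""
    img = sitk.ReadImage(str(path))
    return sitk_to_array(img).astype(float), geometry_from_sitk(img)


def write_volume(values: np.ndarray, geometry: GridGeometry, path: str | Path) -> None:
    values = np.asarray(values)
    if values.ndim == 4:
        img = array_to_sitk(values.astype(float), geometry, vector=True)
    elif values.dtype == bool:
        img = array_to_sitk(values.astype(np.uint8).astype(float), geometry)
        img = sitk.Cast(img, sitk.sitkUInt8)
    else:
        img = array_to_sitk(values.astype(float), geometry)
    sitk.WriteImage(img, str(path))


def mask_to_volume(mask: StructureMask, path: str | Path) -> None:
    """Write a structure mask as a labelled (0/1) raster volume."""
    write_volume(mask.occupancy, mask.geometry, path)


def read_dose(path: str | Path, scale_to_total: bool = False, frame_label: str = "") -> DoseGrid:
    """Read a dose grid from RTDOSE (``.dcm``) or a raster volume."""
    p = Path(path)
    if p.suffix.lower() == ".dcm":
        return read_rtdose(p, scale_to_total=scale_to_total)
    values, geom = read_volume(p)
    return DoseGrid(geometry=geom, values=values, frame_label=frame_label)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


def read_structures(path: str | Path, target: GridGeometry) -> list[StructureMask]:
    """Read OAR structures and rasterize them onto ``target``.

    Accepts a DICOM RTSTRUCT (planar contours, rasterized per slice with
    even-odd polygon fill sampled at voxel centers) or a raster mask volume
    (non-zero occupancy, nearest-neighbour resampled onto the target grid,
    named from the file stem).
    """
    p = Path(path)
    if p.suffix.lower() == ".dcm":
        return _read_rtstruct(p, target)
    values, geom = read_volume(p)
    mask = StructureMask(geometry=geom, occupancy=values > 0.5, name=p.stem)
    if not geom.same_as(target):
        img = array_to_sitk(mask.occupancy.astype(float), geom)
        res = sitk.Resample(img, target.to_sitk_reference(), sitk.Transform(),
                            sitk.sitkNearestNeighbor, 0.0, sitk.sitkFloat64)
        mask = StructureMask(geometry=target, occupancy=sitk_to_array(res) > 0.5, name=p.stem)
    if not mask.occupancy.any():
        warnings.warn(f"structure {mask.name!r} is empty on the target grid", stacklevel=2)
    return [mask]


def _read_rtstruct(path: Path, target: GridGeometry) -> list[StructureMask]:
    ds = pydicom.dcmread(str(path))
    if not hasattr(ds, "ROIContourSequence") or not hasattr(ds, "StructureSetROISequence"):
        raise RasterizationError("not an RTSTRUCT: missing ROI sequences")
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}

    nx, ny, nz = target.dims
    masks: list[StructureMask] = []
    for roi in ds.ROIContourSequence:
        name = names.get(int(roi.ReferencedROINumber), f"ROI{roi.ReferencedROINumber}")
        occ = np.zeros((nx, ny, nz), dtype=bool)
        for contour in getattr(roi, "ContourSequence", []):
            if str(getattr(contour, "ContourGeometricType", "CLOSED_PLANAR")) != "CLOSED_PLANAR":
                continue
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            idx = target.world_to_voxel(pts)
            k_cont = idx[:, 2]
            k = int(np.round(np.mean(k_cont)))
            if np.max(np.abs(k_cont - k)) > 0.5 + 1e-6:
                raise RasterizationError(
                    f"contour of {name!r} not coplanar with any target slice "
                    f"(slice-index spread {np.ptp(k_cont):.3f} voxels)"
                )
            if k < 0 or k >= nz:
                continue  # outside target extent
            # XOR accumulation implements even-odd fill for nested contours
            occ[:, :, k] ^= polygon2mask((nx, ny), idx[:, :2])
        if not occ.any():
            warnings.warn(f"structure {name!r} rasterized to an empty mask", stacklevel=3)
        masks.append(StructureMask(geometry=target, occupancy=occ, name=name))
    return masks


def write_rtstruct(structures: dict[str, list[np.ndarray]], path: str | Path,
                   frame_label: str = "") -> None:
    """Write planar contours as a minimal DICOM RTSTRUCT.

    ``structures`` maps structure name to a list of closed planar contours,
    each an (N, 3) array of patient coordinates (mm) with constant z.
    """
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = _RTSTRUCT_SOP_CLASS
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SOPClassUID = _RTSTRUCT_SOP_CLASS
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "rebed"
    if frame_label:
        ds.FrameOfReferenceUID = frame_label

    roi_seq, contour_seq = [], []
    for number, (name, contours) in enumerate(structures.items(), start=1):
        roi = pydicom.Dataset()
        roi.ROINumber = number
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_label
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(roi)

        rc = pydicom.Dataset()
        rc.ReferencedROINumber = number
        cs = []
        for pts in contours:
            pts = np.asarray(pts, dtype=float).reshape(-1, 3)
            c = pydicom.Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = pts.shape[0]
            c.ContourData = [float(v) for v in pts.ravel()]
            cs.append(c)
        rc.ContourSequence = cs
        contour_seq.append(rc)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERP = {"trilinear": sitk.sitkLinear, "nearest": sitk.sitkNearestNeighbor}


def resample_to_grid(src: DoseGrid, target: GridGeometry, mode: str = "trilinear") -> DoseGrid:
    """Resample a dose grid onto ``target`` at voxel centers.

    Points outside the source support get 0 Gy; the count of such voxels is
    logged. ``mode`` is ``"trilinear"`` or ``"nearest"``.
    """
    if mode not in _INTERP:
        raise ValueError(f"mode must be one of {sorted(_INTERP)}, got {mode!r}")
    ref = target.to_sitk_reference()
    img = array_to_sitk(src.values, src.geometry)
    out = sitk.Resample(img, ref, sitk.Transform(), _INTERP[mode], 0.0, sitk.sitkFloat64)

    support = sitk.Resample(
        array_to_sitk(np.ones(src.geometry.dims), src.geometry),
        ref, sitk.Transform(), sitk.sitkNearestNeighbor, 0.0, sitk.sitkFloat64)
    n_outside = int((sitk_to_array(support) == 0).sum())
    if n_outside:
        logger.info("resample_to_grid: %d target voxels outside source support -> 0 Gy",
                    n_outside)
    return DoseGrid(geometry=target, values=sitk_to_array(out), frame_label=src.frame_label)
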