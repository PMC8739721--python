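"""Grid geometry for dose and image rasters.

All grids live in the DICOM patient coordinate system (LPS, millimetres).
Voxel indices are 0-based and ``origin`` is the patient-space position of the
*center* of voxel (0, 0, 0), matching RTDOSE ImagePositionPatient semantics.
Arrays are indexed ``values[i, j, k]`` with ``dims = (nx, ny, nz)``; the world
position of voxel (i, j, k) is ``origin + direction @ (spacing * (i, j, k))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = ["GridGeometry", "geometry_from_sitk", "array_to_sitk", "sitk_to_array"]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class GridGeometry:
    """Origin/spacing/dims/direction of a 3-D raster in patient coordinates.

    Parameters
    ----------
    origin : (3,) float
        Patient-space position (mm) of the center of voxel (0, 0, 0).
    spacing : (3,) float
        Voxel pitch along each grid axis, mm. Strictly positive.
    dims : (3,) int
        Number of voxels along each axis, ``(nx, ny, nz)``.
    direction : (3, 3) float
        Orthonormal matrix whose *columns* are the direction cosines of the
        grid axes. Defaults to identity (axis-aligned grid).
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        object.__setattr__(
            self, "direction", np.asarray(self.direction, dtype=float).reshape(3, 3)
        )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"dims must be >= 1 in every axis, got {self.dims}")
        err = np.abs(self.direction.T @ self.direction - np.eye(3)).max()
        if err > _ORTHO_TOL:
            raise ValueError(
                f"direction matrix not orthonormal (max deviation {err:.2e})"
            )

    # -- coordinate transforms ------------------------------------------------

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) continuous voxel indices to patient coordinates (mm)."""
        ijk = np.asarray(ijk, dtype=float)
        return np.asarray(self.origin) + (ijk * np.asarray(self.spacing)) @ self.direction.T

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map (..., 3) patient coordinates (mm) to continuous voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return ((xyz - np.asarray(self.origin)) @ self.direction) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """Patient coordinates of every voxel center, shape ``dims + (3,)``."""
        nx, ny, nz = self.dims
        ii, jj, kk = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        ijk = np.stack([ii, jj, kk], axis=-1)
        return self.voxel_to_world(ijk)

    # -- derived quantities ---------------------------------------------------

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of a single voxel in cubic centimetres."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def same_as(self, other: "GridGeometry", tol: float = 1e-6) -> bool:
        """Geometric equality within ``tol`` (mm for origin, relative for rest)."""
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.direction, other.direction, atol=tol)
        )

    # -- SimpleITK bridge -----------------------------------------------------

    def to_sitk_reference(self) -> sitk.Image:
        """An empty SimpleITK image carrying this geometry (for resampling)."""
        img = sitk.Image(self.dims, sitk.sitkFloat64)
        _apply_geometry(img, self)
        return img


def _apply_geometry(img: sitk.Image, geom: GridGeometry) -> None:
    img.SetOrigin(geom.origin)
    img.SetSpacing(geom.spacing)
    # SimpleITK stores the direction matrix row-major with axis cosines in
    # columns -- identical to our convention.
    img.SetDirection(tuple(geom.direction.flatten()))


def geometry_from_sitk(img: sitk.Image) -> GridGeometry:
    return GridGeometry(
        origin=img.GetOrigin(),
        spacing=img.GetSpacing(),
        dims=img.GetSize(),
        direction=np.asarray(img.GetDirection()).reshape(3, 3),
    )


def array_to_sitk(values: np.ndarray, geom: GridGeometry, vector: bool = False) -> sitk.Image:
    """Wrap an ``(nx, ny, nz[, c])`` array as a SimpleITK image with geometry.

    SimpleITK arrays are indexed (z, y, x); transpose on the way in/out.
    """
    if vector:
        arr = np.ascontiguousarray(np.transpose(values, (2, 1, 0, 3)))
        img = sitk.GetImageFromArray(arr, isVector=True)
    else:
        arr = np.ascontiguousarray(values.T)
        img = sitk.GetImageFromArray(arr)
    _apply_geometry(img, geom)
    return img


def sitk_to_array(img: sitk.Image) -> np.ndarray:
    """Array of an image as ``(nx, ny, nz[, c])``."""
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim == 4:
        return np.ascontiguousarray(np.transpose(arr, (2, 1, 0, 3)))
    return np.ascontiguousarray(arr.T)
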