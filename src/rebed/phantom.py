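"""Synthetic re-irradiation cases with analytic ground truth.

Generates paired CT-like thorax analogues (soft-tissue background, a
low-intensity lung region, high-intensity vertebra/rib analogues for bony
registration), spherical target doses with exactly flat plateaus and a
sigmoidal (smoothstep) penumbra, OAR masks (cord, chest wall, lung,
bronchial tree analogues), a known rigid + smooth sinusoidal deformation
between the two time points, and an answer sheet of closed-form values.

Construction avoids numerical field inversion entirely: the *moving* course
lives in the canonical frame (anatomy ``f(p)``, masks ``m(p)``) and the
*reference* course is its analytic pull-back through the ground-truth map
``phi(x) = rigid(x + d(x))`` — i.e. reference anatomy is ``f(phi(x))``
evaluated exactly at reference voxel centers. Warping the moving course
through the true map therefore reproduces the reference voxel-for-voxel,
and the recovered registration can be scored against ``phi`` directly.

Because the dose plateau is exactly flat, any mapping that lands inside the
plateau samples exactly the prescription value, so composite-BED oracles in
the overlap core are closed-form even after interpolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dose_io import (DoseGrid, FractionationScheme, ImageVolume, StructureMask,
                      TreatmentCourse, write_rtdose, write_volume)
from .errors import ConfigError
from .geometry import GridGeometry
from .registration import DeformationField, RigidTransform

__all__ = ["PhantomSpec", "PhantomCase", "make_case", "write_case"]

# Regimens in routine use for lung SABR / conventional courses:
# 50 Gy in 4 fractions, 70 Gy in 10, 60 Gy in 30.
DEFAULT_COURSES: tuple[tuple[float, int], ...] = ((50.0, 4), (70.0, 10))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic two-course re-irradiation case.

    Defaults: 64^3 grid at 2.5 mm isotropic voxels (the working resolution
    for deformation and accumulation), a 25 mm spherical target, 5 mm
    penumbra, 4 mm peak deformation amplitude, and the 50 Gy/4 fx + 70 Gy/10
    fx regimen pair.
    """

    dims: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    target_offset_mm: tuple[float, float, float] = (12.0, 0.0, 0.0)
    target_radius_mm: float = 25.0
    penumbra_mm: float = 5.0
    courses: tuple[tuple[float, int], ...] = DEFAULT_COURSES
    prescription_idl: float | None = None  # e.g. 0.8 -> plateau = Rx / 0.8
    deformation_amplitude_mm: float = 4.0
    deformation_wavelength_mm: float = 80.0
    rigid_translation_mm: tuple[float, float, float] = (4.0, -2.0, 3.0)
    rigid_rotation_deg: float = 3.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        extent = min(d * s for d, s in zip(self.dims, self.spacing_mm))
        if self.deformation_amplitude_mm < 0 or self.deformation_amplitude_mm >= extent / 4:
            raise ConfigError(
                f"deformation amplitude {self.deformation_amplitude_mm} mm must be "
                f"in [0, {extent / 4:.1f}) mm for this grid")
        if self.penumbra_mm <= 0:
            raise ConfigError("penumbra width must be > 0 mm")
        if len(self.courses) < 2:
            raise ConfigError("a re-irradiation case needs >= 2 courses")
        if self.prescription_idl is not None and not (0.5 < self.prescription_idl <= 1.0):
            raise ConfigError("prescription_idl must be in (0.5, 1]")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(origin=(0.0, 0.0, 0.0), spacing=self.spacing_mm,
                            dims=self.dims)

    @property
    def grid_center_mm(self) -> np.ndarray:
        return (np.asarray(self.dims) - 1) * np.asarray(self.spacing_mm) / 2.0

    @property
    def target_center_mm(self) -> np.ndarray:
        return self.grid_center_mm + np.asarray(self.target_offset_mm)


@dataclass
class PhantomCase:
    """A generated case: two courses, ground truth, masks and oracles."""

    spec: PhantomSpec
    reference: TreatmentCourse
    moving: TreatmentCourse
    true_rigid: RigidTransform
    true_field: DeformationField
    masks_reference: list[StructureMask]
    masks_moving: list[StructureMask]
    tumor_mask_reference: StructureMask
    answers: dict = field(default_factory=dict)

    def true_map(self, points: np.ndarray) -> np.ndarray:
        """Ground-truth reference->moving mapping phi(x) = rigid(x + d(x))."""
        pts = np.asarray(points, dtype=float)
        return self.true_rigid.apply(pts + _sinusoid(self.spec, pts))


# ---------------------------------------------------------------------------
# Analytic building blocks
# ---------------------------------------------------------------------------


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _soft_ball(points: np.ndarray, center, radii, edge_mm: float = 2.0) -> np.ndarray:
    """Smooth indicator of an ellipsoid: 1 inside, smoothstep edge, 0 outside."""
    d = (points - np.asarray(center)) / np.asarray(radii)
    r = np.linalg.norm(d, axis=-1)
    # convert the normalized radial overshoot back to ~mm for a fixed edge width
    scale = float(np.min(radii))
    return _smoothstep((1.0 - r) * scale / edge_mm + 0.5)


def _soft_rod_z(points: np.ndarray, center_xy, radius_mm: float,
                edge_mm: float = 2.0) -> np.ndarray:
    d = points[..., :2] - np.asarray(center_xy)
    r = np.linalg.norm(d, axis=-1)
    return _smoothstep((radius_mm - r) / edge_mm + 0.5)


def _anatomy(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Canonical CT-like intensity field f(p), HU-equivalent."""
    c = spec.grid_center_mm
    extent = np.asarray(spec.dims) * np.asarray(spec.spacing_mm)
    out = np.full(points.shape[:-1], -1000.0)

    body = _soft_ball(points, c, 0.45 * extent, edge_mm=3.0)
    out = out + (40.0 - out) * body

    lung = _soft_ball(points, c + np.array([15.0, 0.0, 0.0]),
                      (0.24 * extent[0], 0.21 * extent[1], 0.31 * extent[2]))
    out = out + (-700.0 - out) * lung * body

    tumor = _soft_ball(points, spec.target_center_mm,
                       [spec.target_radius_mm * 0.6] * 3)
    out = out + (60.0 - out) * tumor * body

    bone = np.zeros(points.shape[:-1])
    bone = np.maximum(bone, _soft_rod_z(points, c[:2] + np.array([0.0, 0.3 * extent[1]]),
                                        radius_mm=8.0))
    ring_r = 0.33 * min(extent[0], extent[1])
    for k, ang in enumerate(np.linspace(0.0, 2 * np.pi, 8, endpoint=False)):
        sph_c = c + np.array([ring_r * math.cos(ang), ring_r * math.sin(ang),
                              (0.15 * extent[2]) * (1 if k % 2 else -1)])
        bone = np.maximum(bone, _soft_ball(points, sph_c, [6.0] * 3))
    out = out + (700.0 - out) * bone * body
    return out


def _dose_profile(spec: PhantomSpec, points: np.ndarray, prescription: float) -> np.ndarray:
    """Spherical dose: exactly flat plateau, smoothstep penumbra, zero beyond.

    When ``prescription_idl`` is set the plateau is Rx/IDL so the prescription
    isodose surface sits on the 70-90% level of the maximum, as is typical
    for inhomogeneous SABR plans.
    """
    plateau = prescription / (spec.prescription_idl or 1.0)
    r = np.linalg.norm(points - spec.target_center_mm, axis=-1)
    r_in = spec.target_radius_mm - spec.penumbra_mm / 2.0
    r_out = spec.target_radius_mm + spec.penumbra_mm / 2.0
    return plateau * _smoothstep((r_out - r) / (r_out - r_in))


def _sinusoid(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Smooth sinusoidal displacement with peak magnitude = amplitude."""
    a = spec.deformation_amplitude_mm / math.sqrt(3.0)
    w = 2.0 * np.pi / spec.deformation_wavelength_mm
    x, y, z = points[..., 0], points[..., 1], points[..., 2]
    return np.stack([
        a * np.sin(w * y + 0.4) * np.cos(w * z + 0.9),
        a * np.sin(w * z + 1.3) * np.cos(w * x + 0.2),
        a * np.sin(w * x + 2.1) * np.cos(w * y + 1.7),
    ], axis=-1)


def _oar_indicators(spec: PhantomSpec, points: np.ndarray) -> dict[str, np.ndarray]:
    """Hard (exact) OAR occupancy in the canonical frame."""
    c = spec.grid_center_mm
    extent = np.asarray(spec.dims) * np.asarray(spec.spacing_mm)
    xy = points[..., :2]

    cord = np.linalg.norm(xy - (c[:2] + np.array([0.0, 0.3 * extent[1]])), axis=-1) <= 5.0
    # runs close past the target: the central-structure re-RT scenario
    bronchus = np.linalg.norm(xy - (c[:2] + np.array([-2.0, 0.0])), axis=-1) <= 6.0
    rho = np.linalg.norm(xy - c[:2], axis=-1)
    chest_wall = (rho >= 0.36 * extent[0]) & (rho <= 0.44 * extent[0])
    lung_c = c + np.array([15.0, 0.0, 0.0])
    lung_r = np.array([0.24 * extent[0], 0.21 * extent[1], 0.31 * extent[2]])
    lung = np.linalg.norm((points - lung_c) / lung_r, axis=-1) <= 1.0
    return {"spinal_cord": cord, "bronchial_tree": bronchus & lung,
            "chest_wall": chest_wall, "total_lung": lung}


def _scalar_bed(total_dose: float, n: int, alpha_beta: float) -> float:
    # independent plain-Python evaluation of the LQ closed form for the
    # answer sheet; deliberately not the package's vectorized implementation
    return total_dose * (1.0 + (total_dose / n) / alpha_beta)


# ---------------------------------------------------------------------------
# Case generation
# ---------------------------------------------------------------------------


def make_case(spec: PhantomSpec | None = None) -> PhantomCase:
    """Generate a two-course phantom case with ground truth and oracles."""
    spec = spec or PhantomSpec()
    geom = spec.geometry
    rng = np.random.default_rng(spec.seed)
    pts = geom.voxel_centers()

    center = spec.target_center_mm
    rot = _rotation_z(math.radians(spec.rigid_rotation_deg))
    rigid = RigidTransform.from_parameters(rot, spec.rigid_translation_mm, center=center)
    disp = np.zeros(pts.shape) if spec.deformation_amplitude_mm == 0 else _sinusoid(spec, pts)
    phi = rigid.apply(pts + disp)

    # moving course = canonical frame; reference = analytic pull-back
    anat_mov = _anatomy(spec, pts)
    anat_ref = _anatomy(spec, phi)
    if spec.noise_sigma > 0:
        anat_ref = anat_ref + rng.normal(0.0, spec.noise_sigma, anat_ref.shape)
        anat_mov = anat_mov + rng.normal(0.0, spec.noise_sigma, anat_mov.shape)

    (rx1, n1), (rx2, n2) = spec.courses[0], spec.courses[1]
    dose_ref = _dose_profile(spec, pts, rx1)
    dose_mov = _dose_profile(spec, pts, rx2)

    reference = TreatmentCourse(
        dose=DoseGrid(geometry=geom, values=dose_ref, frame_label="reference"),
        fractionation=FractionationScheme(n1, prescription_dose=rx1),
        anatomy=ImageVolume(geometry=geom, values=anat_ref, frame_label="reference"),
        label="course1",
    )
    moving = TreatmentCourse(
        dose=DoseGrid(geometry=geom, values=dose_mov, frame_label="moving"),
        fractionation=FractionationScheme(n2, prescription_dose=rx2),
        anatomy=ImageVolume(geometry=geom, values=anat_mov, frame_label="moving"),
        label="course2",
    )

    indicators_mov = _oar_indicators(spec, pts)
    indicators_ref = _oar_indicators(spec, phi)
    masks_mov = [StructureMask(geometry=geom, occupancy=v, name=k)
                 for k, v in indicators_mov.items()]
    masks_ref = [StructureMask(geometry=geom, occupancy=v, name=k)
                 for k, v in indicators_ref.items()]
    tumor_ref = StructureMask(
        geometry=geom,
        occupancy=np.linalg.norm(phi - center, axis=-1) <= spec.target_radius_mm * 0.6,
        name="tumor")

    answers = _answer_sheet(spec, pts, phi)
    return PhantomCase(
        spec=spec, reference=reference, moving=moving, true_rigid=rigid,
        true_field=DeformationField(geometry=geom, displacements=disp),
        masks_reference=masks_ref, masks_moving=masks_mov,
        tumor_mask_reference=tumor_ref, answers=answers,
    )


def _rotation_z(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _answer_sheet(spec: PhantomSpec, pts: np.ndarray, phi: np.ndarray) -> dict:
    """Closed-form oracle values, recomputed with plain scalar arithmetic."""
    alpha_beta = 3.0
    r_in = spec.target_radius_mm - spec.penumbra_mm / 2.0
    center = spec.target_center_mm

    # worst-case displacement of a core point under the true map + a margin
    # for registration error, so the warped sample provably stays on plateau
    t_norm = float(np.linalg.norm(spec.rigid_translation_mm))
    rot_factor = 2.0 * math.sin(math.radians(spec.rigid_rotation_deg) / 2.0)
    reg_margin = 3.0
    r_core = (r_in - t_norm - spec.deformation_amplitude_mm - reg_margin) / (1.0 + rot_factor)
    if r_core <= min(spec.spacing_mm):
        raise ConfigError("phantom target too small for an overlap core; enlarge "
                          "target_radius_mm or reduce the transform amplitudes")

    core_ref = np.linalg.norm(pts - center, axis=-1) <= r_core
    core_true_warp = core_ref & (np.linalg.norm(phi - center, axis=-1) <= r_in)

    per_course = []
    nominal_sum = 0.0
    bed_sum = 0.0
    for rx, n in spec.courses:
        plateau = rx / (spec.prescription_idl or 1.0)
        bed = _scalar_bed(plateau, n, alpha_beta)
        per_course.append({"prescription_gy": rx, "n_fractions": n,
                           "plateau_gy": plateau, "plateau_bed_gy": bed})
        nominal_sum += plateau
        bed_sum += bed
    return {
        "alpha_beta": alpha_beta,
        "per_course": per_course,
        "core_radius_mm": r_core,
        "core_mask": core_ref,
        "core_mask_true_warp": core_true_warp,
        "composite_bed_core_gy": bed_sum,
        "nominal_sum_core_gy": nominal_sum,
    }


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------


def write_case(case: PhantomCase, outdir: str | Path, dicom_dose: bool = False) -> dict:
    """Write a case to disk in the raster research format (optionally DICOM
    RTDOSE for the dose grids) and return the file manifest."""
    outdir = Path(outdir).resolve()  # manifest paths must survive a cwd change
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"courses": []}
    for course, masks in ((case.reference, case.masks_reference),
                          (case.moving, case.masks_moving)):
        label = course.label
        if dicom_dose:
            dose_path = outdir / f"dose_{label}.dcm"
            write_rtdose(course.dose, dose_path,
                         n_fractions=course.fractionation.n_fractions)
        else:
            dose_path = outdir / f"dose_{label}.mha"
            write_volume(course.dose.values, course.dose.geometry, dose_path)
        anat_path = outdir / f"ct_{label}.mha"
        write_volume(course.anatomy.values, course.anatomy.geometry, anat_path)
        # one subdirectory per course so structure names (file stems) match
        # across time points
        mask_dir = outdir / f"structures_{label}"
        mask_dir.mkdir(exist_ok=True)
        mask_paths = []
        for m in masks:
            p = mask_dir / f"{m.name}.mha"
            write_volume(m.occupancy, m.geometry, p)
            mask_paths.append(str(p))
        manifest["courses"].append({
            "label": label, "dose": str(dose_path), "anatomy": str(anat_path),
            "structures": mask_paths,
            "n_fractions": course.fractionation.n_fractions,
        })
    tumor_path = outdir / "mask_reference_tumor.mha"
    write_volume(case.tumor_mask_reference.occupancy,
                 case.tumor_mask_reference.geometry, tumor_path)
    manifest["tumor_mask"] = str(tumor_path)
    field_path = outdir / "true_field.mha"
    write_volume(case.true_field.displacements, case.true_field.geometry, field_path)
    manifest["true_field"] = str(field_path)
    return manifest
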