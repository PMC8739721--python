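"""End-to-end orchestration: read -> register -> warp -> convert -> sum -> report.

The stage order is fixed and asserted internally: the moving course's
*physical* dose is warped onto the reference grid first and converted to BED
afterwards (converting before warping gives different values under
interpolation and is rejected). Alongside the composite BED the pipeline
writes the simple nominal-dose sum, so the discrepancy between the two —
the reason BED accumulation exists — is always visible in the report.

All outputs are deterministic: reruns on identical inputs produce identical
bytes (reports carry no timestamps).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import dvh as dvh_mod
from .bed import AlphaBetaRatio, bed_map
from .composite import composite_isodose, sum_bed
from .dose_io import (DoseGrid, FractionationScheme, ImageVolume, StructureMask,
                      TreatmentCourse, read_dose, read_structures, read_volume,
                      resample_to_grid, write_volume)
from .errors import ConfigError, RebedError
from .geometry import GridGeometry
from .registration import (DEFAULT_BONE_THRESHOLD_HU, DeformationField,
                           RigidTransform, deformable_register, rigid_register,
                           validate_oar_preservation, warp_dose, warp_mask,
                           warp_volume)

__all__ = ["CourseConfig", "RunConfig", "load_config", "run_pipeline", "PipelineStageError"]


class PipelineStageError(RebedError):
    """A pipeline stage failed; carries the stage name and completed artifacts."""

    def __init__(self, stage: str, cause: Exception, artifacts: dict):
        self.stage = stage
        self.artifacts = dict(artifacts)
        super().__init__(
            f"pipeline stage {stage!r} failed: {cause}. "
            f"Artifacts completed so far: {sorted(self.artifacts)}"
        )


@dataclass
class CourseConfig:
    label: str
    dose: str
    anatomy: str
    n_fractions: int
    structures: list[str] = dc_field(default_factory=list)


@dataclass
class RunConfig:
    """Configuration of a full re-irradiation accumulation run."""

    courses: list[CourseConfig]
    out_dir: str
    reference: str | None = None           # course label; default: first course
    alpha_betas: list[float] = dc_field(default_factory=lambda: [3.0])
    grid_spacing_mm: float | None = 2.5    # accumulation voxel size; None = native
    levels: int = 3
    smoothing_mm: float = 2.0
    iterations_per_level: int = 50
    bone_threshold_hu: float = DEFAULT_BONE_THRESHOLD_HU
    tolerance_pct: float = 2.0
    isodose_levels: list[float] = dc_field(default_factory=lambda: [100.0, 200.0, 300.0])
    tumor_mask: str | None = None
    constraints: str | None = None
    metrics: dict | None = None
    seed: int | None = None                # recorded for phantom-generated runs

    def __post_init__(self) -> None:
        if len(self.courses) < 2:
            raise ConfigError("a re-irradiation run requires >= 2 courses")
        labels = [c.label for c in self.courses]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate course labels: {labels}")
        if not self.alpha_betas:
            raise ConfigError("alpha_beta list must be non-empty")
        ref = self.reference or labels[0]
        if labels.count(ref) != 1:
            raise ConfigError(f"reference course {ref!r} not among courses {labels}")
        self.reference = ref


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; relative paths resolve against it."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    base = path.parent

    def _resolve(p):
        return str((base / p).resolve()) if p and not Path(p).is_absolute() else p

    courses = []
    for c in raw.get("courses", []):
        courses.append(CourseConfig(
            label=str(c["label"]),
            dose=_resolve(c["dose"]),
            anatomy=_resolve(c["anatomy"]),
            n_fractions=int(c["n_fractions"]),
            structures=[_resolve(s) for s in c.get("structures", [])],
        ))
    ab = raw.get("alpha_beta", [3.0])
    if not isinstance(ab, list):
        ab = [ab]
    return RunConfig(
        courses=courses,
        out_dir=_resolve(raw.get("out_dir", "rebed_out")),
        reference=raw.get("reference"),
        alpha_betas=[float(v) for v in ab],
        grid_spacing_mm=raw.get("grid_spacing_mm", 2.5),
        levels=int(raw.get("levels", 3)),
        smoothing_mm=float(raw.get("smoothing_mm", 2.0)),
        iterations_per_level=int(raw.get("iterations_per_level", 50)),
        bone_threshold_hu=float(raw.get("bone_threshold_hu", DEFAULT_BONE_THRESHOLD_HU)),
        tolerance_pct=float(raw.get("tolerance_pct", 2.0)),
        isodose_levels=[float(v) for v in raw.get("isodose_levels", [100.0, 200.0, 300.0])],
        tumor_mask=_resolve(raw.get("tumor_mask")),
        constraints=_resolve(raw.get("constraints")),
        metrics=raw.get("metrics"),
        seed=raw.get("seed"),
    )


def _accumulation_geometry(native: GridGeometry, spacing_mm: float | None) -> GridGeometry:
    """Isotropic accumulation grid covering the native reference extent."""
    if spacing_mm is None or np.allclose(native.spacing, spacing_mm):
        return native
    extent = np.asarray(native.dims) * np.asarray(native.spacing)
    dims = tuple(int(np.ceil(e / spacing_mm)) for e in extent)
    return GridGeometry(origin=native.origin, spacing=(spacing_mm,) * 3,
                        dims=dims, direction=native.direction)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full accumulation workflow and write the report bundle.

    Returns a manifest dict with artifact paths and headline numbers. Any
    stage failure raises :class:`PipelineStageError` naming the stage and
    listing the artifacts already written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage_order: list[str] = []
    log: dict = {
        "settings": {
            "reference": config.reference,
            "alpha_betas": config.alpha_betas,
            "grid_spacing_mm": config.grid_spacing_mm,
            "levels": config.levels,
            "smoothing_mm": config.smoothing_mm,
            "iterations_per_level": config.iterations_per_level,
            "bone_threshold_hu": config.bone_threshold_hu,
            "tolerance_pct": config.tolerance_pct,
            "isodose_levels": config.isodose_levels,
            "seed": config.seed,
            "assumptions": [
                "per-fraction dose derived as course total / n (identical "
                "spatial distribution every fraction)",
                "no repair correction for the time interval between courses",
                "out-of-support voxels receive 0 Gy",
            ],
        },
        "stages": stage_order,
        "out_of_support_voxels": {},
        "jacobian_positive_fraction": {},
    }

    def _stage(name: str):
        stage_order.append(name)

    try:
        # ---- read ---------------------------------------------------------
        _stage("read")
        courses: dict[str, TreatmentCourse] = {}
        structures: dict[str, list[str]] = {}
        for cc in config.courses:
            anat_values, anat_geom = read_volume(cc.anatomy)
            course = TreatmentCourse(
                dose=read_dose(cc.dose, frame_label=cc.label),
                fractionation=FractionationScheme(cc.n_fractions),
                anatomy=ImageVolume(geometry=anat_geom, values=anat_values,
                                    frame_label=cc.label),
                label=cc.label,
            )
            course.dose.frame_label = cc.label
            courses[cc.label] = course
            structures[cc.label] = cc.structures

        ref_course = courses[config.reference]
        accum_geom = _accumulation_geometry(ref_course.anatomy.geometry,
                                            config.grid_spacing_mm)
        ref_dose_accum = resample_to_grid(ref_course.dose, accum_geom)

        ref_masks: list[StructureMask] = []
        for spath in structures[config.reference]:
            ref_masks.extend(read_structures(spath, accum_geom))

        tumor_mask = None
        if config.tumor_mask:
            tumor_mask = read_structures(config.tumor_mask, accum_geom)[0]

        # ---- register + warp (physical dose first) -------------------------
        warped: dict[str, DoseGrid] = {config.reference: ref_dose_accum}
        validations: dict[str, dict] = {}
        for label, course in courses.items():
            if label == config.reference:
                continue
            _stage(f"rigid:{label}")
            ref_anat = ImageVolume(
                geometry=accum_geom,
                values=warp_volume(ref_course.anatomy.values,
                                   ref_course.anatomy.geometry,
                                   _identity_field(accum_geom), None,
                                   default=float(ref_course.anatomy.values.min())),
                frame_label=config.reference,
            ) if not accum_geom.same_as(ref_course.anatomy.geometry) else ref_course.anatomy
            rigid = rigid_register(ref_anat, course.anatomy,
                                   bone_threshold=config.bone_threshold_hu)

            _stage(f"deformable:{label}")
            field = deformable_register(
                ref_anat, course.anatomy, init=rigid, levels=config.levels,
                smoothing_mm=config.smoothing_mm,
                iterations_per_level=config.iterations_per_level)
            log["jacobian_positive_fraction"][label] = field.jacobian_positive_fraction()

            _stage(f"warp:{label}")
            wdose = warp_dose(course.dose, field, init=rigid)
            warped[label] = wdose
            support = warp_volume(np.ones(course.dose.geometry.dims),
                                  course.dose.geometry, field, rigid, mode="nearest")
            log["out_of_support_voxels"][label] = int((support == 0).sum())
            p = out / f"warped_dose_{label}.mha"
            write_volume(wdose.values, wdose.geometry, p)
            artifacts[f"warped_dose_{label}"] = str(p)

            _stage(f"validate_oar:{label}")
            course_masks = []
            for spath in structures[label]:
                course_masks.extend(read_structures(spath, course.dose.geometry))
            propagated = [warp_mask(m, field, rigid) for m in course_masks]
            validations[label] = validate_oar_preservation(
                course.dose, course_masks, wdose, propagated,
                tolerance_pct=config.tolerance_pct)

        vpath = out / "validation_report.json"
        vpath.write_text(json.dumps(validations, indent=2))
        artifacts["validation_report"] = str(vpath)

        # ---- BED conversion (after warping, by construction) ---------------
        assert any(s.startswith("warp:") for s in stage_order) or len(courses) < 2
        assert "convert" not in stage_order, "BED conversion must run exactly once"
        _stage("convert")
        results: dict[str, dict] = {}
        for ab in config.alpha_betas:
            ab_tag = f"ab{ab:g}"
            beds = []
            for label, course in courses.items():
                grid = warped[label]
                bed = bed_map(grid, alpha_beta=AlphaBetaRatio(ab),
                              exclude=tumor_mask,
                              n_fractions=course.fractionation.n_fractions,
                              label=label)
                p = out / f"bed_{label}_{ab_tag}.mha"
                write_volume(np.nan_to_num(bed.values, nan=-1.0), bed.geometry, p)
                artifacts[f"bed_{label}_{ab_tag}"] = str(p)
                beds.append(bed)

            _stage(f"sum:{ab_tag}")
            comp = sum_bed(beds)
            p = out / f"composite_bed_{ab_tag}.mha"
            write_volume(np.nan_to_num(comp.values, nan=-1.0), comp.geometry, p)
            artifacts[f"composite_bed_{ab_tag}"] = str(p)

            _stage(f"isodose:{ab_tag}")
            for level, m in composite_isodose(comp, sorted(config.isodose_levels)).items():
                p = out / f"isodose_{ab_tag}_{level:g}Gy.mha"
                write_volume(m.occupancy, m.geometry, p)
                artifacts[f"isodose_{ab_tag}_{level:g}"] = str(p)

            _stage(f"metrics:{ab_tag}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                panels = dvh_mod.metric_panel(comp, ref_masks, config=config.metrics)
            csv_p = out / f"metrics_{ab_tag}.csv"
            json_p = out / f"metrics_{ab_tag}.json"
            dvh_mod.write_panels(panels, csv_p, json_p)
            artifacts[f"metrics_{ab_tag}_csv"] = str(csv_p)
            artifacts[f"metrics_{ab_tag}_json"] = str(json_p)

            entry: dict = {
                "composite_max_bed_gy": float(np.nanmax(comp.values)),
                "panels": [pnl.to_dict() for pnl in panels],
            }
            if config.constraints:
                _stage(f"constraints:{ab_tag}")
                cons = yaml.safe_load(Path(config.constraints).read_text()) or []
                report = dvh_mod.compare_constraints(panels, cons)
                p = out / f"constraints_{ab_tag}.json"
                p.write_text(json.dumps(report, indent=2))
                artifacts[f"constraints_{ab_tag}"] = str(p)
                entry["constraints_flagged"] = report["n_flagged"]
            results[ab_tag] = entry

        # ---- nominal simple sum for comparison ------------------------------
        _stage("nominal_sum")
        nominal = np.zeros(accum_geom.dims)
        for grid in warped.values():
            nominal = nominal + grid.values
        p = out / "nominal_dose_sum.mha"
        write_volume(nominal, accum_geom, p)
        artifacts["nominal_dose_sum"] = str(p)

        # artifact paths are recorded relative to the output directory so the
        # report bundle is location-independent (and reruns byte-identical)
        artifacts = {k: str(Path(v).name) for k, v in artifacts.items()}
        manifest = {
            "artifacts": artifacts,
            "results": results,
            "nominal_sum_max_gy": float(nominal.max()),
            "validation": {
                label: {"n_flagged": v["n_flagged"], "n_structures": v["n_structures"]}
                for label, v in validations.items()
            },
        }
        log["artifacts"] = artifacts
        lpath = out / "run_log.json"
        lpath.write_text(json.dumps(log, indent=2))
        mpath = out / "report.json"
        mpath.write_text(json.dumps(manifest, indent=2))
        manifest["report_path"] = str(mpath)
        return manifest
    except RebedError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        raise PipelineStageError(stage_order[-1] if stage_order else "init",
                                 exc, artifacts) from exc


def _identity_field(geometry: GridGeometry) -> DeformationField:
    return DeformationField(geometry=geometry,
                            displacements=np.zeros(geometry.dims + (3,)))
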