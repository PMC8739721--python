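import numpy as np
import pytest

from rebed.dose_io import DoseGrid, StructureMask, resample_to_grid
from rebed.errors import RegistrationError
from rebed.geometry import GridGeometry
from rebed.phantom import PhantomSpec, make_case
from rebed.registration import (DeformationField, RigidTransform,
                                deformable_register, rigid_register,
                                validate_oar_preservation, warp_dose, warp_mask)
from tests.conftest import body_region


def _rotation_error_deg(a: RigidTransform, b: RigidTransform) -> float:
    rel = a.rotation @ b.rotation.T
    return float(np.degrees(np.arccos(np.clip((np.trace(rel) - 1) / 2, -1, 1))))


def _zero_field(geom: GridGeometry) -> DeformationField:
    return DeformationField(geometry=geom, displacements=np.zeros(geom.dims + (3,)))


class TestRigid:
    def test_self_registration_is_identity(self, identity_case):
        tx = rigid_register(identity_case.reference.anatomy,
                            identity_case.moving.anatomy)
        assert np.linalg.norm(tx.translation) < 0.1
        assert _rotation_error_deg(tx, RigidTransform.identity()) < 0.1

    def test_known_translation_recovered(self, rigid_only_case):
        tx = rigid_register(rigid_only_case.reference.anatomy,
                            rigid_only_case.moving.anatomy)
        err = np.linalg.norm(tx.translation - np.array([5.0, -3.0, 2.0]))
        assert err < 0.5
        assert tx.rotation_angle_deg < 0.5

    def test_known_rotation_recovered(self, rotation_only_case):
        tx = rigid_register(rotation_only_case.reference.anatomy,
                            rotation_only_case.moving.anatomy)
        assert abs(tx.rotation_angle_deg - 5.0) < 0.5
        # mapping error over the grid, not just parameter-space agreement
        pts = rotation_only_case.reference.anatomy.geometry.voxel_centers()
        pts = pts[::8, ::8, ::8].reshape(-1, 3)
        err = np.linalg.norm(tx.apply(pts) - rotation_only_case.true_rigid.apply(pts),
                             axis=1)
        assert err.mean() < 0.5

    def test_empty_bone_mask_raises(self, identity_case):
        with pytest.raises(RegistrationError, match="threshold"):
            rigid_register(identity_case.reference.anatomy,
                           identity_case.moving.anatomy, bone_threshold=5000.0)


class TestDeformable:
    def test_self_registration_near_zero_field(self, identity_case):
        field = deformable_register(identity_case.reference.anatomy,
                                    identity_case.moving.anatomy,
                                    init=RigidTransform.identity(), levels=3)
        spacing = min(identity_case.reference.anatomy.geometry.spacing)
        assert field.magnitudes.mean() < 0.25 * spacing

    def test_known_sinusoid_recovered_within_one_voxel(self, default_case, recovered):
        """4 mm-amplitude smooth field: mean endpoint error < 2.5 mm in the
        body (outside the body there is no intensity signal to register)."""
        rigid, field = recovered
        pts = default_case.reference.anatomy.geometry.voxel_centers()
        est = rigid.apply(pts + field.displacements)
        true = default_case.true_map(pts)
        mee = np.linalg.norm(est - true, axis=-1)[body_region(default_case)].mean()
        assert mee < 2.5

    def test_more_levels_improve_recovery(self):
        """Multi-resolution pays off when the field must absorb a large
        coherent displacement (~10 mm) that single-level demons cannot reach."""
        case = make_case(PhantomSpec(deformation_amplitude_mm=0.0,
                                     rigid_translation_mm=(8.0, -5.0, 4.0),
                                     rigid_rotation_deg=0.0))
        pts = case.reference.anatomy.geometry.voxel_centers()
        true = case.true_map(pts)
        errors = []
        for levels in (1, 3):
            field = deformable_register(case.reference.anatomy,
                                        case.moving.anatomy,
                                        init=RigidTransform.identity(),
                                        levels=levels, iterations_per_level=30)
            est = pts + field.displacements
            errors.append(np.linalg.norm(est - true, axis=-1)[body_region(case)].mean())
        assert errors[1] < errors[0]
        assert errors[1] < 2.5

    def test_rigid_offset_already_removed_leaves_small_field(self, rigid_only_case):
        field = deformable_register(rigid_only_case.reference.anatomy,
                                    rigid_only_case.moving.anatomy,
                                    init=rigid_only_case.true_rigid, levels=2)
        assert field.magnitudes[body_region(rigid_only_case)].mean() < 0.5

    def test_field_is_approximately_diffeomorphic(self, recovered):
        _, field = recovered
        assert field.jacobian_positive_fraction() >= 0.99


class TestWarp:
    def test_identity_warp_equals_resample(self, default_case):
        dose = default_case.moving.dose
        geom = dose.geometry
        warped = warp_dose(dose, _zero_field(geom), RigidTransform.identity())
        resampled = resample_to_grid(dose, geom)
        np.testing.assert_allclose(warped.values, resampled.values, atol=1e-12)

    def test_constant_field_invariance(self, default_case):
        geom = default_case.moving.dose.geometry
        uniform = DoseGrid(geometry=geom, values=np.full(geom.dims, 50.0))
        warped = warp_dose(uniform, default_case.true_field, default_case.true_rigid)
        # interior voxels (whose warped sample stays in support) keep 50 Gy
        interior = warped.values[8:-8, 8:-8, 8:-8]
        np.testing.assert_allclose(interior, 50.0, atol=1e-9)

    def test_translation_field_shifts_ramp_exactly(self):
        geom = GridGeometry(origin=(0, 0, 0), spacing=(2.5,) * 3, dims=(16, 16, 16))
        x = geom.voxel_centers()[..., 0]
        ramp = DoseGrid(geometry=geom, values=0.5 * x + 3.0)
        disp = np.zeros(geom.dims + (3,))
        disp[..., 0] = 5.0  # sample 5 mm further along x
        field = DeformationField(geometry=geom, displacements=disp)
        warped = warp_dose(ramp, field)
        expected = 0.5 * (x + 5.0) + 3.0
        interior = np.s_[:-3, :, :]  # last voxels sample outside support
        np.testing.assert_allclose(warped.values[interior], expected[interior], atol=1e-9)

    def test_warp_is_intensity_bounded(self, default_case, recovered):
        rigid, field = recovered
        warped = warp_dose(default_case.moving.dose, field, rigid)
        assert warped.values.min() >= 0.0
        assert warped.values.max() <= default_case.moving.dose.values.max() + 1e-9

    def test_geometry_mismatch_rejected(self, default_case):
        other = GridGeometry(origin=(1, 1, 1), spacing=(2.5,) * 3,
                             dims=default_case.moving.dose.geometry.dims)
        with pytest.raises(ValueError, match="field geometry"):
            warp_dose(default_case.moving.dose,
                      _zero_field(default_case.moving.dose.geometry),
                      output_geometry=other)


class TestOARPreservation:
    def test_identity_warp_zero_differences(self, default_case):
        dose = default_case.moving.dose
        masks = default_case.masks_moving
        report = validate_oar_preservation(dose, masks, dose, masks)
        assert report["n_flagged"] == 0
        for entry in report["entries"]:
            for m in entry["metrics"].values():
                assert m["diff_pct"] == 0.0

    def test_phantom_warp_preserves_metrics_at_2pct(self, default_case, recovered):
        """The deformation QA: dose metrics unchanged after warping."""
        rigid, field = recovered
        warped_dose = warp_dose(default_case.moving.dose, field, rigid)
        propagated = [warp_mask(m, field, rigid) for m in default_case.masks_moving]
        report = validate_oar_preservation(
            default_case.moving.dose, default_case.masks_moving,
            warped_dose, propagated, tolerance_pct=2.0)
        assert report["n_structures"] == len(default_case.masks_moving)
        assert report["n_flagged"] == 0

    def test_mismatched_masks_flagged(self, default_case):
        dose = default_case.moving.dose
        masks = default_case.masks_moving
        shifted = [StructureMask(geometry=m.geometry,
                                 occupancy=np.roll(m.occupancy, 6, axis=0),
                                 name=m.name) for m in masks]
        report = validate_oar_preservation(dose, masks, dose, shifted)
        assert report["n_flagged"] > 0

    def test_missing_structure_is_unvalidatable(self, default_case):
        dose = default_case.moving.dose
        masks = default_case.masks_moving
        report = validate_oar_preservation(dose, masks, dose, masks[:-1])
        assert masks[-1].name in report["unvalidatable"]
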