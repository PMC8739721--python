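import numpy as np
import pydicom
import pytest

from rebed.dose_io import (DoseGrid, StructureMask, read_rtdose, read_structures,
                           read_volume, resample_to_grid, write_rtdose,
                           write_rtstruct, write_volume)
from rebed.errors import DoseFormatError, RasterizationError
from rebed.geometry import GridGeometry


def _ramp_dose(geom: GridGeometry, slope=0.5, offset=2.0) -> DoseGrid:
    x = geom.voxel_centers()[..., 0]
    return DoseGrid(geometry=geom, values=slope * x + offset)


def _circle(center_xy, z, radius, n=72):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center_xy[0] + radius * np.cos(ang),
                            center_xy[1] + radius * np.sin(ang),
                            np.full(n, z)])


# ---------------------------------------------------------------------------
# RTDOSE
# ---------------------------------------------------------------------------


class TestRTDose:
    def test_scaling_identity(self, tmp_path):
        """Stored integers x DoseGridScaling reproduce Gy values."""
        path = tmp_path / "d.dcm"
        geom = GridGeometry(origin=(0, 0, 0), spacing=(2.5, 2.5, 2.5), dims=(4, 4, 4))
        values = np.zeros(geom.dims)
        values[1, 2, 3] = 50.0
        write_rtdose(DoseGrid(geometry=geom, values=values), path)
        ds = pydicom.dcmread(path)
        raw = ds.pixel_array.transpose(2, 1, 0)
        assert raw[1, 2, 3] * ds.DoseGridScaling == pytest.approx(50.0, abs=ds.DoseGridScaling)

    def test_round_trip_within_scaling_quantum(self, tmp_path):
        path = tmp_path / "d.dcm"
        geom = GridGeometry(origin=(-10, 5, 0), spacing=(2.5, 2.0, 3.0), dims=(6, 5, 4))
        rng = np.random.default_rng(1)
        dose = DoseGrid(geometry=geom, values=rng.uniform(0, 80, geom.dims))
        write_rtdose(dose, path)
        back = read_rtdose(path)
        quantum = dose.values.max() / (2**32 - 1)
        assert back.geometry.same_as(geom)
        np.testing.assert_allclose(back.values, dose.values, atol=quantum)

    def test_direction_cosines_survive(self, tmp_path):
        """Non-identity orientation is reconstructed from the header exactly."""
        theta = np.radians(30)
        direction = np.array([[np.cos(theta), -np.sin(theta), 0],
                              [np.sin(theta), np.cos(theta), 0],
                              [0, 0, 1]])
        geom = GridGeometry(origin=(0, 0, 0), spacing=(2, 2, 2), dims=(4, 4, 3),
                            direction=direction)
        path = tmp_path / "d.dcm"
        write_rtdose(DoseGrid(geometry=geom, values=np.ones(geom.dims)), path)
        back = read_rtdose(path)
        # oracle: the orientation tag parsed independently of the reader
        iop = np.asarray(pydicom.dcmread(path).ImageOrientationPatient, dtype=float)
        np.testing.assert_allclose(back.geometry.direction[:, 0], iop[:3], atol=1e-9)
        np.testing.assert_allclose(back.geometry.direction[:, 1], iop[3:], atol=1e-9)
        np.testing.assert_allclose(back.geometry.direction, direction, atol=1e-9)

    def test_missing_geometry_tag_is_format_error(self, tmp_path):
        path = tmp_path / "d.dcm"
        geom = GridGeometry(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(3, 3, 3))
        write_rtdose(DoseGrid(geometry=geom, values=np.ones(geom.dims)), path)
        ds = pydicom.dcmread(path)
        del ds.PixelSpacing
        ds.save_as(path)
        with pytest.raises(DoseFormatError, match="PixelSpacing"):
            read_rtdose(path)

    def test_unsupported_summation_type_named(self, tmp_path):
        path = tmp_path / "d.dcm"
        geom = GridGeometry(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(3, 3, 3))
        write_rtdose(DoseGrid(geometry=geom, values=np.ones(geom.dims)), path)
        ds = pydicom.dcmread(path)
        ds.DoseSummationType = "BEAM"
        ds.save_as(path)
        with pytest.raises(DoseFormatError, match="DoseSummationType"):
            read_rtdose(path)

    def test_per_fraction_scaling(self, tmp_path):
        path = tmp_path / "d.dcm"
        geom = GridGeometry(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(3, 3, 3))
        write_rtdose(DoseGrid(geometry=geom, values=np.full(geom.dims, 12.5)), path,
                     n_fractions=4)
        ds = pydicom.dcmread(path)
        ds.DoseSummationType = "FRACTION"
        ds.save_as(path)
        total = read_rtdose(path, scale_to_total=True)
        np.testing.assert_allclose(total.values, 50.0, atol=1e-5)
        per_fx = read_rtdose(path, scale_to_total=False)
        np.testing.assert_allclose(per_fx.values, 12.5, atol=1e-5)
        del ds.NumberOfFractionsPlanned
        ds.save_as(path)
        with pytest.raises(DoseFormatError, match="FRACTION"):
            read_rtdose(path, scale_to_total=True)


def test_raster_volume_round_trip(tmp_path):
    geom = GridGeometry(origin=(3, -2, 7), spacing=(1.5, 2.5, 2.0), dims=(5, 6, 7))
    values = np.random.default_rng(2).normal(size=geom.dims)
    path = tmp_path / "v.mha"
    write_volume(values, geom, path)
    back, back_geom = read_volume(path)
    assert back_geom.same_as(geom)
    np.testing.assert_allclose(back, values, atol=1e-12)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


class TestStructures:
    def test_cylinder_volume_within_5pct(self, tmp_path):
        """20 mm radius x 40 mm cylinder rasterizes to ~50.27 cc at 2.5 mm."""
        geom = GridGeometry(origin=(0, 0, 0), spacing=(2.5, 2.5, 2.5), dims=(40, 40, 40))
        center = (50.0, 50.0)
        zs = [z * 2.5 for z in range(40) if 30.0 <= z * 2.5 < 70.0]
        contours = [_circle(center, z, 20.0) for z in zs]
        path = tmp_path / "s.dcm"
        write_rtstruct({"cyl": contours}, path)
        (mask,) = read_structures(path, geom)
        analytic = np.pi * 2.0**2 * 4.0  # cc
        assert mask.volume_cc == pytest.approx(analytic, rel=0.05)

    def test_volume_error_decreases_with_spacing(self, tmp_path):
        """Rasterized volume converges to the analytic cylinder volume."""
        analytic = np.pi * 2.0**2 * 4.0
        errors = []
        for spacing in (2.5, 1.25):
            n = int(100 / spacing)
            geom = GridGeometry(origin=(0, 0, 0), spacing=(spacing,) * 3, dims=(n,) * 3)
            zs = [k * spacing for k in range(n) if 30.0 <= k * spacing < 70.0]
            contours = [_circle((50.0, 50.0), z, 20.0) for z in zs]
            path = tmp_path / f"s{spacing}.dcm"
            write_rtstruct({"cyl": contours}, path)
            (mask,) = read_structures(path, geom)
            errors.append(abs(mask.volume_cc - analytic))
        assert errors[1] < errors[0]

    def test_contour_outside_extent_gives_empty_mask(self, tmp_path):
        geom = GridGeometry(origin=(0, 0, 0), spacing=(2.5,) * 3, dims=(10, 10, 10))
        path = tmp_path / "s.dcm"
        write_rtstruct({"far": [_circle((500.0, 500.0), 500.0, 5.0)]}, path)
        with pytest.warns(UserWarning, match="empty"):
            (mask,) = read_structures(path, geom)
        assert not mask.occupancy.any()

    def test_overlapping_structures_are_independent(self, tmp_path):
        geom = GridGeometry(origin=(0, 0, 0), spacing=(2.5,) * 3, dims=(20, 20, 8))
        zs = [k * 2.5 for k in range(8)]
        a = [_circle((20.0, 25.0), z, 10.0) for z in zs]
        b = [_circle((30.0, 25.0), z, 10.0) for z in zs]
        path = tmp_path / "s.dcm"
        write_rtstruct({"A": a, "B": b}, path)
        mask_a, mask_b = read_structures(path, geom)
        overlap = mask_a.occupancy & mask_b.occupancy
        assert overlap.any()
        assert mask_a.occupancy.sum() == pytest.approx(mask_b.occupancy.sum(), rel=0.05)

    def test_non_coplanar_contour_rejected(self, tmp_path):
        geom = GridGeometry(origin=(0, 0, 0), spacing=(2.5,) * 3, dims=(10, 10, 10))
        tilted = _circle((12.0, 12.0), 10.0, 8.0)
        tilted[:, 2] += np.linspace(0, 6.0, len(tilted))  # > half-spacing spread
        path = tmp_path / "s.dcm"
        write_rtstruct({"tilted": [tilted]}, path)
        with pytest.raises(RasterizationError, match="coplanar"):
            read_structures(path, geom)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


class TestResample:
    def test_identity_resample(self):
        geom = GridGeometry(origin=(1, 2, 3), spacing=(2.5,) * 3, dims=(8, 8, 8))
        dose = _ramp_dose(geom)
        nearest = resample_to_grid(dose, geom, mode="nearest")
        assert np.array_equal(nearest.values, dose.values)
        linear = resample_to_grid(dose, geom, mode="trilinear")
        np.testing.assert_allclose(linear.values, dose.values, atol=1e-9)

    def test_constant_field_invariance(self):
        src = GridGeometry(origin=(0, 0, 0), spacing=(2.5,) * 3, dims=(16, 16, 16))
        dose = DoseGrid(geometry=src, values=np.full(src.dims, 10.0))
        half = GridGeometry(origin=(5, 5, 5), spacing=(1.25,) * 3, dims=(24, 24, 24))
        out = resample_to_grid(dose, half)
        np.testing.assert_allclose(out.values, 10.0, atol=1e-12)

    def test_trilinear_reproduces_linear_ramp(self):
        src = GridGeometry(origin=(0, 0, 0), spacing=(2.5,) * 3, dims=(20, 20, 20))
        dose = _ramp_dose(src, slope=0.8, offset=1.0)
        target = GridGeometry(origin=(4.3, 6.1, 5.7), spacing=(1.7,) * 3, dims=(12, 12, 12))
        out = resample_to_grid(dose, target)
        expected = 0.8 * target.voxel_centers()[..., 0] + 1.0
        np.testing.assert_allclose(out.values, expected, atol=1e-9)

    def test_outside_support_is_zero_and_bounded(self):
        src = GridGeometry(origin=(0, 0, 0), spacing=(2.5,) * 3, dims=(8, 8, 8))
        rng = np.random.default_rng(3)
        dose = DoseGrid(geometry=src, values=rng.uniform(0, 60, src.dims))
        big = GridGeometry(origin=(-20, -20, -20), spacing=(2.5,) * 3, dims=(24, 24, 24))
        out = resample_to_grid(dose, big)
        corner = out.values[:4, :4, :4]
        np.testing.assert_array_equal(corner, 0.0)
        # convex-combination property of trilinear interpolation
        assert out.values.max() <= dose.values.max() + 1e-9
        assert out.values.min() >= 0.0

    def test_degenerate_target_rejected(self):
        src = GridGeometry(origin=(0, 0, 0), spacing=(2.5,) * 3, dims=(4, 4, 4))
        with pytest.raises(ValueError):
            GridGeometry(origin=(0, 0, 0), spacing=(2.5,) * 3, dims=(0, 4, 4))
        dose = DoseGrid(geometry=src, values=np.zeros(src.dims))
        with pytest.raises(ValueError, match="mode"):
            resample_to_grid(dose, src, mode="cubic")
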