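"""Volume container, NIfTI round-trips, resampling and smoothing."""

import numpy as np
import nibabel as nib
import pytest

from centipet.errors import (
    ContractViolation,
    DimensionalityError,
    DomainError,
    FormatError,
)
from centipet.image_core import (
    DeformationField,
    RigidTransform,
    Volume,
    fwhm_to_sigma,
    gaussian_smooth,
    read_volume,
    resample,
    write_volume,
)


def _ramp_volume(shape=(16, 16, 16), voxel=2.0):
    data = np.indices(shape, dtype=float)[0] * voxel  # x-world-coordinate ramp
    affine = np.diag([voxel, voxel, voxel, 1.0])
    return Volume(data, affine)


class TestIO:
    def test_round_trip_identity(self, tmp_path):
        v = Volume(np.full((8, 8, 8), 3.5), np.diag([2.0, 2.0, 2.0, 1.0]))
        path = tmp_path / "const.nii.gz"
        write_volume(v, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.data, v.data)
        np.testing.assert_allclose(back.affine, v.affine, atol=1e-6)

    def test_round_trip_float32_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        v = Volume(rng.normal(size=(6, 7, 8)), np.eye(4))
        path = tmp_path / "noise.nii"
        write_volume(v, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.data, v.data, atol=1e-6, rtol=1e-6)

    def test_qform_fallback_when_sform_unset(self, tmp_path):
        """With s-form code 0 the affine must come from the quaternion q-form."""
        data = np.zeros((5, 5, 5), dtype=np.float32)
        img = nib.Nifti1Image(data, np.eye(4))
        qaff = np.diag([2.0, 3.0, 4.0, 1.0])
        qaff[:3, 3] = (-4.0, -6.0, -8.0)
        img.set_qform(qaff, code=1)
        img.set_sform(None, code=0)
        path = tmp_path / "qform.nii"
        nib.save(img, str(path))
        expected = nib.load(str(path)).get_qform()
        back = read_volume(path)
        np.testing.assert_allclose(back.affine, expected, atol=1e-6)

    def test_truncated_file_raises_format_error(self, tmp_path):
        v = Volume(np.zeros((8, 8, 8)), np.eye(4))
        path = tmp_path / "full.nii"
        write_volume(v, path)
        truncated = tmp_path / "broken.nii"
        truncated.write_bytes(path.read_bytes()[:100])
        with pytest.raises(FormatError):
            read_volume(truncated)

    def test_4d_input_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((4, 4, 4, 3), dtype=np.float32),
                              np.eye(4))
        path = tmp_path / "fourd.nii"
        nib.save(img, str(path))
        with pytest.raises(DimensionalityError):
            read_volume(path)


class TestResample:
    def test_identity_is_exact(self):
        v = _ramp_volume()
        out = resample(v, None, v)
        np.testing.assert_array_equal(out.data, v.data)

    def test_known_translation_shifts_one_voxel(self):
        """+2 mm x-translation on a 2 mm grid = one-voxel shift of a ramp."""
        v = _ramp_volume(voxel=2.0)
        t = RigidTransform(np.zeros(3), np.array([2.0, 0.0, 0.0]), np.zeros(3))
        out = resample(v, t, v)
        # interior: out[i] = source at x+2mm = ramp value (i+1)*2
        np.testing.assert_allclose(
            out.data[:-1, 2:-2, 2:-2], v.data[1:, 2:-2, 2:-2], atol=1e-9
        )

    def test_trilinear_range_bounded_by_source(self):
        rng = np.random.default_rng(1)
        v = Volume(rng.uniform(2.0, 5.0, (12, 12, 12)),
                   np.diag([2.0, 2.0, 2.0, 1.0]))
        t = RigidTransform(np.deg2rad([3.0, -2.0, 1.0]),
                           np.array([0.5, -0.3, 0.2]),
                           np.array([12.0, 12.0, 12.0]))
        out = resample(v, t, v)
        inside = out.data > 0  # zero-fill marks out-of-field
        assert out.data[inside].max() <= v.data.max() + 1e-12
        assert out.data[inside].min() >= 0.0

    def test_mask_nearest_preserves_labels(self):
        rng = np.random.default_rng(2)
        mask = Volume((rng.random((10, 10, 10)) > 0.5).astype(float),
                      np.eye(4), modality="MASK")
        t = RigidTransform(np.deg2rad([2.0, 0, 0]), np.array([0.4, 0.1, -0.2]),
                           np.zeros(3))
        out = resample(mask, t, mask, interp="nearest")
        assert set(np.unique(out.data)) <= {0.0, 1.0}

    def test_mask_trilinear_rejected(self):
        mask = Volume(np.ones((4, 4, 4)), np.eye(4), modality="MASK")
        with pytest.raises(ContractViolation):
            resample(mask, None, mask, interp="trilinear")

    def test_forward_inverse_round_trip_small_error(self):
        """resample(resample(v,T),T^-1) ~ v on the interior for smooth data."""
        shape = (20, 20, 20)
        x, y, z = np.indices(shape, dtype=float)
        data = np.sin(x / 4.0) + np.cos(y / 5.0) + 0.5 * np.sin(z / 3.0)
        v = Volume(data + 2.0, np.diag([2.0, 2.0, 2.0, 1.0]))
        t = RigidTransform(np.deg2rad([4.0, -3.0, 2.0]),
                           np.array([1.5, -1.0, 0.8]),
                           np.array([20.0, 20.0, 20.0]))
        back = resample(resample(v, t, v), t.inverse(), v)
        interior = (slice(4, -4),) * 3
        mae = np.abs(back.data[interior] - v.data[interior]).mean()
        assert mae < 0.02 * np.ptp(v.data)


class TestSmoothing:
    def test_sigma_conversion_matches_definition(self):
        assert fwhm_to_sigma(8.0) / 2.0 == pytest.approx(1.69864, abs=1e-5)

    def test_constant_preserved(self):
        v = Volume(np.ones((10, 10, 10)), np.diag([2.0, 2.0, 2.0, 1.0]))
        out = gaussian_smooth(v, 8.0)
        np.testing.assert_allclose(out.data, 1.0, atol=1e-10)

    def test_max_does_not_increase(self):
        rng = np.random.default_rng(3)
        v = Volume(rng.random((12, 12, 12)), np.eye(4))
        assert gaussian_smooth(v, 5.0).data.max() <= v.data.max() + 1e-12

    def test_impulse_center_matches_discrete_kernel(self):
        """Central value of a smoothed impulse = discrete kernel peak weight."""
        shape = (33, 33, 33)
        data = np.zeros(shape)
        data[16, 16, 16] = 1.0
        voxel = 2.0
        v = Volume(data, np.diag([voxel, voxel, voxel, 1.0]))
        fwhm = 8.0
        out = gaussian_smooth(v, fwhm)
        # oracle: explicit normalized discrete Gaussian kernel summation
        # over the same 4-sigma support the implementation uses
        sigma = fwhm_to_sigma(fwhm) / voxel
        radius = int(4.0 * sigma + 0.5)
        r = np.arange(-radius, radius + 1)
        w1d = np.exp(-0.5 * (r / sigma) ** 2)
        w1d /= w1d.sum()
        expected = w1d[radius] ** 3
        assert out.data[16, 16, 16] == pytest.approx(expected, rel=1e-6)

    def test_commutes_with_scaling(self):
        rng = np.random.default_rng(4)
        v = Volume(rng.random((10, 10, 10)), np.eye(4))
        a = gaussian_smooth(v.with_data(3.7 * v.data), 6.0).data
        b = 3.7 * gaussian_smooth(v, 6.0).data
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_nonpositive_fwhm_rejected(self):
        v = Volume(np.ones((4, 4, 4)), np.eye(4))
        with pytest.raises(DomainError):
            gaussian_smooth(v, 0.0)


class TestTransforms:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_inverse_composition_is_identity(self, seed):
        rng = np.random.default_rng(seed)
        t = RigidTransform(rng.uniform(-0.3, 0.3, 3), rng.uniform(-10, 10, 3),
                           rng.uniform(-5, 5, 3))
        comp = t.compose(t.inverse())
        np.testing.assert_allclose(comp, np.eye(4), atol=1e-9)
        # parameter-level identity of inverse-of-inverse
        t2 = t.inverse().inverse()
        np.testing.assert_allclose(t2.rotation, t.rotation, atol=1e-9)
        np.testing.assert_allclose(t2.translation, t.translation, atol=1e-9)

    def test_zero_deformation_is_identity(self):
        field = DeformationField.zero((6, 6, 6), np.diag([3.0, 3.0, 3.0, 1.0]))
        pts = np.random.default_rng(0).uniform(0, 15, (3, 50))
        np.testing.assert_array_equal(field.apply(pts), pts)
        np.testing.assert_allclose(field.jacobian_determinant(), 1.0,
                                   atol=1e-12)

    def test_nonfinite_data_rejected(self):
        with pytest.raises(ContractViolation):
            Volume(np.full((3, 3, 3), np.nan), np.eye(4))
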