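"""Volume I/O, coordinate geometry, resampling, cropping, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortamark import (
    GridSpec,
    LandmarkSet,
    Volume3D,
    crop_centered,
    random_similarity_transform,
    read_landmarks,
    read_volume,
    resample_isotropic,
    voxel_to_world,
    world_to_voxel,
    write_landmarks,
    write_volume,
)
from aortamark.volumetric_io import _rotation_matrix


class TestNiftiRoundTrip:
    def test_values_and_geometry_preserved(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = Volume3D(
            rng.normal(100, 300, size=(20, 24, 18)).astype(np.float32),
            spacing=[0.7, 0.7, 0.9],
            origin=[-12.0, 5.5, 30.0],
        )
        path = tmp_path / "vol.nii.gz"
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.values, vol.values)
        assert np.allclose(back.spacing, vol.spacing, atol=1e-6)
        assert np.allclose(back.origin, vol.origin, atol=1e-6)
        assert np.allclose(back.direction, vol.direction, atol=1e-6)
        assert back.unit == "HU"

    def test_isotropic_spacing_passthrough(self, tmp_path):
        vol = Volume3D(np.zeros((8, 8, 8), dtype=np.float32), spacing=[0.7, 0.7, 0.7])
        write_volume(vol, tmp_path / "p.nii.gz")
        assert np.allclose(read_volume(tmp_path / "p.nii.gz").spacing, 0.7)

    @pytest.mark.parametrize(
        "unit,values",
        [
            ("probability", np.linspace(0, 1, 27).reshape(3, 3, 3).astype(np.float32)),
            ("label", np.arange(27).reshape(3, 3, 3).astype(np.int16) % 6),
        ],
    )
    def test_unit_round_trip(self, tmp_path, unit, values):
        vol = Volume3D(values, unit=unit)
        write_volume(vol, tmp_path / "u.nii.gz")
        back = read_volume(tmp_path / "u.nii.gz")
        assert back.unit == unit
        np.testing.assert_allclose(back.values, values, atol=1e-7)

    def test_non_3d_image_rejected(self, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((4, 4)), np.eye(4)), str(tmp_path / "flat.nii"))
        with pytest.raises(ValueError, match="3D"):
            read_volume(tmp_path / "flat.nii")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(tmp_path / "nope.nii.gz")

    def test_sheared_affine_rejected(self, tmp_path):
        import nibabel as nib

        aff = np.eye(4)
        aff[0, 1] = 0.3  # shear
        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4)), aff), str(tmp_path / "shear.nii"))
        with pytest.raises(ValueError, match="orthonormal"):
            read_volume(tmp_path / "shear.nii")


class TestCoordinates:
    def test_identity_geometry(self):
        grid = GridSpec((10, 10, 10))
        np.testing.assert_allclose(voxel_to_world(grid, [5, 6, 7]), [5, 6, 7])

    def test_offset_scaled_grid(self):
        # origin (10,10,10), spacing 2: index (1,1,1) -> 10 + 2*1 = 12 per axis
        grid = GridSpec((8, 8, 8), spacing=[2, 2, 2], origin=[10, 10, 10])
        np.testing.assert_allclose(voxel_to_world(grid, [1, 1, 1]), [12, 12, 12])
        np.testing.assert_allclose(world_to_voxel(grid, [12, 12, 12]), [1, 1, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_inverse(self, seed):
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        grid = GridSpec(
            (16, 16, 16),
            spacing=rng.uniform(0.3, 2.5, 3),
            origin=rng.uniform(-50, 50, 3),
            direction=q,
        )
        idx = rng.uniform(-10, 30, size=(4, 3))
        np.testing.assert_allclose(
            world_to_voxel(grid, voxel_to_world(grid, idx)), idx, atol=1e-9
        )

    def test_landmark_json_round_trip(self, tmp_path, landmarks):
        write_landmarks(landmarks, tmp_path / "lm.json")
        back = read_landmarks(tmp_path / "lm.json")
        np.testing.assert_allclose(back.as_array(), landmarks.as_array())


class TestResampleIsotropic:
    def test_output_shape_from_physical_extent(self):
        vol = Volume3D(np.zeros((100, 100, 100), dtype=np.float32), spacing=[0.5, 0.5, 0.8])
        out = resample_isotropic(vol, 1.0)
        assert out.values.shape == (50, 50, 80)
        np.testing.assert_allclose(out.spacing, 1.0)

    def test_constant_volume_stays_constant(self):
        vol = Volume3D(np.full((20, 20, 20), 321.0), spacing=[0.7, 0.7, 0.7])
        out = resample_isotropic(vol, 1.0)
        np.testing.assert_allclose(out.values, 321.0, atol=1e-9)

    def test_identity_at_knots_when_already_isotropic(self):
        rng = np.random.default_rng(3)
        vol = Volume3D(rng.normal(size=(16, 16, 16)))
        out = resample_isotropic(vol, 1.0)
        np.testing.assert_allclose(out.values, vol.values, atol=1e-6)

    def test_hu_scale_preserved(self):
        # a linear HU ramp is reproduced exactly by a cubic spline
        x = np.arange(24, dtype=float)
        vol = Volume3D(np.broadcast_to(x[:, None, None] * 10, (24, 24, 24)).copy(),
                       spacing=[0.5, 0.5, 0.5])
        out = resample_isotropic(vol, 1.0)
        assert out.values.shape == (12, 12, 12)
        # output voxel j sits at input index 2j, so the ramp value is 10 * 2j
        np.testing.assert_allclose(out.values[1:10, 5, 5], 20.0 * np.arange(1, 10), atol=1e-6)

    def test_bad_target_spacing(self):
        vol = Volume3D(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            resample_isotropic(vol, 0.0)


class TestCropCentered:
    def test_interior_crop_is_pure_subarray(self):
        rng = np.random.default_rng(1)
        vol = Volume3D(rng.normal(size=(64, 64, 64)))
        out = crop_centered(vol, [32.0, 32.0, 32.0], size=16)
        np.testing.assert_array_equal(out.values, vol.values[24:40, 24:40, 24:40])
        assert not np.any(out.values == -1024.0)

    def test_corner_crop_pads_seven_eighths(self):
        vol = Volume3D(np.ones((40, 40, 40)))
        out = crop_centered(vol, [0.0, 0.0, 0.0], size=16)
        n_fill = int(np.sum(out.values == -1024.0))
        # the crop spans indices [-8, 8); only the [0,8)^3 octant has data
        assert n_fill == 16**3 - 8**3

    def test_world_coordinates_preserved(self, landmarks):
        rng = np.random.default_rng(2)
        vol = Volume3D(rng.normal(size=(128, 128, 128)))
        point = landmarks["LCC"]
        before = vol.values[tuple(np.round(world_to_voxel(vol.grid, point)).astype(int))]
        out = crop_centered(vol, [64.0, 64.0, 64.0], size=64)
        after = out.values[tuple(np.round(world_to_voxel(out.grid, point)).astype(int))]
        assert before == after

    def test_anisotropic_rejected(self):
        vol = Volume3D(np.zeros((8, 8, 8)), spacing=[1, 1, 2])
        with pytest.raises(ValueError, match="isotropic"):
            crop_centered(vol, [4, 4, 4], size=4)


class TestRandomSimilarityTransform:
    def test_limit_zero_is_identity(self, landmarks):
        rng = np.random.default_rng(5)
        vol = Volume3D(rng.normal(size=(24, 24, 24)))
        out_vol, out_lm = random_similarity_transform(vol, landmarks, seed=9, limit=0.0)
        np.testing.assert_array_equal(out_lm.as_array(), landmarks.as_array())
        np.testing.assert_allclose(out_vol.values, vol.values, atol=1e-6)

    def test_seeded_determinism(self, landmarks):
        vol = Volume3D(np.random.default_rng(0).normal(size=(16, 16, 16)))
        a_vol, a_lm = random_similarity_transform(vol, landmarks, seed=123)
        b_vol, b_lm = random_similarity_transform(vol, landmarks, seed=123)
        np.testing.assert_array_equal(a_vol.values, b_vol.values)
        np.testing.assert_array_equal(a_lm.as_array(), b_lm.as_array())

    def test_landmarks_match_analytic_matrix(self, landmarks):
        vol = Volume3D(np.zeros((64, 64, 64)))
        seed, limit = 77, 3.0
        _, out_lm = random_similarity_transform(vol, landmarks, seed=seed, limit=limit)
        # rebuild the similarity transform from the same seeded draws
        u = np.random.default_rng(seed).uniform(-limit, limit, size=4)
        s = 1 + u[0] / 100
        rot = _rotation_matrix(u[1:])
        center = np.full(3, 63 / 2)
        for name in landmarks.points:
            expected = center + s * rot @ (landmarks[name] - center)
            np.testing.assert_allclose(out_lm[name], expected, atol=1e-9)

    def test_image_follows_landmarks(self):
        # a bright blob moves to where the transformed landmark says it is
        vol_values = np.zeros((48, 48, 48))
        vol_values[20, 24, 26] = 1000.0
        vol = Volume3D(vol_values)
        lm = LandmarkSet({n: [20.0, 24.0, 26.0] for n in ("LCC", "NCC", "RCC", "LCO", "RCO")})
        out_vol, out_lm = random_similarity_transform(vol, lm, seed=4, limit=3.0)
        peak = np.unravel_index(np.argmax(out_vol.values), out_vol.values.shape)
        assert np.linalg.norm(np.array(peak) - out_lm["LCC"]) < 1.0
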