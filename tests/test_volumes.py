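"""Voxel grids, sphere ROIs, smoothing, masking, NIfTI round trips."""

import numpy as np
import pytest

from imagerylink import volumes
from imagerylink.errors import (
    EmptyMaskError,
    GridMismatchError,
    UnsupportedOrientationError,
    ValidationError,
)


def brute_force_sphere(center, radius, grid):
    """Independent oracle: test every voxel center in the full grid."""
    hits = []
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                w = grid.index_to_world(np.array([i, j, k]))
                if np.sqrt(((w - np.asarray(center)) ** 2).sum()) <= radius:
                    hits.append((i, j, k))
    return set(hits)


class TestSphereMask:
    def test_12mm_sphere_on_2mm_grid_has_925_voxels(self, grid2mm):
        mask = volumes.make_sphere_mask((0.0, 0.0, 0.0), 12.0, grid2mm)
        assert mask.n_voxels == 925

    def test_zero_radius_on_voxel_center_is_single_voxel(self, grid2mm):
        mask = volumes.make_sphere_mask((0.0, 0.0, 0.0), 0.0, grid2mm)
        assert mask.n_voxels == 1

    def test_15mm_grid_count_matches_lattice_enumeration(self, grid15mm):
        center = grid15mm.index_to_world(np.array([12, 14, 12]))
        mask = volumes.make_sphere_mask(center, 12.0, grid15mm)
        # offsets with ||1.5 * (i,j,k)|| <= 12  <=>  i^2+j^2+k^2 <= 64
        expected = sum(
            1
            for i in range(-8, 9)
            for j in range(-8, 9)
            for k in range(-8, 9)
            if i * i + j * j + k * k <= 64
        )
        assert mask.n_voxels == expected

    def test_random_spheres_match_brute_force_oracle(self, rng):
        grid = volumes.VoxelGrid.isotropic((11, 12, 13), 2.0)
        for _ in range(20):
            center = rng.uniform(-8, 8, 3)
            radius = rng.uniform(0, 9)
            try:
                mask = volumes.make_sphere_mask(center, radius, grid)
                got = set(map(tuple, mask.voxel_indices))
            except EmptyMaskError:
                got = set()
            assert got == brute_force_sphere(center, radius, grid)

    def test_reflection_symmetry_about_voxel_center(self, grid2mm):
        mask = volumes.make_sphere_mask((0.0, 0.0, 0.0), 7.0, grid2mm)
        center_idx = np.asarray(grid2mm.world_to_index((0, 0, 0)), dtype=int)
        offsets = set(map(tuple, mask.voxel_indices - center_idx))
        assert offsets == {tuple(-np.array(o)) for o in offsets}

    def test_sphere_outside_grid_raises(self, grid2mm):
        with pytest.raises(EmptyMaskError):
            volumes.make_sphere_mask((500.0, 0.0, 0.0), 5.0, grid2mm)

    def test_negative_radius_rejected(self, grid2mm):
        with pytest.raises(ValidationError):
            volumes.make_sphere_mask((0, 0, 0), -1.0, grid2mm)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self, grid2mm, rng):
        vol = volumes.VolumeMap(grid2mm, rng.standard_normal(grid2mm.shape))
        out = volumes.gaussian_smooth(vol, 0.0)
        np.testing.assert_array_equal(out.values, vol.values)

    def test_interior_impulse_conserves_mass(self, grid2mm):
        data = np.zeros(grid2mm.shape)
        data[12, 14, 12] = 1.0
        out = volumes.gaussian_smooth(volumes.VolumeMap(grid2mm, data), 6.0)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_impulse_matches_dense_convolution_oracle(self, grid2mm):
        data = np.zeros(grid2mm.shape)
        data[12, 14, 12] = 1.0
        fwhm = 5.0
        out = volumes.gaussian_smooth(volumes.VolumeMap(grid2mm, data), fwhm)
        sigma_vox = fwhm * volumes.FWHM_TO_SIGMA / 2.0
        ax = np.arange(-8, 9)
        k1 = np.exp(-0.5 * (ax / sigma_vox) ** 2)
        k1 /= k1.sum()
        kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
        sl = tuple(slice(c - 8, c + 9) for c in (12, 14, 12))
        # separable filtering truncates the kernel at 4 sigma; the dense
        # oracle does not, so agreement is to ~1e-6 absolute
        np.testing.assert_allclose(out.values[sl], kernel, atol=1e-5)

    def test_linearity(self, grid2mm, rng):
        a = volumes.VolumeMap(grid2mm, rng.standard_normal(grid2mm.shape))
        b = volumes.VolumeMap(grid2mm, rng.standard_normal(grid2mm.shape))
        combo = volumes.VolumeMap(grid2mm, 2.0 * a.values - 3.0 * b.values)
        lhs = volumes.gaussian_smooth(combo, 8.0).values
        rhs = (
            2.0 * volumes.gaussian_smooth(a, 8.0).values
            - 3.0 * volumes.gaussian_smooth(b, 8.0).values
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_agrees_with_nilearn_oracle(self, rng):
        nl_image = pytest.importorskip("nilearn.image")
        import nibabel as nib

        grid = volumes.VoxelGrid.isotropic((15, 15, 15), 2.0)
        vol = volumes.VolumeMap(grid, rng.standard_normal(grid.shape))
        ours = volumes.gaussian_smooth(vol, 6.0, mode="nearest")
        img = nib.Nifti1Image(vol.values, grid.affine())
        ref = nl_image.smooth_img(img, fwhm=6.0).get_fdata()
        # interior voxels only: boundary handling differs between packages
        core = (slice(4, -4),) * 3
        np.testing.assert_allclose(ours.values[core], ref[core], rtol=1e-4, atol=1e-6)

    def test_negative_fwhm_rejected(self, grid2mm):
        with pytest.raises(ValidationError):
            volumes.gaussian_smooth(volumes.VolumeMap(grid2mm, np.zeros(grid2mm.shape)), -1)


class TestAbsoluteMask:
    def test_threshold_zero_keeps_everything_nonnegative(self, grid2mm, rng):
        maps = [
            volumes.VolumeMap(grid2mm, rng.uniform(0, 1, grid2mm.shape), "gray_matter")
            for _ in range(3)
        ]
        assert volumes.absolute_mask(maps, 0.0).values.all()

    def test_single_low_subject_excludes_voxel(self, grid2mm):
        ones = np.ones(grid2mm.shape)
        low = ones.copy()
        low[3, 4, 5] = 0.01
        maps = [
            volumes.VolumeMap(grid2mm, ones, "gray_matter"),
            volumes.VolumeMap(grid2mm, low, "gray_matter"),
        ]
        mask = volumes.absolute_mask(maps, 0.05)
        assert mask.values[3, 4, 5] == 0 and mask.values.sum() == ones.size - 1

    def test_matches_all_subject_minimum_oracle(self, grid2mm, rng):
        maps = [
            volumes.VolumeMap(grid2mm, rng.uniform(0, 0.2, grid2mm.shape), "gray_matter")
            for _ in range(5)
        ]
        mask = volumes.absolute_mask(maps, 0.05)
        oracle = np.min([m.values for m in maps], axis=0) >= 0.05
        np.testing.assert_array_equal(mask.values.astype(bool), oracle)

    def test_grid_mismatch_rejected(self, grid2mm, grid15mm):
        a = volumes.VolumeMap(grid2mm, np.ones(grid2mm.shape), "gray_matter")
        b = volumes.VolumeMap(grid15mm, np.ones(grid15mm.shape), "gray_matter")
        with pytest.raises(GridMismatchError):
            volumes.absolute_mask([a, b])


class TestNiftiIO:
    def test_roundtrip_preserves_grid_and_float32_values(self, tmp_path, rng):
        grid = volumes.VoxelGrid((9, 8, 7), (1.5, 1.5, 1.5), (-6.0, 3.0, 2.5))
        vol = volumes.VolumeMap(grid, rng.standard_normal((9, 8, 7)).astype(np.float32))
        path = tmp_path / "vol.nii.gz"
        volumes.write_volume(vol, path)
        back = volumes.read_volume(path)
        assert back.grid == grid
        np.testing.assert_array_equal(back.values, vol.values)

    def test_4d_stack_roundtrip(self, tmp_path, grid2mm, rng):
        maps = [
            volumes.VolumeMap(grid2mm, rng.standard_normal(grid2mm.shape).astype(np.float32))
            for _ in range(4)
        ]
        path = tmp_path / "stack.nii.gz"
        volumes.write_volume_stack(maps, path)
        back = volumes.read_volume_stack(path)
        assert len(back) == 4
        for a, b in zip(maps, back):
            assert b.grid == grid2mm
            np.testing.assert_array_equal(a.values, b.values)

    def test_oblique_affine_rejected(self, tmp_path, rng):
        import nibabel as nib

        aff = np.eye(4)
        aff[0, 1] = 0.3  # shear -> not axis-aligned
        nib.save(nib.Nifti1Image(rng.standard_normal((5, 5, 5)), aff), tmp_path / "o.nii")
        with pytest.raises(UnsupportedOrientationError):
            volumes.read_volume(tmp_path / "o.nii")
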