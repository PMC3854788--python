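"""Pre-processing stage contracts: resampling, smoothing, enhancement."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import spotquant as sq
from spotquant.preprocess import preprocess_stack

from conftest import normalized_grid


class TestResample:
    def test_constant_grid_stays_constant(self):
        grid = sq.VoxelGrid(np.full((5, 7, 9), 3.5), (0.7, 0.3, 0.5))
        out = sq.resample_isotropic(grid, 0.2)
        assert out.spacing_um == (0.2, 0.2, 0.2)
        np.testing.assert_allclose(out.data, 3.5)

    def test_identity_when_already_isotropic(self):
        rng = np.random.default_rng(0)
        grid = sq.VoxelGrid(rng.random((6, 6, 6)), (0.2, 0.2, 0.2))
        out = sq.resample_isotropic(grid, 0.2)
        assert out.shape == grid.shape
        np.testing.assert_allclose(out.data, grid.data, atol=1e-12)

    def test_z_ramp_interpolates_midplanes(self):
        # ramp along z sampled at 0.4 µm; resampling to 0.2 µm must put
        # mid-planes exactly at the average of their flanking input planes
        nz = 5
        ramp = np.arange(nz, dtype=float)[:, None, None] * np.ones((1, 4, 4))
        grid = sq.VoxelGrid(ramp, (0.4, 0.2, 0.2))
        out = sq.resample_isotropic(grid, 0.2)
        assert out.shape[0] == 2 * nz - 1
        np.testing.assert_allclose(out.data[1], (ramp[0] + ramp[1]) / 2)
        np.testing.assert_allclose(out.data[2], ramp[1])

    def test_physical_extent_preserved(self):
        grid = sq.VoxelGrid(np.zeros((10, 20, 20)), (0.5, 0.25, 0.25))
        out = sq.resample_isotropic(grid, 0.2)
        for n_out, n_in, s_in in zip(out.shape, grid.shape, grid.spacing_um):
            assert abs((n_out - 1) * 0.2 - (n_in - 1) * s_in) <= 0.2

    def test_oversized_target_errors(self):
        grid = sq.VoxelGrid(np.zeros((3, 3, 3)), (0.2, 0.2, 0.2))
        with pytest.raises(ValueError, match="extent"):
            sq.resample_isotropic(grid, 5.0)


class TestSmooth:
    def test_constant_unchanged(self):
        grid = sq.VoxelGrid(np.full((6, 6, 6), 2.0), (0.2, 0.2, 0.2))
        out = sq.smooth_gaussian(grid, 0.3)
        np.testing.assert_allclose(out.data, 2.0, atol=1e-12)

    def test_impulse_response_is_normalized_kernel(self):
        data = np.zeros((11, 11, 11))
        data[5, 5, 5] = 1.0
        out = sq.smooth_gaussian(sq.VoxelGrid(data, (0.2, 0.2, 0.2)), 0.2)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.unravel_index(np.argmax(out.data), out.shape) == (5, 5, 5)
        # symmetric about the impulse
        np.testing.assert_allclose(out.data, out.data[::-1, :, :], atol=1e-12)

    def test_reduces_white_noise_variance(self):
        rng = np.random.default_rng(42)
        grid = sq.VoxelGrid(rng.normal(10, 2, (16, 16, 16)), (0.2, 0.2, 0.2))
        out = sq.smooth_gaussian(grid, 0.3)
        assert out.data.var() < grid.data.var()

    def test_requires_isotropic(self):
        grid = sq.VoxelGrid(np.zeros((4, 4, 4)), (0.4, 0.2, 0.2))
        with pytest.raises(ValueError, match="isotropic"):
            sq.smooth_gaussian(grid, 0.2)


class TestHistogram:
    def test_two_valued_grid_maps_to_zero_and_max(self):
        data = np.where(np.arange(1000).reshape(10, 10, 10) < 500, 10.0, 20.0)
        out = sq.enhance_histogram(sq.VoxelGrid(data, (0.2,) * 3), (0.5, 99.5))
        assert set(np.unique(out.data)) == {0.0, 20.0}
        assert ((data == 20.0) == (out.data == 20.0)).all()

    def test_full_range_percentiles_preserve_ranks(self):
        rng = np.random.default_rng(1)
        data = rng.random((8, 8, 8)) + 0.5
        out = sq.enhance_histogram(sq.VoxelGrid(data, (0.2,) * 3), (0.0, 100.0))
        rho = spearmanr(data.ravel(), out.data.ravel()).statistic
        assert rho == pytest.approx(1.0)
        assert out.data.min() == pytest.approx(0.0, abs=1e-12)
        assert out.data.max() == pytest.approx(data.max())

    def test_monotone_within_clip_range(self):
        rng = np.random.default_rng(2)
        data = rng.random((8, 8, 8))
        out = sq.enhance_histogram(sq.VoxelGrid(data, (0.2,) * 3), (5.0, 95.0))
        lo, hi = np.percentile(data, [5.0, 95.0])
        inside = (data > lo) & (data < hi)
        rho = spearmanr(data[inside], out.data[inside]).statistic
        assert rho == pytest.approx(1.0)

    def test_constant_grid_warns_and_returns_unchanged(self):
        grid = sq.VoxelGrid(np.full((4, 4, 4), 7.0), (0.2,) * 3)
        with pytest.warns(UserWarning, match="constant"):
            out = sq.enhance_histogram(grid, (0.5, 99.5))
        np.testing.assert_array_equal(out.data, 7.0)


class TestLaplacian:
    def test_weight_zero_is_identity(self):
        rng = np.random.default_rng(3)
        grid = sq.VoxelGrid(rng.random((5, 5, 5)), (0.2,) * 3)
        out = sq.enhance_laplacian(grid, 0.0)
        np.testing.assert_array_equal(out.data, grid.data)

    def test_constant_grid_unchanged(self):
        grid = sq.VoxelGrid(np.full((5, 5, 5), 4.0), (0.2,) * 3)
        out = sq.enhance_laplacian(grid, 1.0)
        np.testing.assert_allclose(out.data, 4.0)

    def test_step_edge_overshoots_on_bright_side(self):
        # 1x1x8 step profile: the 6-neighbor stencil must produce an
        # overshoot adjacent to the edge exceeding both plateau values
        step = np.array([0.0, 0, 0, 0, 1, 1, 1, 1]).reshape(1, 1, 8)
        out = sq.enhance_laplacian(sq.VoxelGrid(step, (0.2,) * 3), 1.0)
        assert out.data[0, 0, 4] == pytest.approx(2.0)  # overshoot > both plateaus
        assert out.data[0, 0, 3] == pytest.approx(0.0)  # dark side clipped at 0


class TestNormalize:
    def test_scales_by_global_max(self):
        data = np.linspace(0, 512, 64).reshape(4, 4, 4)
        out = sq.normalize_intensity(sq.VoxelGrid(data, (0.2,) * 3))
        assert out.normalized and out.data.max() == 1.0
        np.testing.assert_allclose(out.data, data / 512)

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        grid = sq.VoxelGrid(rng.random((5, 5, 5)), (0.2,) * 3)
        once = sq.normalize_intensity(grid)
        twice = sq.normalize_intensity(once)
        np.testing.assert_array_equal(once.data, twice.data)

    def test_argmax_position_unchanged(self):
        rng = np.random.default_rng(5)
        data = rng.random((6, 7, 8))
        out = sq.normalize_intensity(sq.VoxelGrid(data, (0.2,) * 3))
        assert np.argmax(out.data) == np.argmax(data)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="empty image"):
            sq.normalize_intensity(sq.VoxelGrid(np.zeros((3, 3, 3)), (0.2,) * 3))


class TestPipelineProperties:
    def test_deterministic_bit_for_bit(self):
        rng = np.random.default_rng(6)
        grid = sq.VoxelGrid(rng.random((8, 16, 16)) * 100, (0.4, 0.2, 0.2))
        a = preprocess_stack(grid)
        b = preprocess_stack(grid)
        assert a.data.tobytes() == b.data.tobytes()

    def test_translation_equivariance_of_stages(self):
        # a spot shifted by whole voxels shifts every stage output equally
        z, y, x = np.mgrid[0:20, 0:20, 0:20].astype(float)
        spot = lambda c: 100 * np.exp(-(((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2) / 3.0))
        g0 = sq.VoxelGrid(10 + spot((9, 9, 9)), (0.2,) * 3)
        g1 = sq.VoxelGrid(10 + spot((9, 11, 10)), (0.2,) * 3)
        for stage in (
            lambda g: sq.smooth_gaussian(g, 0.3),
            lambda g: sq.enhance_laplacian(g, 1.0),
        ):
            a, b = stage(g0).data, stage(g1).data
            # compare interior, shifted by (0, 2, 1) voxels
            np.testing.assert_allclose(a[4:16, 4:14, 4:15], b[4:16, 6:16, 5:16], atol=1e-8)
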