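import numpy as np
import pytest

from wsimil.heatmap import (
    STEP_BY_SCALE,
    HeatmapRaster,
    multiscale_heatmap,
    render_heatmap,
    scale_difference,
    upsample_nearest,
    window_schedule,
)

from conftest import (
    noisy_tissue_patch,
    prefix_sum_heatmap_oracle,
    reference_grey_tissue_count,
)


def mean_pixel_predictor(stack):
    """Deterministic stub: prediction = mean pixel value / 255."""
    return stack.reshape(stack.shape[0], -1).mean(axis=1) / 255.0


class TestWindowSchedule:
    @pytest.mark.parametrize(
        "dims,scale,expected",
        [
            ((512, 512), 20.0, 4),  # step 256: 2 x 2
            ((512, 512), 10.0, 9),  # step 128: floor((512-256)/128)+1 = 3 per axis
            ((512, 512), 5.0, 25),  # step 64: 5 per axis
            ((256, 256), 2.5, 1),
        ],
    )
    def test_counts(self, dims, scale, expected):
        assert len(window_schedule(dims, scale)) == expected

    def test_small_plane_empty_with_warning(self):
        with pytest.warns(UserWarning):
            assert window_schedule((200, 512), 20.0) == []

    def test_origins_are_step_multiples(self):
        for r, c in window_schedule((700, 700), 10.0):
            assert r % 128 == 0 and c % 128 == 0
            assert r + 256 <= 700 and c + 256 <= 700

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValueError):
            window_schedule((512, 512), 40.0)


class TestRenderHeatmap:
    def test_single_window_constant(self, rng):
        plane = noisy_tissue_patch(rng, 256)
        raster = render_heatmap(plane, lambda s: np.full(s.shape[0], 0.7), 20.0)
        assert np.allclose(raster.values, 0.7)
        assert np.all(raster.coverage == 1)

    def test_overlap_averages_two_windows(self):
        # 256 x 384 plane at 10x (step 128): windows at col 0 and col 128
        plane = np.full((256, 384, 3), 128, dtype=np.uint8)
        calls = iter([0.3, 0.7])
        raster = render_heatmap(
            plane, lambda s: np.array([next(calls) for _ in range(s.shape[0])]), 10.0
        )
        assert np.allclose(raster.values[:, :128], 0.3)
        assert np.allclose(raster.values[:, 128:256], 0.5)  # covered by both
        assert np.allclose(raster.values[:, 256:], 0.7)
        assert raster.coverage.max() == 2

    def test_tissue_gate_excludes_background(self, rng):
        plane = np.full((256, 512, 3), 255, dtype=np.uint8)  # right half white
        plane[:, :256] = noisy_tissue_patch(rng, 256)
        raster = render_heatmap(plane, lambda s: np.full(s.shape[0], 0.9), 20.0)
        assert np.all(raster.coverage[:, 256:] == 0)
        assert np.all(np.isnan(raster.values[:, 256:]))
        assert np.all(raster.coverage[:, :256] == 1)

    def test_empty_raster_warns(self):
        plane = np.full((256, 256, 3), 255, dtype=np.uint8)
        with pytest.warns(UserWarning):
            raster = render_heatmap(plane, mean_pixel_predictor, 20.0)
        assert not raster.defined().any()

    @pytest.mark.parametrize("scale", [20.0, 10.0, 5.0, 2.5])
    def test_matches_prefix_sum_oracle(self, rng, scale):
        plane = np.full((512, 384, 3), 255, dtype=np.uint8)
        plane[:384] = noisy_tissue_patch(rng, 512)[:384, :384]
        raster = render_heatmap(plane, mean_pixel_predictor, scale)
        step = STEP_BY_SCALE[scale]
        preds = {}
        for r in range(0, 512 - 256 + 1, step):
            for c in range(0, 384 - 256 + 1, step):
                win = plane[r : r + 256, c : c + 256]
                if reference_grey_tissue_count(win) / 65536 > 0.5:
                    preds[(r, c)] = win.reshape(-1).mean() / 255.0
        values, coverage = prefix_sum_heatmap_oracle((512, 384), 256, step, preds)
        np.testing.assert_array_equal(raster.coverage, coverage)
        np.testing.assert_allclose(raster.values, values, atol=1e-9, equal_nan=True)

    def test_values_within_window_prediction_bounds(self, rng):
        plane = noisy_tissue_patch(rng, 512)
        raster = render_heatmap(plane, mean_pixel_predictor, 5.0)
        preds = mean_pixel_predictor(
            np.stack(
                [plane[r : r + 256, c : c + 256] for r, c in window_schedule((512, 512), 5.0)]
            )
        )
        assert np.nanmin(raster.values) >= preds.min() - 1e-12
        assert np.nanmax(raster.values) <= preds.max() + 1e-12

    def test_halving_step_never_reduces_coverage(self, rng):
        plane = noisy_tissue_patch(rng, 512)
        cov_256 = render_heatmap(plane, mean_pixel_predictor, 20.0).coverage
        cov_128 = render_heatmap(plane, mean_pixel_predictor, 10.0).coverage
        assert np.all(cov_128 >= cov_256)


class TestScaleDifference:
    def _const_raster(self, value, size, scale, coverage=None):
        cov = coverage if coverage is not None else np.ones((size, size), dtype=int)
        vals = np.where(cov > 0, float(value), np.nan)
        return HeatmapRaster(vals, cov, scale, STEP_BY_SCALE[scale])

    def test_identical_maps_zero(self):
        a = self._const_raster(0.6, 64, 20.0)
        diff = scale_difference(a, self._const_raster(0.6, 64, 20.0))
        assert np.allclose(diff.values, 0.0)

    def test_hi_minus_lo(self):
        hi = self._const_raster(0.9, 64, 20.0)
        lo = self._const_raster(0.2, 8, 2.5)  # upsampled x8 to the 20x grid
        diff = scale_difference(hi, lo)
        assert diff.values.shape == (64, 64)
        assert np.allclose(diff.values, 0.7)

    def test_nested_coverage_intersection(self):
        cov_hi = np.zeros((64, 64), dtype=int)
        cov_hi[:32] = 1
        hi = self._const_raster(0.6, 64, 20.0, cov_hi)
        lo = self._const_raster(0.4, 64, 20.0)
        diff = scale_difference(hi, lo)
        assert np.allclose(diff.values[:32], 0.2)
        assert np.all(np.isnan(diff.values[32:]))

    def test_disjoint_coverage_warns(self):
        cov_a = np.zeros((64, 64), dtype=int)
        cov_a[:32] = 1
        cov_b = np.zeros((64, 64), dtype=int)
        cov_b[32:] = 1
        with pytest.warns(UserWarning):
            diff = scale_difference(
                self._const_raster(0.5, 64, 20.0, cov_a),
                self._const_raster(0.5, 64, 20.0, cov_b),
            )
        assert not diff.defined().any()


def test_multiscale_heatmap_mean_on_common_grid():
    rasters = {}
    for scale, val in ((20.0, 0.8), (10.0, 0.6), (5.0, 0.4), (2.5, 0.2)):
        size = int(64 * scale / 2.5) // 8  # grids shrink with magnification ratio
        size = {20.0: 64, 10.0: 32, 5.0: 16, 2.5: 8}[scale]
        cov = np.ones((size, size), dtype=int)
        rasters[scale] = HeatmapRaster(
            np.full((size, size), val), cov, scale, STEP_BY_SCALE[scale]
        )
    out = multiscale_heatmap(rasters)
    assert out.values.shape == (64, 64)
    assert np.allclose(out.values, 0.5)
    with pytest.raises(ValueError):
        multiscale_heatmap({20.0: rasters[20.0]})


def test_upsample_nearest_blocks():
    r = HeatmapRaster(np.array([[0.1, 0.9]]), np.array([[1, 2]]), 2.5, 32)
    up = upsample_nearest(r, 2)
    assert up.values.shape == (2, 4)
    assert np.all(up.values[:, :2] == 0.1) and np.all(up.values[:, 2:] == 0.9)
    assert np.all(up.coverage[:, 2:] == 2)
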