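import json

import numpy as np
import pytest

from wsimil import tiling
from wsimil.tiling import (
    ArtifactConfig,
    Patch,
    SlideRecord,
    Slide,
    grid_origins,
    open_slide,
    qualify_patch,
    tile_plane,
    tile_slide,
    tissue_fraction,
    to_greyscale,
)

from conftest import brute_force_tile_scan, make_textured_plane, noisy_tissue_patch


def _flat_slide(tmp_path, plane, base=40.0, **meta):
    from PIL import Image

    path = tmp_path / "s1.png"
    Image.fromarray(plane).save(path)
    sidecar = {"slide_id": "s1", "patient_id": "p1", "label": 0, "base_magnification": base}
    sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar))
    return path


class TestOpenSlide:
    def test_pyramid_arithmetic(self, tmp_path, rng):
        plane = rng.integers(0, 256, (4096, 4096, 3)).astype(np.uint8)
        slide = Slide(
            SlideRecord("s", "p", 0, tmp_path, base_magnification=40.0), plane
        )
        assert slide.plane(20.0).shape == (2048, 2048, 3)
        assert slide.plane(2.5).shape == (256, 256, 3)
        assert slide.plane_dims(10.0) == (1024, 1024)

    def test_downsample_is_block_mean(self):
        plane = np.zeros((4, 4, 3), dtype=np.uint8)
        plane[:2, :2] = 100
        plane[:2, 2:] = 200
        out = tiling.area_downsample(plane, 2)
        assert out.shape == (2, 2, 3)
        assert out[0, 0, 0] == 100 and out[0, 1, 0] == 200 and out[1, 0, 0] == 0

    def test_scale_above_base_rejected(self, tmp_path, rng):
        path = _flat_slide(tmp_path, rng.integers(0, 256, (512, 512, 3)).astype(np.uint8), base=20.0)
        slide = open_slide(path)
        with pytest.raises(ValueError, match="exceeds base"):
            slide.plane(40.0)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            open_slide(tmp_path / "nope.png")

    def test_sidecar_metadata(self, tmp_path, rng):
        path = _flat_slide(
            tmp_path,
            rng.integers(0, 256, (512, 512, 3)).astype(np.uint8),
            base=20.0,
            label=1,
        )
        slide = open_slide(path)
        rec = slide.record
        assert (rec.slide_id, rec.patient_id, rec.label) == ("s1", "p1", 1)
        assert rec.base_magnification == 20.0


class TestTissueFraction:
    @pytest.mark.parametrize(
        "value,expected",
        [(255, 0.0), (0, 0.0), (40, None), (215, None)],
    )
    def test_constant_patches(self, value, expected):
        patch = np.full((256, 256, 3), value, dtype=np.uint8)
        frac = tissue_fraction(patch)
        if expected is None:  # endpoints are inclusive
            assert frac == 1.0
        else:
            assert frac == expected

    def test_half_grey_half_white(self):
        patch = np.full((256, 256, 3), 255, dtype=np.uint8)
        patch[:, :128] = 128
        assert tissue_fraction(patch) == 0.5

    def test_permutation_invariant(self, rng):
        patch = rng.integers(0, 256, (256, 256, 3)).astype(np.uint8)
        flat = patch.reshape(-1, 3)
        shuffled = flat[rng.permutation(len(flat))].reshape(256, 256, 3)
        assert tissue_fraction(patch) == tissue_fraction(shuffled)

    def test_luminance_rounding(self):
        # 0.299*50 + 0.587*50 + 0.114*50 = 50 exactly; off-grey checks rint
        patch = np.zeros((1, 1, 3), dtype=np.uint8)
        patch[..., :] = (10, 50, 200)
        expected = round(0.299 * 10 + 0.587 * 50 + 0.114 * 200)
        assert to_greyscale(patch)[0, 0] == expected

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            tissue_fraction(np.zeros((256, 256)))


class TestQualifyPatch:
    def _patch(self, pixels):
        return Patch("s", 20.0, (0, 0), pixels, tissue_fraction(pixels))

    def test_exactly_75_percent_rejected(self, rng):
        # strictly-greater rule: exactly 3/4 tissue must fail
        pixels = np.full((256, 256, 3), 255, dtype=np.uint8)
        pixels[:192] = noisy_tissue_patch(rng)[:192]
        patch = self._patch(pixels)
        assert patch.tissue_fraction == 0.75
        assert not qualify_patch(patch)

    def test_just_above_threshold_accepted(self, rng):
        pixels = np.full((256, 256, 3), 255, dtype=np.uint8)
        pixels[:193] = noisy_tissue_patch(rng)[:193]
        patch = self._patch(pixels)
        assert patch.tissue_fraction > 0.75
        assert qualify_patch(patch)

    def test_pen_marked_patch_rejected(self, rng):
        pixels = noisy_tissue_patch(rng)
        # 5% saturated-green pixels: hue 1/3, saturation 1
        n = int(0.05 * 256 * 256)
        idx = rng.choice(256 * 256, size=n, replace=False)
        flat = pixels.reshape(-1, 3)
        flat[idx] = (0, 200, 30)
        patch = self._patch(flat.reshape(256, 256, 3))
        assert patch.tissue_fraction > 0.75
        assert not qualify_patch(patch)

    def test_blurred_patch_rejected(self, rng):
        from scipy.ndimage import gaussian_filter

        pixels = noisy_tissue_patch(rng).astype(np.float64)
        blurred = np.rint(gaussian_filter(pixels, sigma=(8, 8, 0))).astype(np.uint8)
        patch = self._patch(blurred)
        assert patch.tissue_fraction > 0.75
        assert not qualify_patch(patch)

    def test_artifact_rules_configurable(self, rng):
        from scipy.ndimage import gaussian_filter

        pixels = noisy_tissue_patch(rng).astype(np.float64)
        blurred = np.rint(gaussian_filter(pixels, sigma=(8, 8, 0))).astype(np.uint8)
        patch = self._patch(blurred)
        assert qualify_patch(patch, ArtifactConfig(enable_blur=False))


class TestTileSlide:
    def _slide(self, plane, base=20.0):
        return Slide(SlideRecord("s", "p", 0, None, base_magnification=base), plane)

    def test_all_tissue_grid_count(self, rng):
        plane = noisy_tissue_patch(rng, size=1024)
        patches = tile_slide(self._slide(plane), 20.0)
        assert len(patches) == 16

    def test_quadrant_tissue(self, rng):
        plane = np.full((1024, 1024, 3), 255, dtype=np.uint8)
        plane[:512, :512] = noisy_tissue_patch(rng, 512)
        patches = tile_slide(self._slide(plane), 20.0)
        assert len(patches) == 4
        assert all(p.origin[0] < 512 and p.origin[1] < 512 for p in patches)

    def test_edge_remainder_dropped(self):
        assert grid_origins(300, 300) == [(0, 0)]
        assert grid_origins(255, 1024) == []

    def test_origins_on_grid_and_disjoint(self, rng):
        plane = make_textured_plane(rng, size=1024)
        patches = tile_slide(self._slide(plane), 20.0)
        origins = [p.origin for p in patches]
        assert len(set(origins)) == len(origins)
        for r, c in origins:
            assert r % 256 == 0 and c % 256 == 0

    def test_matches_brute_force_reference(self, rng):
        for _ in range(3):
            plane = make_textured_plane(rng, size=1024)
            patches = tile_slide(self._slide(plane), 20.0)
            ref = brute_force_tile_scan(plane)
            assert [(p.origin[0], p.origin[1]) for p in patches] == [
                (r, c) for r, c, _ in ref
            ]
            for p, (_, _, frac) in zip(patches, ref):
                assert p.tissue_fraction == frac

    def test_unknown_scale_rejected(self, rng):
        with pytest.raises(ValueError):
            tile_slide(self._slide(noisy_tissue_patch(rng, 512)), 7.5)

    def test_manifest_covers_every_grid_cell(self, rng):
        plane = make_textured_plane(rng, size=1024)
        patches, manifest = tile_plane(plane, "s", 20.0)
        assert len(manifest) == 16
        assert manifest["qualified"].sum() == len(patches)
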