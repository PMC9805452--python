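"""Whole-slide reading, tissue masking and 256x256 patch extraction.

Slides are tiled into non-overlapping 256x256 patches at four nominal
magnifications (2.5x, 5x, 10x, 20x), realized as integer area-average
downsamples of the base scan. A greyscale pixel is informative tissue when
its luminance lies in [40, 215]: brighter pixels are background whitespace,
darker ones folded/overstained tissue. A patch qualifies for modelling when
strictly more than 75% of its pixels are tissue and it passes configurable
pen-mark and blur exclusion rules.

Two on-disk slide forms are supported: pyramidal TIFF (read with tifffile)
and a "flat dialect" — one PNG/TIFF plane plus a JSON sidecar carrying
slide_id, patient_id, label and base_magnification — used for synthetic
cohorts and fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

TILE = 256
SCALES = (2.5, 5.0, 10.0, 20.0)
GREY_LOW = 40
GREY_HIGH = 215
TISSUE_MIN_FRACTION = 0.75

#: ITU-R 601 luminance weights (configurable via the ``weights`` arguments).
LUMA_601 = (0.299, 0.587, 0.114)


@dataclass
class SlideRecord:
    """Identity and label metadata for one slide."""

    slide_id: str
    patient_id: str
    label: int
    path: Path
    base_magnification: float = 40.0
    expert_scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.base_magnification <= 0:
            raise ValueError("base_magnification must be positive")
        for pid, s in (self.expert_scores or {}).items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"expert score {s} for {pid} outside [0, 1]")


@dataclass
class Patch:
    """One 256x256 RGB tile at a stated scale.

    ``origin`` is the 0-based (row, col) of the top-left pixel in the
    scale-s plane; the tile covers the half-open box
    [row, row+256) x [col, col+256).
    """

    slide_id: str
    scale: float
    origin: tuple[int, int]
    pixels: np.ndarray
    tissue_fraction: float

    def __post_init__(self) -> None:
        if self.pixels.shape != (TILE, TILE, 3):
            raise ValueError(f"patch pixels must be {TILE}x{TILE}x3")


@dataclass
class ArtifactConfig:
    """Pen-mark and blur exclusion thresholds.

    The exclusion heuristics mirror common marker colors: a patch is
    pen-marked when more than ``pen_fraction`` of its pixels are highly
    saturated (S > ``pen_saturation``) with hue inside a blue, green or red
    marker band, and blurred when the variance of a 3x3 Laplacian of the
    greyscale plane falls below ``blur_min_laplacian_var``. Defaults are a
    documented choice of this package.
    """

    pen_saturation: float = 0.8
    pen_fraction: float = 0.02
    # hue bands in [0, 1): red wraps around 0
    pen_hue_bands: tuple[tuple[float, float], ...] = (
        (0.20, 0.45),  # green markers
        (0.50, 0.75),  # blue markers
        (0.95, 1.00),  # red, upper wrap
        (0.00, 0.05),  # red, lower wrap
    )
    blur_min_laplacian_var: float = 10.0
    enable_pen: bool = True
    enable_blur: bool = True


def to_greyscale(
    pixels: np.ndarray, weights: tuple[float, float, float] = LUMA_601
) -> np.ndarray:
    """RGB -> integer luminance, rounded to the nearest integer."""
    arr = np.asarray(pixels, dtype=np.float64)
    grey = arr[..., 0] * weights[0] + arr[..., 1] * weights[1] + arr[..., 2] * weights[2]
    return np.rint(grey).astype(np.int64)


def tissue_mask(
    pixels: np.ndarray,
    grey_low: int = GREY_LOW,
    grey_high: int = GREY_HIGH,
    weights: tuple[float, float, float] = LUMA_601,
) -> np.ndarray:
    """Boolean mask of informative-tissue pixels (luminance in [40, 215])."""
    grey = to_greyscale(pixels, weights)
    return (grey >= grey_low) & (grey <= grey_high)


def tissue_fraction(pixels: np.ndarray, **kwargs) -> float:
    """Fraction of a 256x256 patch's pixels that are informative tissue."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[-1] != 3:
        raise ValueError(f"expected an RGB array, got shape {pixels.shape}")
    return float(tissue_mask(pixels, **kwargs).mean())


def _rgb_to_hsv(pixels: np.ndarray) -> np.ndarray:
    from .colorconv import rgb_to_hsv

    return rgb_to_hsv(np.asarray(pixels, dtype=np.float32) / 255.0)


def is_pen_marked(pixels: np.ndarray, cfg: ArtifactConfig | None = None) -> bool:
    cfg = cfg or ArtifactConfig()
    hsv = _rgb_to_hsv(pixels)
    hue, sat = hsv[..., 0], hsv[..., 1]
    in_band = np.zeros(hue.shape, dtype=bool)
    for lo, hi in cfg.pen_hue_bands:
        in_band |= (hue >= lo) & (hue < hi)
    frac = float(((sat > cfg.pen_saturation) & in_band).mean())
    return frac > cfg.pen_fraction


def is_blurred(pixels: np.ndarray, cfg: ArtifactConfig | None = None) -> bool:
    from scipy.ndimage import laplace

    cfg = cfg or ArtifactConfig()
    grey = to_greyscale(pixels).astype(np.float64)
    return float(laplace(grey).var()) < cfg.blur_min_laplacian_var


def qualify_patch(
    patch: Patch,
    artifact_rules: ArtifactConfig | None = None,
    min_tissue: float = TISSUE_MIN_FRACTION,
) -> bool:
    """True iff tissue fraction is strictly above 75% and no artifact fires."""
    cfg = artifact_rules or ArtifactConfig()
    if not patch.tissue_fraction > min_tissue:
        return False
    if cfg.enable_pen and is_pen_marked(patch.pixels, cfg):
        return False
    if cfg.enable_blur and is_blurred(patch.pixels, cfg):
        return False
    return True


# ---------------------------------------------------------------------------
# slide handles
# ---------------------------------------------------------------------------


class Slide:
    """Open slide exposing one RGB plane per requested magnification.

    The scale-s plane is the base plane area-averaged by the integer factor
    base_magnification / s. Planes are cached per scale. The whole base
    plane is held in memory, which is appropriate for the synthetic and
    desk-scale slides this package targets.
    """

    def __init__(self, record: SlideRecord, base_plane: np.ndarray) -> None:
        if base_plane.ndim != 3 or base_plane.shape[-1] != 3:
            raise IOError(f"slide plane must be RGB, got shape {base_plane.shape}")
        self.record = record
        self._base = base_plane
        self._planes: dict[float, np.ndarray] = {record.base_magnification: base_plane}

    def downsample_factor(self, scale: float) -> int:
        base = self.record.base_magnification
        if scale > base:
            raise ValueError(
                f"requested scale {scale}x exceeds base magnification {base}x"
            )
        factor = base / scale
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError(
                f"scale {scale}x is not an integer downsample of base {base}x"
            )
        return int(round(factor))

    def plane(self, scale: float) -> np.ndarray:
        if scale not in self._planes:
            f = self.downsample_factor(scale)
            self._planes[scale] = area_downsample(self._base, f)
        return self._planes[scale]

    def plane_dims(self, scale: float) -> tuple[int, int]:
        f = self.downsample_factor(scale)
        h, w = self._base.shape[:2]
        return h // f, w // f


def area_downsample(plane: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsample by an integer factor, cropping any remainder."""
    if factor == 1:
        return plane
    h, w = plane.shape[:2]
    hc, wc = (h // factor) * factor, (w // factor) * factor
    blocks = plane[:hc, :wc].reshape(
        hc // factor, factor, wc // factor, factor, plane.shape[2]
    )
    return np.rint(blocks.astype(np.float64).mean(axis=(1, 3))).astype(np.uint8)


def _read_plane(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff", ".svs"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return np.ascontiguousarray(arr.astype(np.uint8))


def open_slide(
    path: str | Path,
    base_magnification: float | None = None,
    slide_id: str | None = None,
    patient_id: str | None = None,
    label: int = 0,
) -> Slide:
    """Open a flat-dialect or pyramidal-TIFF slide.

    A JSON sidecar (same stem, ``.json`` extension) supplies slide metadata
    when present; explicit arguments override it.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"slide file not found: {path}")
    meta: dict = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    record = SlideRecord(
        slide_id=slide_id or meta.get("slide_id", path.stem),
        patient_id=patient_id or meta.get("patient_id", path.stem),
        label=int(meta.get("label", label)) if "label" in meta else label,
        path=path,
        base_magnification=float(
            base_magnification
            if base_magnification is not None
            else meta.get("base_magnification", 40.0)
        ),
        expert_scores=meta.get("expert_scores"),
    )
    return Slide(record, _read_plane(path))


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------


def grid_origins(height: int, width: int, tile: int = TILE) -> list[tuple[int, int]]:
    """Row-major top-left corners of the non-overlapping tile grid.

    Partial edge tiles are dropped: only full ``tile`` x ``tile`` boxes.
    """
    return [
        (r, c)
        for r in range(0, height - tile + 1, tile)
        for c in range(0, width - tile + 1, tile)
    ]


def tile_plane(
    plane: np.ndarray,
    slide_id: str,
    scale: float,
    artifact_rules: ArtifactConfig | None = None,
) -> tuple[list[Patch], pd.DataFrame]:
    """Scan the non-overlapping grid; return qualifying patches + manifest.

    The manifest records every full grid cell (qualified or not) with its
    tissue fraction, in deterministic row-major order.
    """
    cfg = artifact_rules or ArtifactConfig()
    h, w = plane.shape[:2]
    patches: list[Patch] = []
    rows = []
    for r, c in grid_origins(h, w):
        pix = plane[r : r + TILE, c : c + TILE]
        tf = tissue_fraction(pix)
        patch = Patch(slide_id, scale, (r, c), pix, tf)
        ok = qualify_patch(patch, cfg)
        rows.append(
            {
                "slide_id": slide_id,
                "scale": scale,
                "row": r,
                "col": c,
                "tissue_fraction": tf,
                "qualified": ok,
            }
        )
        if ok:
            patches.append(patch)
    manifest = pd.DataFrame(
        rows, columns=["slide_id", "scale", "row", "col", "tissue_fraction", "qualified"]
    )
    return patches, manifest


def tile_slide(
    slide: Slide,
    scale: float,
    artifact_rules: ArtifactConfig | None = None,
) -> list[Patch]:
    """All qualifying 256x256 patches of the scale-s plane, row-major."""
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}, got {scale}")
    plane = slide.plane(scale)
    patches, _ = tile_plane(plane, slide.record.slide_id, scale, artifact_rules)
    return patches


def write_patch_manifest(manifests: list[pd.DataFrame], path: str | Path) -> None:
    pd.concat(manifests, ignore_index=True).to_csv(path, index=False)


def export_patches(patches: list[Patch], outdir: str | Path) -> list[Path]:
    """Optionally dump patches as ``{slide_id}_{scale}_{row}_{col}.png``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in patches:
        path = outdir / f"{p.slide_id}_{p.scale:g}_{p.origin[0]}_{p.origin[1]}.png"
        Image.fromarray(p.pixels).save(path)
        paths.append(path)
    return paths
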