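"""Sliding-window prediction heatmaps and cross-scale difference maps.

A 256x256 window slides over the scale-s plane with a scale-dependent step
(256 at 20x, 128 at 10x, 64 at 5x, 32 at 2.5x, so each window covers the
same tissue extent in base-scan units). Windows with more than 50% tissue
are scored by the model; every pixel's heatmap value is the mean prediction
over the qualifying windows that contain it. A coverage plane counts the
contributing windows per pixel; values are undefined (NaN) where coverage
is zero. Subtracting the upsampled 2.5x map from the 20x map localizes
where high-magnification cytology and low-magnification architecture
disagree.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tiling import TILE, tissue_fraction

#: step size per nominal magnification (window = 256 everywhere)
STEP_BY_SCALE = {20.0: 256, 10.0: 128, 5.0: 64, 2.5: 32}
HEATMAP_TISSUE_MIN = 0.5


@dataclass
class HeatmapRaster:
    values: np.ndarray  # float plane; NaN where coverage == 0
    coverage: np.ndarray  # int plane
    scale: float
    step: int

    def defined(self) -> np.ndarray:
        return self.coverage > 0


def window_schedule(
    plane_dims: tuple[int, int], scale: float, window: int = TILE
) -> list[tuple[int, int]]:
    """Row-major window origins at multiples of the scale's step size."""
    if scale not in STEP_BY_SCALE:
        raise ValueError(f"scale must be one of {sorted(STEP_BY_SCALE)}, got {scale}")
    step = STEP_BY_SCALE[scale]
    h, w = plane_dims
    if h < window or w < window:
        warnings.warn(f"plane {plane_dims} smaller than the {window}px window")
        return []
    return [
        (r, c)
        for r in range(0, h - window + 1, step)
        for c in range(0, w - window + 1, step)
    ]


def render_heatmap(
    plane: np.ndarray,
    predictor,
    scale: float,
    tissue_threshold: float = HEATMAP_TISSUE_MIN,
    window: int = TILE,
    chunk: int = 32,
) -> HeatmapRaster:
    """Slide a 256-window over ``plane`` and average predictions per pixel.

    ``predictor`` maps a uint8 stack (n, 256, 256, 3) to n probabilities —
    typically the seed-averaged single-scale ensemble scoring each window as
    a one-patch bag. Accumulation is an exact running sum + count per pixel.
    """
    h, w = plane.shape[:2]
    step = STEP_BY_SCALE[scale]
    origins = [
        (r, c)
        for (r, c) in window_schedule((h, w), scale, window)
        if tissue_fraction(plane[r : r + window, c : c + window]) > tissue_threshold
    ]
    acc = np.zeros((h, w), dtype=np.float64)
    cov = np.zeros((h, w), dtype=np.int64)
    if not origins:
        warnings.warn("no window passed the tissue gate; heatmap is empty")
    for i in range(0, len(origins), chunk):
        block = origins[i : i + chunk]
        stack = np.stack([plane[r : r + window, c : c + window] for r, c in block])
        preds = np.asarray(predictor(stack), dtype=np.float64)
        for (r, c), p in zip(block, preds):
            acc[r : r + window, c : c + window] += p
            cov[r : r + window, c : c + window] += 1
    values = np.full((h, w), np.nan)
    defined = cov > 0
    values[defined] = acc[defined] / cov[defined]
    return HeatmapRaster(values=values, coverage=cov, scale=scale, step=step)


def upsample_nearest(raster: HeatmapRaster, factor: int) -> HeatmapRaster:
    """Nearest-neighbor upsampling onto a finer grid (for compositing)."""
    return HeatmapRaster(
        values=np.repeat(np.repeat(raster.values, factor, 0), factor, 1),
        coverage=np.repeat(np.repeat(raster.coverage, factor, 0), factor, 1),
        scale=raster.scale,
        step=raster.step,
    )


def scale_difference(map_hi: HeatmapRaster, map_lo: HeatmapRaster) -> HeatmapRaster:
    """Per-pixel (high-mag - low-mag) prediction difference.

    The low-magnification raster is first upsampled (nearest neighbor) onto
    the high-magnification grid. Values are defined only where both maps
    have coverage.
    """
    factor = int(round(map_hi.scale / map_lo.scale))
    lo = upsample_nearest(map_lo, factor) if factor > 1 else map_lo
    h = min(map_hi.values.shape[0], lo.values.shape[0])
    w = min(map_hi.values.shape[1], lo.values.shape[1])
    both = (map_hi.coverage[:h, :w] > 0) & (lo.coverage[:h, :w] > 0)
    if not both.any():
        warnings.warn("difference map has no jointly covered pixel")
    values = np.full((h, w), np.nan)
    values[both] = map_hi.values[:h, :w][both] - lo.values[:h, :w][both]
    return HeatmapRaster(
        values=values,
        coverage=np.minimum(map_hi.coverage[:h, :w], lo.coverage[:h, :w]) * both,
        scale=map_hi.scale,
        step=map_hi.step,
    )


def multiscale_heatmap(rasters: dict[float, HeatmapRaster]) -> HeatmapRaster:
    """Pixel-wise mean of the four single-scale maps on the 20x grid."""
    missing = set(STEP_BY_SCALE) - set(rasters)
    if missing:
        raise ValueError(f"multiscale heatmap missing scales {sorted(missing)}")
    base = rasters[20.0]
    h, w = base.values.shape
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w), dtype=np.int64)
    for scale, raster in rasters.items():
        factor = int(round(20.0 / scale))
        up = upsample_nearest(raster, factor) if factor > 1 else raster
        vh = min(h, up.values.shape[0])
        vw = min(w, up.values.shape[1])
        d = up.coverage[:vh, :vw] > 0
        acc[:vh, :vw][d] += up.values[:vh, :vw][d]
        cnt[:vh, :vw][d] += 1
    values = np.full((h, w), np.nan)
    values[cnt == 4] = acc[cnt == 4] / 4.0
    return HeatmapRaster(values=values, coverage=(cnt == 4).astype(np.int64), scale=20.0, step=base.step)


def save_raster(
    raster: HeatmapRaster,
    stem: str | Path,
    background: np.ndarray | None = None,
    meta: dict | None = None,
) -> None:
    """Write value/coverage TIFF planes, a PNG overlay, and run metadata."""
    import tifffile
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(f"{stem}_values.tif", raster.values.astype(np.float32))
    tifffile.imwrite(f"{stem}_coverage.tif", raster.coverage.astype(np.int32))
    fig, ax = plt.subplots(figsize=(6, 6))
    if background is not None:
        ax.imshow(background)
    symmetric = np.nanmin(raster.values) < 0 if raster.defined().any() else False
    kw = {"vmin": -1, "vmax": 1} if symmetric else {"vmin": 0, "vmax": 1}
    im = ax.imshow(raster.values, cmap="coolwarm", alpha=0.6, **kw)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_axis_off()
    fig.savefig(f"{stem}_overlay.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
    info = {"scale": raster.scale, "step": raster.step, "tissue_threshold": HEATMAP_TISSUE_MIN}
    info.update(meta or {})
    Path(f"{stem}_meta.json").write_text(json.dumps(info, indent=2))
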