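"""Training-time augmentation: slide-level HSV color jitter + patch flips/rotations.

Color augmentation is shared across a mini-batch: because every mini-batch
holds patches from a single slide, one set of HSV affine parameters is drawn
per slide per iteration and applied to all of its patches, emulating
slide-to-slide staining variation rather than per-patch noise. Each HSV
channel c (values in [0, 1]) is mapped to alpha_c * I_c + beta_c with
alpha_c ~ U(1 - sigma, 1 + sigma) and beta_c ~ U(-sigma, sigma); the default
augmentation degree is sigma = 0.05. Channels are clipped back to [0, 1]
after the affine map (hue may optionally wrap circularly instead).

Geometric augmentation is per patch: a flip with probability 1/2 (vertical
or horizontal, equiprobable) and an independent rotation drawn uniformly
from {0, 90, 180, 270} degrees.

Augmentation applies during training only — never at inference, evaluation
or heatmap time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorconv import hsv_to_rgb, rgb_to_hsv

DEFAULT_SIGMA = 0.05


@dataclass(frozen=True)
class ColorAugParams:
    """One slide-level draw of HSV affine jitter: channel order (H, S, V)."""

    alpha: tuple[float, float, float]
    beta: tuple[float, float, float]

    @property
    def is_identity(self) -> bool:
        return all(a == 1.0 for a in self.alpha) and all(b == 0.0 for b in self.beta)


@dataclass(frozen=True)
class GeomAugParams:
    flip: bool
    flip_axis: int  # 0 = vertical (up/down), 1 = horizontal (left/right)
    rotations: int  # number of 90-degree CCW turns, in {0, 1, 2, 3}


def sample_color_params(
    sigma: float = DEFAULT_SIGMA, rng: np.random.Generator | None = None
) -> ColorAugParams:
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    rng = rng or np.random.default_rng()
    alpha = rng.uniform(1.0 - sigma, 1.0 + sigma, size=3)
    beta = rng.uniform(-sigma, sigma, size=3)
    return ColorAugParams(alpha=tuple(alpha.tolist()), beta=tuple(beta.tolist()))


def sample_geom_params(rng: np.random.Generator | None = None) -> GeomAugParams:
    rng = rng or np.random.default_rng()
    flip = bool(rng.random() < 0.5)
    flip_axis = int(rng.integers(0, 2))
    rotations = int(rng.integers(0, 4))
    return GeomAugParams(flip=flip, flip_axis=flip_axis, rotations=rotations)


def apply_color_aug(
    pixels: np.ndarray, params: ColorAugParams, circular_hue: bool = False
) -> np.ndarray:
    """HSV affine jitter on a uint8 RGB patch; exact identity when untouched."""
    pixels = np.asarray(pixels)
    if params.is_identity:
        return pixels.copy()
    hsv = rgb_to_hsv(pixels.astype(np.float32) / 255.0)
    alpha = np.asarray(params.alpha, dtype=np.float32)
    beta = np.asarray(params.beta, dtype=np.float32)
    hsv = hsv * alpha + beta
    if circular_hue:
        hsv[..., 0] = np.mod(hsv[..., 0], 1.0)
        hsv[..., 1:] = np.clip(hsv[..., 1:], 0.0, 1.0)
    else:
        hsv = np.clip(hsv, 0.0, 1.0)
    rgb = hsv_to_rgb(hsv)
    return np.rint(rgb * 255.0).astype(np.uint8)


def apply_geom(pixels: np.ndarray, params: GeomAugParams) -> np.ndarray:
    out = pixels
    if params.flip:
        out = np.flip(out, axis=params.flip_axis)
    if params.rotations:
        out = np.rot90(out, k=params.rotations, axes=(0, 1))
    return np.ascontiguousarray(out)


def apply_geometric_aug(
    pixels: np.ndarray, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Random flip (p = 1/2) plus uniform 90-degree rotation of a square patch."""
    if pixels.shape[0] != pixels.shape[1]:
        raise ValueError("geometric augmentation expects a square patch")
    return apply_geom(pixels, sample_geom_params(rng))


def augment_batch(
    batch: np.ndarray,
    color: ColorAugParams,
    rng: np.random.Generator,
    circular_hue: bool = False,
) -> tuple[np.ndarray, list[GeomAugParams]]:
    """Augment a (n, H, W, 3) slide batch: shared color params, per-patch geometry.

    Returns the augmented batch and the per-patch geometric draws (useful for
    instrumentation and reproducibility checks).
    """
    colored = apply_color_aug(batch, color, circular_hue)  # one draw, whole bag
    out = np.empty_like(batch)
    geoms: list[GeomAugParams] = []
    for i in range(batch.shape[0]):
        g = sample_geom_params(rng)
        geoms.append(g)
        out[i] = apply_geom(colored[i], g)
    return out, geoms
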