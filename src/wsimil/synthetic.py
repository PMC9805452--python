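"""Synthetic multi-resolution H&E-like cohorts with plantable class signal.

The generator emulates the structure the pipeline consumes — patient-grouped
slides, two classes, background whitespace, artifacts, per-lab staining
shifts — without attempting photo-realism. Tissue is a flat eosin-pink base
plus smooth low-frequency "cellularity" variation and fine per-pixel
speckle, constructed so that tissue luminance stays inside the informative
[40, 215] greyscale band while background stays above it. The class signal
is plantable and optionally scale-dependent:

* ``blob_density`` — bright microcyst-like blobs whose expected count per
  slide is (1 + effect_size) times higher in class 1. With
  ``signal_scale="coarse"`` the blobs are broad low-contrast Gaussian bumps
  that survive area-downsampling to 2.5x while staying near the speckle
  floor at 20x; ``"fine"`` plants small hard-edged discs that wash out at
  low magnification; ``"both"`` sits in between.
* ``color_shift`` — a small class-dependent hue/saturation offset.

Per-"lab" batch effects reuse the HSV affine machinery of the augmentation
module with a fixed per-lab draw. Slides are written in the flat dialect
(one raster plane + JSON sidecar) plus a cohort manifest CSV.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import augment
from .tiling import SlideRecord

# channel clip bounds keeping tissue luminance strictly inside [40, 215]
TISSUE_CHANNEL_LO = 48
TISSUE_CHANNEL_HI = 213
BACKGROUND_VALUE = 255

#: signal geometry per scale regime: (blob radius in base pixels, contrast,
#: hard edge?, density multiplier). Coarse bumps are smooth and low-contrast
#: relative to the fine per-pixel speckle: area-averaging to low
#: magnification attenuates the speckle ~8-fold while the bumps pass
#: through, so the signal stands clear at 2.5x and sits near the noise
#: floor at native resolution. Fine discs are small and sharp: resolvable
#: at high power, washed out at low power.
SIGNAL_GEOMETRY = {
    "coarse": (48.0, 16.0, False, 1.0),
    "fine": (4.0, 40.0, True, 1.0),
    "both": (16.0, 18.0, False, 1.0),
}


@dataclass
class SyntheticSpec:
    n_patients: int = 70
    slides_per_patient: tuple[int, int] = (1, 1)
    class_balance: float = 0.5
    plane_size: int = 2048
    base_magnification: float = 20.0
    tissue_coverage: float = 1.0
    signal_type: str = "blob_density"
    effect_size: float = 1.5
    signal_scale: str = "both"
    base_blob_rate: float = 30.0  # expected blobs per 1024x1024 base pixels, class 0
    speckle_sigma: float = 14.0
    cellularity_sigma: float = 8.0
    nuisance_strength: float = 1.0
    tint_sigma: float = 6.0  # per-channel sd of the label-independent stain tint
    batch_effect_strength: float = 0.0
    n_labs: int = 2
    pen_rate: float = 0.0
    blur_rate: float = 0.0
    rng_seed: int = 0
    format: str = "tif"

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not 0.0 < self.tissue_coverage <= 1.0:
            raise ValueError("tissue_coverage must be in (0, 1]")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError("class_balance must be a probability")
        if self.signal_scale not in SIGNAL_GEOMETRY:
            raise ValueError(f"signal_scale must be one of {sorted(SIGNAL_GEOMETRY)}")


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of the cohort seed."""
    return np.random.default_rng([seed % (2**31), zlib.crc32(name.encode())])


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

EOSIN_BASE = np.array([196.0, 148.0, 176.0])  # luminance ~ 166


def _tissue_mask_region(size: int, coverage: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean tissue region: full plane, or a random union of discs."""
    if coverage >= 1.0:
        return np.ones((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    mask = np.zeros((size, size), dtype=bool)
    target = coverage * size * size
    r = size * 0.28
    while mask.sum() < target:
        cy, cx = rng.uniform(r * 0.7, size - r * 0.7, size=2)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


def _add_blob(lum: np.ndarray, cy: float, cx: float, radius: float, contrast: float, hard: bool) -> None:
    size = lum.shape[0]
    pad = int(np.ceil(radius * (1.0 if hard else 3.0))) + 1
    y0, y1 = max(0, int(cy) - pad), min(size, int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(size, int(cx) + pad + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    if hard:
        lum[y0:y1, x0:x1] += contrast * (d2 <= radius**2)
    else:
        lum[y0:y1, x0:x1] += contrast * np.exp(-0.5 * d2 / radius**2)


def render_slide_plane(spec: SyntheticSpec, label: int, rng: np.random.Generator) -> np.ndarray:
    """One base-magnification RGB plane with the class signal planted."""
    size = spec.plane_size
    region = _tissue_mask_region(size, spec.tissue_coverage, rng)
    # label-independent per-slide nuisances: staining tint, cellularity and
    # speckle amplitude, blob size. Real cohorts vary along many such axes;
    # without them every random embedding projection would align with the
    # single planted-signal axis and null controls could not sit at chance.
    ns = spec.nuisance_strength
    tint = rng.normal(0.0, spec.tint_sigma * ns, size=3)
    cell_amp = spec.cellularity_sigma * (1.0 + ns * rng.uniform(-0.5, 0.5))
    speckle_amp = spec.speckle_sigma * (1.0 + ns * rng.uniform(-0.25, 0.25))
    radius_jitter = 1.0 + ns * rng.uniform(-0.2, 0.2)
    # luminance modulation: smooth cellularity field + fine speckle, plus a
    # label-independent medium-scale field (correlation ~128 px). The medium
    # field gives every high-magnification patch a nuisance mean offset far
    # larger than any single bump's contribution, so patch-mean brightness
    # carries no class information at 20x.
    coarse = rng.normal(0.0, 1.0, (size // 32 + 1, size // 32 + 1))
    cellularity = gaussian_filter(np.kron(coarse, np.ones((32, 32)))[:size, :size], 16.0)
    cellularity *= cell_amp / max(cellularity.std(), 1e-9)
    med = rng.normal(0.0, 1.0, (size // 64 + 1, size // 64 + 1))
    medium = gaussian_filter(np.kron(med, np.ones((64, 64)))[:size, :size], 48.0)
    medium *= (3.0 * ns) / max(medium.std(), 1e-9)
    lum = cellularity + medium + rng.normal(0.0, speckle_amp, (size, size))
    # planted blobs
    if spec.signal_type == "blob_density":
        radius, contrast, hard, rate_mult = SIGNAL_GEOMETRY[spec.signal_scale]
        rate = spec.base_blob_rate * rate_mult * (size / 1024.0) ** 2 * spec.tissue_coverage
        if label == 1:
            rate *= 1.0 + spec.effect_size
        for _ in range(rng.poisson(rate)):
            cy, cx = rng.uniform(0, size, size=2)
            _add_blob(lum, cy, cx, radius * radius_jitter, contrast, hard)
    # zero-center the modulation: blob density must be a textural signal,
    # not a slide-mean brightness offset (which would survive any downsample)
    lum -= lum.mean()
    plane = EOSIN_BASE[None, None, :] + tint[None, None, :] + lum[:, :, None]
    if spec.signal_type == "color_shift" and label == 1:
        # small eosin->hematoxylin tint: move red down, blue up
        shift = 6.0 * spec.effect_size
        plane[..., 0] -= shift
        plane[..., 2] += shift
    plane = np.clip(plane, TISSUE_CHANNEL_LO, TISSUE_CHANNEL_HI)
    out = np.full((size, size, 3), float(BACKGROUND_VALUE))
    out[region] = plane[region]
    return out.astype(np.uint8)


def _apply_pen_mark(plane: np.ndarray, rng: np.random.Generator) -> None:
    """A saturated marker stroke (grey value inside the tissue band, so only
    the pen rule can reject it)."""
    size = plane.shape[0]
    color = [(0, 200, 30), (20, 60, 220), (220, 20, 30)][int(rng.integers(0, 3))]
    cy, cx = rng.uniform(size * 0.2, size * 0.8, size=2)
    r = size * 0.08
    yy, xx = np.mgrid[0:size, 0:size]
    stroke = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    plane[stroke] = color


def _apply_blur_region(plane: np.ndarray, rng: np.random.Generator) -> None:
    size = plane.shape[0]
    s = size // 3
    y0 = int(rng.integers(0, size - s))
    x0 = int(rng.integers(0, size - s))
    sub = plane[y0 : y0 + s, x0 : x0 + s].astype(np.float64)
    plane[y0 : y0 + s, x0 : x0 + s] = np.rint(
        gaussian_filter(sub, sigma=(6, 6, 0))
    ).astype(np.uint8)


def _lab_color_params(strength: float, lab: int, seed: int) -> augment.ColorAugParams:
    rng = substream(seed, f"lab-{lab}")
    return augment.sample_color_params(strength, rng)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(spec: SyntheticSpec, outdir: str | Path) -> pd.DataFrame:
    """Write a flat-dialect cohort; return (and save) the manifest.

    Manifest columns: slide_id, patient_id, label, lab, path,
    base_magnification. Labels are assigned per patient; all slides of a
    patient share the label and lab.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geom = substream(spec.rng_seed, "cohort")
    # exact class composition (a designed cohort), in shuffled patient order
    n_mut = int(round(spec.n_patients * spec.class_balance))
    labels = np.zeros(spec.n_patients, dtype=int)
    labels[:n_mut] = 1
    labels = labels[geom.permutation(spec.n_patients)]
    rows = []
    for p in range(spec.n_patients):
        patient_id = f"P{p:04d}"
        label = int(labels[p])
        lab = int(geom.integers(0, max(spec.n_labs, 1)))
        lo, hi = spec.slides_per_patient
        n_slides = int(geom.integers(lo, hi + 1))
        for s in range(n_slides):
            slide_id = f"{patient_id}S{s}"
            srng = substream(spec.rng_seed, f"slide-{slide_id}")
            plane = render_slide_plane(spec, label, srng)
            if spec.batch_effect_strength > 0:
                params = _lab_color_params(spec.batch_effect_strength, lab, spec.rng_seed)
                plane = augment.apply_color_aug(plane, params)
            if srng.random() < spec.pen_rate:
                _apply_pen_mark(plane, srng)
            if srng.random() < spec.blur_rate:
                _apply_blur_region(plane, srng)
            path = outdir / f"{slide_id}.{spec.format}"
            _write_plane(plane, path)
            path.with_suffix(".json").write_text(
                json.dumps(
                    {
                        "slide_id": slide_id,
                        "patient_id": patient_id,
                        "label": label,
                        "base_magnification": spec.base_magnification,
                        "lab": lab,
                    }
                )
            )
            rows.append(
                {
                    "slide_id": slide_id,
                    "patient_id": patient_id,
                    "label": label,
                    "lab": lab,
                    "path": str(path),
                    "base_magnification": spec.base_magnification,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    (outdir / "spec.json").write_text(json.dumps(asdict(spec), indent=2))
    return manifest


def _write_plane(plane: np.ndarray, path: Path) -> None:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, plane, photometric="rgb")
    else:
        from PIL import Image

        Image.fromarray(plane).save(path)


def records_from_manifest(manifest: pd.DataFrame) -> list[SlideRecord]:
    return [
        SlideRecord(
            slide_id=r.slide_id,
            patient_id=r.patient_id,
            label=int(r.label),
            path=Path(r.path),
            base_magnification=float(r.base_magnification),
        )
        for r in manifest.itertuples()
    ]


def load_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# synthetic expert scores
# ---------------------------------------------------------------------------


@dataclass
class ExpertProfile:
    """Signal-to-noise description of one simulated rater."""

    pathologist_id: str
    snr: float = 2.0
    noise_sd: float = 1.0


def generate_expert_scores(
    manifest: pd.DataFrame,
    profiles: list[ExpertProfile],
    rng: np.random.Generator | None = None,
    shared_sd: float = 1.0,
) -> pd.DataFrame:
    """Semiquantitative scores in [0, 1] correlated with the slide labels.

    Each slide has a latent signal u = +/-1 from its label plus a shared
    "case difficulty" noise term (common to all raters, controlling
    inter-rater correlation); each rater adds private noise and squashes
    through a logistic, so score = sigmoid(snr * u + shared + private).
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for r in manifest.itertuples():
        u = 2.0 * float(r.label) - 1.0
        shared = rng.normal(0.0, shared_sd)
        for prof in profiles:
            z = prof.snr * u + shared + rng.normal(0.0, prof.noise_sd)
            rows.append(
                {
                    "slide_id": r.slide_id,
                    "pathologist_id": prof.pathologist_id,
                    "score": float(1.0 / (1.0 + np.exp(-z))),
                }
            )
    return pd.DataFrame(rows)
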