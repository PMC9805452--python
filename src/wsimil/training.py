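"""Single-scale model training: one-WSI mini-batches, balanced epochs,
best-validation checkpointing.

Each optimizer step consumes one slide: up to ``patches_per_step`` (default
200) qualifying patches are drawn without replacement from that slide, a
single slide-level color-augmentation draw plus per-patch flips/rotations
are applied, and one Adam update is taken against the binary cross-entropy
of the slide probability. Epoch rosters are class-balanced: every epoch
takes all minority-class slides (or a fixed per-class count) and a fresh
random subset of the majority class. After each epoch the mean validation
loss is computed without augmentation; the checkpoint with the lowest
validation loss is retained (earliest epoch wins ties).

Paper-faithful defaults: 200 patches per step, 140 slides per class per
epoch, Adam at learning rate 1e-5, at most 100 epochs, three replicate
seeds. Desk-scale configurations shrink the per-class counts to the
smallest class and raise the learning rate for the compact backbone.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import augment, nn
from .model import MILModel
from .tiling import ArtifactConfig, Patch, open_slide, tile_slide, SlideRecord

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    scale: float = 10.0
    seed: int = 0
    patches_per_step: int = 200
    n_per_class: int = 140  # slides per class per epoch; auto-shrinks
    learning_rate: float = 1e-5
    adam_betas: tuple[float, float] = (0.9, 0.999)
    max_epochs: int = 100
    checkpoint_rule: str = "best_val"  # or "last": keep the final epoch
    embed_dim: int = 64
    backbone: str = "tiny_cnn"
    sigma: float = augment.DEFAULT_SIGMA
    enable_color_aug: bool = True
    enable_geom_aug: bool = True
    circular_hue: bool = False
    val_patch_cap: int = 500

    def __post_init__(self) -> None:
        if self.patches_per_step < 1:
            raise ValueError("patches_per_step must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class Checkpoint:
    state: dict[str, np.ndarray]
    epoch: int
    val_loss: float
    config: TrainConfig

    def to_model(self) -> MILModel:
        model = MILModel(
            d=self.config.embed_dim, backbone=self.config.backbone, seed=self.config.seed
        )
        model.load_state_dict(self.state)
        return model

    def save(self, path: str | Path) -> None:
        model = self.to_model()
        model.save(
            path,
            meta={
                "scale": self.config.scale,
                "seed": self.config.seed,
                "D": self.config.embed_dim,
                "backbone_name": self.config.backbone,
                "epoch": self.epoch,
                "val_loss": self.val_loss,
            },
        )


class PatchStore:
    """Caches each slide's qualifying patch pixels per scale.

    Tiling a slide is deterministic, so the cache is purely an efficiency
    device; entries are uint8 stacks shaped (n_patches, 256, 256, 3).
    """

    def __init__(
        self,
        records: list[SlideRecord],
        artifact_rules: ArtifactConfig | None = None,
        preloaded: dict[tuple[str, float], np.ndarray] | None = None,
    ) -> None:
        self.records = {r.slide_id: r for r in records}
        self.rules = artifact_rules or ArtifactConfig()
        self._cache: dict[tuple[str, float], np.ndarray] = dict(preloaded or {})

    def patches(self, slide_id: str, scale: float) -> np.ndarray:
        key = (slide_id, scale)
        if key not in self._cache:
            rec = self.records[slide_id]
            slide = open_slide(rec.path, rec.base_magnification)
            tiles = tile_slide(slide, scale, self.rules)
            if tiles:
                self._cache[key] = np.stack([p.pixels for p in tiles])
            else:
                self._cache[key] = np.empty((0, 256, 256, 3), dtype=np.uint8)
        return self._cache[key]


def build_epoch_roster(
    slides: list[SlideRecord], cfg: TrainConfig, rng: np.random.Generator
) -> list[SlideRecord]:
    """Class-balanced, shuffled slide roster for one epoch.

    Takes ``n = min(cfg.n_per_class, smallest class size)`` slides per class.
    When a class holds exactly n slides all of them are used every epoch
    (so a 140-slide minority class is used in full); larger classes are resampled afresh.
    """
    by_class = {0: [s for s in slides if s.label == 0], 1: [s for s in slides if s.label == 1]}
    for lbl, group in by_class.items():
        if not group:
            raise ValueError(f"cannot build a balanced epoch: class {lbl} has no slides")
    n = min(cfg.n_per_class, len(by_class[0]), len(by_class[1]))
    roster: list[SlideRecord] = []
    for group in by_class.values():
        if len(group) == n:
            roster.extend(group)
        else:
            idx = rng.choice(len(group), size=n, replace=False)
            roster.extend(group[i] for i in idx)
    order = rng.permutation(len(roster))
    return [roster[i] for i in order]


def training_step(
    model: MILModel,
    optimizer: nn.Adam,
    batch_pixels: np.ndarray,
    label: int,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[float, dict]:
    """One optimizer update from one slide's patch bag; returns (loss, info).

    ``info`` exposes the slide-level color draw and per-patch geometric draws
    so tests can assert the parameter-sharing contract.
    """
    n = batch_pixels.shape[0]
    if n == 0:
        raise ValueError("training_step requires at least one qualifying patch")
    m = min(cfg.patches_per_step, n)
    idx = rng.choice(n, size=m, replace=False)
    batch = batch_pixels[idx]
    color = (
        augment.sample_color_params(cfg.sigma, rng)
        if cfg.enable_color_aug
        else augment.ColorAugParams((1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
    )
    if cfg.enable_geom_aug:
        batch, geoms = augment.augment_batch(batch, color, rng, cfg.circular_hue)
    else:
        geoms = []
        if not color.is_identity:
            batch = np.stack(
                [augment.apply_color_aug(b, color, cfg.circular_hue) for b in batch]
            )
    model.zero_grad()
    loss, prob = model.loss_and_grads(batch, label)
    optimizer.step(model.named_grads())
    info = {"batch_size": m, "color_params": color, "geom_params": geoms, "prob": prob}
    return loss, info


def _stable_slide_seed(base_seed: int, slide_id: str) -> int:
    return (base_seed * 1_000_003 + zlib.crc32(slide_id.encode())) % (2**31)


def slide_probability(
    model: MILModel,
    pixels: np.ndarray,
    patch_cap: int,
    base_seed: int,
    slide_id: str,
) -> float:
    """Inference-time slide score: all qualifying patches, deterministically
    capped at ``patch_cap`` by a per-slide seeded subsample."""
    n = pixels.shape[0]
    if n == 0:
        raise ValueError(f"slide {slide_id} has no qualifying patches")
    if n > patch_cap:
        rng = np.random.default_rng(_stable_slide_seed(base_seed, slide_id))
        idx = np.sort(rng.choice(n, size=patch_cap, replace=False))
        pixels = pixels[idx]
    emb = model.encode_patches(pixels)
    return model.predict_slide(emb)


def validate(
    model: MILModel, slides: list[SlideRecord], store: PatchStore, cfg: TrainConfig
) -> float:
    """Mean BCE over validation slides, no augmentation."""
    losses = []
    for rec in slides:
        pixels = store.patches(rec.slide_id, cfg.scale)
        if pixels.shape[0] == 0:
            log.warning("validation slide %s has no qualifying patches", rec.slide_id)
            continue
        p = slide_probability(model, pixels, cfg.val_patch_cap, cfg.seed, rec.slide_id)
        losses.append(nn.bce_loss(p, float(rec.label)))
    if not losses:
        raise ValueError("no validation slide produced a prediction")
    return float(np.mean(losses))


def fit(
    train: list[SlideRecord],
    val: list[SlideRecord],
    cfg: TrainConfig,
    store: PatchStore | None = None,
    log_path: str | Path | None = None,
) -> Checkpoint:
    """Train one single-scale model; return the best-validation checkpoint."""
    if not train or not val:
        raise ValueError("fit requires non-empty train and validation sets")
    store = store or PatchStore(train + val)
    rng = np.random.default_rng(cfg.seed)
    model = MILModel(d=cfg.embed_dim, backbone=cfg.backbone, seed=cfg.seed)
    optimizer = nn.Adam(
        model.trainable_params(), lr=cfg.learning_rate, betas=cfg.adam_betas
    )
    best: Checkpoint | None = None
    history = []
    for epoch in range(1, cfg.max_epochs + 1):
        roster = build_epoch_roster(train, cfg, rng)
        epoch_losses = []
        for rec in roster:
            pixels = store.patches(rec.slide_id, cfg.scale)
            if pixels.shape[0] == 0:
                log.warning("skipping slide %s: no qualifying patches", rec.slide_id)
                continue
            loss, _ = training_step(model, optimizer, pixels, rec.label, cfg, rng)
            epoch_losses.append(loss)
        val_loss = validate(model, val, store, cfg)
        if not np.isfinite(val_loss):
            raise FloatingPointError(
                f"validation loss became non-finite at epoch {epoch}"
            )
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)) if epoch_losses else float("nan"),
            "val_loss": val_loss,
        }
        history.append(entry)
        log.info("epoch %d train %.4f val %.4f", epoch, entry["train_loss"], val_loss)
        take = (
            best is None
            or cfg.checkpoint_rule == "last"
            or val_loss < best.val_loss  # ties keep the earliest epoch
        )
        if take:
            best = Checkpoint(model.state_dict(), epoch, val_loss, cfg)
    if log_path is not None:
        Path(log_path).write_text(
            "\n".join(json.dumps(e) for e in history) + "\n"
        )
    best.history = history
    return best


def predict_slides(
    model: MILModel,
    slides: list[SlideRecord],
    store: PatchStore,
    scale: float,
    seed: int,
    patch_cap: int = 500,
) -> pd.DataFrame:
    """Slide-level probabilities for a trained model (no augmentation)."""
    rows = []
    for rec in slides:
        pixels = store.patches(rec.slide_id, scale)
        if pixels.shape[0] == 0:
            log.warning("skipping slide %s: no qualifying patches", rec.slide_id)
            continue
        p = slide_probability(model, pixels, patch_cap, seed, rec.slide_id)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "slide_id": rec.slide_id,
                "scale": scale,
                "seed": seed,
                "label": rec.label,
                "score": p,
            }
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "slide_id", "scale", "seed", "label", "score"]
    )
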