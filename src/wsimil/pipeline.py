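"""Stage-wise end-to-end pipeline over file artifacts.

Stages run in dependency order — synth -> tile -> train -> predict ->
ensemble -> evaluate -> heatmap -> umap — each reading its inputs from and
writing its outputs to the run directory, so a run is crash-resumable and
every artifact is traceable to the stored config copy and hash.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import ensembling, embedviz, evalstats, heatmap as hm, synthetic, training
from .config import RunConfig, split_cohort
from .model import MILModel
from .tiling import open_slide, tile_plane
from .training import PatchStore, TrainConfig

log = logging.getLogger(__name__)

STAGES = ("synth", "tile", "train", "predict", "ensemble", "evaluate", "heatmap", "umap")


class MissingArtifact(RuntimeError):
    def __init__(self, path: Path, stage: str) -> None:
        super().__init__(
            f"missing artifact {path}; run the {stage!r} stage first"
        )


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise MissingArtifact(path, producing_stage)
    return path


def _records_by_split(root: Path):
    splits = pd.read_csv(_require(root / "splits.csv", "tile"))
    recs = synthetic.records_from_manifest(splits)
    by = {}
    for rec, split in zip(recs, splits["split"]):
        by.setdefault(split, []).append(rec)
    return splits, by


def _train_cfg(cfg: RunConfig, scale: float, seed: int) -> TrainConfig:
    return TrainConfig(scale=scale, seed=seed, **cfg.train)


def run_pipeline(cfg: RunConfig, stages=STAGES) -> dict:
    """Execute the requested stage subset in dependency order."""
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]
    root = Path(cfg.out_root)
    root.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(root / "runconfig.yaml")
    (root / "config_hash.txt").write_text(cfg.config_hash() + "\n")
    timings = {}
    for stage in stages:
        t0 = time.time()
        globals()[f"stage_{stage}"](cfg, root)
        timings[stage] = round(time.time() - t0, 2)
        log.info("stage %s done in %.1fs", stage, timings[stage])
    (root / "timings.json").write_text(json.dumps(timings, indent=2))
    return timings


def stage_synth(cfg: RunConfig, root: Path) -> None:
    spec = synthetic.SyntheticSpec(rng_seed=cfg.seed, **cfg.synthetic)
    synthetic.generate_cohort(spec, root / "cohort")
    manifest = synthetic.load_manifest(root / "cohort" / "manifest.csv")
    scores = synthetic.generate_expert_scores(
        manifest,
        [
            synthetic.ExpertProfile(f"SP{i + 1}", snr=s)
            for i, s in enumerate(cfg.expert_snrs)
        ],
        rng=np.random.default_rng([cfg.seed % (2**31), 17]),
    )
    scores.to_csv(root / "expert_scores.csv", index=False)


def stage_tile(cfg: RunConfig, root: Path) -> None:
    manifest = synthetic.load_manifest(
        _require(root / "cohort" / "manifest.csv", "synth")
    )
    splits = split_cohort(
        manifest, cfg.split_fractions, seed=cfg.seed, balance=cfg.split_balance
    )
    splits.to_csv(root / "splits.csv", index=False)
    manifests = []
    for rec in synthetic.records_from_manifest(manifest):
        slide = open_slide(rec.path, rec.base_magnification)
        for scale in cfg.scales:
            _, m = tile_plane(slide.plane(scale), rec.slide_id, scale)
            manifests.append(m)
    pd.concat(manifests, ignore_index=True).to_csv(
        root / "patch_manifest.csv", index=False
    )


def stage_train(cfg: RunConfig, root: Path) -> None:
    _, by = _records_by_split(root)
    ckdir = root / "checkpoints"
    ckdir.mkdir(exist_ok=True)
    store = PatchStore(by["train"] + by["val"])
    for scale in cfg.scales:
        for seed in cfg.seeds:
            tc = _train_cfg(cfg, scale, seed)
            ck = training.fit(
                by["train"],
                by["val"],
                tc,
                store,
                log_path=ckdir / f"scale{scale:g}_seed{seed}.log.jsonl",
            )
            ck.save(ckdir / f"scale{scale:g}_seed{seed}")


def stage_predict(cfg: RunConfig, root: Path) -> None:
    _, by = _records_by_split(root)
    store = PatchStore(by["test"])
    frames = []
    for scale in cfg.scales:
        for seed in cfg.seeds:
            path = root / "checkpoints" / f"scale{scale:g}_seed{seed}"
            _require(path.with_suffix(".npz"), "train")
            model = MILModel.load(path)
            frames.append(
                training.predict_slides(model, by["test"], store, scale, seed)
            )
    (root / "predictions").mkdir(exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(
        root / "predictions" / "raw.csv", index=False, float_format="%.10g"
    )


def stage_ensemble(cfg: RunConfig, root: Path) -> None:
    raw = pd.read_csv(_require(root / "predictions" / "raw.csv", "predict"))
    slide_variants = ensembling.ensemble_table(raw)
    experts_path = root / "expert_scores.csv"
    if experts_path.exists():
        experts = pd.read_csv(experts_path)
        experts = experts[experts["slide_id"].isin(slide_variants["slide_id"])]
        slide_variants = ensembling.attach_expert_variants(slide_variants, experts)
    slide_variants.to_csv(
        root / "predictions" / "slide_variants.csv", index=False, float_format="%.10g"
    )
    ensembling.patient_table(slide_variants).to_csv(
        root / "predictions" / "patient_variants.csv", index=False, float_format="%.10g"
    )


def stage_evaluate(cfg: RunConfig, root: Path) -> None:
    (root / "eval").mkdir(exist_ok=True)
    for level, fname in (("slide", "slide_variants.csv"), ("patient", "patient_variants.csv")):
        table = pd.read_csv(_require(root / "predictions" / fname, "ensemble"))
        report = evalstats.evaluate_variants(
            table,
            level=level,
            reps=cfg.bootstrap_reps,
            rng=np.random.default_rng([cfg.seed % (2**31), 23]),
        )
        report.to_json(root / "eval" / f"report_{level}.json")
        report.to_frame().to_csv(root / "eval" / f"report_{level}.csv", index=False)
        evalstats.plot_roc(table, root / "eval" / f"roc_{level}.png", title=level)


def _ensemble_predictor(models):
    def predict(stack):
        return np.mean([m.predict_pixel_batch(stack) for m in models], axis=0)

    return predict


def stage_heatmap(cfg: RunConfig, root: Path) -> None:
    _, by = _records_by_split(root)
    rec = by["test"][0]  # demonstration heatmaps for the first test slide
    slide = open_slide(rec.path, rec.base_magnification)
    rasters = {}
    outdir = root / "heatmaps"
    for scale in cfg.heatmap_scales:
        models = [
            MILModel.load(
                _require(
                    (root / "checkpoints" / f"scale{scale:g}_seed{seed}").with_suffix(".npz"),
                    "train",
                ).with_suffix("")
            )
            for seed in cfg.seeds
        ]
        raster = hm.render_heatmap(slide.plane(scale), _ensemble_predictor(models), scale)
        rasters[scale] = raster
        hm.save_raster(
            raster,
            outdir / f"{rec.slide_id}_scale{scale:g}",
            background=slide.plane(scale),
            meta={"slide_id": rec.slide_id},
        )
    if {20.0, 2.5} <= set(rasters):
        diff = hm.scale_difference(rasters[20.0], rasters[2.5])
        hm.save_raster(diff, outdir / f"{rec.slide_id}_diff_20x_minus_2.5x")


def stage_umap(cfg: RunConfig, root: Path) -> None:
    _, by = _records_by_split(root)
    store = PatchStore(by["test"])
    # best 10x model by validation loss
    best_path, best_loss = None, np.inf
    for seed in cfg.seeds:
        path = root / "checkpoints" / f"scale10_seed{seed}"
        _require(path.with_suffix(".json"), "train")
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta["val_loss"] < best_loss:
            best_path, best_loss = path, meta["val_loss"]
    model = MILModel.load(best_path)
    stack, prov = embedviz.sample_patches_for_projection(
        by["test"], store, rng=np.random.default_rng([cfg.seed % (2**31), 29])
    )
    slide_scores = {}
    var_path = root / "predictions" / "slide_variants.csv"
    if var_path.exists():
        sv = pd.read_csv(var_path)
        mse = sv[sv["variant"] == "mse"]
        slide_scores = dict(zip(mse["slide_id"], mse["score"]))
    table, used = embedviz.project_embeddings(
        model, stack, prov, slide_scores, method=cfg.projection_method,
        random_state=cfg.seed % (2**31),
    )
    outdir = root / "umap"
    outdir.mkdir(exist_ok=True)
    table.to_csv(outdir / "projection.csv", index=False, float_format="%.10g")
    (outdir / "projection_meta.json").write_text(json.dumps(used, indent=2, default=str))
    embedviz.plot_projection(table, outdir / "projection")
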