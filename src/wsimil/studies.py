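"""Desk-scale simulation studies exercising the full pipeline.

These protocols reproduce, on synthetic cohorts, the qualitative findings
the method is built around: a planted class signal is recoverable from
weak slide-level supervision; the magnification that matches the signal's
spatial scale wins; label-permuted training collapses to chance; and
averaging a model with an independent expert beats either alone.

Problem sizes are chosen for a single CPU: 70 one-slide patients (40
train / 10 val / 20 test after a balanced split), 2048-pixel base planes at
nominal 20x, a 32-wide compact backbone trained for 6 epochs at learning
rate 3e-3 — the paper-scale hyperparameters (DenseNet-width embeddings, lr
1e-5, 100 epochs) remain available in TrainConfig for full-size runs.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import split_cohort
from .evalstats import bootstrap_ci, roc_auc
from .synthetic import (
    ExpertProfile,
    SyntheticSpec,
    generate_cohort,
    generate_expert_scores,
    records_from_manifest,
)
from .training import PatchStore, TrainConfig, fit, predict_slides

#: compact-backbone training settings used by every desk-scale study
DESK_TRAIN = dict(
    learning_rate=3e-3, embed_dim=32, max_epochs=6, val_patch_cap=64, n_per_class=140
)

#: cohort conditions for the planted-signal studies: smooth bumps at a
#: class-1 density of (1 + 3)x, under speckle heavy enough that the signal
#: is clearest after area-averaging to the matched 2.5x magnification
PLANTED_SPEC = dict(
    n_patients=70,
    plane_size=2048,
    base_magnification=20.0,
    signal_scale="coarse",
    effect_size=3.0,
    speckle_sigma=24.0,
)


def _split_records(manifest: pd.DataFrame, seed: int):
    splits = split_cohort(
        manifest,
        {"train": 0.6, "val": 0.15, "test": 0.25},
        seed=seed,
        balance={"val": 5, "test": 10},  # balanced val/test, as in a 30/30 design
    )
    recs = records_from_manifest(splits)
    by: dict[str, list] = {}
    for rec, split in zip(recs, splits["split"]):
        by.setdefault(split, []).append(rec)
    return by


def _test_auc(model, records, store, scale, seed) -> float:
    preds = predict_slides(model, records, store, scale, seed, patch_cap=64)
    return roc_auc(preds["score"], preds["label"])


def _fit_with_restarts(
    train, val, store, scale: float, seed: int, max_restarts: int = 1
):
    """Fit one arm, restarting on optimization failure.

    At this step budget a small fraction of initializations never escape the
    ln 2 loss plateau; such a run is detected by its selected checkpoint
    failing to rank even the slides it was fitted on (AUC over the pooled
    train + validation slides < 0.7 — a sample large enough that the check
    is not defeated by ranking noise) and is rerun with a fresh
    initialization, at most ``max_restarts`` times. The rule sees only
    training-side data, never the test set, and a run that learns on the
    first attempt is bitwise unaffected.
    """
    ck = None
    for attempt in range(max_restarts + 1):
        cfg = TrainConfig(
            scale=scale, seed=(seed + 1000 * attempt) % (2**31), **DESK_TRAIN
        )
        ck = fit(train, val, cfg, store)
        if _test_auc(ck.to_model(), train + val, store, scale, seed) >= 0.7:
            break
    return ck


def planted_signal_study(
    seed: int,
    workdir: str | Path,
    scales: tuple[float, float] = (2.5, 20.0),
    include_null: bool = True,
) -> dict[str, float]:
    """Coarse-signal recovery across magnifications, plus a permuted null.

    Trains one compact model per requested scale on a coarse-signal cohort
    and reports held-out slide-level AUCs; the label-permuted control runs
    on a matched no-signal cohort (see :func:`label_permuted_null`).
    """
    workdir = Path(workdir)
    spec = SyntheticSpec(rng_seed=seed % (2**31), **PLANTED_SPEC)
    manifest = generate_cohort(spec, workdir / "cohort")
    by = _split_records(manifest, seed)
    store = PatchStore(by["train"] + by["val"] + by["test"])
    out: dict[str, float] = {
        "n_train": len(by["train"]),
        "n_val": len(by["val"]),
        "n_test": len(by["test"]),
    }
    for scale in scales:
        ck = _fit_with_restarts(by["train"], by["val"], store, scale, seed % (2**31))
        out[f"auc_{scale:g}x"] = _test_auc(ck.to_model(), by["test"], store, scale, seed)
    if include_null:
        out["auc_label_permuted"] = label_permuted_null(
            seed, workdir / "null_cohort", scale=min(scales)
        )
    return out


def label_permuted_null(
    seed: int,
    workdir: str | Path,
    scale: float = 2.5,
    n_replicates: int = 3,
    n_patients: int = 50,
) -> float:
    """Mean AUC of models trained on permuted labels of a no-signal cohort.

    The control cohort matches the planted-signal design in every respect
    except the planted effect (effect_size = 0, so the two classes are
    exchangeable by construction); training labels are additionally
    permuted. Each replicate draws a fresh permutation and initialization
    and is scored against the cohort's true labels; the mean over
    replicates is reported.

    The control deliberately carries no signal at all rather than permuting
    the signal cohort's labels: a low-capacity network trained for a few
    hundred steps barely moves from its initialization, and on a cohort
    with a strong planted feature the initialization's arbitrary projection
    of that feature still ranks slides — with a random sign — so permuted
    AUCs there measure the initialization, not the pipeline. With no signal
    present, every ranking is label-independent and the classical
    permutation distribution (centered at 1/2) applies.
    """
    spec = SyntheticSpec(
        rng_seed=(seed + 17) % (2**31),
        **{**PLANTED_SPEC, "n_patients": n_patients, "effect_size": 0.0},
    )
    manifest = generate_cohort(spec, Path(workdir))
    splits = split_cohort(manifest, {"train": 0.9, "val": 0.1}, seed=seed, balance={"val": 5})
    recs = records_from_manifest(splits)
    pool_train = [r for r, s in zip(recs, splits["split"]) if s == "train"]
    pool_val = [r for r, s in zip(recs, splits["split"]) if s == "val"]
    store = PatchStore(recs)
    aucs = []
    for k in range(n_replicates):
        rng = np.random.default_rng([seed % (2**31), 101, k])
        pool = pool_train + pool_val
        permuted_labels = rng.permutation([r.label for r in pool])
        permuted = [replace(r, label=int(l)) for r, l in zip(pool, permuted_labels)]
        n_train = len(pool_train)
        cfg = TrainConfig(scale=scale, seed=(seed + 1 + k) % (2**31), **DESK_TRAIN)
        ck = fit(permuted[:n_train], permuted[n_train:], cfg, store)
        aucs.append(_test_auc(ck.to_model(), recs, store, scale, seed))
    return float(np.mean(aucs))


def hybrid_synergy_study(
    seed: int,
    n_replicates: int = 20,
    n_slides: int = 200,
    expert_snr: float = 1.5,
    model_snr: float = 1.5,
) -> pd.DataFrame:
    """Expert + model averaging with independent errors, at the score level.

    Each replicate simulates one cohort: a semiquantitative expert score and
    a model probability are drawn from the same label with *independent*
    noise, and the hybrid is their mean. Columns: expert_auc, model_auc,
    hybrid_auc, gain (hybrid minus the better single rater).
    """
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed % (2**31), 7, rep])
        labels = rng.integers(0, 2, n_slides)
        manifest = pd.DataFrame(
            {"slide_id": [f"s{i}" for i in range(n_slides)], "label": labels}
        )
        expert = generate_expert_scores(
            manifest, [ExpertProfile("E", snr=expert_snr)], rng, shared_sd=0.0
        )["score"].to_numpy()
        model = generate_expert_scores(
            manifest, [ExpertProfile("M", snr=model_snr)], rng, shared_sd=0.0
        )["score"].to_numpy()
        hybrid = (expert + model) / 2.0
        ea, ma, ha = (
            roc_auc(expert, labels),
            roc_auc(model, labels),
            roc_auc(hybrid, labels),
        )
        rows.append(
            {
                "replicate": rep,
                "expert_auc": ea,
                "model_auc": ma,
                "hybrid_auc": ha,
                "gain": ha - max(ea, ma),
            }
        )
    return pd.DataFrame(rows)


def bootstrap_coverage_study(
    seed: int,
    n_datasets: int = 200,
    n_per_class: int = 50,
    mu: float = 1.0,
    reps: int = 1000,
) -> float:
    """Fraction of percentile-bootstrap 95% CIs covering the true AUC.

    Scores follow the binormal model N(0,1) vs N(mu,1), whose true AUC is
    Phi(mu / sqrt(2)) in closed form.
    """
    from scipy.stats import norm

    true_auc = float(norm.cdf(mu / np.sqrt(2.0)))
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    covered = 0
    for i in range(n_datasets):
        rng = np.random.default_rng([seed % (2**31), 13, i])
        scores = np.concatenate(
            [rng.normal(0, 1, n_per_class), rng.normal(mu, 1, n_per_class)]
        )
        lo, hi = bootstrap_ci(scores, labels, reps=reps, rng=rng)
        covered += lo <= true_auc <= hi
    return covered / n_datasets
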