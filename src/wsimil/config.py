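"""Run configuration and patient-disjoint cohort splitting."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tiling import SCALES


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; serialized alongside outputs."""

    out_root: str = "runs/demo"
    seed: int = 0
    scales: tuple[float, ...] = SCALES
    seeds: tuple[int, ...] = (0, 1, 2)
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    split_fractions: dict = field(default_factory=lambda: {"train": 0.6, "val": 0.2, "test": 0.2})
    split_balance: dict = field(default_factory=dict)  # split -> slides per class
    expert_snrs: tuple[float, ...] = (2.0, 2.0)
    heatmap_scales: tuple[float, ...] = (20.0, 2.5)
    bootstrap_reps: int = 1000
    projection_method: str = "umap"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for name in ("scales", "seeds", "expert_snrs", "heatmap_scales"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def split_cohort(
    manifest: pd.DataFrame,
    fractions: dict[str, float] | None = None,
    seed: int = 0,
    balance: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Assign slides to train/val/test with all of a patient's slides together.

    ``fractions`` gives target slide fractions per split. ``balance`` maps a
    split name to an exact per-class slide count (e.g. a balanced test set);
    balanced splits are filled first, the rest proportionally. Raises when a
    balance constraint cannot be met exactly.
    """
    fractions = fractions or {"train": 0.6, "val": 0.2, "test": 0.2}
    balance = balance or {}
    rng = np.random.default_rng(seed)
    patients = (
        manifest.groupby("patient_id")
        .agg(label=("label", "first"), n_slides=("slide_id", "count"))
        .reset_index()
    )
    order = rng.permutation(len(patients))
    patients = patients.iloc[order].reset_index(drop=True)
    assignment: dict[str, str] = {}

    for split, per_class in balance.items():
        for cls in (0, 1):
            need = per_class
            for row in patients.itertuples():
                if row.patient_id in assignment or row.label != cls:
                    continue
                if row.n_slides <= need:
                    assignment[row.patient_id] = split
                    need -= row.n_slides
                if need == 0:
                    break
            if need != 0:
                raise ValueError(
                    f"cannot reach {per_class} class-{cls} slides in split {split!r}"
                )

    open_splits = [s for s in fractions if s not in balance]
    if open_splits:
        weights = np.array([fractions[s] for s in open_splits], dtype=float)
        weights = weights / weights.sum()
        remaining = [r for r in patients.itertuples() if r.patient_id not in assignment]
        total = sum(r.n_slides for r in remaining)
        targets = {s: w * total for s, w in zip(open_splits, weights)}
        filled = {s: 0 for s in open_splits}
        for row in remaining:
            deficits = {s: targets[s] - filled[s] for s in open_splits}
            best = max(open_splits, key=lambda s: deficits[s])
            assignment[row.patient_id] = best
            filled[best] += row.n_slides

    out = manifest.copy()
    out["split"] = out["patient_id"].map(assignment)
    # patient-disjointness is structural; assert it anyway
    check = out.groupby("patient_id")["split"].nunique()
    assert (check == 1).all(), "patient assigned to multiple splits"
    return out
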