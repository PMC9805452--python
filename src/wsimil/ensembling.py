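"""Prediction ensembling: seed averages, the multi-scale ensemble, patient
aggregation, and human-ML hybrid scores.

All combinations are plain arithmetic means, applied in a fixed order:

1. single-scale ensemble — mean over the replicate seeds at one scale;
2. multi-scale ensemble (MSE) — mean of the four single-scale ensembles
   (2.5x, 5x, 10x, 20x), which must all be present;
3. patient level — mean of a patient's slide-level scores (after step 2);
4. expert consensus — mean of the pathologists' semiquantitative scores;
   hybrid — mean of one expert's (or the consensus) score with the MSE.

Binary calls use a 0.5 cutoff; a score of exactly 0.5 is called mutant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .tiling import SCALES

THRESHOLD = 0.5


def binary_call(scores, threshold: float = THRESHOLD) -> np.ndarray:
    """Mutant iff score >= threshold (ties at the cutoff call mutant)."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def single_scale_ensemble(seed_scores) -> float:
    """Mean of the replicate-seed probabilities at one scale."""
    arr = np.asarray(list(seed_scores), dtype=float)
    if arr.size == 0:
        raise ValueError("single_scale_ensemble requires at least one seed score")
    if arr.size < 3:
        warnings.warn(f"single-scale ensemble built from only {arr.size} seed(s)")
    return float(arr.mean())


def multiscale_ensemble(scale_scores: dict[float, float], allow_partial: bool = False) -> float:
    """Mean of the four single-scale ensemble probabilities."""
    present = set(scale_scores)
    if not allow_partial and present != set(SCALES):
        missing = sorted(set(SCALES) - present)
        raise ValueError(f"multi-scale ensemble missing scales {missing}")
    return float(np.mean(list(scale_scores.values())))


def patient_level(slide_scores) -> float:
    """Mean over a patient's slide-level scores."""
    arr = np.asarray(list(slide_scores), dtype=float)
    if arr.size == 0:
        raise ValueError("patient_level requires at least one slide score")
    return float(arr.mean())


def consensus_and_hybrid(expert_scores: dict[str, float], mse: float) -> dict:
    """Expert consensus, per-expert hybrids, and the consensus hybrid.

    consensus = mean of expert scores; hybrid_e = (expert_e + mse) / 2;
    consensus_hybrid = (consensus + mse) / 2.
    """
    if not expert_scores:
        raise ValueError("consensus requires at least one expert score")
    for pid, s in expert_scores.items():
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"expert score {s} for {pid} outside [0, 1]")
    consensus = float(np.mean(list(expert_scores.values())))
    return {
        "consensus": consensus,
        "hybrid_per_expert": {
            pid: (s + mse) / 2.0 for pid, s in expert_scores.items()
        },
        "consensus_hybrid": (consensus + mse) / 2.0,
    }


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------


def ensemble_table(raw: pd.DataFrame, allow_partial: bool = False) -> pd.DataFrame:
    """(slide, scale, seed) score table -> tidy table of ensemble variants.

    Input columns: patient_id, slide_id, scale, seed, score (label optional,
    carried through). Output rows per slide: one ``scale_<s>`` variant per
    scale (the seed average) and one ``mse`` variant.
    """
    required = {"patient_id", "slide_id", "scale", "seed", "score"}
    if not required.issubset(raw.columns):
        raise ValueError(f"prediction table missing columns {required - set(raw.columns)}")
    if ((raw["score"] < 0) | (raw["score"] > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    meta_cols = [c for c in ("label",) if c in raw.columns]
    rows = []
    for (patient, slide), grp in raw.groupby(["patient_id", "slide_id"], sort=True):
        meta = {c: grp[c].iloc[0] for c in meta_cols}
        sse = {}
        for scale, sg in grp.groupby("scale", sort=True):
            sse[float(scale)] = single_scale_ensemble(sg["score"])
        for scale, score in sse.items():
            rows.append(
                {
                    "patient_id": patient,
                    "slide_id": slide,
                    "variant": f"scale_{scale:g}x",
                    "score": score,
                    **meta,
                }
            )
        mse = multiscale_ensemble(sse, allow_partial=allow_partial)
        rows.append(
            {
                "patient_id": patient,
                "slide_id": slide,
                "variant": "mse",
                "score": mse,
                **meta,
            }
        )
    return pd.DataFrame(rows)


def patient_table(slide_variants: pd.DataFrame) -> pd.DataFrame:
    """Slide-level variant table -> patient-level means per variant."""
    agg = {"score": "mean"}
    if "label" in slide_variants.columns:
        agg["label"] = "max"  # slides of one patient share the label
    out = (
        slide_variants.groupby(["patient_id", "variant"], sort=True)
        .agg(agg)
        .reset_index()
    )
    return out


def attach_expert_variants(
    slide_variants: pd.DataFrame, expert_scores: pd.DataFrame
) -> pd.DataFrame:
    """Add expert, consensus and hybrid variants to a slide variant table.

    ``expert_scores`` columns: slide_id, pathologist_id, score (in [0, 1]).
    """
    mse = slide_variants[slide_variants["variant"] == "mse"].set_index("slide_id")
    meta_cols = [c for c in ("patient_id", "label") if c in slide_variants.columns]
    rows = []
    for slide_id, grp in expert_scores.groupby("slide_id"):
        if slide_id not in mse.index:
            warnings.warn(f"expert scores for unknown slide {slide_id}; skipped")
            continue
        scores = dict(zip(grp["pathologist_id"], grp["score"]))
        combo = consensus_and_hybrid(scores, float(mse.loc[slide_id, "score"]))
        meta = {c: mse.loc[slide_id, c] for c in meta_cols}
        for pid, s in scores.items():
            rows.append({"slide_id": slide_id, "variant": f"expert_{pid}", "score": s, **meta})
            rows.append(
                {
                    "slide_id": slide_id,
                    "variant": f"hybrid_{pid}",
                    "score": combo["hybrid_per_expert"][pid],
                    **meta,
                }
            )
        rows.append(
            {"slide_id": slide_id, "variant": "consensus", "score": combo["consensus"], **meta}
        )
        rows.append(
            {
                "slide_id": slide_id,
                "variant": "consensus_hybrid",
                "score": combo["consensus_hybrid"],
                **meta,
            }
        )
    return pd.concat([slide_variants, pd.DataFrame(rows)], ignore_index=True)
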