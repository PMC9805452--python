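"""Embedding-space visualization: sample patches, project to 2-D, emit
labeled coordinate tables and scatter figures.

Five qualifying 10x patches per slide are sampled (all, if a slide has
fewer), embedded with the best 10x classifier, and projected with UMAP
under its default hyper-parameters (PCA is available as a deterministic
fallback). Each projected point carries its patch-level prediction (the
patch scored as a one-patch bag), the slide-level prediction, and the slide
label, so morphology clusters can be read against model behavior.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model import MILModel
from .training import PatchStore
from .tiling import SlideRecord

PATCHES_PER_SLIDE = 5
PROJECTION_SCALE = 10.0


def sample_patches_for_projection(
    slides: list[SlideRecord],
    store: PatchStore,
    per_slide: int = PATCHES_PER_SLIDE,
    scale: float = PROJECTION_SCALE,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Uniform without-replacement patch sample per slide, seeded.

    Returns the sampled pixel stack and a provenance frame aligned row-for-
    row (slide_id, patient_id, label, patch_index).
    """
    rng = rng or np.random.default_rng(0)
    stacks, rows = [], []
    for rec in slides:
        pixels = store.patches(rec.slide_id, scale)
        n = pixels.shape[0]
        if n == 0:
            warnings.warn(f"slide {rec.slide_id} has no qualifying patches; skipped")
            continue
        k = min(per_slide, n)
        idx = np.sort(rng.choice(n, size=k, replace=False))
        stacks.append(pixels[idx])
        for i in idx:
            rows.append(
                {
                    "slide_id": rec.slide_id,
                    "patient_id": rec.patient_id,
                    "label": rec.label,
                    "patch_index": int(i),
                    "scale": scale,
                }
            )
    if not stacks:
        raise ValueError("no slide yielded qualifying patches to project")
    return np.concatenate(stacks), pd.DataFrame(rows)


def project_coords(
    embeddings: np.ndarray,
    method: str = "umap",
    random_state: int = 0,
    **params,
) -> tuple[np.ndarray, dict]:
    """n x D embeddings -> n x 2 coordinates, plus the parameters used."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    n = embeddings.shape[0]
    if n < 10:
        raise ValueError(f"projection needs at least 10 rows, got {n}")
    if method == "pca":
        from sklearn.decomposition import PCA

        proj = PCA(n_components=2, random_state=random_state)
        coords = proj.fit_transform(embeddings)
        used = {"method": "pca", "n_components": 2, "random_state": random_state}
    elif method == "umap":
        import umap

        n_neighbors = params.pop("n_neighbors", 15)
        if n_neighbors >= n:
            warnings.warn(
                f"n_neighbors {n_neighbors} >= n rows {n}; shrinking to {n - 1}"
            )
            n_neighbors = n - 1
        proj = umap.UMAP(
            n_components=2, n_neighbors=n_neighbors, random_state=random_state, **params
        )
        coords = proj.fit_transform(embeddings)
        used = {
            "method": "umap",
            **{
                k: getattr(proj, k)
                for k in ("n_neighbors", "min_dist", "metric", "n_components")
            },
            "random_state": random_state,
        }
    else:
        raise ValueError(f"unknown projection method {method!r}")
    coords = np.asarray(coords, dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise FloatingPointError("projection produced non-finite coordinates")
    return coords, used


def project_embeddings(
    model: MILModel,
    patch_stack: np.ndarray,
    provenance: pd.DataFrame,
    slide_scores: dict[str, float] | None = None,
    method: str = "umap",
    random_state: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Build the full projection table for a sampled patch stack.

    Output columns: slide_id, patient_id, label, patch_index, scale, x, y,
    patch_pred, slide_pred. Row count equals the input patch count.
    """
    emb = model.encode_patches(patch_stack)
    coords, used = project_coords(emb.embeddings, method=method, random_state=random_state)
    table = provenance.copy().reset_index(drop=True)
    table["x"] = coords[:, 0]
    table["y"] = coords[:, 1]
    table["patch_pred"] = model.predict_patches(emb)
    if slide_scores:
        table["slide_pred"] = table["slide_id"].map(slide_scores)
    return table, used


def plot_projection(table: pd.DataFrame, stem, color_cols=("label", "patch_pred")) -> None:
    """One scatter figure per label column."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for col in color_cols:
        if col not in table.columns:
            continue
        fig, ax = plt.subplots(figsize=(5, 5))
        sc = ax.scatter(table["x"], table["y"], c=table[col], s=12, cmap="coolwarm")
        fig.colorbar(sc, ax=ax, shrink=0.8, label=col)
        ax.set_xlabel("UMAP 1")
        ax.set_ylabel("UMAP 2")
        fig.savefig(f"{stem}_{col}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
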