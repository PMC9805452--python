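"""Evaluation statistics: ROC/AUC with bootstrap CIs, sensitivity and
specificity at the 0.5 cutoff, Cohen's kappa, and Pearson correlation.

Confidence intervals are percentile bootstrap over (score, label) pairs,
1000 resamples by default; resamples that lose one of the classes are
redrawn so the metric stays defined.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .ensembling import THRESHOLD, binary_call

BOOTSTRAP_REPS = 1000


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("metric undefined: labels contain a single class")


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve: Mann-Whitney rank form, midrank ties.

    AUC = (R1 - n1 (n1 + 1) / 2) / (n1 n0) with R1 the midrank sum of the
    positive class — equivalent to trapezoidal integration of the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def sens_spec(scores, labels, threshold: float = THRESHOLD) -> tuple[float, float]:
    """Sensitivity and specificity of the thresholded calls (>= is positive)."""
    labels = np.asarray(labels, dtype=int)
    calls = binary_call(scores, threshold)
    pos = labels == 1
    sens = float((calls[pos] == 1).mean()) if pos.any() else float("nan")
    spec = float((calls[~pos] == 0).mean()) if (~pos).any() else float("nan")
    return sens, spec


def bootstrap_ci(
    scores,
    labels,
    metric=roc_auc,
    reps: int = BOOTSTRAP_REPS,
    rng: np.random.Generator | None = None,
    level: float = 0.95,
    stratified: bool = False,
    max_redraws: int = 1000,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ``metric`` over (score, label) pairs.

    Plain pair resampling by default; ``stratified`` resamples within each
    class. Degenerate single-class resamples are redrawn.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    rng = rng or np.random.default_rng()
    n = len(scores)
    vals = np.empty(reps)
    for i in range(reps):
        for _ in range(max_redraws):
            if stratified:
                idx = np.concatenate(
                    [
                        rng.choice(np.flatnonzero(labels == c), size=(labels == c).sum())
                        for c in np.unique(labels)
                    ]
                )
            else:
                idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) > 1:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap resample")
        vals[i] = metric(scores[idx], labels[idx])
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(vals, alpha)),
        float(np.quantile(vals, 1.0 - alpha)),
    )


def cohens_kappa(calls_a, calls_b) -> float:
    """Cohen's kappa between two binary call vectors."""
    a = np.asarray(calls_a, dtype=int)
    b = np.asarray(calls_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("call vectors must have equal length")
    # chance agreement from marginal products; undefined when it is 1
    pa = np.mean(a)
    pb = np.mean(b)
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0 - 1e-15:
        raise ValueError(
            "kappa undefined: expected agreement is 1 (both raters constant)"
        )
    return float(skm.cohen_kappa_score(a, b, labels=[0, 1]))


def pearson_r(x, y) -> float:
    """Product-moment correlation; requires non-degenerate inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson r undefined: zero variance input")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class VariantStats:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    n: int


@dataclass
class EvalReport:
    level: str  # "slide" or "patient"
    variants: dict[str, VariantStats] = field(default_factory=dict)
    kappa: dict[str, dict[str, float]] = field(default_factory=dict)
    pearson: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant": name,
                "auc": v.auc,
                "auc_lo": v.auc_ci[0],
                "auc_hi": v.auc_ci[1],
                "sensitivity": v.sensitivity,
                "specificity": v.specificity,
                "n": v.n,
            }
            for name, v in self.variants.items()
        ]
        return pd.DataFrame(rows)


def evaluate_variants(
    table: pd.DataFrame,
    level: str = "slide",
    reps: int = BOOTSTRAP_REPS,
    rng: np.random.Generator | None = None,
) -> EvalReport:
    """Per-variant AUC/CI/sens/spec plus pairwise kappa and Pearson matrices.

    ``table`` is tidy with columns (variant, score, label) and one row per
    slide or patient per variant.
    """
    rng = rng or np.random.default_rng(0)
    report = EvalReport(level=level)
    wide_scores: dict[str, pd.Series] = {}
    key = "patient_id" if level == "patient" else "slide_id"
    for variant, grp in table.groupby("variant", sort=True):
        scores = grp["score"].to_numpy()
        labels = grp["label"].to_numpy().astype(int)
        if len(np.unique(labels)) < 2:
            warnings.warn(f"variant {variant}: single-class labels, skipped")
            continue
        ci = bootstrap_ci(scores, labels, reps=reps, rng=rng)
        sens, spec = sens_spec(scores, labels)
        report.variants[variant] = VariantStats(
            auc=roc_auc(scores, labels),
            auc_ci=ci,
            sensitivity=sens,
            specificity=spec,
            n=len(scores),
        )
        if key in grp.columns:
            wide_scores[variant] = grp.set_index(key)["score"]
    names = sorted(wide_scores)
    for a in names:
        for b in names:
            if a >= b:
                continue
            joined = pd.concat(
                [wide_scores[a].rename("a"), wide_scores[b].rename("b")],
                axis=1,
                join="inner",
            ).dropna()
            if len(joined) < 2:
                continue
            try:
                report.kappa.setdefault(a, {})[b] = cohens_kappa(
                    binary_call(joined["a"]), binary_call(joined["b"])
                )
            except ValueError:
                pass
            try:
                report.pearson.setdefault(a, {})[b] = pearson_r(
                    joined["a"], joined["b"]
                )
            except ValueError:
                pass
    return report


def plot_roc(table: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """One ROC curve per variant on a shared axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for variant, grp in table.groupby("variant", sort=True):
        labels = grp["label"].to_numpy().astype(int)
        scores = grp["score"].to_numpy()
        if len(np.unique(labels)) < 2:
            continue
        fpr, tpr, _ = skm.roc_curve(labels, scores)
        ax.plot(fpr, tpr, label=f"{variant} (AUC {roc_auc(scores, labels):.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
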