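"""The multiple-instance slide classifier.

A slide is a bag of 256x256 patches carrying a single binary label (here:
IDH mutation status). The model encodes every patch into a fixed-width
embedding, aggregates the bag by average pooling into one slide embedding,
and maps that through a single affine + logistic head to a slide-level
mutation probability:

    p(slide) = sigmoid( w . mean_i f(patch_i) + b )

Mean aggregation makes the prediction exactly invariant to patch order and
lets the gradient of the slide loss distribute uniformly over patches, which
is what makes weak slide-level supervision trainable. A gated attention
aggregator (a learned convex combination of patch embeddings) is available
as an optional inference-time mode; average pooling is the default.

The patch encoder is pluggable. The default ``tiny_cnn`` backbone is a
compact four-conv-block network (configurable embedding width, default 64)
that trains on one CPU; wider ImageNet-style backbones can be registered
without touching the MIL contract, whose embedding width in paper-faithful
configurations is 1024.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .tiling import Patch

DEFAULT_EMBED_DIM = 64


def build_encoder(name: str, d: int, rng: np.random.Generator) -> nn.Sequential:
    """Backbone registry. Input is (n, 3, 256, 256) float32 in [-0.5, 0.5]."""
    if name == "tiny_cnn":
        # 4x4 mean stem then four conv blocks; total spatial reduction 256 -> 4
        return nn.Sequential(
            [
                nn.AvgPool2d(4),
                nn.Conv2d(3, 8, rng),
                nn.ReLU(),
                nn.AvgPool2d(2),
                nn.Conv2d(8, 16, rng),
                nn.ReLU(),
                nn.AvgPool2d(2),
                nn.Conv2d(16, 32, rng),
                nn.ReLU(),
                nn.AvgPool2d(2),
                nn.Conv2d(32, d, rng),
                nn.ReLU(),
                nn.AvgPool2d(2),
                nn.GlobalAvgPool(),
            ]
        )
    raise ValueError(f"unknown backbone {name!r}")


def preprocess(batch: np.ndarray) -> np.ndarray:
    """uint8 (n, H, W, 3) -> float32 (n, 3, H, W), centered at zero."""
    x = np.asarray(batch, dtype=np.float32) / 255.0 - 0.5
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _as_pixel_stack(patches) -> np.ndarray:
    if isinstance(patches, np.ndarray):
        if patches.ndim == 3:
            patches = patches[None]
        return patches
    if len(patches) == 0:
        raise ValueError("encode_patches requires at least one patch")
    if isinstance(patches[0], Patch):
        return np.stack([p.pixels for p in patches])
    return np.stack(list(patches))


@dataclass
class EmbeddingBatch:
    """n patch embeddings with provenance back to the tile grid."""

    embeddings: np.ndarray  # (n, D)
    slide_id: str = ""
    scale: float | None = None
    origins: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.embeddings = np.atleast_2d(np.asarray(self.embeddings))
        if self.embeddings.shape[0] < 1:
            raise ValueError("embedding batch must contain at least one row")
        if not np.all(np.isfinite(self.embeddings)):
            raise ValueError("embeddings contain non-finite entries")

    @property
    def n(self) -> int:
        return self.embeddings.shape[0]


class MILModel:
    def __init__(
        self,
        d: int = DEFAULT_EMBED_DIM,
        backbone: str = "tiny_cnn",
        aggregation: str = "mean",
        seed: int = 0,
        attention_dim: int = 32,
    ) -> None:
        if aggregation not in ("mean", "attention"):
            raise ValueError(f"unknown aggregation {aggregation!r}")
        rng = np.random.default_rng(seed)
        self.d = d
        self.backbone = backbone
        self.aggregation = aggregation
        self.encoder = build_encoder(backbone, d, rng)
        self.head = nn.Linear(d, 1, rng)
        # gated attention parameters (used only in attention mode)
        self._att_V = rng.normal(0, np.sqrt(1.0 / d), (attention_dim, d)).astype(
            np.float32
        )
        self._att_U = rng.normal(0, np.sqrt(1.0 / d), (attention_dim, d)).astype(
            np.float32
        )
        self._att_w = rng.normal(0, np.sqrt(1.0 / attention_dim), attention_dim).astype(
            np.float32
        )

    # -- parameters ---------------------------------------------------------

    def named_params(self) -> dict[str, np.ndarray]:
        out = self.encoder.named_params("enc.")
        out.update({f"head.{k}": v for k, v in self.head.params.items()})
        out.update(
            {"att.V": self._att_V, "att.U": self._att_U, "att.w": self._att_w}
        )
        return out

    def trainable_params(self) -> dict[str, np.ndarray]:
        out = self.encoder.named_params("enc.")
        out.update({f"head.{k}": v for k, v in self.head.params.items()})
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out = self.encoder.named_grads("enc.")
        out.update({f"head.{k}": v for k, v in self.head.grads.items()})
        return out

    def zero_grad(self) -> None:
        self.encoder.zero_grad()
        self.head.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.encoder.load_params(state, "enc.")
        for k in self.head.params:
            self.head.params[k] = state[f"head.{k}"].astype(np.float32).copy()
        self._att_V = state["att.V"].astype(np.float32).copy()
        self._att_U = state["att.U"].astype(np.float32).copy()
        self._att_w = state["att.w"].astype(np.float32).copy()

    # -- inference ----------------------------------------------------------

    def encode_patches(self, patches, chunk: int = 32) -> EmbeddingBatch:
        """Embed patches in deterministic order-preserving chunks."""
        stack = _as_pixel_stack(patches)
        embs = []
        for i in range(0, stack.shape[0], chunk):
            x = preprocess(stack[i : i + chunk])
            embs.append(self.encoder.forward(x))
        slide_id = ""
        scale = None
        origins = None
        if not isinstance(patches, np.ndarray) and isinstance(patches[0], Patch):
            slide_id = patches[0].slide_id
            scale = patches[0].scale
            origins = [p.origin for p in patches]
        return EmbeddingBatch(np.concatenate(embs), slide_id, scale, origins)

    def attention_weights(self, emb: np.ndarray) -> np.ndarray:
        """Softmax-normalized gated attention weights over patches.

        The normalizer is accumulated over rows in a canonical (lexicographic)
        order so the weights do not depend on patch order at the bit level.
        """
        e = np.asarray(emb, dtype=np.float64)
        gate = np.tanh(e @ self._att_V.T) * nn.sigmoid(e @ self._att_U.T)
        scores = gate @ self._att_w
        w = np.exp(scores - scores.max())
        z = w[np.lexsort(np.concatenate([e.T, w[None, :]]))].sum()
        return w / z

    def aggregate(self, emb: EmbeddingBatch | np.ndarray, mode: str | None = None):
        """Bag of patch embeddings -> one slide embedding of length D."""
        mode = mode or self.aggregation
        e = emb.embeddings if isinstance(emb, EmbeddingBatch) else np.atleast_2d(emb)
        if mode == "mean":
            # summing each column in sorted order makes the mean bitwise
            # invariant to patch order, so bag predictions are exactly
            # permutation-invariant rather than merely close
            return np.sort(e.astype(np.float64), axis=0).sum(axis=0) / e.shape[0]
        if mode == "attention":
            w = self.attention_weights(e)
            e64 = e.astype(np.float64)
            order = np.lexsort(np.concatenate([e64.T, w[None, :]]))
            return (w[order, None] * e64[order]).sum(axis=0)
        raise ValueError(f"unknown aggregation {mode!r}")

    def head_probability(self, slide_embedding: np.ndarray) -> float:
        z = float(slide_embedding @ self.head.params["W"][0] + self.head.params["b"][0])
        return float(nn.sigmoid(z))

    def predict_slide(self, emb: EmbeddingBatch | np.ndarray, mode: str | None = None) -> float:
        return self.head_probability(self.aggregate(emb, mode))

    def predict_patches(self, emb: EmbeddingBatch | np.ndarray) -> np.ndarray:
        """Per-patch probabilities: each patch scored as its own 1-patch bag."""
        e = emb.embeddings if isinstance(emb, EmbeddingBatch) else np.atleast_2d(emb)
        z = e @ self.head.params["W"][0] + self.head.params["b"][0]
        return np.asarray(nn.sigmoid(z), dtype=np.float64)

    def predict_pixel_batch(self, batch: np.ndarray) -> np.ndarray:
        """uint8 pixel stack -> per-patch probabilities (1-patch bags)."""
        return self.predict_patches(self.encode_patches(batch))

    # -- training -----------------------------------------------------------

    def loss_and_grads(
        self, batch: np.ndarray, label: int, chunk: int = 32
    ) -> tuple[float, float]:
        """BCE loss for one slide bag; gradients accumulate into the layers.

        Mean aggregation allows a memory-light two-pass scheme: a first pass
        collects all patch embeddings (fixing the slide probability and the
        per-patch upstream gradient dL/de_i = (p - y) w / n), a second pass
        re-runs each chunk with caches and backpropagates. Only training with
        mean aggregation is supported.
        """
        if self.aggregation != "mean":
            raise NotImplementedError("training supports mean aggregation only")
        stack = _as_pixel_stack(batch)
        n = stack.shape[0]
        embs = []
        for i in range(0, n, chunk):
            embs.append(self.encoder.forward(preprocess(stack[i : i + chunk])))
        emb = np.concatenate(embs)
        z_vec = emb.mean(axis=0, dtype=np.float64)
        logit = float(z_vec @ self.head.params["W"][0] + self.head.params["b"][0])
        p = float(nn.sigmoid(logit))
        y = float(label)
        loss = nn.bce_loss(p, y)
        # d loss / d logit for sigmoid + BCE
        dlogit = p - y
        self.head.grads["W"] += (dlogit * z_vec[None, :]).astype(np.float32)
        self.head.grads["b"] += np.float32(dlogit)
        de = (dlogit / n) * self.head.params["W"][0].astype(np.float64)
        de32 = de.astype(np.float32)
        for i in range(0, n, chunk):
            x = preprocess(stack[i : i + chunk])
            self.encoder.forward(x)
            m = x.shape[0]
            self.encoder.backward(np.tile(de32, (m, 1)))
        return loss, p

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        """Write ``<path>.npz`` (parameters) and ``<path>.json`` (metadata)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.named_params())
        info = {
            "d": self.d,
            "backbone": self.backbone,
            "aggregation": self.aggregation,
        }
        info.update(meta or {})
        path.with_suffix(".json").write_text(json.dumps(info, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "MILModel":
        path = Path(path)
        info = json.loads(path.with_suffix(".json").read_text())
        model = cls(
            d=info["d"], backbone=info["backbone"], aggregation=info["aggregation"]
        )
        with np.load(path.with_suffix(".npz")) as npz:
            model.load_state_dict(dict(npz))
        model.meta = info
        return model
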