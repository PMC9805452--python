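import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_textured_plane(
    rng: np.random.Generator,
    size: int = 1024,
    block: int = 64,
    p_white: float = 0.3,
    p_black: float = 0.1,
) -> np.ndarray:
    """Random plane of 64px blocks: background white, folded-dark, or noisy
    mid-grey tissue. Tissue blocks carry +/-8 grey noise so the blur rule
    never fires on them; no saturated color, so the pen rule never fires."""
    nb = size // block
    kinds = rng.choice(3, size=(nb, nb), p=[p_white, p_black, 1 - p_white - p_black])
    base = rng.uniform(70, 190, size=(nb, nb))
    plane = np.zeros((size, size), dtype=np.float64)
    for i in range(nb):
        for j in range(nb):
            sl = np.s_[i * block : (i + 1) * block, j * block : (j + 1) * block]
            if kinds[i, j] == 0:
                plane[sl] = 255.0
            elif kinds[i, j] == 1:
                plane[sl] = 5.0
            else:
                plane[sl] = base[i, j] + rng.uniform(-8, 8, size=(block, block))
    return np.clip(np.rint(plane), 0, 255).astype(np.uint8)[:, :, None].repeat(3, axis=2)


def reference_grey_tissue_count(pixels: np.ndarray) -> int:
    """Independent greyscale tissue count: ITU-R 601 luminance, rounded,
    counted inside the closed [40, 215] band."""
    arr = pixels.astype(np.float64)
    grey = np.rint(0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2])
    return int(((grey >= 40) & (grey <= 215)).sum())


def brute_force_tile_scan(plane: np.ndarray, tile: int = 256):
    """Reference grid scan: every full 256-cell with strictly more than 75%
    tissue pixels, in row-major order. Returns [(row, col, fraction), ...]."""
    h, w = plane.shape[:2]
    out = []
    for r in range(0, h - tile + 1, tile):
        for c in range(0, w - tile + 1, tile):
            count = reference_grey_tissue_count(plane[r : r + tile, c : c + tile])
            frac = count / (tile * tile)
            if frac > 0.75:
                out.append((r, c, frac))
    return out


def noisy_tissue_patch(rng: np.random.Generator, size: int = 256) -> np.ndarray:
    """A fully qualifying patch: mid-grey with noise (tissue fraction 1.0,
    sharp texture, unsaturated)."""
    g = rng.integers(100, 156, size=(size, size), dtype=np.int64)
    return g[:, :, None].repeat(3, axis=2).astype(np.uint8)


def pair_counting_auc(scores, labels) -> float:
    """Brute-force AUC over every (positive, negative) pair; ties count 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def prefix_sum_heatmap_oracle(shape, window, step, preds):
    """Independent per-pixel accumulation oracle built on 2-D prefix sums.

    ``preds`` maps qualifying window origins (r, c) to predictions. For each
    pixel the covering window-origin index range is computed arithmetically
    and the sum/count read off rectangle queries, i.e. a different algorithm
    from the implementation's additive rasterization.
    """
    h, w = shape
    nr = (h - window) // step + 1
    nc = (w - window) // step + 1
    grid = np.zeros((nr, nc))
    qual = np.zeros((nr, nc))
    for (r, c), p in preds.items():
        grid[r // step, c // step] = p
        qual[r // step, c // step] = 1.0
    ps = np.zeros((nr + 1, nc + 1))
    qs = np.zeros((nr + 1, nc + 1))
    ps[1:, 1:] = grid.cumsum(0).cumsum(1)
    qs[1:, 1:] = qual.cumsum(0).cumsum(1)

    y = np.arange(h)
    x = np.arange(w)
    r_lo = np.ceil(np.maximum(0, y - window + 1) / step).astype(int)
    r_hi = np.minimum(y, h - window) // step
    c_lo = np.ceil(np.maximum(0, x - window + 1) / step).astype(int)
    c_hi = np.minimum(x, w - window) // step
    r_lo = np.clip(r_lo, 0, nr)
    c_lo = np.clip(c_lo, 0, nc)

    def rect(mat):
        return (
            mat[np.ix_(r_hi + 1, c_hi + 1)]
            - mat[np.ix_(r_lo, c_hi + 1)]
            - mat[np.ix_(r_hi + 1, c_lo)]
            + mat[np.ix_(r_lo, c_lo)]
        )

    valid = (r_hi[:, None] >= r_lo[:, None]) & (c_hi[None, :] >= c_lo[None, :])
    total = np.where(valid, rect(ps), 0.0)
    count = np.where(valid, rect(qs), 0.0)
    values = np.full((h, w), np.nan)
    nz = count > 0
    values[nz] = total[nz] / count[nz]
    return values, count.astype(int)
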