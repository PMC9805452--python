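"""Vectorized float32 RGB <-> HSV conversion.

Same convention as matplotlib.colors (all channels in [0, 1], hue wraps at
1), but compiled with numba, because color jitter runs on every training
batch and the pen-mark rule on every tile.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _rgb_to_hsv_flat(rgb: np.ndarray, out: np.ndarray) -> None:
    for i in range(rgb.shape[0]):
        r, g, b = rgb[i, 0], rgb[i, 1], rgb[i, 2]
        maxc = max(r, g, b)
        minc = min(r, g, b)
        delta = maxc - minc
        if delta == 0.0:
            h = 0.0
        elif maxc == r:
            h = ((g - b) / delta) % 6.0
        elif maxc == g:
            h = (b - r) / delta + 2.0
        else:
            h = (r - g) / delta + 4.0
        out[i, 0] = (h / 6.0) % 1.0
        out[i, 1] = delta / maxc if maxc > 0.0 else 0.0
        out[i, 2] = maxc


@njit(cache=True)
def _hsv_to_rgb_flat(hsv: np.ndarray, out: np.ndarray) -> None:
    for i in range(hsv.shape[0]):
        h, s, v = hsv[i, 0], hsv[i, 1], hsv[i, 2]
        h6 = (h % 1.0) * 6.0
        k = int(h6) % 6
        f = h6 - int(h6)
        p = v * (1.0 - s)
        q = v * (1.0 - s * f)
        t = v * (1.0 - s * (1.0 - f))
        if k == 0:
            r, g, b = v, t, p
        elif k == 1:
            r, g, b = q, v, p
        elif k == 2:
            r, g, b = p, v, t
        elif k == 3:
            r, g, b = p, q, v
        elif k == 4:
            r, g, b = t, p, v
        else:
            r, g, b = v, p, q
        out[i, 0] = r
        out[i, 1] = g
        out[i, 2] = b


def rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    """(..., 3) RGB in [0, 1] -> (..., 3) HSV in [0, 1]."""
    rgb = np.ascontiguousarray(rgb, dtype=np.float32)
    flat = rgb.reshape(-1, 3)
    out = np.empty_like(flat)
    _rgb_to_hsv_flat(flat, out)
    return out.reshape(rgb.shape)


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """(..., 3) HSV in [0, 1] -> (..., 3) RGB in [0, 1]."""
    hsv = np.ascontiguousarray(hsv, dtype=np.float32)
    flat = hsv.reshape(-1, 3)
    out = np.empty_like(flat)
    _hsv_to_rgb_flat(flat, out)
    return out.reshape(hsv.shape)
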