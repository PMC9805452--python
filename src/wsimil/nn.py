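"""Minimal CPU tensor layers with hand-written backpropagation.

The multiple-instance classifier in this package needs only a small set of
primitives: 3x3 same-padding convolution, average pooling, ReLU, a linear
head and Adam. They are implemented directly on numpy arrays so that slide
classifiers remain trainable and fully deterministic on a single CPU.

Conventions: activations are float32 arrays shaped (N, C, H, W); parameters
live in per-layer dicts so a whole network serializes as one flat mapping of
named arrays. Gradients are accumulated into ``layer.grads`` by ``backward``
calls, which also return the gradient with respect to the layer input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameter-free layers inherit the empty dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H+2, W+2) padded input -> (N, H*W, C*9) patch matrix."""
    n, c, hp, wp = x.shape
    h, w = hp - 2, wp - 2
    win = sliding_window_view(x, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * 9)


class Conv2d(Layer):
    """3x3 convolution, stride 1, zero padding 1 (shape-preserving)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * 9
        # He initialization, appropriate for the ReLU nonlinearity that follows
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(c_out, np.float32)}
        self.zero_grad()
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = _im2col(xp)  # (N, HW, C*9)
        wmat = self.params["W"].reshape(self.c_out, -1)
        y = cols @ wmat.T + self.params["b"]
        self._cache = (cols, (n, c, h, w))
        return y.transpose(0, 2, 1).reshape(n, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        dy_flat = dy.reshape(n, self.c_out, h * w).transpose(0, 2, 1)  # (N, HW, Cout)
        k = self.c_in * 9
        self.grads["W"] += (
            dy_flat.reshape(-1, self.c_out).T @ cols.reshape(-1, k)
        ).reshape(self.c_out, self.c_in, 3, 3)
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        # dx is the full correlation of dy with the 180-degree-rotated kernels
        w_flip = self.params["W"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dyp = np.pad(dy, ((0, 0), (0, 0), (1, 1), (1, 1)))
        dcols = _im2col(dyp)  # (N, HW, Cout*9)
        dx = dcols @ w_flip.reshape(self.c_in, -1).T
        return dx.transpose(0, 2, 1).reshape(n, c, h, w).astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class AvgPool2d(Layer):
    """Non-overlapping k x k mean pooling; input dims must divide by k."""

    def __init__(self, k: int) -> None:
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        if h % k or w % k:
            raise ValueError(f"pool size {k} does not divide {(h, w)}")
        self._in_shape = x.shape
        return x.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k = self.k
        dy = dy / (k * k)
        return np.broadcast_to(
            dy[:, :, :, None, :, None],
            (dy.shape[0], dy.shape[1], dy.shape[2], k, dy.shape[3], k),
        ).reshape(self._in_shape)


class GlobalAvgPool(Layer):
    """(N, C, H, W) -> (N, C) spatial mean."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._in_shape).astype(
            np.float32
        )


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        w = rng.normal(0.0, np.sqrt(1.0 / d_in), size=(d_out, d_in))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(d_out, np.float32)}
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"]


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def named_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"{prefix}{i}.{k}"] = v
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads.items():
                out[f"{prefix}{i}.{k}"] = v
        return out

    def load_params(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k] = state[f"{prefix}{i}.{k}"].astype(np.float32).copy()


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(z, dtype=np.float64)))


def bce_loss(p: float, y: float, eps: float = 1e-7) -> float:
    """Binary cross-entropy for a single slide probability."""
    p = float(np.clip(p, eps, 1.0 - eps))
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


class Adam:
    """Adam over a flat named-parameter mapping (shared array references)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
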