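"""A compact CPU neural-network engine (NHWC, float32, explicit backprop).

Implements exactly the layer vocabulary the classifiers need: stride-1
"same" 2-D convolution, 2x2 max pooling, global max pooling, dense layers
with optional L1/L2 kernel penalties, ReLU / sigmoid activations and
inverted dropout — each with a hand-written backward pass, verified against
finite differences in the test suite. Gradients with respect to intermediate
feature maps are exposed as well, which is what Grad-CAM needs.

Convolutions use an im2col formulation (patch extraction via
``sliding_window_view`` plus one matmul), which is the fastest pure-NumPy
route at the image sizes used here.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Layer", "Conv2D", "MaxPool2D", "GlobalMaxPool2D", "ReLU", "Sigmoid",
    "Dropout", "Dense", "Network", "Adam", "he_init",
]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Layer:
    """Base layer: ``forward`` caches whatever ``backward`` needs."""

    trainable: bool = True

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def penalty(self) -> float:
        return 0.0

    def add_penalty_grads(self) -> None:
        pass


class Conv2D(Layer):
    """Stride-1 'same' convolution with a square kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = kernel * kernel * in_channels
        self.w = he_init(rng, (fan_in, out_channels), fan_in)
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, C, k, k) -> (N, H, W, k, k, C)
        cols = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        return np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        self._shape = x.shape
        n, h, w, _ = x.shape
        cols = self._im2col(x).reshape(n * h * w, -1)
        self._cols = cols if training else None
        y = cols @ self.w + self.b
        return y.reshape(n, h, w, self.out_channels)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        n, h, w, _ = self._shape
        dy2 = dy.reshape(n * h * w, self.out_channels).astype(np.float32)
        if self._cols is not None:
            self.dw = self._cols.T @ dy2
            self.db = dy2.sum(axis=0)
        if not need_dx:  # bottom layer: input gradient is never consumed
            return np.zeros(self._shape, dtype=np.float32)
        k, p = self.kernel, self.kernel // 2
        # one GEMM back to patch space, then scatter-add the k*k shifts
        dcols = (dy2 @ self.w.T).reshape(n, h, w, k, k, self.in_channels)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.in_channels), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; odd edges padded with -inf (dropped)."""

    trainable = False

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        p = self.pool
        n, h, w, c = x.shape
        hp, wp = -(-h // p) * p, -(-w // p) * p
        if (hp, wp) != (h, w):
            x = np.pad(x, ((0, 0), (0, hp - h), (0, wp - w), (0, 0)), constant_values=-np.inf)
        xr = x.reshape(n, hp // p, p, wp // p, p, c)
        y = xr.max(axis=(2, 4))
        self._shape = (n, h, w, c)
        mask = (xr == y[:, :, None, :, None, :]).astype(np.float32)
        mask /= np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1.0)
        self._mask = mask
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        dxr = self._mask * dy[:, :, None, :, None, :]
        p = self.pool
        dx = dxr.reshape(n, dxr.shape[1] * p, dxr.shape[3] * p, c)
        return dx[:, :h, :w, :].astype(np.float32)


class GlobalMaxPool2D(Layer):
    """(N, H, W, C) -> (N, C) by spatial maximum."""

    trainable = False

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        n, h, w, c = x.shape
        y = x.max(axis=(1, 2))
        mask = (x == y[:, None, None, :]).astype(np.float32)
        mask /= np.maximum(mask.sum(axis=(1, 2), keepdims=True), 1.0)
        self._mask = mask
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (self._mask * dy[:, None, None, :]).astype(np.float32)


class ReLU(Layer):
    trainable = False

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._pos = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._pos


class Sigmoid(Layer):
    trainable = False

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class ChannelScale(Layer):
    """Fixed per-channel gain (non-trainable), e.g. a calibrated response
    normalization at a backbone's output so features are O(1)."""

    trainable = False

    def __init__(self, gain: np.ndarray):
        self.gain = np.asarray(gain, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return x * self.gain

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self.gain

    def params(self):
        return {"gain": self.gain}

    def grads(self):
        return {"gain": np.zeros_like(self.gain)}


class Dropout(Layer):
    """Inverted dropout; identity (and identity gradient) at inference."""

    trainable = False

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else (dy * self._mask).astype(np.float32)


class Dense(Layer):
    """Fully connected layer; optional L1/L2 penalty on the kernel."""

    def __init__(self, in_features: int, out_features: int, l1: float = 0.0, l2: float = 0.0,
                 rng: np.random.Generator | None = None, bias_init: float = 0.0,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        # zero_init suits output heads: the classifier starts at p = 0.5
        # instead of spending epochs undoing a confident random logit
        if zero_init:
            self.w = np.zeros((in_features, out_features), dtype=np.float32)
        else:
            self.w = he_init(rng, (in_features, out_features), in_features)
        # small positive bias on ReLU-feeding layers wards off dead units
        self.b = np.full(out_features, bias_init, dtype=np.float32)
        self.l1, self.l2 = l1, l2
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = np.asarray(x, dtype=np.float32)
        return self._x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy.astype(np.float32)
        self.dw = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def penalty(self) -> float:
        return float(self.l1 * np.abs(self.w).sum() + self.l2 * np.square(self.w).sum())

    def add_penalty_grads(self) -> None:
        if self.l1:
            self.dw += self.l1 * np.sign(self.w)
        if self.l2:
            self.dw += 2.0 * self.l2 * self.w


class Network:
    """A plain sequential network with partial backward passes.

    ``frozen`` marks layers excluded from optimization (transfer-learning
    backbones in off-the-shelf mode). ``backward_from`` lets callers seed the
    gradient at an arbitrary layer output — used both to start backprop at
    the logit (folding the sigmoid into the cross-entropy gradient) and to
    recover Grad-CAM feature-map gradients.
    """

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)
        self.frozen: set[int] = set()

    # -- forward ----------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False,
                capture: int | None = None) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
        """Run all layers; optionally also return the output of layer ``capture``."""
        out = np.asarray(x, dtype=np.float32)
        captured = None
        for i, layer in enumerate(self.layers):
            out = layer.forward(out, training=training)
            if capture is not None and i == capture:
                captured = out
        return (out, captured) if capture is not None else out

    def forward_range(self, x: np.ndarray, start: int = 0, stop: int | None = None,
                      training: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=np.float32)
        for layer in self.layers[start:stop]:
            out = layer.forward(out, training=training)
        return out

    # -- backward ---------------------------------------------------------
    def backward_from(self, grad: np.ndarray, from_layer: int, to_layer: int = 0) -> np.ndarray:
        """Backpropagate ``grad`` (w.r.t. the *output* of ``from_layer``) down
        to the output of layer ``to_layer - 1``; returns that gradient."""
        for i in range(from_layer, to_layer - 1, -1):
            layer = self.layers[i]
            if i == to_layer == 0 and isinstance(layer, Conv2D):
                grad = layer.backward(grad, need_dx=False)
            else:
                grad = layer.backward(grad)
        return grad

    # -- parameter plumbing ------------------------------------------------
    def trainable_entries(self, layer_slice: slice | None = None) -> list[tuple[Layer, str]]:
        sl = layer_slice or slice(None)
        entries = []
        for i, layer in list(enumerate(self.layers))[sl]:
            if layer.trainable and i not in self.frozen:
                entries.extend((layer, name) for name in layer.params())
        return entries

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(v.copy() for v in layer.params().values())
        return out

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for name, v in layer.params().items():
                new = next(it)
                if new.shape != v.shape:
                    raise ValueError("weight shape mismatch")
                v[...] = new

    def penalty(self) -> float:
        return sum(layer.penalty() for layer in self.layers)

    def add_penalty_grads(self) -> None:
        for i, layer in enumerate(self.layers):
            if i not in self.frozen:
                layer.add_penalty_grads()

    def seed_dropout(self, seed: int) -> None:
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Dropout):
                layer.rng = np.random.default_rng((seed + 7919 * i) & 0x7FFFFFFF)

    # -- persistence -------------------------------------------------------
    def describe(self) -> list[dict]:
        desc = []
        for layer in self.layers:
            entry = {"type": type(layer).__name__}
            entry.update({k: list(v.shape) for k, v in layer.params().items()})
            desc.append(entry)
        return desc

    def save(self, directory: str | Path, name: str = "model") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {f"w{i}": w for i, w in enumerate(self.get_weights())}
        np.savez(directory / f"{name}.npz", **arrays)
        (directory / f"{name}.json").write_text(json.dumps(self.describe(), indent=2))

    def load(self, directory: str | Path, name: str = "model") -> None:
        data = np.load(Path(directory) / f"{name}.npz")
        self.set_weights([data[f"w{i}"] for i in range(len(data.files))])


class Adam:
    """Adam with independent parameter groups (e.g. head vs backbone rates)."""

    def __init__(self, groups: list[tuple[list[tuple[Layer, str]], float]],
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.groups = groups
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for entries, lr in self.groups:
            for layer, name in entries:
                p = layer.params()[name]
                g = layer.grads()[name]
                key = id(p)
                if key not in self.state:
                    self.state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self.state[key]
                m[...] = b1 * m + (1 - b1) * g
                v[...] = b2 * v + (1 - b2) * g * g
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
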