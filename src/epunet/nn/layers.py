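"""Minimal trainable CNN layer stack on NumPy.

All layers operate on float32 arrays in NCHW layout (batch, channels,
height, width) and implement explicit forward/backward passes. Convolutions
use im2col + GEMM so the heavy lifting runs through BLAS. Parameters and
their gradients live in per-layer dicts keyed by name, which makes
serialization and the SGD update loop trivial.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2D",
    "MaxPool2x2",
    "AvgPool3x3Same",
    "BatchNorm2D",
    "Dense",
    "Flatten",
    "ReLU",
    "Tanh",
    "Inception",
    "Sequential",
]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> (B*H*W, C*k*k) patch matrix, stride 1, 'same' output."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # (B, C, H, W, k, k) view, then bring spatial axes forward
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    b, c, h, w = x.shape[0], x.shape[1], win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)
    return np.ascontiguousarray(cols)


class Layer:
    """Base class: stateless unless it declares params/grads dicts."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 'same' convolution with square odd kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_ch, np.float32)}
        self.grads = {}
        self._x: np.ndarray | None = None

    def forward(self, x, train=False):
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[1]}")
        self._x = x if train else None
        b, _, h, w = x.shape
        cols = _im2col(x, self.k, self.k // 2)
        wmat = self.params["W"].reshape(self.out_ch, -1).T  # (C*k*k, F)
        out = cols @ wmat + self.params["b"]
        return out.reshape(b, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy):
        x = self._x
        assert x is not None, "backward() requires a forward(train=True) pass"
        b, _, h, w = x.shape
        k = self.k
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.out_ch)
        cols = _im2col(x, k, k // 2)
        dw = (cols.T @ dyf).T.reshape(self.params["W"].shape)
        self.grads["W"] = dw
        self.grads["b"] = dyf.sum(axis=0)
        # dX as a full correlation of dY with the flipped kernels
        wrot = self.params["W"][:, :, ::-1, ::-1].transpose(0, 2, 3, 1)  # (F,k,k,C)
        wrot = np.ascontiguousarray(wrot).reshape(self.out_ch * k * k, self.in_ch)
        dcols = _im2col(dy, k, k // 2)  # (B*H*W, F*k*k)
        dx = (dcols @ wrot).reshape(b, h, w, self.in_ch).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(dx)


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; input spatial dims must be even."""

    def __init__(self) -> None:
        super().__init__()
        self._idx = None
        self._shape = None

    def forward(self, x, train=False):
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2x2 requires even spatial dimensions")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(b, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return out

    def backward(self, dy):
        b, c, h, w = self._shape
        dxr = np.zeros((b, c, h // 2, w // 2, 4), dy.dtype)
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return np.ascontiguousarray(dx.reshape(b, c, h, w))


class AvgPool3x3Same(Layer):
    """3x3 stride-1 average pool with zero padding (used by the inception
    branch); the operator is its own adjoint, so backward reuses forward."""

    def forward(self, x, train=False):
        return self._apply(x)

    def backward(self, dy):
        return self._apply(dy)

    @staticmethod
    def _apply(x):
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))
        return (win.sum(axis=(-2, -1)) / 9.0).astype(x.dtype)


class BatchNorm2D(Layer):
    """Per-channel batch normalization.

    Inference statistics are an exponential moving average of the
    training-batch statistics. The default momentum (0.7) forgets the (0, 1)
    initialization within a couple of dozen updates, which keeps short
    desk-scale runs calibrated; ``momentum=None`` switches to the cumulative
    average of all batch statistics.
    """

    def __init__(self, channels: int, momentum: float | None = 0.7,
                 eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {
            "gamma": np.ones(channels, np.float32),
            "beta": np.zeros(channels, np.float32),
        }
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self._n_updates = 0
        self._cache = None

    def forward(self, x, train=False):
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            if self.momentum is None:
                n = self._n_updates
                self.running_mean = (
                    (n * self.running_mean + mean) / (n + 1)
                ).astype(np.float32)
                self.running_var = (
                    (n * self.running_var + var) / (n + 1)
                ).astype(np.float32)
                self._n_updates = n + 1
            else:
                self.running_mean = (
                    self.momentum * self.running_mean + (1 - self.momentum) * mean
                ).astype(np.float32)
                self.running_var = (
                    self.momentum * self.running_var + (1 - self.momentum) * var
                ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd)
        return g * xhat + b

    def backward(self, dy):
        xhat, invstd = self._cache
        g = self.params["gamma"]
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        dg = (dy * xhat).sum(axis=(0, 2, 3))
        db = dy.sum(axis=(0, 2, 3))
        self.grads["gamma"], self.grads["beta"] = dg, db
        coef = (g * invstd / m)[None, :, None, None]
        dx = coef * (
            m * dy
            - db[None, :, None, None]
            - xhat * dg[None, :, None, None]
        )
        return dx


class Dense(Layer):
    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        weight_scale: float | None = None,
    ):
        super().__init__()
        scale = np.sqrt(2.0 / in_dim) if weight_scale is None else weight_scale
        w = rng.normal(0.0, scale, size=(in_dim, out_dim)) if scale > 0 else np.zeros((in_dim, out_dim))
        self.params = {"W": w.astype(np.float32), "b": np.zeros(out_dim, np.float32)}
        self._x = None

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape = None

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy):
        return dy * self._mask


class Tanh(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._out = None

    def forward(self, x, train=False):
        out = np.tanh(x)
        if train:
            self._out = out
        return out

    def backward(self, dy):
        return dy * (1.0 - self._out**2)


class Inception(Layer):
    """Parallel 1x1 / 3x3 / 5x5 / avg-pool+1x1 branches, channel-concatenated.

    Each convolution is followed by a ReLU inside the branch. Output width is
    the sum of the branch widths.
    """

    def __init__(
        self,
        in_ch: int,
        rng: np.random.Generator,
        widths: tuple[int, int, int, int] = (16, 32, 8, 8),
    ):
        super().__init__()
        w1, w3, w5, wp = widths
        self.branches: list[list[Layer]] = [
            [Conv2D(in_ch, w1, 1, rng), ReLU()],
            [Conv2D(in_ch, w3, 3, rng), ReLU()],
            [Conv2D(in_ch, w5, 5, rng), ReLU()],
            [AvgPool3x3Same(), Conv2D(in_ch, wp, 1, rng), ReLU()],
        ]
        self.widths = widths
        self.out_ch = sum(widths)

    def forward(self, x, train=False):
        outs = []
        for branch in self.branches:
            h = x
            for layer in branch:
                h = layer.forward(h, train=train)
            outs.append(h)
        return np.concatenate(outs, axis=1)

    def backward(self, dy):
        dx = None
        start = 0
        for branch, w in zip(self.branches, self.widths):
            d = dy[:, start : start + w]
            for layer in reversed(branch):
                d = layer.backward(d)
            dx = d if dx is None else dx + d
            start += w
        return dx

    # parameter plumbing: expose branch conv params under prefixed names
    def iter_sublayers(self):
        for bi, branch in enumerate(self.branches):
            for li, layer in enumerate(branch):
                if layer.params:
                    yield f"b{bi}_{li}", layer


class Sequential:
    """Ordered layer container with flat parameter addressing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, capture: dict | None = None):
        """Run the stack; if `capture` is given, store the output of layer
        indices listed in capture['at'] into capture['out'][index]."""
        at = capture["at"] if capture else ()
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, train=train)
            if capture and i in at:
                capture["out"][i] = x
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def named_params(self):
        """Yield (path, layer, key) triples for every trainable array."""
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Inception):
                for sub_name, sub in layer.iter_sublayers():
                    for key in sub.params:
                        yield f"l{i}_{sub_name}_{key}", sub, key
            elif layer.params:
                for key in layer.params:
                    yield f"l{i}_{key}", layer, key

    def state_arrays(self):
        """All arrays needed to reconstruct the model state (params +
        batch-norm running statistics)."""
        out = {}
        for path, layer, key in self.named_params():
            out[path] = layer.params[key]
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2D):
                out[f"l{i}_running_mean"] = layer.running_mean
                out[f"l{i}_running_var"] = layer.running_var
        return out

    def load_state_arrays(self, arrays: dict, prefix: str = ""):
        for path, layer, key in self.named_params():
            layer.params[key] = arrays[prefix + path].astype(np.float32).copy()
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2D):
                layer.running_mean = arrays[f"{prefix}l{i}_running_mean"].astype(np.float32).copy()
                layer.running_var = arrays[f"{prefix}l{i}_running_var"].astype(np.float32).copy()
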