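"""Minimal CPU neural-network core for the spatiotemporal decoder.

Layers operate on ``(N, C, D1, D2, D3)`` arrays (batch, feature
channels, grid rows, grid columns, time).  Convolutions run through
JIT-compiled direct kernels (`topodecode._convkernels`); an im2col
reference path is kept for cross-checking.  Every layer implements
an explicit ``backward`` so gradients are exact and checkable against
finite differences, training is bit-deterministic for a fixed seed, and
intermediate activations/gradients are accessible (needed for
gradient-weighted class-activation maps).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._convkernels import conv3d_forward, conv3d_grad_w, conv3d_grad_x

__all__ = [
    "Layer",
    "Conv3d",
    "MaxPool3d",
    "BatchNorm",
    "ReLU",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy",
]

class Layer:
    """Base class: stateless unless it has ``params``/``grads`` dicts."""

    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, kernel: tuple[int, int, int]) -> np.ndarray:
    """(N, C, D1, D2, D3) -> (N, O1, O2, O3, C*k1*k2*k3) patch matrix."""
    v = sliding_window_view(x, kernel, axis=(2, 3, 4))
    # (N, C, O1, O2, O3, k1, k2, k3) -> (N, O1, O2, O3, C, k1, k2, k3)
    v = v.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    n, o1, o2, o3 = v.shape[:4]
    return np.ascontiguousarray(v).reshape(n, o1, o2, o3, -1)


class Conv3d(Layer):
    """3-D convolution (stride 1) with optional per-axis zero padding.

    ``kernel`` is (rows, cols, time); ``pad`` gives symmetric padding
    per spatial axis, e.g. 'same' row/col padding with valid time.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int, int],
        pad: tuple[int, int, int] = (0, 0, 0),
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        self.pad = tuple(pad)
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * int(np.prod(kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, *kernel))
        self.params = {"W": w.astype(dtype), "b": np.zeros(out_channels, dtype=dtype)}
        self.grads = {}
        self._x = None

    def out_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple(
            in_shape[i] + 2 * self.pad[i] - self.kernel[i] + 1 for i in range(3)
        )

    def _pad(self, x: np.ndarray, extra: tuple[int, int, int] = (0, 0, 0)) -> np.ndarray:
        p = [(0, 0), (0, 0)] + [
            (self.pad[i] + extra[i],) * 2 for i in range(3)
        ]
        if any(sum(q) for q in p):
            return np.pad(x, p)
        return x

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        xp = self._pad(x)
        self._xp = xp
        return conv3d_forward(xp, self.params["W"], self.params["b"])

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        w = self.params["W"]
        dout = np.ascontiguousarray(dout)
        db = dout.sum(axis=(0, 2, 3, 4))
        dw = conv3d_grad_w(self._xp, dout, w.shape)
        self.grads = {"W": dw.astype(w.dtype), "b": db.astype(w.dtype)}
        if not need_dx:
            return None
        dxp = conv3d_grad_x(dout, w, self._xp.shape)
        p1, p2, p3 = self.pad
        i1, i2, i3 = self._xp.shape[2:]
        return dxp[
            :,
            :,
            p1 : i1 - p1 or None,
            p2 : i2 - p2 or None,
            p3 : i3 - p3 or None,
        ]


class MaxPool3d(Layer):
    """Non-overlapping max pooling with window = stride; trailing
    samples that do not fill a window are cropped."""

    def __init__(self, window: tuple[int, int, int]) -> None:
        super().__init__()
        self.window = tuple(window)
        self._cache = None

    def out_shape(self, in_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        return tuple(in_shape[i] // self.window[i] for i in range(3))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p1, p2, p3 = self.window
        n, c, d1, d2, d3 = x.shape
        o1, o2, o3 = d1 // p1, d2 // p2, d3 // p3
        xc = x[:, :, : o1 * p1, : o2 * p2, : o3 * p3]
        xr = xc.reshape(n, c, o1, p1, o2, p2, o3, p3)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, o1, o2, o3, p1 * p2 * p3
        )
        idx = np.argmax(xr, axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        in_shape, idx = self._cache
        p1, p2, p3 = self.window
        n, c, d1, d2, d3 = in_shape
        o1, o2, o3 = d1 // p1, d2 // p2, d3 // p3
        dxr = np.zeros((n, c, o1, o2, o3, p1 * p2 * p3), dtype=dout.dtype)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(n, c, o1, o2, o3, p1, p2, p3).transpose(
            0, 1, 2, 5, 3, 6, 4, 7
        )
        dx = np.zeros(in_shape, dtype=dout.dtype)
        dx[:, :, : o1 * p1, : o2 * p2, : o3 * p3] = dxr.reshape(
            n, c, o1 * p1, o2 * p2, o3 * p3
        )
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes except the feature channel."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(n_features, dtype=dtype),
            "beta": np.zeros(n_features, dtype=dtype),
        }
        self.grads = {}
        self.running_mean = np.zeros(n_features, dtype=np.float64)
        self.running_var = np.ones(n_features, dtype=np.float64)
        self._cache = None

    @staticmethod
    def _bshape(x: np.ndarray) -> tuple:
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.astype(np.float64)
            self.running_var = (1 - m) * self.running_var + m * var.astype(np.float64)
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, axes, shape, train)
        return self.params["gamma"].reshape(shape) * xhat + self.params[
            "beta"
        ].reshape(shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape, trained = self._cache
        gamma = self.params["gamma"].reshape(shape)
        self.grads = {
            "gamma": (dout * xhat).sum(axis=axes).astype(self.params["gamma"].dtype),
            "beta": dout.sum(axis=axes).astype(self.params["beta"].dtype),
        }
        if not trained:
            return dout * gamma * inv.reshape(shape)
        m = float(np.prod([dout.shape[a] for a in axes]))
        dxhat = dout * gamma
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - xhat * (dxhat * xhat).mean(axis=axes).reshape(shape)
        )
        return term * inv.reshape(shape)


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.params = {"W": w.astype(dtype), "b": np.zeros(n_out, dtype=dtype)}
        self.grads = {}
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads = {
            "W": (self._x.T @ dout).astype(self.params["W"].dtype),
            "b": dout.sum(axis=0).astype(self.params["b"].dtype),
        }
        return dout @ self.params["W"].T


class Sequential:
    """Layer stack with cached inter-layer gradients for saliency."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers
        self._between_grads: list[np.ndarray | None] = [None] * (len(layers) + 1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._activations = [x]
        for layer in self.layers:
            x = layer.forward(x, train=train)
            self._activations.append(x)
        return x

    def backward(self, dout: np.ndarray, until: int = 0) -> np.ndarray:
        """Backpropagate; ``until`` stops before layer index ``until``."""
        self._between_grads = [None] * (len(self.layers) + 1)
        self._between_grads[len(self.layers)] = dout
        for i in range(len(self.layers) - 1, until - 1, -1):
            layer = self.layers[i]
            if i == until and isinstance(layer, Conv3d):
                # input gradient of the bottom conv layer is never consumed
                layer.backward(dout, need_dx=False)
                dout = None
            else:
                dout = layer.backward(dout)
            self._between_grads[i] = dout
        return dout

    def activation(self, layer_idx: int) -> np.ndarray:
        """Output of layer ``layer_idx - 1`` (input of ``layer_idx``)."""
        return self._activations[layer_idx]

    def grad_at(self, layer_idx: int) -> np.ndarray:
        """Gradient w.r.t. the input of layer ``layer_idx``."""
        g = self._between_grads[layer_idx]
        if g is None:
            raise RuntimeError("no cached gradient; call backward first")
        return g

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(l, k) for l in self.layers for k in l.params]

    def state(self) -> list[np.ndarray]:
        out = [l.params[k].copy() for l, k in self.parameters()]
        for l in self.layers:
            if isinstance(l, BatchNorm):
                out += [l.running_mean.copy(), l.running_var.copy()]
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = len(y)
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-300)).mean())
    dlogits = p
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(logits.dtype)


class Adam:
    """Adam optimizer over a `Sequential`'s parameters."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for i, (layer, key) in enumerate(model.parameters()):
            self.m[i] = np.zeros_like(layer.params[key], dtype=np.float64)
            self.v[i] = np.zeros_like(layer.params[key], dtype=np.float64)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, key) in enumerate(self.model.parameters()):
            g = layer.grads[key].astype(np.float64)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            layer.params[key] -= (
                self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(layer.params[key].dtype)
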