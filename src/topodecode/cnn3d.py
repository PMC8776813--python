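"""Five-layer spatiotemporal convolutional decoder.

Input is a topography-preserving trial ``X in R^{13 x 9 x T}``.  The
first three learnable layers are 3-D convolutions with kernel
3 x 4 x 5 (grid rows x grid columns x time samples); the fourth is a
2-D convolution with kernel 3 x 5 that slides over the (row, time)
plane with its weights shared across grid columns — it consumes the
3-D feature stack as input channels while costing only a 2-D kernel's
worth of parameters.  Each convolution is followed by ReLU, batch
normalization and max pooling; the fifth layer is fully connected with
a K-way softmax.

Geometry notes.  The 3-D convolutions use 'same' zero padding on the
two spatial axes (a 9-column grid cannot survive three valid
4-column kernels) and valid convolution in time; pooling is temporal
only until the final 2-D stage, so the full 13 x 9 scalp grid is
visible to every layer.  Filter counts default to 4/8/8 (3-D) and 16
(2-D) — modest on purpose, sized for single-core training — and are
configurable.  A ``cam_resolution`` variant shrinks the
pooling windows so the final convolutional feature maps keep a fine
time resolution for class-activation mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .topomap import TopoTensorSet

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "TrainedModel",
    "ArchitectureError",
    "DivergenceError",
    "build_model",
    "build_model_2d",
    "train",
    "predict",
]


class ArchitectureError(ValueError):
    """The layer stack collapses a dimension below its kernel size."""


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite loss at epoch {epoch}")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyper-parameters of the 5-layer decoder."""

    n_rows: int = 13
    n_cols: int = 9
    conv3d_kernel: tuple[int, int, int] = (3, 4, 5)
    conv3d_filters: tuple[int, int, int] = (4, 8, 8)
    conv2d_kernel: tuple[int, int] = (3, 5)
    conv2d_filters: int = 16
    pool3d: tuple[int, int, int] = (1, 1, 2)   # after each 3-D conv
    pool2d: tuple[int, int] = (2, 2)           # (rows, time) after the 2-D conv
    cam_resolution: bool = False

    @property
    def n_learnable_layers(self) -> int:
        return len(self.conv3d_filters) + 2  # 3-D convs + 2-D conv + dense

    @property
    def kernels(self) -> list[tuple[int, ...]]:
        """Reported kernel per learnable convolutional layer."""
        return [self.conv3d_kernel] * len(self.conv3d_filters) + [self.conv2d_kernel]

    def pooling_schedule(self) -> tuple[list[tuple[int, int, int]], tuple[int, int, int]]:
        """Per-3-D-layer pool windows and the final-stage pool window."""
        if not self.cam_resolution:
            pools3d = [self.pool3d] * len(self.conv3d_filters)
            pool2d = (self.pool2d[0], 1, self.pool2d[1])
        else:
            # keep one temporal pool for cost, none afterwards, and no
            # pooling after the 2-D stage: high-resolution feature maps
            pools3d = [self.pool3d] + [(1, 1, 1)] * (len(self.conv3d_filters) - 1)
            pool2d = (1, 1, 1)
        return pools3d, pool2d


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (cross-entropy loss, Adam)."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 60
    seed: int = 0
    deterministic_mode: bool = True  # training is seeded and single-threaded;
    # the flag is kept as an explicit statement of the reproducibility contract
    shuffle: bool = True
    early_stop_accuracy: float | None = None  # stop once training accuracy
    # reaches this level (checked after each epoch); None trains all epochs

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning rate, batch size and epochs must be positive")


@dataclass
class TrainedModel:
    """A (possibly still untrained) decoder with its provenance."""

    net: nn.Sequential
    arch: ArchitectureSpec
    input_T: int
    K: int
    seed: int
    history: list[float] = field(default_factory=list)
    cam_layer_index: int | None = None  # index of the 2-D conv ReLU output

    def parameters(self):
        return self.net.parameters()

    @property
    def n_learnable_layers(self) -> int:
        return self.arch.n_learnable_layers


def _shape_after(
    name: str, shape: tuple[int, int, int], kernel: tuple[int, int, int],
    pad: tuple[int, int, int],
) -> tuple[int, int, int]:
    out = tuple(shape[i] + 2 * pad[i] - kernel[i] + 1 for i in range(3))
    if min(out) < 1:
        raise ArchitectureError(
            f"{name}: kernel {kernel} collapses input {shape} (pad {pad}) to {out}"
        )
    return out


def _pool_after(
    name: str, shape: tuple[int, int, int], window: tuple[int, int, int]
) -> tuple[int, int, int]:
    out = tuple(shape[i] // window[i] for i in range(3))
    if min(out) < 1:
        raise ArchitectureError(
            f"{name}: pool {window} collapses input {shape} to {out}"
        )
    return out


def build_model(
    arch: ArchitectureSpec, input_T: int, K: int, seed: int = 0
) -> TrainedModel:
    """Assemble the 5-layer decoder for ``(13, 9, input_T)`` inputs."""
    rng = np.random.default_rng(seed)
    pools3d, pool2d = arch.pooling_schedule()
    kr, kc, kt = arch.conv3d_kernel
    pad = (kr // 2, kc // 2, 0)  # 'same' rows/cols, valid time

    layers: list[nn.Layer] = []
    shape = (arch.n_rows, arch.n_cols, input_T)
    c_in = 1
    cam_index = None
    for i, c_out in enumerate(arch.conv3d_filters):
        conv = nn.Conv3d(c_in, c_out, arch.conv3d_kernel, pad=pad, rng=rng)
        shape = _shape_after(f"conv3d_{i + 1}", shape, arch.conv3d_kernel, pad)
        layers += [conv, nn.ReLU(), nn.BatchNorm(c_out)]
        shape = _pool_after(f"pool_{i + 1}", shape, pools3d[i])
        layers.append(nn.MaxPool3d(pools3d[i]))
        c_in = c_out

    # 2-D stage: kernel (rows, time) shared across grid columns
    k2r, k2t = arch.conv2d_kernel
    kernel2 = (k2r, 1, k2t)
    conv2 = nn.Conv3d(c_in, arch.conv2d_filters, kernel2, pad=(0, 0, 0), rng=rng)
    shape = _shape_after("conv2d", shape, kernel2, (0, 0, 0))
    layers += [conv2, nn.ReLU()]
    cam_index = len(layers)  # activation index of the 2-D conv's ReLU output
    layers.append(nn.BatchNorm(arch.conv2d_filters))
    shape = _pool_after("pool2d", shape, pool2d)
    layers.append(nn.MaxPool3d(pool2d))

    n_flat = arch.conv2d_filters * int(np.prod(shape))
    layers += [nn.Flatten(), nn.Dense(n_flat, K, rng=rng)]
    return TrainedModel(
        net=nn.Sequential(layers),
        arch=arch,
        input_T=input_T,
        K=K,
        seed=seed,
        cam_layer_index=cam_index,
    )


def build_model_2d(
    input_channels: int, input_T: int, K: int,
    filters: tuple[int, ...] = (8, 16, 16, 32), seed: int = 0,
) -> TrainedModel:
    """Reference decoder on stacked channels x time inputs.

    A sanity baseline of matching depth that forgoes the
    topography-preserving grid: trials enter as ``(channels, T)``
    images (one spatial axis), convolved with (1, 1, 5) temporal
    kernels and a final (channels-collapsing) dense stage.
    """
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    shape = (input_channels, 1, input_T)
    c_in = 1
    for i, c_out in enumerate(filters):
        kernel = (3, 1, 5)  # slides down the arbitrary channel stacking
        layers.append(nn.Conv3d(c_in, c_out, kernel, pad=(0, 0, 0), rng=rng))
        shape = _shape_after(f"conv_{i + 1}", shape, kernel, (0, 0, 0))
        layers += [nn.ReLU(), nn.BatchNorm(c_out)]
        shape = _pool_after(f"pool_{i + 1}", shape, (1, 1, 2))
        layers.append(nn.MaxPool3d((1, 1, 2)))
        c_in = c_out
    n_flat = c_in * int(np.prod(shape))
    layers += [nn.Flatten(), nn.Dense(n_flat, K, rng=rng)]
    arch = ArchitectureSpec()
    return TrainedModel(
        net=nn.Sequential(layers), arch=arch, input_T=input_T, K=K, seed=seed
    )


def _check_shape(model: TrainedModel, x: np.ndarray) -> None:
    if x.shape[4] != model.input_T:
        raise ValueError(
            f"input has T={x.shape[4]}, model expects T={model.input_T}"
        )
    if model.cam_layer_index is not None and x.shape[2:4] != (
        model.arch.n_rows,
        model.arch.n_cols,
    ):
        raise ValueError(
            f"input grid {x.shape[2:4]} does not match "
            f"({model.arch.n_rows}, {model.arch.n_cols})"
        )


def _as_input(data) -> np.ndarray:
    arr = np.asarray(getattr(data, "data", data), dtype=np.float32)
    if arr.ndim == 4:
        arr = arr[:, None]
    return arr


def train(
    model: TrainedModel,
    train_set: TopoTensorSet,
    config: TrainingConfig = TrainingConfig(),
) -> TrainedModel:
    """Minimize mean cross-entropy with Adam; records per-epoch loss."""
    x = _as_input(train_set)
    y = np.asarray(train_set.labels, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training set must span at least 2 classes")
    _check_shape(model, x)

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.net, lr=config.learning_rate)
    n = len(x)
    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        losses = []
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            logits = model.net.forward(x[idx], train=True)
            loss, dlogits = nn.cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
        model.history.append(float(np.sum(losses) / n))
        if config.early_stop_accuracy is not None:
            _, pred = predict(model, x)
            if np.mean(pred == y) >= config.early_stop_accuracy:
                break
    return model


def predict(
    model: TrainedModel, inputs, batch_size: int = 256
) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels for a set of trials."""
    x = _as_input(inputs)
    _check_shape(model, x)
    probs = []
    for s in range(0, len(x), batch_size):
        logits = model.net.forward(x[s : s + batch_size], train=False)
        probs.append(nn.softmax(logits.astype(np.float64)))
    proba = np.concatenate(probs) if probs else np.empty((0, model.K))
    return proba, proba.argmax(axis=1)
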