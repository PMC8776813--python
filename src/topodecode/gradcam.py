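"""Gradient-weighted class activation maps for the EEG decoder.

For a trained decoder, the saliency of a trial for class ``c`` is
computed from the feature maps ``A_k`` of the last 2-D convolutional
layer (after ReLU): the gradient of the class score (pre-softmax
logit) with respect to each feature map is averaged over space and
time to give an importance weight ``alpha_k``, the weighted
combination ``sum_k alpha_k A_k`` is rectified, upsampled to the
``(13, 9, T)`` input space with multilinear interpolation, and
max-normalized.  Maps should be computed from a model built with
``cam_resolution=True`` so the feature maps keep fine time
resolution; per-class averages over validation trials give the
final interpretation maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cnn3d import TrainedModel, _as_input

__all__ = [
    "ActivationMap",
    "grad_cam",
    "average_maps",
    "localization_score",
]


@dataclass
class ActivationMap:
    """Nonnegative, max-normalized saliency over the input space."""

    values: np.ndarray          # (13, 9, T), >= 0, max 1 when nonzero
    class_id: int
    n_trials_averaged: int = 1
    model: TrainedModel | None = None
    raw_magnitude: float = 0.0  # pre-normalization mean, for class contrast

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("saliency values must be nonnegative")


def grad_cam(
    model: TrainedModel,
    trial: np.ndarray,
    target_class: int,
    interpolation: str = "linear",
) -> ActivationMap:
    """Class activation map of one trial in the (13, 9, T) input space.

    ``trial`` is a single (13, 9, T) input (a leading batch axis of 1
    is accepted).  The map is rectified, upsampled and max-normalized;
    an all-zero map (no feature evidence for the class) is returned
    as-is with a warning.
    """
    if model.cam_layer_index is None:
        raise ValueError("model does not expose a 2-D convolution stage")
    if not 0 <= target_class < model.K:
        raise ValueError(f"target_class {target_class} outside 0..{model.K - 1}")
    x = np.asarray(trial, dtype=np.float32)
    if x.ndim == 3:
        x = x[None]
    x = _as_input(x)

    net = model.net
    logits = net.forward(x, train=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    net.backward(dlogits, until=model.cam_layer_index)

    feats = net.activation(model.cam_layer_index)[0]     # (C, r, c, t)
    grads = net.grad_at(model.cam_layer_index)[0]        # (C, r, c, t)
    alpha = grads.mean(axis=(1, 2, 3))                   # importance per map
    coarse = np.einsum("k,krct->rct", alpha, feats)
    coarse = np.maximum(coarse, 0.0)

    target_shape = x.shape[2:]
    order = 1 if interpolation == "linear" else 0
    zoom = [t / s for t, s in zip(target_shape, coarse.shape)]
    values = ndimage.zoom(coarse.astype(np.float64), zoom, order=order, mode="nearest")
    values = np.maximum(values, 0.0)
    raw = float(values.mean())
    peak = values.max()
    if peak > 0:
        values = values / peak
    else:
        warnings.warn("degenerate saliency: activation map is identically zero")
    return ActivationMap(
        values=values,
        class_id=int(target_class),
        n_trials_averaged=1,
        model=model,
        raw_magnitude=raw,
    )


def average_maps(maps: list[ActivationMap]) -> dict[int, ActivationMap]:
    """Arithmetic per-class mean of maps, re-normalized to max 1."""
    if not maps:
        raise ValueError("no maps to average")
    by_class: dict[int, list[ActivationMap]] = {}
    for m in maps:
        by_class.setdefault(m.class_id, []).append(m)
    out = {}
    for cls, group in sorted(by_class.items()):
        stack = np.stack([m.values for m in group])
        mean = stack.mean(axis=0)
        raw = float(np.mean([m.raw_magnitude for m in group]))
        peak = mean.max()
        if peak > 0:
            mean = mean / peak
        out[cls] = ActivationMap(
            values=mean,
            class_id=cls,
            n_trials_averaged=len(group),
            model=group[0].model,
            raw_magnitude=raw,
        )
    return out


def localization_score(
    map_: ActivationMap | np.ndarray, planted_mask: np.ndarray, top_fraction: float = 0.05
) -> float:
    """Fraction of the top-saliency mass that falls inside a region.

    The top region is every cell whose saliency reaches the
    ``1 - top_fraction`` quantile (ties included, so a uniform map's
    top region is the whole volume); the score is the saliency mass of
    that region lying inside ``planted_mask``, divided by the region's
    total mass.
    """
    values = map_.values if isinstance(map_, ActivationMap) else np.asarray(map_)
    mask = np.asarray(planted_mask, dtype=bool)
    if mask.shape != values.shape:
        raise ValueError("mask and map shapes differ")
    if not mask.any():
        raise ValueError("planted mask is empty")
    thr = np.quantile(values, 1.0 - top_fraction)
    region = values >= thr
    total = values[region].sum()
    if total == 0:
        return 0.0
    return float(values[region & mask].sum() / total)
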