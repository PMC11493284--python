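"""Guided Grad-CAM attribution and median-threshold mask binarisation.

Grad-CAM forms a coarse class-discriminative map at a convolutional
layer: each activation channel is weighted by the spatial mean of the
gradient of the target-class score with respect to that channel, the
weighted sum is rectified, and the result is trilinearly upsampled to
the input grid.  Guided backpropagation produces a fine-grained input
gradient in which every ReLU transmits only where its forward input was
positive and the incoming backward signal is positive.  Guided Grad-CAM
is their element-wise product: coarse class evidence sharpened to voxel
resolution.  The attention map inherits the input volume's grid and
affine exactly, so it lives in the participant's native space.

The raw product is used as the importance score (no absolute value by
default); the Grad-CAM factor is already non-negative through its ReLU,
so negative scores can only come through the guided-backprop factor and
in practice fall below the median threshold that the downstream
binarisation applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_core import Volume
from .model import Classifier

__all__ = [
    "AttentionMap",
    "AttentionMask",
    "gradcam",
    "guided_backprop",
    "guided_gradcam",
    "class_symmetric_guided_gradcam",
    "binarize_attention",
]


@dataclass
class AttentionMap:
    """Voxelwise importance scores on the classifier-input grid."""

    volume: Volume
    target_class: int
    layer: str

    def __post_init__(self) -> None:
        if self.target_class not in (0, 1):
            raise ValueError("target_class must be 0 or 1")


@dataclass
class AttentionMask:
    """Binary mask M: 1 where importance strictly exceeds the map median."""

    mask: np.ndarray
    affine: np.ndarray
    threshold_value: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        vals = np.unique(self.mask)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be binary")


def _trilinear_resize(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Trilinear resize treating voxels as cells (centre-aligned grids)."""
    if arr.shape == tuple(shape):
        return arr.copy()
    coords = np.meshgrid(
        *[(np.arange(t) + 0.5) * (s / t) - 0.5 for s, t in zip(arr.shape, shape)],
        indexing="ij",
    )
    return ndimage.map_coordinates(arr, np.stack(coords), order=1, mode="nearest")


def gradcam(c: Classifier, v: Volume, target_class: int, layer: str | None = None) -> AttentionMap:
    """Class activation map at ``layer``.

    map = ReLU( sum_k alpha_k * A_k ) with alpha_k the spatial mean of
    d(score_c)/d(A_k); upsampled trilinearly to the input grid.  The
    default layer is the first convolutional block's rectified output —
    the finest-resolution feature maps of the network.
    """
    layer = layer or c.attribution_layer
    grads = c.class_score_gradients(v, target_class)
    if layer not in grads:
        raise KeyError(f"no layer named {layer!r}")
    g = grads[layer]
    a = c.activation(layer)
    if g.ndim != 5:
        raise ValueError(f"layer {layer!r} has no spatial axes; Grad-CAM needs a conv layer")
    weights = g[0].mean(axis=(1, 2, 3))                      # (C,)
    cam = np.maximum((weights[:, None, None, None] * a[0]).sum(axis=0), 0.0)
    data = _trilinear_resize(cam, v.shape)
    return AttentionMap(volume=Volume(data=data, affine=v.affine.copy(), id=v.id),
                        target_class=target_class, layer=layer)


def guided_backprop(c: Classifier, v: Volume, target_class: int) -> AttentionMap:
    """Input-space saliency with the guided ReLU backward rule.

    Values can be negative only through linear layers encountered before
    the first ReLU on the backward path (the input convolution).
    """
    grads = c.class_score_gradients(v, target_class, guided=True)
    data = grads["input"][0, 0]
    return AttentionMap(volume=Volume(data=data, affine=v.affine.copy(), id=v.id),
                        target_class=target_class, layer="input")


def guided_gradcam(c: Classifier, v: Volume, target_class: int,
                   layer: str | None = None, absolute: bool = False) -> AttentionMap:
    """Element-wise product of the Grad-CAM and guided-backprop maps."""
    layer = layer or c.attribution_layer
    cam = gradcam(c, v, target_class, layer)
    gbp = guided_backprop(c, v, target_class)
    data = cam.volume.data * gbp.volume.data
    if absolute:
        data = np.abs(data)
    return AttentionMap(volume=Volume(data=data, affine=v.affine.copy(), id=v.id),
                        target_class=target_class, layer=layer)


def class_symmetric_guided_gradcam(c: Classifier, v: Volume,
                                   layer: str | None = None) -> AttentionMap:
    """Polarity-invariant importance: sum of guided Grad-CAM over both classes.

    With a two-class softmax only the logit difference matters, so a
    trained network may encode the same discriminative evidence as
    positive drive on either logit; guided backpropagation transmits
    only positive-evidence paths and therefore sees that evidence from
    one class's score but not the other's.  Summing the guided Grad-CAM
    maps of both class scores yields a map of decision-relevant voxels
    that does not depend on the arbitrary polarity the training run
    happened to pick.  The recorded ``target_class`` is 1 by convention.
    """
    layer = layer or c.attribution_layer
    g1 = guided_gradcam(c, v, 1, layer)
    g0 = guided_gradcam(c, v, 0, layer)
    data = g1.volume.data + g0.volume.data
    return AttentionMap(volume=Volume(data=data, affine=v.affine.copy(), id=v.id),
                        target_class=1, layer=layer)


def binarize_attention(a: AttentionMap) -> AttentionMask:
    """Threshold an attention map at its median importance q_50%.

    M(x) = 1 iff a(x) > q_50% strictly; values equal to the median map to
    0.  The median interpolates linearly between the two central order
    statistics, so for maps with all-distinct values exactly half the
    voxels (even count) end up flagged.
    """
    data = a.volume.data
    if data.size == 0:
        raise ValueError("empty attention map")
    q50 = float(np.median(data))
    return AttentionMask(mask=(data > q50).astype(np.uint8),
                         affine=a.volume.affine.copy(), threshold_value=q50)
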