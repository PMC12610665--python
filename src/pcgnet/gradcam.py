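"""Grad-CAM heatmaps over the MFCC input plane.

Grad-CAM explains a class prediction by weighting a convolutional layer's
channels with the global average of the class-score gradient, summing,
rectifying, and upsampling the result onto the input geometry.  Here the
input plane is MFCC dimensions x frames, so the heatmaps show which
coefficient rows and time frames carry the evidence for each heart-valve
class — the basis for deciding how many static coefficients are worth
keeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import nn
from .model import WCNNClassifier

__all__ = ["Heatmap", "gradcam", "attention_profile"]


@dataclass
class Heatmap:
    """Normalized attention map with the model-input geometry.

    ``values`` lies in [0, 1] (max 1 unless the raw map was identically zero,
    in which case ``flagged`` is True).
    """

    values: np.ndarray
    target_class: str
    source_layer: int
    flagged: bool = False

    @property
    def shape(self):
        return self.values.shape


def _conv_layer_indices(network: nn.Network) -> list[int]:
    return [i for i, l in enumerate(network.layers) if isinstance(l, nn.Conv2D)]


def gradcam(
    clf: WCNNClassifier,
    feature_map: np.ndarray,
    target_class=None,
    source_layer: int | None = None,
) -> Heatmap:
    """Grad-CAM heatmap for one MFCC feature map.

    Parameters
    ----------
    clf : fitted :class:`~pcgnet.model.WCNNClassifier`
    feature_map : (dims, frames) array, the model input
    target_class : class label to explain (default: the predicted class)
    source_layer : index into ``clf.network_.layers`` of a conv layer
        (default: the last convolution)

    The per-channel weights are the global averages of the target-class
    logit's gradient with respect to the layer's activation; the weighted
    channel sum is rectified, bilinearly upsampled to the input geometry and
    min-max normalized to [0, 1].  A degenerate all-zero map is returned
    flagged rather than raising.
    """
    network = clf.network_
    conv_idx = _conv_layer_indices(network)
    if source_layer is None:
        source_layer = conv_idx[-1]
    elif source_layer not in conv_idx:
        raise ValueError(f"layer {source_layer} is not a convolution layer")

    fm = np.asarray(feature_map, dtype=np.float64)
    if fm.ndim != 2:
        raise ValueError("feature_map must be 2-D (dims, frames)")
    x = fm[None, None, :, :]

    logits = network.forward(x, training=False)
    n_out = logits.shape[1]
    if target_class is None:
        if n_out == 1:
            cls_idx = int(logits.ravel()[0] > 0)
        else:
            cls_idx = int(logits.argmax())
        target_class = clf.classes_[cls_idx]
    else:
        cls_idx = int(np.searchsorted(clf.classes_, target_class))
        if not (0 <= cls_idx < clf.classes_.size) or clf.classes_[cls_idx] != target_class:
            raise ValueError(f"unknown class {target_class!r}")

    dlogits = np.zeros_like(logits)
    if n_out == 1:
        # single sigmoid logit: its gradient explains the positive class;
        # negate for the negative class
        dlogits[0, 0] = 1.0 if cls_idx == 1 else -1.0
    else:
        dlogits[0, cls_idx] = 1.0
    act, grad = network.activation_and_gradient(x, dlogits, source_layer)

    weights = grad[0].mean(axis=(1, 2))                     # (C,)
    cam = np.maximum(np.einsum("c,chw->hw", weights, act[0]), 0.0)
    cam = resize(cam, fm.shape, order=1, mode="edge", anti_aliasing=False)
    lo, hi = cam.min(), cam.max()
    if hi <= 0.0:
        return Heatmap(np.zeros(fm.shape), str(target_class), source_layer, flagged=True)
    cam = (cam - lo) / (hi - lo)
    return Heatmap(cam, str(target_class), source_layer)


def attention_profile(heatmaps) -> np.ndarray:
    """Mean attention per MFCC dimension across a collection of heatmaps.

    Averages the maps over samples, then over frames, yielding one score per
    feature dimension — the quantity used to judge which coefficient rows the
    model actually attends to.
    """
    maps = [h.values if isinstance(h, Heatmap) else np.asarray(h) for h in heatmaps]
    if not maps:
        raise ValueError("empty heatmap collection")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("heatmap shapes differ")
    return np.stack(maps).mean(axis=0).mean(axis=1)
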