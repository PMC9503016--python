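"""Gradient-weighted class-activation maps for the patch classifier.

For a target class, the gradient of its (pre-softmax) score is taken with
respect to the last convolutional feature block.  Channel weights are the
spatial means of those gradients; the saliency map is the rectified,
channel-weighted sum of the activations, normalized to [0, 1] and
bilinearly upsampled to the input patch size.  On this pipeline the maps
are the check that class identity is carried by tissue *texture* rather
than by planted deposits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .classifier import ClassifierModel

__all__ = ["SaliencyMap", "gradcam_map", "saliency_overlay"]


@dataclass
class SaliencyMap:
    values: np.ndarray          # (patch, patch) in [0, 1]
    target_class: int

    def __post_init__(self):
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("saliency values must lie in [0, 1]")


def gradcam_map(model: ClassifierModel, patch: np.ndarray,
                target_class: int, layer: int = -1) -> SaliencyMap:
    """Saliency of ``target_class`` for one patch.

    ``layer`` selects the convolutional block whose activations are
    weighted: -1 (default) is the final block, smaller indices give
    higher-resolution (less semantic) maps.  An all-zero map (degenerate
    gradients) is returned as zeros rather than dividing by zero.
    """
    if not (0 <= target_class < model.arch.num_classes):
        raise ValueError("target class out of range")
    logits, _, features = model.forward(patch[None], return_features=True,
                                        feature_layer=layer)
    features.retain_grad()
    logits[0, target_class].backward()
    grads = features.grad[0]                     # (C, h, w)
    activations = features.data[0]
    alpha = grads.mean(axis=(1, 2))              # channel weights
    cam = np.maximum((alpha[:, None, None] * activations).sum(axis=0), 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    size = patch.shape[0]
    zoom = (size / cam.shape[0], size / cam.shape[1])
    up = np.clip(ndi.zoom(cam, zoom, order=1), 0.0, 1.0)
    return SaliencyMap(values=up, target_class=target_class)


def saliency_overlay(patch: np.ndarray, saliency: SaliencyMap,
                     alpha: float = 0.5) -> np.ndarray:
    """Jet-colormapped saliency blended over the patch (uint8 RGB)."""
    v = saliency.values
    # compact jet ramp: blue -> cyan -> yellow -> red
    r = np.clip(1.5 - np.abs(4 * v - 3), 0, 1)
    g = np.clip(1.5 - np.abs(4 * v - 2), 0, 1)
    b = np.clip(1.5 - np.abs(4 * v - 1), 0, 1)
    heat = np.stack([r, g, b], axis=-1) * 255
    out = (1 - alpha) * patch.astype(np.float64) + alpha * heat
    return np.clip(out, 0, 255).astype(np.uint8)
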