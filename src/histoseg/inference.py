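"""Sliding-window reconstruction of a pixel-wise mask from patch labels.

A window of ``patch_size`` pixels slides over the (reflection-padded) image
at ``stride`` steps; the predicted class of each window is painted onto the
central ``stride x stride`` block, so the blocks tile the image exactly.
Larger strides are cheaper and coarser around boundaries; stride 128 with
patch 256 is the standard segmentation setting, while pathology heatmaps
use stride 16.

Optionally each window's label is replaced by the argmax of the central
marginal of a CRF over the g x g neighborhood of windows (mean-field
inference over classifier embeddings) — the spatially smoothed variant.
With all pairwise weights zero this reduces bit-for-bit to the plain
per-window argmax.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from . import ncrf
from .classifier import ClassifierModel
from .patches import crop_patch
from .synthetic import BACKGROUND, GM, WM

__all__ = ["LabelMask", "InferenceConfig", "window_grid",
           "sliding_window_predict", "ModelPredictor", "MaskOracleClassifier",
           "save_mask", "load_mask", "mask_overlay"]

ORACLE_LOGIT = 12.0   # one-hot logit scale used by stub classifiers


@dataclass
class LabelMask:
    labels: np.ndarray            # 2-D uint8 raster of {0,1,2}
    downsample_factor: int = 1    # per-axis, relative to the source image

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        bad = set(np.unique(self.labels)) - {BACKGROUND, GM, WM}
        if bad:
            raise ValueError(f"mask contains invalid labels {sorted(bad)}")
        if self.downsample_factor < 1:
            raise ValueError("downsample factor must be >= 1")


@dataclass(frozen=True)
class InferenceConfig:
    patch_size: int = 256
    stride: int = 128
    use_ncrf: bool = False
    grid_size: int = 3
    pairwise_weight: float = 1.0
    output_resolution: str = "full"      # "full" | "stride"
    batch_size: int = 64

    def __post_init__(self):
        if self.stride > self.patch_size:
            raise ValueError("stride must not exceed patch size")
        if self.patch_size % 2:
            raise ValueError("patch size must be even")
        if self.grid_size % 2 == 0:
            raise ValueError("CRF grid size must be odd")
        if self.output_resolution not in ("full", "stride"):
            raise ValueError("output_resolution must be 'full' or 'stride'")


def window_grid(image_shape: tuple, cfg: InferenceConfig) -> list[tuple]:
    """Row-major window centers (left to right, top to bottom).

    Window k along an axis owns the central block
    ``[k*stride, (k+1)*stride)``; its center sits at ``k*stride + stride//2``.
    ``ceil(dim / stride)`` windows cover each axis.
    """
    h, w = image_shape[:2]
    s = cfg.stride
    ny = -(-h // s)
    nx = -(-w // s)
    return [(kx * s + s // 2, ky * s + s // 2)
            for ky in range(ny) for kx in range(nx)]


class ModelPredictor:
    """Adapter: crops windows and runs the CNN in batches."""

    def __init__(self, model: ClassifierModel):
        self.model = model

    def predict_windows(self, image, centers, patch_size, batch_size=64):
        h, w = image.shape[:2]
        logits = np.empty((len(centers), 3))
        embeddings = np.empty((len(centers), self.model.embedding_dim))
        for start in range(0, len(centers), batch_size):
            chunk = centers[start:start + batch_size]
            patches = np.stack([
                crop_patch(image, (min(x, w - 1), min(y, h - 1)), patch_size)
                for x, y in chunk])
            out_logits, out_emb = self.model.forward(patches)
            logits[start:start + len(chunk)] = out_logits.data
            embeddings[start:start + len(chunk)] = out_emb.data
        return logits, embeddings


class MaskOracleClassifier:
    """Stub classifier wrapping a ground-truth mask.

    Returns one-hot logits (and one-hot embeddings) for the mask label at
    each window center — the reference predictor for reconstruction tests.
    """

    def __init__(self, mask: np.ndarray):
        self.mask = np.asarray(mask)

    def predict_windows(self, image, centers, patch_size, batch_size=None):
        h, w = self.mask.shape
        labels = np.array([self.mask[min(y, h - 1), min(x, w - 1)]
                           for x, y in centers], dtype=int)
        logits = np.full((len(centers), 3), -ORACLE_LOGIT)
        logits[np.arange(len(centers)), labels] = ORACLE_LOGIT
        embeddings = np.eye(3)[labels] + 1e-3   # nonzero norm, class-aligned
        return logits, embeddings


def _reflect_index(i: int, n: int) -> int:
    """Mirror an out-of-range grid index back into [0, n)."""
    if n == 1:
        return 0
    period = 2 * n - 2
    i = abs(i) % period
    return i if i < n else period - i


def _ncrf_window_labels(logits: np.ndarray, embeddings: np.ndarray,
                        ny: int, nx: int, cfg: InferenceConfig) -> np.ndarray:
    g = cfg.grid_size
    half = g // 2
    weights = ncrf.grid_pairwise_weights((g, g), cfg.pairwise_weight)
    labels = np.empty(ny * nx, dtype=int)
    for ky in range(ny):
        for kx in range(nx):
            idx = [_reflect_index(ky + dy, ny) * nx
                   + _reflect_index(kx + dx, nx)
                   for dy in range(-half, half + 1)
                   for dx in range(-half, half + 1)]
            obs = ncrf.PatchGridObservation(
                grid_shape=(g, g), embeddings=embeddings[idx],
                unary_scores=logits[idx])
            field = ncrf.meanfield_infer(obs, weights)
            center = ncrf.center_marginal(field, (g, g))
            labels[ky * nx + kx] = int(np.argmax(center))
    return labels


def sliding_window_predict(image: np.ndarray, model,
                           cfg: InferenceConfig = InferenceConfig()
                           ) -> LabelMask:
    """Classify every window and paint central blocks into a label mask.

    ``model`` is either a :class:`ClassifierModel` or any object exposing
    ``predict_windows(image, centers, patch_size)`` (e.g. the mask oracle).
    """
    predictor = (ModelPredictor(model) if isinstance(model, ClassifierModel)
                 else model)
    h, w = image.shape[:2]
    s = cfg.stride
    centers = window_grid(image.shape, cfg)
    logits, embeddings = predictor.predict_windows(
        image, centers, cfg.patch_size)
    ny, nx = -(-h // s), -(-w // s)
    if cfg.use_ncrf:
        labels = _ncrf_window_labels(logits, embeddings, ny, nx, cfg)
    else:
        labels = np.argmax(logits, axis=1)
    grid = labels.reshape(ny, nx).astype(np.uint8)
    if cfg.output_resolution == "stride":
        return LabelMask(labels=grid, downsample_factor=s)
    full = np.repeat(np.repeat(grid, s, axis=0), s, axis=1)[:h, :w]
    return LabelMask(labels=full, downsample_factor=1)


# -- mask I/O -----------------------------------------------------------------

def save_mask(mask: LabelMask, path) -> None:
    path = Path(path)
    Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(
        {"downsample_factor_per_axis": mask.downsample_factor}))


def load_mask(path) -> LabelMask:
    path = Path(path)
    labels = np.asarray(Image.open(path))
    sidecar = path.with_suffix(path.suffix + ".json")
    factor = 1
    if sidecar.exists():
        factor = int(json.loads(sidecar.read_text())
                     ["downsample_factor_per_axis"])
    return LabelMask(labels=labels, downsample_factor=factor)


def mask_overlay(mask: LabelMask) -> np.ndarray:
    """Color rendering: cyan GM, yellow WM, black background."""
    palette = np.array([[0, 0, 0], [0, 255, 255], [255, 255, 0]],
                       dtype=np.uint8)
    return palette[mask.labels]
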