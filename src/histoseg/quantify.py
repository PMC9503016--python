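"""Region-stratified quantification of amyloid deposits.

A pluggable plaque classifier ``f`` maps a 256x256 patch to three
independent confidence scores in [0, 1] — cored, diffuse, CAA (multi-label
contract).  Sliding ``f`` over the slide at stride 16 yields three
confidence heatmaps at 1/16 of the source resolution.  Each heatmap is
thresholded into a binary mask and blob-labeled (8-connectivity); counting
then stratifies detections by the grey/white-matter segmentation ``g``:

* ``blob`` mode (headline): each supra-threshold blob contributes one
  count to C[type, region] where region is the segmentation label under
  the blob centroid; blobs whose centroid lands on background are dropped
  and reported.
* ``patch`` mode: the literal per-window accumulator — every window whose
  score clears the threshold adds a one-hot increment for (type, region of
  the window center).

The result is the 1x6 count vector C indexed (cored, diffuse, CAA) x
(GM, WM), plus a provenance table of counted detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .inference import InferenceConfig, LabelMask, window_grid
from .patches import crop_patch
from .synthetic import BACKGROUND, GM, WM, PLAQUE_TYPES, SyntheticSample

__all__ = ["ConfidenceHeatmap", "PlaqueCountVector", "PlaqueOracle",
           "generate_confidence_heatmaps", "threshold_and_label",
           "quantify_plaques", "render_overlay"]

EIGHT = np.ones((3, 3), dtype=bool)
REGIONS = ("GM", "WM")
REGION_VALUE = {"GM": GM, "WM": WM}


@dataclass
class ConfidenceHeatmap:
    """Per-type confidence rasters at 1/stride of source resolution."""
    cored: np.ndarray
    diffuse: np.ndarray
    caa: np.ndarray
    stride: int = 16

    def __post_init__(self):
        shapes = {self.cored.shape, self.diffuse.shape, self.caa.shape}
        if len(shapes) != 1:
            raise ValueError("heatmap layers must share one shape")
        for layer in self.layers().values():
            if layer.min() < 0 or layer.max() > 1:
                raise ValueError("confidences must lie in [0, 1]")

    def layers(self) -> dict[str, np.ndarray]:
        return {"cored": self.cored, "diffuse": self.diffuse,
                "CAA": self.caa}


@dataclass
class PlaqueCountVector:
    """6 counters: (cored, diffuse, CAA) x (GM, WM), plus provenance."""
    counts: dict = field(default_factory=lambda: {
        (t, r): 0 for t in PLAQUE_TYPES for r in REGIONS})
    detections: list = field(default_factory=list)  # (x, y, type, region, s)
    dropped: list = field(default_factory=list)     # centroid on background

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[(t, r)]
                         for t in PLAQUE_TYPES for r in REGIONS], dtype=int)

    def total(self) -> int:
        return int(self.as_vector().sum())


class PlaqueOracle:
    """Ground-truth-backed stand-in for the plaque classifier contract.

    Scores 1.0 for a type exactly when a planted deposit center of that
    type lies in the window's central ``stride x stride`` block, else 0.
    Synthetic: used to exercise the counting framework without a trained
    deposit model.
    """

    def __init__(self, sample: SyntheticSample, stride: int = 16):
        self.stride = stride
        # central blocks tile the slide; block index of a point is p // stride
        self.blocks = {t: {(x // stride, y // stride)
                           for x, y, k in sample.plaques if k == t}
                       for t in PLAQUE_TYPES}

    def __call__(self, patch: np.ndarray, center: tuple) -> np.ndarray:
        cx, cy = center
        s = self.stride
        block = ((cx - s // 2) // s, (cy - s // 2) // s)
        return np.array([1.0 if block in self.blocks[t] else 0.0
                         for t in PLAQUE_TYPES])


def generate_confidence_heatmaps(image: np.ndarray, f, stride: int = 16,
                                 patch_size: int = 256) -> ConfidenceHeatmap:
    """Slide ``f`` over the image; one score triple per window, row-major.

    ``f`` is called as ``f(patch, center)`` when it accepts the window
    center (oracles), else as ``f(patch)``.
    """
    cfg = InferenceConfig(patch_size=patch_size, stride=stride)
    centers = window_grid(image.shape, cfg)
    h, w = image.shape[:2]
    ny, nx = -(-h // stride), -(-w // stride)
    out = np.zeros((3, ny, nx))
    wants_center = isinstance(f, PlaqueOracle) or getattr(
        f, "wants_center", False)
    for k, (x, y) in enumerate(centers):
        patch = crop_patch(image, (min(x, w - 1), min(y, h - 1)), patch_size)
        scores = f(patch, (x, y)) if wants_center else f(patch)
        out[:, k // nx, k % nx] = np.clip(scores, 0.0, 1.0)
    return ConfidenceHeatmap(cored=out[0], diffuse=out[1], caa=out[2],
                             stride=stride)


def threshold_and_label(layer: np.ndarray, threshold: float
                        ) -> tuple[np.ndarray, int, np.ndarray]:
    """Binarize (ties count as detections) and 8-connected blob label.

    Returns (binary mask, blob count, (n, 2) centroid array in heatmap
    coordinates, (x, y) order).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    binary = layer >= threshold
    labels, n = ndimage.label(binary, structure=EIGHT)
    if n == 0:
        return binary, 0, np.empty((0, 2))
    cyx = ndimage.center_of_mass(binary, labels, index=range(1, n + 1))
    centroids = np.array(cyx)[:, ::-1]      # (row, col) -> (x, y)
    return binary, n, centroids


def quantify_plaques(image: np.ndarray, f, g: LabelMask,
                     mode: str = "blob", stride: int = 16,
                     thresholds: dict | None = None,
                     patch_size: int = 256,
                     heatmaps: ConfidenceHeatmap | None = None
                     ) -> PlaqueCountVector:
    """Count deposits per (type, region) under segmentation ``g``.

    ``g`` must be a full-resolution :class:`LabelMask` of the same image
    (the region raster and the heatmaps are kept shape-congruent by using
    the same stride).  Precomputed ``heatmaps`` may be passed to skip the
    sliding-window pass.
    """
    if mode not in ("blob", "patch"):
        raise ValueError("mode must be 'blob' or 'patch'")
    thresholds = dict(thresholds or {})
    for t in PLAQUE_TYPES:
        thresholds.setdefault(t, 0.5)
    if heatmaps is None:
        heatmaps = generate_confidence_heatmaps(image, f, stride=stride,
                                                patch_size=patch_size)
    if heatmaps.stride != stride:
        raise ValueError("heatmap stride differs from requested stride")
    region_raster = g.labels
    if g.downsample_factor != 1 or region_raster.shape != image.shape[:2]:
        raise ValueError("segmentation mask must be full-resolution "
                         "and match the image")
    h, w = image.shape[:2]
    result = PlaqueCountVector()
    for t, layer in heatmaps.layers().items():
        if mode == "blob":
            _, n, centroids = threshold_and_label(layer, thresholds[t])
            for hx, hy in centroids:
                px = min(int(round(hx * stride + stride // 2)), w - 1)
                py = min(int(round(hy * stride + stride // 2)), h - 1)
                region_val = int(region_raster[py, px])
                score = float(layer[int(round(hy)), int(round(hx))])
                if region_val == BACKGROUND:
                    result.dropped.append((px, py, t))
                    continue
                region = "GM" if region_val == GM else "WM"
                result.counts[(t, region)] += 1
                result.detections.append((px, py, t, region, score))
        else:
            ny, nx = layer.shape
            for ky in range(ny):
                for kx in range(nx):
                    if layer[ky, kx] < thresholds[t]:
                        continue
                    px = min(kx * stride + stride // 2, w - 1)
                    py = min(ky * stride + stride // 2, h - 1)
                    region_val = int(region_raster[py, px])
                    if region_val == BACKGROUND:
                        result.dropped.append((px, py, t))
                        continue
                    region = "GM" if region_val == GM else "WM"
                    result.counts[(t, region)] += 1
                    result.detections.append(
                        (px, py, t, region, float(layer[ky, kx])))
    return result


def counts_csv(result: PlaqueCountVector) -> str:
    lines = ["type,region,count"]
    for t in PLAQUE_TYPES:
        for r in REGIONS:
            lines.append(f"{t},{r},{result.counts[(t, r)]}")
    return "\n".join(lines) + "\n"


def save_heatmaps(heatmaps: ConfidenceHeatmap, path) -> None:
    """Write the three confidence layers as one float32 TIFF stack."""
    import tifffile
    stack = np.stack([heatmaps.cored, heatmaps.diffuse, heatmaps.caa])
    tifffile.imwrite(str(path), stack.astype(np.float32),
                     photometric="minisblack")


def load_heatmaps(path, stride: int = 16) -> ConfidenceHeatmap:
    import tifffile
    stack = tifffile.imread(str(path))
    return ConfidenceHeatmap(cored=stack[0].astype(np.float64),
                             diffuse=stack[1].astype(np.float64),
                             caa=stack[2].astype(np.float64), stride=stride)


def detections_csv(result: PlaqueCountVector) -> str:
    lines = ["x,y,type,region,score"]
    for x, y, t, region, score in result.detections:
        lines.append(f"{x},{y},{t},{region},{score}")
    return "\n".join(lines) + "\n"


def render_overlay(image: np.ndarray, heatmaps: ConfidenceHeatmap,
                   mask: LabelMask,
                   thresholds: dict | None = None) -> np.ndarray:
    """Deterministic overlay: GM/WM tint plus orange detection markers."""
    thresholds = dict(thresholds or {})
    for t in PLAQUE_TYPES:
        thresholds.setdefault(t, 0.5)
    if mask.labels.shape != image.shape[:2]:
        raise ValueError("mask and image shapes differ")
    out = image.astype(np.float64).copy()
    tint = np.zeros_like(out)
    tint[mask.labels == GM] = (0, 255, 255)
    tint[mask.labels == WM] = (255, 255, 0)
    sel = mask.labels != BACKGROUND
    out[sel] = 0.7 * out[sel] + 0.3 * tint[sel]
    stride = heatmaps.stride
    h, w = image.shape[:2]
    for t, layer in heatmaps.layers().items():
        _, n, centroids = threshold_and_label(layer, thresholds[t])
        for hx, hy in centroids:
            px = min(int(round(hx * stride + stride // 2)), w - 1)
            py = min(int(round(hy * stride + stride // 2)), h - 1)
            y0, y1 = max(0, py - 3), min(h, py + 4)
            x0, x1 = max(0, px - 3), min(w, px + 4)
            out[y0:y1, x0:x1] = (255, 140, 0)       # orange marker
    return np.clip(out, 0, 255).astype(np.uint8)
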