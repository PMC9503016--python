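"""Patch extraction, center-pixel labeling, and inverse-frequency weights.

A slide is turned into a classification dataset by cropping fixed-size RGB
patches and labeling each with the class of its *central* pixel in the
ground-truth mask.  Class imbalance (GM and background dominate WM) is
handled downstream by weighting the cross-entropy loss with the inverse of
the class frequencies, normalized so the smallest weight is 1.

Coordinate convention (repo-wide): 0-based, x to the right, y down, pixel
centers at integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import SyntheticSample

__all__ = ["PatchSample", "ClassWeights", "crop_patch",
           "sample_training_patches", "compute_class_weights"]


@dataclass(frozen=True)
class PatchSample:
    pixels: np.ndarray          # (size, size, 3) uint8
    center: tuple               # (x, y) in full-resolution coordinates
    label: int                  # {0=background, 1=GM, 2=WM}


@dataclass(frozen=True)
class ClassWeights:
    """Loss weights per class, min-normalized to 1."""
    w_background: float
    w_gm: float
    w_wm: float

    def as_array(self) -> np.ndarray:
        return np.array([self.w_background, self.w_gm, self.w_wm])


def crop_patch(image: np.ndarray, center: tuple, size: int) -> np.ndarray:
    """Crop a ``size``×``size`` window centered at ``(x, y)``.

    The window covers ``[c - size//2, c + size//2)`` on each axis; parts
    falling outside the image are filled by reflection (mirror about the
    edge pixel, which is not repeated), so any in-image center is valid.
    """
    if size < 32 or size % 2:
        raise ValueError("patch size must be even and >= 32")
    x, y = center
    h, w = image.shape[:2]
    if not (0 <= x < w and 0 <= y < h):
        raise IndexError(f"center {center} outside image of shape {w}x{h}")
    half = size // 2
    y0, y1 = y - half, y + half
    x0, x1 = x - half, x + half
    pad_t, pad_b = max(0, -y0), max(0, y1 - h)
    pad_l, pad_r = max(0, -x0), max(0, x1 - w)
    if pad_t or pad_b or pad_l or pad_r:
        pads = ((pad_t, pad_b), (pad_l, pad_r)) + ((0, 0),) * (image.ndim - 2)
        image = np.pad(image, pads, mode="reflect")
        y0, y1 = y0 + pad_t, y1 + pad_t
        x0, x1 = x0 + pad_l, x1 + pad_l
    return image[y0:y1, x0:x1].copy()


def sample_training_patches(sample: SyntheticSample, n: int, size: int = 256,
                            seed: int = 0,
                            boundary_exclusion_radius: int = 0
                            ) -> list[PatchSample]:
    """Draw ``n`` patches with centers uniform over the slide.

    Labels come from the mask at the center pixel.  If
    ``boundary_exclusion_radius`` > 0, centers closer than that to a
    class boundary are rejected (patches straddling the GM/WM boundary are
    kept by default, labeled by their center).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = sample.mask.shape
    valid = None
    if boundary_exclusion_radius > 0:
        from scipy import ndimage
        interior = np.ones((h, w), dtype=bool)
        for c in (0, 1, 2):
            layer = sample.mask == c
            edge = layer ^ ndimage.binary_erosion(layer, border_value=1)
            near = ndimage.binary_dilation(
                edge, iterations=boundary_exclusion_radius)
            interior &= ~near
        valid = np.nonzero(interior)

    out: list[PatchSample] = []
    while len(out) < n:
        if valid is None:
            x = int(rng.integers(0, w))
            y = int(rng.integers(0, h))
        else:
            k = int(rng.integers(0, valid[0].size))
            y, x = int(valid[0][k]), int(valid[1][k])
        pixels = crop_patch(sample.image, (x, y), size)
        out.append(PatchSample(pixels=pixels, center=(x, y),
                               label=int(sample.mask[y, x])))
    return out


def save_patch_dataset(samples: list[PatchSample], directory) -> None:
    """Write patches as PNGs with a CSV manifest (path, x, y, label)."""
    from pathlib import Path
    from PIL import Image
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = ["path,x,y,label"]
    for k, p in enumerate(samples):
        name = f"patch_{k:06d}.png"
        Image.fromarray(p.pixels).save(directory / name)
        rows.append(f"{name},{p.center[0]},{p.center[1]},{p.label}")
    (directory / "manifest.csv").write_text("\n".join(rows) + "\n")


def load_patch_dataset(directory) -> list[PatchSample]:
    from pathlib import Path
    from PIL import Image
    directory = Path(directory)
    out = []
    rows = (directory / "manifest.csv").read_text().strip().splitlines()[1:]
    for row in rows:
        name, x, y, label = row.split(",")
        pixels = np.asarray(Image.open(directory / name))
        out.append(PatchSample(pixels=pixels, center=(int(x), int(y)),
                               label=int(label)))
    return out


def compute_class_weights(counts) -> ClassWeights:
    """Inverse-frequency weights, normalized so the minimum weight is 1.

    ``counts`` maps class index (or the names ``background/GM/WM``) to the
    number of training patches of that class.  With counts of roughly
    310k GM / 100k WM / 300k background this yields the 1 : 3.1 : 1.03
    (background : WM normalized against GM) pattern that rounds to the
    canonical 1:3:1 weighting.
    """
    name_to_idx = {"background": 0, "GM": 1, "WM": 2, 0: 0, 1: 1, 2: 2}
    arr = np.zeros(3)
    for key, value in dict(counts).items():
        arr[name_to_idx[key]] = value
    if np.any(arr <= 0):
        raise ValueError("all class counts must be positive")
    weights = arr.max() / arr          # 1/freq, min weight = 1
    return ClassWeights(w_background=float(weights[0]),
                        w_gm=float(weights[1]), w_wm=float(weights[2]))
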