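"""Seeded generator of synthetic brain-tissue images with ground truth.

Emulates the geometry of a cortical section at desk scale: a near-white
slide background, a grey-matter (GM) ribbon and an adjacent white-matter
(WM) band separated by a gently curved boundary.  The three classes are
made separable by *texture*, mirroring what drives the real discrimination:

* background — bright, almost noise-free;
* GM — darker tan base carpeted with dense, isotropic cell-like speckle
  (high local variance);
* WM — lighter base with oriented fiber striations (intermediate variance).

Amyloid-like deposits of three types (cored, diffuse, CAA) are planted as
brown blobs with Poisson counts per region, and their exact centers/types
are returned as ground truth.  Slide artifacts (detached tissue fragments,
speckles) can be painted onto the background with exact pixel areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

BACKGROUND, GM, WM = 0, 1, 2
CLASS_NAMES = ("background", "GM", "WM")
PLAQUE_TYPES = ("cored", "diffuse", "CAA")

__all__ = ["SyntheticSpec", "SyntheticSample", "generate_tissue_sample",
           "inject_artifacts", "BACKGROUND", "GM", "WM", "CLASS_NAMES",
           "PLAQUE_TYPES"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic slide.

    ``plaque_rates`` maps ``(type, region)`` with type in
    ``{"cored","diffuse","CAA"}`` and region in ``{"GM","WM"}`` to the
    expected (Poisson) number of deposits planted in that region.
    ``gm_wm_ratio`` is the target GM:WM area ratio; real sections range
    from about 3:1 to 1:1, so the default sits in between.
    """

    image_width: int = 1024
    image_height: int = 1024
    region_layout_seed: int = 0
    gm_wm_ratio: float = 2.0
    background_fraction: float = 0.25
    boundary_curvature: float = 0.04   # amplitude as a fraction of height
    background_brightness: int = 242
    background_noise: float = 3.0
    gm_blob_density: float = 0.10      # fraction of GM pixels seeded as cells
    wm_fiber_spacing: float = 9.0      # stripe period, px
    wm_fiber_angle: float = 0.35       # radians from horizontal
    plaque_rates: dict = field(default_factory=lambda: {
        ("cored", "GM"): 6.0, ("cored", "WM"): 1.0,
        ("diffuse", "GM"): 8.0, ("diffuse", "WM"): 1.0,
        ("CAA", "GM"): 2.0, ("CAA", "WM"): 0.5,
    })
    plaque_radius_range: tuple = (6, 14)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.image_width < 512 or self.image_height < 512:
            raise ValueError("image dimensions must be >= 512 px")
        if any(r < 0 for r in self.plaque_rates.values()):
            raise ValueError("plaque rates must be non-negative")
        lo, hi = self.plaque_radius_range
        if not (4 <= lo <= hi <= 64):
            raise ValueError("plaque radii must lie within [4, 64] px")
        if not 0 < self.gm_wm_ratio:
            raise ValueError("gm_wm_ratio must be positive")


@dataclass
class SyntheticSample:
    image: np.ndarray                   # (H, W, 3) uint8
    mask: np.ndarray                    # (H, W) uint8 in {0,1,2}
    plaques: list                       # [(x, y, type_str), ...]
    artifacts: list = field(default_factory=list)   # [set of (y, x) pixels]
    spec: SyntheticSpec | None = None

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions differ")


def _region_bands(spec: SyntheticSpec) -> np.ndarray:
    """Mask of {0,1,2}: background margins, GM ribbon, WM band below it."""
    h, w = spec.image_height, spec.image_width
    rng = np.random.default_rng(spec.region_layout_seed)
    tissue_frac = 1.0 - spec.background_fraction
    gm_frac = tissue_frac * spec.gm_wm_ratio / (1.0 + spec.gm_wm_ratio)
    wm_frac = tissue_frac - gm_frac
    top_frac = spec.background_fraction / 2.0

    x = np.arange(w)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    amp = spec.boundary_curvature * h

    def curve(y0: float) -> np.ndarray:
        wave = (np.sin(2 * np.pi * x / w + phase[0])
                + 0.5 * np.sin(4 * np.pi * x / w + phase[1]))
        return y0 + amp * wave / 1.5

    y_top = curve(top_frac * h)
    y_mid = curve((top_frac + gm_frac) * h)
    y_bot = curve((top_frac + gm_frac + wm_frac) * h)

    yy = np.arange(h)[:, None]
    mask = np.zeros((h, w), dtype=np.uint8)
    mask[(yy >= y_top) & (yy < y_mid)] = GM
    mask[(yy >= y_mid) & (yy < y_bot)] = WM
    return mask


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma)


def _paint_textures(spec: SyntheticSpec, mask: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    h, w = mask.shape
    img = np.empty((h, w, 3), dtype=np.float64)

    # background: bright, nearly flat
    bg = spec.background_brightness + rng.normal(0, spec.background_noise,
                                                 (h, w))
    img[:] = bg[..., None]

    # GM: tan base + dense dark cell speckle
    gm_base = np.array([196.0, 166.0, 148.0])
    cells = rng.random((h, w)) < spec.gm_blob_density
    cells = ndimage.binary_dilation(cells, iterations=1)
    gm_tex = np.where(cells, -70.0, 12.0) + 10 * _smooth_noise(rng, (h, w), 2)
    gm_img = gm_base[None, None, :] + gm_tex[..., None] * np.array(
        [1.0, 1.05, 1.1])[None, None, :]
    sel = mask == GM
    img[sel] = gm_img[sel]

    # WM: brighter base + oriented fiber striations
    wm_base = np.array([228.0, 211.0, 198.0])
    yy, xx = np.mgrid[0:h, 0:w]
    proj = xx * np.cos(spec.wm_fiber_angle) + yy * np.sin(spec.wm_fiber_angle)
    stripes = np.sin(2 * np.pi * proj / spec.wm_fiber_spacing)
    jitter = 4 * _smooth_noise(rng, (h, w), 3)
    wm_tex = 9.0 * stripes + jitter
    wm_img = wm_base[None, None, :] + wm_tex[..., None]
    sel = mask == WM
    img[sel] = wm_img[sel]
    return img


def _plaque_stamp(kind: str, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (alpha, color) for one deposit; alpha in [0,1] over a square."""
    r = radius
    size = 2 * r + 1
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    d = np.sqrt(yy ** 2 + xx ** 2)
    if kind == "cored":
        alpha = np.clip(1.2 - d / r, 0, 1) ** 0.8       # dense, sharp edge
        color = np.array([120.0, 72.0, 30.0])           # dark DAB brown
    elif kind == "diffuse":
        alpha = 0.55 * np.clip(1.0 - (d / (1.0 * r)) ** 2, 0, 1)
        color = np.array([165.0, 116.0, 66.0])          # pale brown, fuzzy
    elif kind == "CAA":
        ring = np.exp(-((d - 0.7 * r) ** 2) / (0.15 * r ** 2 + 1e-9))
        alpha = np.clip(ring, 0, 1)                     # vessel-wall annulus
        color = np.array([135.0, 82.0, 38.0])
    else:
        raise ValueError(f"unknown plaque type {kind!r}")
    return alpha.reshape(size, size), color


def _plant_plaques(spec: SyntheticSpec, img: np.ndarray, mask: np.ndarray,
                   rng: np.random.Generator) -> list:
    plaques = []
    h, w = mask.shape
    lo, hi = spec.plaque_radius_range
    for kind in PLAQUE_TYPES:
        for region_name, region_val in (("GM", GM), ("WM", WM)):
            rate = spec.plaque_rates.get((kind, region_name), 0.0)
            count = int(rng.poisson(rate)) if rate > 0 else 0
            if count == 0:
                continue
            # candidate centers: region eroded so the disk stays inside it
            eroded = ndimage.binary_erosion(
                mask == region_val, structure=np.ones((3, 3)),
                iterations=hi + 1)
            ys, xs = np.nonzero(eroded)
            if ys.size == 0:
                continue
            idx = rng.integers(0, ys.size, size=count)
            for k in idx:
                cy, cx = int(ys[k]), int(xs[k])
                radius = int(rng.integers(lo, hi + 1))
                alpha, color = _plaque_stamp(kind, radius)
                y0, x0 = cy - radius, cx - radius
                y1, x1 = cy + radius + 1, cx + radius + 1
                tile = img[y0:y1, x0:x1]
                a = alpha[..., None]
                tile[:] = (1 - a) * tile + a * color[None, None, :]
                plaques.append((cx, cy, kind))
    return plaques


def generate_tissue_sample(spec: SyntheticSpec) -> SyntheticSample:
    """Render one synthetic slide: image, label mask and plaque ground truth.

    Deterministic for a fixed ``(region_layout_seed, rng_seed)`` pair.
    """
    spec.validate()
    mask = _region_bands(spec)
    rng = np.random.default_rng(spec.rng_seed)
    img = _paint_textures(spec, mask, rng)
    plaques = _plant_plaques(spec, img, mask, rng)
    image = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticSample(image=image, mask=mask, plaques=plaques, spec=spec)


def _grow_blob(rng: np.random.Generator, allowed: np.ndarray,
               seed_yx: tuple[int, int], area: int) -> set:
    """Grow a connected pixel set of exactly ``area`` px from a seed.

    Randomized region growing restricted to ``allowed`` pixels; guarantees
    4-connectivity and the exact requested area.
    """
    h, w = allowed.shape
    sy, sx = seed_yx
    if not (0 <= sy < h and 0 <= sx < w):
        raise ValueError(f"artifact seed {seed_yx} outside image bounds")
    if not allowed[sy, sx]:
        raise ValueError("artifact seed does not fall on background")
    blob = {(sy, sx)}
    frontier = [(sy, sx)]
    while len(blob) < area:
        if not frontier:
            raise ValueError("artifact area exceeds available background")
        i = int(rng.integers(0, len(frontier)))
        cy, cx = frontier[i]
        nbrs = [(cy + dy, cx + dx)
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= cy + dy < h and 0 <= cx + dx < w
                and allowed[cy + dy, cx + dx]
                and (cy + dy, cx + dx) not in blob]
        if not nbrs:
            frontier.pop(i)
            continue
        pick = nbrs[int(rng.integers(0, len(nbrs)))]
        blob.add(pick)
        frontier.append(pick)
    return blob


def inject_artifacts(sample: SyntheticSample, artifact_spec: list,
                     seed: int = 0) -> SyntheticSample:
    """Paint tissue-colored artifact components onto background regions.

    ``artifact_spec`` is a list of ``(shape, area_px, location)`` with shape
    in ``{"fragment", "speckle"}``, an exact pixel area, and location either
    ``None`` (random background spot) or an ``(x, y)`` seed.  Returns a new
    sample; the label mask is untouched (artifacts are *not* tissue), the
    painted pixel sets are recorded in ``sample.artifacts``.
    """
    if not artifact_spec:
        return sample
    rng = np.random.default_rng(seed)
    img = sample.image.astype(np.float64).copy()
    artifacts = list(sample.artifacts)
    # keep clear of real tissue so components stay detached
    near_tissue = ndimage.binary_dilation(sample.mask != BACKGROUND,
                                          iterations=8)
    allowed = ~near_tissue
    for shape, area, location in artifact_spec:
        if area <= 0:
            raise ValueError("artifact area must be positive")
        if location is None:
            ys, xs = np.nonzero(ndimage.binary_erosion(allowed, iterations=4))
            if ys.size == 0:
                raise ValueError("no background available for artifact")
            k = int(rng.integers(0, ys.size))
            seed_yx = (int(ys[k]), int(xs[k]))
        else:
            x, y = location
            seed_yx = (int(y), int(x))
        blob = _grow_blob(rng, allowed, seed_yx, int(area))
        color = (np.array([188.0, 158.0, 140.0])
                 if shape == "fragment" else np.array([120.0, 100.0, 90.0]))
        for (py, px) in blob:
            noise = rng.normal(0, 6, size=3)
            img[py, px] = np.clip(color + noise, 0, 255)
            allowed[py, px] = False   # keep later artifacts disjoint
        artifacts.append(blob)
    out = SyntheticSample(image=np.clip(img, 0, 255).astype(np.uint8),
                          mask=sample.mask.copy(),
                          plaques=list(sample.plaques),
                          artifacts=artifacts, spec=sample.spec)
    return out


def default_spec(**overrides) -> SyntheticSpec:
    """The study conditions used throughout the test-bench."""
    return replace(SyntheticSpec(), **overrides)
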