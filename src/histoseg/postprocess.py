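"""Morphological refinement of predicted masks.

The raw sliding-window output contains fuzzy speckle and detached tissue
fragments.  The refinement downsamples by 4 per axis (area factor 16) to
keep the morphology cheap, then, in order:

1. area openings on the GM layer, then the WM layer, removing components
   with area < 20,000 downsampled px (fuzzy tissue predictions);
2. an area closing filling background components with area < 12,500 px
   (fuzzy background inside tissue);
3. removal of tissue components smaller than 5% of the raster area
   (detached residues/fragments);
4. a morphological opening with a disk kernel of radius 8 on each tissue
   layer (boundary smoothing);
5. nearest-neighbor upsampling back to the input resolution.

The area thresholds are interpreted in downsampled pixels (the unit the
morphology runs in); pass ``areas_at_full_resolution=True`` to state them
at full resolution instead.  Pixels vacated by a removed class become
background; filled background components take the label of the largest
adjacent tissue component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .inference import LabelMask
from .synthetic import BACKGROUND, GM, WM

__all__ = ["PostprocessParams", "refine_mask", "connected_components"]

EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PostprocessParams:
    downsample_per_axis: int = 4
    gm_wm_min_area: int = 20_000        # downsampled px, strict <
    background_close_area: int = 12_500
    residue_fraction: float = 0.05      # of the full raster area
    disk_radius: int = 8
    areas_at_full_resolution: bool = False
    connectivity: int = 2               # scikit-image convention: 2 == 8-conn

    def __post_init__(self):
        if min(self.downsample_per_axis, self.gm_wm_min_area,
               self.background_close_area, self.disk_radius) <= 0:
            raise ValueError("all postprocessing sizes must be positive")
        if not 0 < self.residue_fraction < 1:
            raise ValueError("residue_fraction must lie in (0, 1)")


#: raster size the default area thresholds were stated for (a typical
#: whole-slide scan of ~60,000 x 50,000 px)
REFERENCE_WSI_SHAPE = (50_000, 60_000)


def scaled_params(image_shape: tuple,
                  base: PostprocessParams = PostprocessParams()
                  ) -> PostprocessParams:
    """Rescale the absolute area thresholds to a smaller raster.

    The stated component-area thresholds are implicit *fractions* of a
    full slide scan; applying them verbatim to a desk-scale image would
    delete all tissue.  Areas scale with raster area; the disk radius
    scales with linear size (floor 1).
    """
    ref_h, ref_w = REFERENCE_WSI_SHAPE
    area_factor = (image_shape[0] * image_shape[1]) / (ref_h * ref_w)
    linear_factor = np.sqrt(area_factor)
    return PostprocessParams(
        downsample_per_axis=base.downsample_per_axis,
        gm_wm_min_area=max(1, round(base.gm_wm_min_area * area_factor)),
        background_close_area=max(
            1, round(base.background_close_area * area_factor)),
        residue_fraction=base.residue_fraction,
        disk_radius=max(1, round(base.disk_radius * linear_factor)),
        areas_at_full_resolution=base.areas_at_full_resolution,
        connectivity=base.connectivity)


def connected_components(layer: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """8-connected labeling of a binary layer -> (labels, areas).

    ``areas[k]`` is the pixel count of component ``k + 1``.
    """
    layer = np.asarray(layer, dtype=bool)
    labels, n = ndimage.label(layer, structure=EIGHT)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, areas


def _remove_small(layer: np.ndarray, min_area: int) -> np.ndarray:
    """Area opening: drop components with area strictly below ``min_area``."""
    labels, areas = connected_components(layer)
    keep = np.flatnonzero(areas >= min_area) + 1
    return np.isin(labels, keep)


def _fill_small_background(mask: np.ndarray, max_area: int) -> np.ndarray:
    """Area closing: give small background islands the label of the largest
    adjacent tissue component."""
    out = mask.copy()
    labels, areas = connected_components(mask == BACKGROUND)
    tissue_labels, tissue_areas = connected_components(mask != BACKGROUND)
    for k in np.flatnonzero(areas < max_area):
        comp = labels == k + 1
        ring = ndimage.binary_dilation(comp, structure=EIGHT) & ~comp
        neighbor_comps = np.unique(tissue_labels[ring])
        neighbor_comps = neighbor_comps[neighbor_comps > 0]
        if neighbor_comps.size == 0:
            continue
        # resolve in favor of the largest adjacent tissue component
        winner = neighbor_comps[np.argmax(tissue_areas[neighbor_comps - 1])]
        values, counts = np.unique(
            out[(tissue_labels == winner) & ring], return_counts=True)
        out[comp] = values[np.argmax(counts)]
    return out


def refine_mask(mask: LabelMask,
                params: PostprocessParams = PostprocessParams()) -> LabelMask:
    """Run the refinement pipeline; returns a mask at the input resolution."""
    labels = np.asarray(mask.labels)
    if set(np.unique(labels)) - {BACKGROUND, GM, WM}:
        raise ValueError("mask contains labels outside {0, 1, 2}")
    f = params.downsample_per_axis
    small = labels[::f, ::f].copy()

    scale = f * f if params.areas_at_full_resolution else 1
    min_area = -(-params.gm_wm_min_area // scale)
    close_area = -(-params.background_close_area // scale)

    # (1)+(2) area openings on GM then WM
    for cls in (GM, WM):
        layer = small == cls
        kept = _remove_small(layer, min_area)
        small[layer & ~kept] = BACKGROUND

    # (3) area closing of small background islands
    small = _fill_small_background(small, close_area)

    # (4) residue removal: tissue components < 5% of the raster area
    residue_px = params.residue_fraction * small.size
    tissue_labels, tissue_areas = connected_components(small != BACKGROUND)
    drop = np.flatnonzero(tissue_areas < residue_px) + 1
    small[np.isin(tissue_labels, drop)] = BACKGROUND

    # (5) disk opening on each tissue layer
    disk = morphology.disk(params.disk_radius)
    for cls in (GM, WM):
        layer = small == cls
        opened = morphology.opening(layer, disk)
        small[layer & ~opened] = BACKGROUND

    # (6) nearest-neighbor upsample back to the input raster
    full = np.repeat(np.repeat(small, f, axis=0), f, axis=1)
    full = full[:labels.shape[0], :labels.shape[1]]
    if full.shape != labels.shape:   # input not divisible by f: pad by edge
        pad_y = labels.shape[0] - full.shape[0]
        pad_x = labels.shape[1] - full.shape[1]
        full = np.pad(full, ((0, pad_y), (0, pad_x)), mode="edge")
    return LabelMask(labels=full.astype(np.uint8),
                     downsample_factor=mask.downsample_factor)
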