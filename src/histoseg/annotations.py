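"""Mask boundaries as viewer-compatible XML annotation files.

Segmentation masks are converted to outer boundary polygons per connected
component and written in the de-facto Aperio ImageScope schema::

    Annotations
      Annotation (Name="GM"/"WM", LineColor=...)
        Regions
          Region
            Vertices
              Vertex (X, Y)    # integer level-0 pixel coordinates

Vertices are emitted in level-0 (full-resolution) coordinates by scaling
with the mask's downsample factor, and contours may be decimated (keep
every k-th vertex) to keep the files light for interactive viewing; the
conventional decimation factor is 50.  GM regions are drawn cyan and WM
yellow.  A GeoJSON export is provided for modern viewers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree
from skimage import measure

from .inference import LabelMask
from .synthetic import GM, WM

__all__ = ["AnnotationSet", "mask_to_contours", "decimate_contour",
           "write_imagescope_xml", "parse_imagescope_xml", "write_geojson"]

CLASS_NAME = {GM: "GM", WM: "WM"}
NAME_CLASS = {"GM": GM, "WM": WM}
# BGR-packed integers as ImageScope stores them: cyan and yellow
LINE_COLOR = {GM: 16776960, WM: 65535}


@dataclass
class AnnotationSet:
    """Polygons per tissue class, vertex coordinates at level 0."""
    regions: list = field(default_factory=list)   # [(class, (n,2) xy array)]

    def __post_init__(self):
        for cls, poly in self.regions:
            if cls not in (GM, WM):
                raise ValueError("annotation class must be GM or WM")
            if len(poly) < 3:
                raise ValueError("polygons need at least 3 vertices")


def _polygon_area_signed(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def mask_to_contours(mask: LabelMask, cls: int) -> list[np.ndarray]:
    """Outer boundary polygons of all components of ``cls``.

    Returns (n, 2) arrays of (x, y) level-0 coordinates, counter-clockwise
    in the image frame (y down).  An absent class yields an empty list.
    """
    if cls not in (GM, WM):
        raise ValueError("contour class must be GM or WM")
    from .postprocess import connected_components
    layer = mask.labels == cls
    labels, areas = connected_components(layer)
    polys: list[np.ndarray] = []
    for k in range(len(areas)):
        comp = labels == k + 1
        padded = np.pad(comp.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            continue
        outer = max(contours, key=len)          # outer boundary, not holes
        xy = outer[:, ::-1] - 1.0               # (row, col) -> (x, y), unpad
        if _polygon_area_signed(xy) > 0:        # CCW with y down => negative
            xy = xy[::-1]
        polys.append(xy * mask.downsample_factor)
    return polys


def decimate_contour(polygon: np.ndarray, factor: int = 50) -> np.ndarray:
    """Keep every ``factor``-th vertex (first always kept), min 3 retained."""
    if factor < 1:
        raise ValueError("decimation factor must be >= 1")
    polygon = np.asarray(polygon)
    if factor == 1:
        return polygon.copy()
    kept = polygon[::factor]
    if len(kept) < 3:
        n = len(polygon)
        idx = np.linspace(0, n - 1, 3).astype(int)
        kept = polygon[idx]
    return kept.copy()


def annotation_set_from_mask(mask: LabelMask,
                             decimation: int = 50) -> AnnotationSet:
    regions = []
    for cls in (GM, WM):
        for poly in mask_to_contours(mask, cls):
            regions.append((cls, decimate_contour(poly, decimation)))
    return AnnotationSet(regions=regions)


def write_imagescope_xml(annotations: AnnotationSet, path) -> None:
    root = etree.Element("Annotations")
    for cls in (GM, WM):
        polys = [p for c, p in annotations.regions if c == cls]
        ann = etree.SubElement(root, "Annotation",
                               Name=CLASS_NAME[cls],
                               LineColor=str(LINE_COLOR[cls]))
        regions_el = etree.SubElement(ann, "Regions")
        for rid, poly in enumerate(polys, start=1):
            region = etree.SubElement(regions_el, "Region", Id=str(rid))
            vertices = etree.SubElement(region, "Vertices")
            for x, y in np.rint(poly).astype(int):
                etree.SubElement(vertices, "Vertex", X=str(int(x)),
                                 Y=str(int(y)))
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="utf-8")


class AnnotationFormatError(ValueError):
    pass


def parse_imagescope_xml(path) -> AnnotationSet:
    """Parse an ImageScope XML file; malformed input raises
    :class:`AnnotationFormatError` carrying the offending line number."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise AnnotationFormatError(
            f"malformed XML at line {exc.lineno}: {exc.msg}") from exc
    regions = []
    for ann in tree.getroot().iter("Annotation"):
        name = ann.get("Name")
        if name not in NAME_CLASS:
            continue
        cls = NAME_CLASS[name]
        for region in ann.iter("Region"):
            verts = [(int(v.get("X")), int(v.get("Y")))
                     for v in region.iter("Vertex")]
            if len(verts) >= 3:
                regions.append((cls, np.array(verts, dtype=float)))
    return AnnotationSet(regions=regions)


def write_geojson(annotations: AnnotationSet, path) -> None:
    features = []
    for cls, poly in annotations.regions:
        ring = poly.tolist() + [poly[0].tolist()]
        features.append({
            "type": "Feature",
            "properties": {"classification": CLASS_NAME[cls]},
            "geometry": {"type": "Polygon", "coordinates": [ring]},
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))
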