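"""Global silhouette traits measured on an organ mask.

These are the whole-organ estimators followed over time: projected area,
bounding width and height (reported as root-system depth for roots),
convex-hull area (explored space) and, for the rosette, the maximum Feret
diameter.  All values come out in cm / cm² via the mask's scale.

Connected-component policy: root traits use *all* foreground pixels (thin
roots fragment at mesh crossings; discarding fragments would bias area
low), while the shoot mask is already reduced to the largest component by
the segmenter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .imgio import TraitRecord
from .segmentation import BinaryMask

__all__ = [
    "GlobalTraitSet",
    "projected_area",
    "bounding_extent",
    "convex_hull_area",
    "rosette_diameter",
    "measure_global_traits",
    "global_traits_to_records",
]


@dataclass
class GlobalTraitSet:
    """Global traits of one organ mask (cm / cm²)."""

    organ: str
    projected_area: float
    width: float
    height_or_depth: float
    convex_hull_area: float
    diameter: float | None = None  # shoot only


def projected_area(mask: BinaryMask) -> float:
    """Projected surface in cm²: foreground pixel count × scale²."""
    return float(mask.area_px) * mask.scale ** 2


def bounding_extent(mask: BinaryMask) -> tuple[float, float]:
    """(width_cm, height_cm) of the foreground bounding box.

    Width/height count pixels inclusively: a vertical 1-px line of 500 px
    is (1 px, 500 px).  For root masks the height is the root-system
    depth.  Raises on an empty mask (extent undefined).
    """
    rows, cols = np.nonzero(mask.pixels)
    if rows.size == 0:
        raise ValueError("bounding extent undefined for an empty mask")
    width = (cols.max() - cols.min() + 1) * mask.scale
    height = (rows.max() - rows.min() + 1) * mask.scale
    return float(width), float(height)


def _foreground_points(mask: BinaryMask, points: str) -> np.ndarray:
    """Foreground point cloud as (x, y) coordinates.

    ``points="centers"`` uses pixel centers (integer coordinates);
    ``points="corners"`` uses the four corners of each pixel square, which
    makes the hull contain the full painted area (so that
    projected_area <= hull area holds on every mask).
    """
    rows, cols = np.nonzero(mask.pixels)
    if points == "centers":
        return np.column_stack([cols, rows]).astype(float)
    if points == "corners":
        x = cols.astype(float)
        y = rows.astype(float)
        pts = [np.column_stack([x + dx, y + dy])
               for dx in (-0.5, 0.5) for dy in (-0.5, 0.5)]
        return np.concatenate(pts)
    raise ValueError("points must be 'centers' or 'corners'")


def convex_hull_area(mask: BinaryMask, points: str = "centers") -> float:
    """Convex-hull area of the foreground in cm².

    Computed on pixel centers by default (sub-pixel bias, documented);
    ``points="corners"`` bounds the painted area from above.  Fewer than
    three points, or a collinear cloud, gives a degenerate hull: the
    function warns and returns 0.
    """
    pts = _foreground_points(mask, points)
    if len(pts) < 3:
        warnings.warn("fewer than 3 foreground pixels: degenerate hull, area 0")
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        warnings.warn("collinear foreground: degenerate hull, area 0")
        return 0.0
    return float(hull.volume) * mask.scale ** 2  # qhull 'volume' is area in 2-D


def rosette_diameter(mask: BinaryMask) -> float:
    """Maximum Feret diameter in cm (greatest pairwise point distance).

    Measured over convex-hull vertices of the pixel-center cloud, which is
    how one would put a ruler across the widest span of a rosette.
    """
    pts = _foreground_points(mask, "centers")
    if len(pts) == 0:
        raise ValueError("diameter undefined for an empty mask")
    if len(pts) <= 2:
        if len(pts) == 1:
            return 0.0
        return float(np.linalg.norm(pts[1] - pts[0])) * mask.scale
    try:
        hull = ConvexHull(pts)
        verts = pts[hull.vertices]
    except QhullError:
        verts = pts
    diffs = verts[:, None, :] - verts[None, :, :]
    d = np.sqrt((diffs ** 2).sum(-1)).max()
    return float(d) * mask.scale


def measure_global_traits(mask: BinaryMask) -> GlobalTraitSet:
    """All global traits of a mask; diameter only for shoot masks."""
    area = projected_area(mask)
    if mask.is_empty:
        return GlobalTraitSet(mask.organ, 0.0, 0.0, 0.0, 0.0,
                              0.0 if mask.organ == "shoot" else None)
    width, height = bounding_extent(mask)
    hull = convex_hull_area(mask)
    diam = rosette_diameter(mask) if mask.organ == "shoot" else None
    return GlobalTraitSet(mask.organ, area, width, height, hull, diam)


def global_traits_to_records(traits: GlobalTraitSet,
                             plant_id: str,
                             timepoint: int,
                             treatment: str = "") -> list[TraitRecord]:
    """Convert a GlobalTraitSet to rows of the canonical trait table."""
    def rec(name: str, value: float, unit: str) -> TraitRecord:
        return TraitRecord(plant_id, timepoint, treatment, traits.organ,
                           name, value, unit)

    if traits.organ == "shoot":
        out = [
            rec("projected_rosette_area", traits.projected_area, "cm2"),
            rec("rosette_convex_hull_area", traits.convex_hull_area, "cm2"),
            rec("rosette_diameter", traits.diameter or 0.0, "cm"),
        ]
    else:
        out = [
            rec("projected_root_surface", traits.projected_area, "cm2"),
            rec("root_system_width", traits.width, "cm"),
            rec("root_system_depth", traits.height_or_depth, "cm"),
            rec("root_system_convex_hull_area", traits.convex_hull_area, "cm2"),
        ]
    return out
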