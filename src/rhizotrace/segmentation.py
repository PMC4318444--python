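"""Organ segmentation by HSV channel selection.

The two organs call for different channels.  The rosette is green on a
grey setup, so the Hue channel separates plant from hardware.  Roots on
the dark mesh are near-achromatic: hue carries no signal there, but under
indirect backlighting the roots are brighter than both the background and
the mesh, so the Value channel (after a robust contrast stretch) does the
job.  Both routes end in a deterministic pipeline:

    channel -> (stretch) -> threshold -> despeckle -> fill 1-px holes

with every parameter recorded in the mask's provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import color as skcolor
from skimage import filters, measure, morphology

from .imgio import CalibratedImage

__all__ = [
    "BinaryMask",
    "split_hsv",
    "enhance_contrast",
    "segment_shoot",
    "segment_root",
    "foreground_f1",
]


@dataclass
class BinaryMask:
    """A boolean organ mask sharing the source image's scale.

    ``provenance`` records the channel, threshold and cleanup parameters
    that produced the mask, so any trait value can be traced back to its
    segmentation settings.
    """

    pixels: np.ndarray
    scale: float
    organ: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.pixels = px.astype(bool)
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.organ not in ("shoot", "root"):
            raise ValueError("organ must be 'shoot' or 'root'")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.pixels.any()


def split_hsv(image: CalibratedImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a color image into hue, saturation and value rasters.

    Returns three float rasters on the 0–255 scale (hue maps 360° to 255
    so that pure green, 120°, lands at ≈85).  Float output keeps the
    HSV→RGB round trip within one grey level.
    """
    if not image.is_color:
        raise ValueError("split_hsv requires a 3-channel color image")
    hsv = skcolor.rgb2hsv(image.pixels)
    hue = hsv[:, :, 0] * 255.0
    sat = hsv[:, :, 1] * 255.0
    val = hsv[:, :, 2] * 255.0
    return hue, sat, val


def enhance_contrast(raster: np.ndarray,
                     low_pct: float = 1.0,
                     high_pct: float = 99.0) -> np.ndarray:
    """Linear percentile stretch of a grayscale raster to [0, 255].

    The intensities at ``low_pct`` / ``high_pct`` map to 0 / 255; values
    outside are clipped.  A constant raster is returned unchanged with a
    warning (there is nothing to stretch).
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    raster = np.asarray(raster, dtype=np.float64)
    lo, hi = np.percentile(raster, [low_pct, high_pct])
    if hi <= lo:
        warnings.warn("constant (or near-constant) raster: contrast unchanged")
        return raster.copy()
    out = (raster - lo) * (255.0 / (hi - lo))
    return np.clip(out, 0.0, 255.0)


def _keep_largest(mask: np.ndarray) -> np.ndarray:
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def segment_shoot(image: CalibratedImage,
                  hue_window_deg: tuple[float, float] = (90.0, 150.0),
                  sat_min: float = 40.0,
                  min_area_px: int = 1000) -> BinaryMask:
    """Segment the rosette: green-hued pixels on the grey setup.

    A hue window centred on green (default 90°–150°) gates the pixels; a
    saturation floor rejects achromatic pixels whose hue is noise.  Small
    components below ``min_area_px`` are dropped and the largest remaining
    component is kept as the rosette (one plant per frame).
    """
    if image.organ_hint == "root":
        raise ValueError("organ_hint says this is a root image")
    hue, sat, _ = split_hsv(image)
    lo = hue_window_deg[0] / 360.0 * 255.0
    hi = hue_window_deg[1] / 360.0 * 255.0
    mask = (hue >= lo) & (hue <= hi) & (sat >= sat_min)
    mask = morphology.remove_small_objects(mask, connectivity=2,
                                           max_size=min_area_px - 1)
    mask = _keep_largest(mask)
    if not mask.any():
        warnings.warn("shoot segmentation produced an empty mask")
    prov = {
        "channel": "hue",
        "hue_window_deg": list(hue_window_deg),
        "sat_min": sat_min,
        "min_area_px": min_area_px,
    }
    return BinaryMask(mask, image.scale, "shoot", prov)


def segment_root(image: CalibratedImage,
                 low_pct: float = 1.0,
                 high_pct: float = 99.0,
                 threshold: float | str = "otsu",
                 min_area_px: int = 25,
                 fill_holes: bool = True,
                 channel: str = "value",
                 max_foreground_frac: float = 0.10) -> BinaryMask:
    """Segment roots imaged on the mesh under indirect backlighting.

    Pipeline: chosen channel (Value by default; Hue is available for
    comparison experiments) → percentile contrast stretch → global
    threshold (Otsu or a fixed level on the stretched raster) → despeckle
    (drop components below ``min_area_px``) → fill 1-px holes.

    Otsu always splits the histogram somewhere; on a frame with no roots
    that split falls inside the background/mesh hump and selects a huge
    share of the frame.  Roots are thin structures occupying at most a few
    percent of a frame, so a foreground fraction above
    ``max_foreground_frac`` is treated as "nothing segmentable" and an
    empty mask is returned with a warning.
    """
    if image.organ_hint == "shoot":
        raise ValueError("organ_hint says this is a shoot image")
    hue, _, val = split_hsv(image)
    raster = {"value": val, "hue": hue}[channel]
    # Threshold on the *unclipped* affine stretch: roots occupy well under
    # 1% of a frame, so they sit above the high percentile and saturating
    # them would fold the root mode into the background range and derail
    # Otsu.  The clipped stretch is what one would look at (and what a
    # fixed threshold refers to); the affine map is identical below the
    # high percentile.
    lo, hi = np.percentile(raster, [low_pct, high_pct])
    if hi <= lo:
        # degenerate percentile window (e.g. a noise-free background that
        # dominates both percentiles): fall back to the full range
        lo, hi = float(raster.min()), float(raster.max())
    if hi <= lo:
        warnings.warn("flat channel: empty mask")
        stretched = raster
    else:
        stretched = (raster - lo) * (255.0 / (hi - lo))
    if threshold == "otsu":
        thr = float(filters.threshold_otsu(stretched)) if hi > lo else np.inf
    else:
        thr = float(threshold)
    mask = stretched > thr
    frac = mask.mean()
    if frac > max_foreground_frac:
        warnings.warn(
            f"threshold selected {frac:.1%} of the frame "
            f"(> {max_foreground_frac:.0%}); declaring the mask empty"
        )
        mask = np.zeros_like(mask)
    mask = morphology.remove_small_objects(mask, connectivity=2,
                                           max_size=min_area_px - 1)
    if fill_holes:
        mask = morphology.remove_small_holes(mask, max_size=1)
    if not mask.any():
        warnings.warn("root segmentation produced an empty mask")
    prov = {
        "channel": channel,
        "stretch_pct": [low_pct, high_pct],
        "threshold": thr,
        "min_area_px": min_area_px,
        "fill_holes": fill_holes,
        "max_foreground_frac": max_foreground_frac,
    }
    return BinaryMask(mask, image.scale, "root", prov)


def foreground_f1(mask: BinaryMask | np.ndarray,
                  truth: BinaryMask | np.ndarray) -> float:
    """Pixelwise F1 score of a mask against a ground-truth raster.

    Returns 0.0 when the mask has no foreground (precision undefined).
    """
    m = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    t = truth.pixels if isinstance(truth, BinaryMask) else np.asarray(truth, bool)
    if m.shape != t.shape:
        raise ValueError("mask and truth shapes differ")
    tp = np.logical_and(m, t).sum()
    if m.sum() == 0 or t.sum() == 0 or tp == 0:
        return 0.0
    precision = tp / m.sum()
    recall = tp / t.sum()
    return float(2 * precision * recall / (precision + recall))
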