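"""Image and trait-table I/O with explicit spatial calibration.

Every quantitative trait downstream is reported in cm or cm², so images are
always paired with a cm-per-pixel scale at load time.  The scale is either
given directly or derived from a scale bar of known physical length (the
root photographs carry a 3 cm bar).  Acquisition metadata (plant id,
timepoint, treatment) travels in an optional JSON sidecar with the same
file stem as the image.

Pixel convention: 0-based, origin at the top-left corner, x to the right,
y downward.  Root depth therefore grows with +y (seed holder at the top of
the frame).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "CalibratedImage",
    "TraitRecord",
    "TRAIT_UNITS",
    "resolve_scale",
    "load_image",
    "save_image",
    "read_traits",
    "write_traits",
    "records_to_frame",
    "frame_to_records",
]

ORGANS = ("shoot", "root", "unknown")

#: Canonical trait vocabulary and the unit each trait must carry.
TRAIT_UNITS = {
    "projected_rosette_area": "cm2",
    "rosette_diameter": "cm",
    "rosette_convex_hull_area": "cm2",
    "leaf_count": "count",
    "projected_root_surface": "cm2",
    "root_system_depth": "cm",
    "root_system_width": "cm",
    "root_system_convex_hull_area": "cm2",
    "lateral_root_density": "count_per_cm",
    "lauz": "cm",
    "branched_zone_length": "cm",
    "lateral_root_length": "cm",
    "lateral_count": "count",
    "primary_root_length": "cm",
    "total_root_length": "cm",
    "root_biomass_proxy": "cm3",
}

_UNITS = ("cm", "cm2", "cm3", "count", "count_per_cm")


@dataclass
class CalibratedImage:
    """A color or grayscale raster with a physical pixel size.

    Parameters
    ----------
    pixels:
        ``(H, W)`` or ``(H, W, 3)`` uint8 array.
    scale:
        Physical size of one pixel in cm (cm / px), strictly positive.
    organ_hint:
        One of ``{"shoot", "root", "unknown"}``; advisory only.
    meta:
        Free-form acquisition metadata (timepoint, plant id, treatment...).
    """

    pixels: np.ndarray
    scale: float
    organ_hint: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError(f"pixels must be HxW or HxWx3, got shape {px.shape}")
        if px.size == 0:
            raise ValueError("image must have at least one pixel")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"scale must be a positive real (cm/px), got {self.scale}")
        if self.organ_hint not in ORGANS:
            raise ValueError(f"organ_hint must be one of {ORGANS}")

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def physical_extent(self) -> tuple[float, float]:
        """(width_cm, height_cm) of the full frame."""
        return self.width * self.scale, self.height * self.scale


@dataclass(frozen=True)
class TraitRecord:
    """One measured trait value keyed by plant, time, treatment and organ."""

    plant_id: str
    timepoint: int
    treatment: str
    organ: str
    trait_name: str
    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.organ not in ("shoot", "root"):
            raise ValueError(f"organ must be 'shoot' or 'root', got {self.organ!r}")
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}, got {self.unit!r}")
        expected = TRAIT_UNITS.get(self.trait_name)
        if expected is not None and expected != self.unit:
            raise ValueError(
                f"trait {self.trait_name!r} must carry unit {expected!r}, got {self.unit!r}"
            )
        if np.isfinite(self.value) and self.value < 0:
            raise ValueError(f"trait values are non-negative, got {self.value}")


def resolve_scale(scale: float | None = None,
                  scale_bar: tuple[float, float] | None = None) -> float:
    """Resolve a cm-per-pixel scale from either a direct value or a scale bar.

    ``scale_bar`` is ``(bar_length_cm, bar_length_px)``, e.g. a 3 cm bar
    spanning 300 px gives 0.01 cm/px.
    """
    if (scale is None) == (scale_bar is None):
        raise ValueError("give exactly one of scale or scale_bar")
    if scale_bar is not None:
        bar_cm, bar_px = scale_bar
        if bar_cm <= 0 or bar_px <= 0:
            raise ValueError("scale bar lengths must be positive")
        scale = bar_cm / bar_px
    if not np.isfinite(scale) or scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    return float(scale)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def load_image(path: str | Path,
               scale: float | None = None,
               scale_bar: tuple[float, float] | None = None,
               organ_hint: str = "unknown") -> CalibratedImage:
    """Read a PNG/TIFF/JPEG image and attach its spatial calibration.

    A JSON sidecar with the same stem (``img.png`` → ``img.json``), if
    present, is loaded into ``meta``; its ``organ_hint`` key overrides the
    argument when the argument is ``"unknown"``.
    """
    path = Path(path)
    px = iio.imread(path)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[:, :, :3]
    if px.ndim == 3 and px.shape[2] == 1:
        px = px[:, :, 0]
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if organ_hint == "unknown":
            organ_hint = meta.get("organ_hint", "unknown")
    s = resolve_scale(scale, scale_bar)
    return CalibratedImage(pixels=px, scale=s, organ_hint=organ_hint, meta=meta)


def save_image(image: CalibratedImage, path: str | Path,
               write_sidecar: bool = True) -> None:
    """Write the raster as PNG/TIFF/JPEG plus a JSON metadata sidecar."""
    path = Path(path)
    iio.imwrite(path, image.pixels)
    if write_sidecar:
        meta = dict(image.meta)
        meta.setdefault("scale_cm_per_px", image.scale)
        meta.setdefault("organ_hint", image.organ_hint)
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))


_TRAIT_COLUMNS = ["plant_id", "timepoint", "treatment", "organ",
                  "trait_name", "value", "unit"]


def records_to_frame(records: Iterable[TraitRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    if not rows:
        raise ValueError("empty record list")
    return pd.DataFrame(rows, columns=_TRAIT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[TraitRecord]:
    return [
        TraitRecord(
            plant_id=str(row.plant_id),
            timepoint=int(row.timepoint),
            treatment=str(row.treatment),
            organ=str(row.organ),
            trait_name=str(row.trait_name),
            value=float(row.value),
            unit=str(row.unit),
        )
        for row in df.itertuples(index=False)
    ]


def write_traits(records: Sequence[TraitRecord], path: str | Path) -> None:
    """Write trait records as CSV (header + one row per record).

    The CSV round-trips losslessly through :func:`read_traits` (float
    values use shortest-repr formatting).
    """
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty trait table")
    # %.17g guarantees binary64 round-trip through the text table
    records_to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_traits(path: str | Path) -> list[TraitRecord]:
    """Read a trait CSV written by :func:`write_traits`."""
    df = pd.read_csv(
        path,
        dtype={"plant_id": str, "treatment": str, "organ": str,
               "trait_name": str, "unit": str},
        keep_default_na=False,
        float_precision="round_trip",
    )
    missing = set(_TRAIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    return frame_to_records(df)
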