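"""Synthetic hydroponic-rhizotron scenes with exact ground truth.

The generator emulates the imaging conditions of the apparatus: a dark,
slightly under-exposed frame crossed by a fine nylon-mesh grid (0.5 mm²
cells) with occasional specular glints, root strokes rendered brighter
than the background (indirect backlighting), radial vignetting and
Gaussian sensor noise; and, for the shoot, a green lobed rosette on a
grey background.  Every rendered scene carries the exact geometry it was
drawn from — polylines, insertion positions, lateral lengths — plus the
exact pre-noise stroke raster, so every pipeline stage can be validated
against ground truth.

Plant model
-----------
The primary root is a unit-speed wavy curve growing downward.  Lateral
roots emerge behind a fixed apical unbranched distance along a hard-core
renewal process (minimum insertion gap, gap mean chosen so the intensity
equals ``lateral_rate`` exactly); insertion sides alternate left/right,
as Arabidopsis lateral files do.  Lateral lengths follow a day-quantized
acropetal rule — elongation rate × whole days since emergence — i.e. the
natural growth model for a daily-photographed time course, which also
means older (more basal) laterals are longer.  Treatments are
phenomenological rate multipliers, not a toxicity model.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from shapely.geometry import LineString
from skimage import draw as skdraw

from .architecture import Lateral, RootTopology, measure_local_traits, LocalTraitSet
from .global_traits import GlobalTraitSet
from .imgio import CalibratedImage, TraitRecord
from .segmentation import BinaryMask

__all__ = [
    "PlantModel",
    "PlantGeometry",
    "SyntheticScene",
    "sample_plant",
    "render_scene",
    "render_rosette",
    "simulate_timecourse",
    "cd_like",
    "cohort_models",
    "FRAME_CM",
    "MESH_PITCH_CM",
]

#: Physical frame of the rhizotron: 335 mm high × 250 mm wide.
FRAME_CM: tuple[float, float] = (33.5, 25.0)  # (height, width)

#: Mesh cell area 0.5 mm² → grid pitch √0.5 mm ≈ 0.0707 cm.
MESH_PITCH_CM: float = 0.0707


@dataclass(frozen=True)
class PlantModel:
    """Parameters of one synthetic root system (lengths in cm, rates /day)."""

    primary_length: float = 18.0        # primary arclength at imaging time
    initial_length: float = 1.0         # seedling primary length at transfer
    primary_elong_rate: float = 1.0     # cm/day
    waviness_amplitude: float = 0.2     # cm, lateral excursion of the primary
    waviness_wavelength: float = 5.0    # cm
    lateral_rate: float = 1.5           # emergences per cm (process intensity)
    lateral_min_gap: float = 0.3        # cm, hard-core spacing between insertions
    lateral_elong_rate: float = 0.4     # cm/day
    lateral_max_days: int = 8           # determinate growth: elongation stops
    lauz: float = 2.0                   # apical unbranched distance behind the tip
    branch_angle_deg: float = 60.0      # mean insertion angle off the primary
    branch_angle_sd: float = 4.0
    root_width_px: int = 3              # rendered ribbon width
    growth_factor: float = 1.0          # treatment multiplier on elongation
    lateral_length_rule: Callable[[float], float] | None = None
    # optional override: age (days) -> length (cm); default day-quantized rule

    def __post_init__(self) -> None:
        if self.primary_length < self.initial_length:
            raise ValueError("primary_length must be >= initial_length")
        if not (0 < self.growth_factor <= 1):
            raise ValueError("growth_factor must be in (0, 1]")
        if self.lateral_rate < 0 or self.lauz < 0:
            raise ValueError("rates and lengths must be non-negative")
        if self.lateral_rate > 0 and self.lateral_min_gap >= 1.0 / self.lateral_rate:
            raise ValueError("lateral_min_gap must be below 1/lateral_rate")

    def length_of(self, age_days: float) -> float:
        """Lateral length for a given age in days (0 for age < 1 day)."""
        if self.lateral_length_rule is not None:
            return max(0.0, self.lateral_length_rule(age_days))
        days = min(np.floor(max(age_days, 0.0)), self.lateral_max_days)
        return self.lateral_elong_rate * days


@dataclass
class _GtLateral:
    insertion: float        # arclength from the base, cm
    side: int               # +1 right, -1 left
    angle_deg: float        # off the local primary direction
    length: float           # cm
    polyline: np.ndarray    # (N, 2) cm, (x, y)


@dataclass
class PlantGeometry:
    """Exact root-system geometry in cm, base at the origin, +y downward."""

    primary: np.ndarray                 # (N, 2) unit-speed polyline
    primary_length: float
    laterals: list[_GtLateral]
    lauz_param: float
    root_width_px: int
    rng_seed: int

    @property
    def polylines(self) -> list[np.ndarray]:
        return [self.primary] + [l.polyline for l in self.laterals]

    @property
    def total_length(self) -> float:
        return self.primary_length + sum(l.length for l in self.laterals)

    def truth_topology(self) -> RootTopology:
        """Exact topology (the analytic ground truth, not a measurement)."""
        lats = [
            Lateral(
                insertion_arclength=l.insertion,
                insertion_from_apex=self.primary_length - l.insertion,
                polyline=l.polyline,
                length=l.length,
            )
            for l in sorted(self.laterals, key=lambda l: l.insertion)
        ]
        return RootTopology(primary=self.primary, laterals=lats,
                            primary_length=self.primary_length)

    def shifted(self, dx: float, dy: float) -> "PlantGeometry":
        off = np.array([dx, dy])
        lats = [dataclasses.replace(l, polyline=l.polyline + off)
                for l in self.laterals]
        return PlantGeometry(self.primary + off, self.primary_length, lats,
                             self.lauz_param, self.root_width_px, self.rng_seed)


@dataclass
class SyntheticScene:
    """One rendered plant with its exact ground truth attached."""

    image: CalibratedImage
    truth_mask: BinaryMask
    truth_topology: RootTopology | None
    truth_global: GlobalTraitSet
    truth_local: LocalTraitSet | None
    seed_px: tuple[float, float] | None
    rng_seed: int
    geometry: PlantGeometry | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry sampling

_STEP_CM = 0.05  # polyline sampling step (unit-speed parameter)


def _primary_curve(params: PlantModel, length: float, phase: float) -> np.ndarray:
    """Unit-speed wavy curve of the given arclength, base at (0, 0).

    The heading oscillates about vertical: θ(t) = θmax sin(2πt/λ + φ)
    with θmax = atan(2πA/λ), which gives an x-excursion of roughly ±A.
    Unit speed makes the arclength parameter exact.
    """
    # fixed arclength grid from the base: a shorter (earlier) curve's
    # vertices are a prefix of a longer one's, so time courses nest
    t = np.arange(0.0, length, _STEP_CM)
    if length - t[-1] > 1e-9:
        t = np.append(t, length)
    if params.waviness_amplitude <= 0 or params.waviness_wavelength <= 0:
        theta = np.zeros_like(t)
    else:
        theta_max = np.arctan(2 * np.pi * params.waviness_amplitude
                              / params.waviness_wavelength)
        theta = theta_max * np.sin(2 * np.pi * t / params.waviness_wavelength + phase)
    dt = np.diff(t)
    dx = np.sin(theta[:-1]) * dt
    dy = np.cos(theta[:-1]) * dt
    x = np.concatenate([[0.0], np.cumsum(dx)])
    y = np.concatenate([[0.0], np.cumsum(dy)])
    return np.column_stack([x, y])


def _heading_at(params: PlantModel, s: float, phase: float) -> float:
    if params.waviness_amplitude <= 0 or params.waviness_wavelength <= 0:
        return 0.0
    theta_max = np.arctan(2 * np.pi * params.waviness_amplitude
                          / params.waviness_wavelength)
    return float(theta_max * np.sin(2 * np.pi * s / params.waviness_wavelength + phase))


def _point_at(primary: np.ndarray, s: float) -> np.ndarray:
    idx = s / _STEP_CM
    i = int(np.floor(idx))
    i = min(max(i, 0), len(primary) - 2)
    frac = idx - i
    return primary[i] * (1 - frac) + primary[i + 1] * min(frac, 1.0)


def _draw_insertions(params: PlantModel, max_span: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Hard-core renewal insertions on [0, max_span] with intensity λ.

    Gaps are min_gap + Exp(μ) with 1/μ = 1/λ − min_gap so the mean gap is
    exactly 1/λ.
    """
    if params.lateral_rate <= 0 or max_span <= 0:
        return np.zeros(0)
    mean_exp = 1.0 / params.lateral_rate - params.lateral_min_gap
    pos, out = 0.0, []
    # first insertion: plain exponential start (stationary enough at these n)
    pos = rng.exponential(1.0 / params.lateral_rate)
    while pos <= max_span:
        out.append(pos)
        pos += params.lateral_min_gap + rng.exponential(mean_exp)
    return np.asarray(out)


def _lateral_polyline(params: PlantModel, primary: np.ndarray, phase: float,
                      s: float, side: int, angle_deg: float,
                      length: float) -> np.ndarray:
    base = _point_at(primary, s)
    heading = _heading_at(params, s, phase)
    alpha = heading + side * np.deg2rad(angle_deg)
    direction = np.array([np.sin(alpha), np.cos(alpha)])
    t = np.arange(0.0, length, _STEP_CM)
    if length - t[-1] > 1e-9:
        t = np.append(t, length)
    return base[None, :] + t[:, None] * direction[None, :]


def _non_crossing_angle(params: PlantModel, primary: np.ndarray, phase: float,
                        s: float, side: int, length: float,
                        existing: list[LineString], primary_ls: LineString,
                        rng: np.random.Generator,
                        clearance: float = 0.05, tries: int = 30) -> float:
    """Draw a branch angle whose straight lateral stays clear of the rest.

    The mesh combs the root system flat and untangled, so overlapping
    laterals are both unrealistic here and fatal to exact ground truth;
    angles are redrawn until the candidate keeps ``clearance`` cm from
    every other lateral and from the primary away from its insertion.
    """
    best, best_clear = None, -np.inf
    for k in range(tries):
        sd = params.branch_angle_sd * (1 + k // 10)  # widen when cramped
        angle = float(np.clip(rng.normal(params.branch_angle_deg, sd),
                              30.0, 85.0))
        poly = _lateral_polyline(params, primary, phase, s, side, angle,
                                 max(length, 0.2))
        ls = LineString(poly[1:])  # skip the on-primary base point
        d_lat = min((ls.distance(o) for o in existing), default=np.inf)
        base = _point_at(primary, s)
        d_pri = primary_ls.distance(ls)
        # distance to the primary counts only beyond the insertion zone
        near_base = np.hypot(*(np.asarray(ls.coords[0]) - base)) < 0.3
        d_pri = np.inf if near_base and d_pri < clearance else d_pri
        clear = min(d_lat, d_pri if d_pri > 0 else np.inf)
        if clear >= clearance:
            return angle
        if clear > best_clear:
            best, best_clear = angle, clear
    return best if best is not None else params.branch_angle_deg


def sample_plant(params: PlantModel, rng_seed: int) -> PlantGeometry:
    """Sample one exact root-system geometry (pure function of inputs).

    The plant's developmental age is ``(primary_length − initial_length) /
    primary_elong_rate`` days; each lateral's age follows from when the
    tip passed its insertion plus the unbranched-zone delay, and its
    length from the acropetal growth rule.  Laterals whose rule gives
    zero length (emerged less than a day ago) are not yet visible and are
    not emitted.
    """
    rng = np.random.default_rng(rng_seed)
    phase = rng.uniform(0, 2 * np.pi)
    primary = _primary_curve(params, params.primary_length, phase)
    primary_ls = LineString(primary)

    span = params.primary_length - params.lauz
    insertions = _draw_insertions(params, max(span, 0.0), rng)
    side = int(rng.integers(0, 2)) * 2 - 1
    age_days = (params.primary_length - params.initial_length) / params.primary_elong_rate

    laterals: list[_GtLateral] = []
    existing: list[LineString] = []
    for s in insertions:
        side = -side
        emerged_at = max(s + params.lauz - params.initial_length, 0.0) \
            / params.primary_elong_rate
        length = params.length_of(age_days - emerged_at)
        angle = float(np.clip(rng.normal(params.branch_angle_deg,
                                         params.branch_angle_sd), 30.0, 85.0))
        if length <= 0:
            continue
        angle = _non_crossing_angle(params, primary, phase, s, side, length,
                                    existing, primary_ls, rng)
        poly = _lateral_polyline(params, primary, phase, s, side, angle, length)
        laterals.append(_GtLateral(float(s), side, angle, float(length), poly))
        existing.append(LineString(poly[1:]))

    return PlantGeometry(primary, float(params.primary_length), laterals,
                         params.lauz, params.root_width_px, rng_seed)


# ---------------------------------------------------------------------------
# rendering

def _rasterize_polyline(canvas: np.ndarray, poly_px: np.ndarray,
                        width_px: float) -> None:
    """Paint a flat-capped ribbon of the given width along a polyline.

    Flat caps keep the painted extent from overshooting the true tip,
    which matters for depth/width ground-truth comparisons.
    """
    pts = np.asarray(poly_px, float)
    if len(pts) < 2:
        return
    # one quad per polyline segment: the geometry's own fixed arclength
    # grid keeps successive growth stages' strokes nested
    xs, ys = pts[:, 0], pts[:, 1]
    half = width_px / 2.0
    for i in range(len(pts) - 1):
        p = np.array([xs[i], ys[i]])
        q = np.array([xs[i + 1], ys[i + 1]])
        d = q - p
        norm = np.hypot(*d)
        if norm == 0:
            continue
        nvec = np.array([-d[1], d[0]]) / norm * half
        quad_x = [p[0] + nvec[0], q[0] + nvec[0], q[0] - nvec[0], p[0] - nvec[0]]
        quad_y = [p[1] + nvec[1], q[1] + nvec[1], q[1] - nvec[1], p[1] - nvec[1]]
        rr, cc = skdraw.polygon(quad_y, quad_x, shape=canvas.shape)
        canvas[rr, cc] = True


def _truth_global(geometry: PlantGeometry, truth_mask: np.ndarray,
                  scale: float) -> GlobalTraitSet:
    pts = np.concatenate(geometry.polylines)
    width = float(pts[:, 0].max() - pts[:, 0].min())
    depth = float(pts[:, 1].max() - pts[:, 1].min())
    area = float(truth_mask.sum()) * scale ** 2
    try:
        from scipy.spatial import ConvexHull
        hull = float(ConvexHull(pts).volume)
    except Exception:
        hull = 0.0
    return GlobalTraitSet("root", area, width, depth, hull, None)


def render_scene(geometry: PlantGeometry | None,
                 scale: float = 0.01,
                 frame_cm: tuple[float, float] = FRAME_CM,
                 mesh_pitch_cm: float = MESH_PITCH_CM,
                 noise_sd: float = 4.0,
                 vignette: float = 0.08,
                 rng_seed: int = 0,
                 crop_margin_cm: float | None = 2.0,
                 background_level: float = 30.0,
                 mesh_brightness: float = 3.0,
                 glint_brightness: float = 35.0,
                 glint_fraction: float = 0.03,
                 root_value: float = 160.0,
                 root_tint: tuple[float, float, float] = (1.04, 1.0, 0.90),
                 window_cm: tuple[float, float, float, float] | None = None,
                 ) -> SyntheticScene:
    """Render a root-system geometry over the mesh background.

    The plant hangs from the seed holder at the top middle of the frame.
    By default the output is cropped to the plant's bounding box plus
    ``crop_margin_cm`` (photographs are framed on the root system);
    ``crop_margin_cm=None`` renders the whole frame, and ``window_cm``
    ``(x0, y0, x1, y1)`` forces a fixed window (useful for nested time
    courses).  The image is globally darker than mid-grey, emulating the
    deliberately under-exposed capture.
    """
    frame_h, frame_w = frame_cm
    rng = np.random.default_rng(rng_seed)

    if geometry is not None:
        base_xy = np.array([frame_w / 2.0, 0.5])
        geom = geometry.shifted(*base_xy)
        pts = np.concatenate(geom.polylines)
        if (pts[:, 0].min() < 0 or pts[:, 0].max() > frame_w
                or pts[:, 1].min() < 0 or pts[:, 1].max() > frame_h):
            warnings.warn("geometry extends outside the frame; strokes clipped")
    else:
        geom, pts = None, None

    if window_cm is not None:
        x0, y0, x1, y1 = window_cm
    elif geom is not None and crop_margin_cm is not None:
        m = crop_margin_cm
        x0 = max(pts[:, 0].min() - m, 0.0)
        x1 = min(pts[:, 0].max() + m, frame_w)
        y0 = max(pts[:, 1].min() - m, 0.0)
        y1 = min(pts[:, 1].max() + m, frame_h)
    else:
        x0, y0, x1, y1 = 0.0, 0.0, frame_w, frame_h
    # snap the window to the pixel grid so the mesh stays frame-anchored
    x0, y0 = np.floor(x0 / scale) * scale, np.floor(y0 / scale) * scale
    w_px = int(np.ceil((x1 - x0) / scale))
    h_px = int(np.ceil((y1 - y0) / scale))

    val = np.full((h_px, w_px), background_level, dtype=np.float32)

    # mesh grid, anchored to the frame origin
    col_lines = np.arange(np.ceil(x0 / mesh_pitch_cm) * mesh_pitch_cm,
                          x0 + w_px * scale, mesh_pitch_cm)
    row_lines = np.arange(np.ceil(y0 / mesh_pitch_cm) * mesh_pitch_cm,
                          y0 + h_px * scale, mesh_pitch_cm)
    cols = np.unique(((col_lines - x0) / scale).astype(int).clip(0, w_px - 1))
    rows = np.unique(((row_lines - y0) / scale).astype(int).clip(0, h_px - 1))
    val[:, cols] += mesh_brightness
    val[rows, :] += mesh_brightness
    # glints: bright specks where mesh threads cross
    if len(rows) and len(cols) and glint_fraction > 0:
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        inter = np.column_stack([rr.ravel(), cc.ravel()])
        pick = inter[rng.random(len(inter)) < glint_fraction]
        for r, c in pick:
            val[r:r + 2, c:c + 2] = background_level + glint_brightness

    truth = np.zeros((h_px, w_px), dtype=bool)
    if geom is not None:
        for poly in geom.polylines:
            poly_px = (poly - [x0, y0]) / scale
            _rasterize_polyline(truth, poly_px, geom.root_width_px)
        val[truth] = root_value

    rgb = np.repeat(val[:, :, None], 3, axis=2)
    if geom is not None:
        rgb[truth] = val[truth, None] * np.asarray(root_tint, dtype=np.float32)

    if vignette > 0:
        yy = (np.arange(h_px) - h_px / 2) / max(h_px, w_px)
        xx = (np.arange(w_px) - w_px / 2) / max(h_px, w_px)
        r2 = yy[:, None] ** 2 + xx[None, :] ** 2
        rgb *= (1.0 - vignette * (r2 / max(r2.max(), 1e-9)))[:, :, None]

    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, rgb.shape).astype(np.float32)
    img = np.clip(rgb, 0, 255).astype(np.uint8)

    meta = {"window_cm": [float(x0), float(y0), float(x0 + w_px * scale),
                          float(y0 + h_px * scale)],
            "noise_sd": noise_sd, "rng_seed": int(rng_seed)}
    cimg = CalibratedImage(img, scale, organ_hint="root", meta=meta)
    tmask = BinaryMask(truth, scale, "root", {"channel": "value",
                                              "source": "synthetic-truth"})
    if geom is not None:
        local_geom = geom.shifted(-x0, -y0)
        topo = local_geom.truth_topology()
        tglobal = _truth_global(local_geom, truth, scale)
        tlocal = measure_local_traits(topo)
        seed_px = ((base_xy[0] - x0) / scale, (base_xy[1] - y0) / scale)
    else:
        topo, tlocal, seed_px = None, None, None
        tglobal = GlobalTraitSet("root", 0.0, 0.0, 0.0, 0.0, None)
    return SyntheticScene(cimg, tmask, topo, tglobal, tlocal, seed_px,
                          int(rng_seed), geometry=geom)


# ---------------------------------------------------------------------------
# rosette renderer

def render_rosette(n_leaves: int = 12,
                   rosette_radius: float = 3.0,
                   rng_seed: int = 0,
                   scale: float = 0.01,
                   frame_cm: tuple[float, float] = (8.0, 8.0),
                   noise_sd: float = 3.0,
                   vignette: float = 0.1,
                   background_grey: float = 150.0,
                   leaf_aspect: float = 0.45,
                   leaf_length_cm: float | None = None) -> SyntheticScene:
    """Render a green lobed rosette on a grey background (top view).

    Leaves are ellipses placed at golden-angle phyllotaxis (137.5°),
    older leaves longer, reaching ``rosette_radius`` at most.  The truth
    mask is the exact union raster of the drawn ellipses.
    """
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    rng = np.random.default_rng(rng_seed)
    frame_h, frame_w = frame_cm
    h_px, w_px = int(frame_h / scale), int(frame_w / scale)
    center = np.array([w_px / 2.0, h_px / 2.0])

    rgb = np.full((h_px, w_px, 3), background_grey, dtype=np.float32)
    truth = np.zeros((h_px, w_px), dtype=bool)
    golden = np.deg2rad(137.50776)
    for k in range(n_leaves):
        ang = k * golden + rng.normal(0, np.deg2rad(2.0))
        if leaf_length_cm is not None:
            l_cm = leaf_length_cm
        else:
            frac = (k + 1) / n_leaves
            l_cm = rosette_radius * (0.35 + 0.65 * frac) * rng.uniform(0.95, 1.05)
            l_cm = min(l_cm, rosette_radius)
        w_cm = leaf_aspect * l_cm
        c = center + (l_cm / 2 / scale) * np.array([np.cos(ang), np.sin(ang)])
        rr, cc = skdraw.ellipse(c[1], c[0], w_cm / 2 / scale, l_cm / 2 / scale,
                                shape=truth.shape, rotation=-ang)
        truth[rr, cc] = True
        # leaf green: hue ~120°, clearly saturated against the grey setup
        g = np.array([55, 135, 60]) + rng.normal(0, 6, 3)
        rgb[rr, cc] = np.clip(g, 0, 255)

    if vignette > 0:
        yy = (np.arange(h_px) - h_px / 2) / max(h_px, w_px)
        xx = (np.arange(w_px) - w_px / 2) / max(h_px, w_px)
        r2 = yy[:, None] ** 2 + xx[None, :] ** 2
        rgb *= (1.0 - vignette * (r2 / max(r2.max(), 1e-9)))[:, :, None]
    if noise_sd > 0:
        rgb = rgb + rng.normal(0.0, noise_sd, rgb.shape).astype(np.float32)
    img = np.clip(rgb, 0, 255).astype(np.uint8)

    area_cm2 = float(truth.sum()) * scale ** 2
    cimg = CalibratedImage(img, scale, organ_hint="shoot",
                           meta={"rng_seed": int(rng_seed)})
    tmask = BinaryMask(truth, scale, "shoot", {"source": "synthetic-truth"})
    tglobal = GlobalTraitSet("shoot", area_cm2, 0.0, 0.0, 0.0, None)
    return SyntheticScene(cimg, tmask, None, tglobal, None, None, int(rng_seed))


# ---------------------------------------------------------------------------
# time course and treatments

def cd_like(params: PlantModel,
            rate_factor: float = 0.5,
            lauz_factor: float = 2.0,
            elong_factor: float = 0.5) -> PlantModel:
    """A lateral-root-inhibition regime (heavy-metal-stress-like).

    Halves the emergence intensity, doubles the unbranched apical
    distance and halves lateral elongation — the qualitative inhibition
    pattern such treatments produce (fewer, shorter laterals; longer
    unbranched zone).
    """
    return dataclasses.replace(
        params,
        lateral_rate=params.lateral_rate * rate_factor,
        lauz=params.lauz * lauz_factor,
        lateral_elong_rate=params.lateral_elong_rate * elong_factor,
    )


def cohort_models(n_plants: int, rng_seed: int,
                  base: PlantModel | None = None,
                  length_sd: float = 2.5) -> list[PlantModel]:
    """Plant-to-plant variation for a cohort: primary length and vigour."""
    base = base or PlantModel()
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_plants):
        length = float(np.clip(rng.normal(base.primary_length, length_sd),
                               8.0, 22.0))
        vigour = float(rng.uniform(0.85, 1.15))
        out.append(dataclasses.replace(
            base,
            primary_length=length,
            lateral_elong_rate=base.lateral_elong_rate * vigour,
        ))
    return out


def simulate_timecourse(params: PlantModel,
                        n_timepoints: int = 14,
                        treatment_start: int = 7,
                        growth_factor: float = 1.0,
                        rng_seed: int = 0,
                        plant_id: str = "plant_1",
                        treatment_label: str | None = None,
                        scale: float = 0.01,
                        render: bool = False,
                        render_kwargs: dict | None = None,
                        ) -> tuple[list, list[TraitRecord]]:
    """Simulate daily growth, optionally under a treatment, with truth traits.

    Days run 1..n_timepoints; from ``treatment_start`` onward every
    elongation rate is multiplied by ``growth_factor`` (1.0 = mock).
    Growth only adds material: each day's geometry extends the previous
    day's (same waviness phase, same insertion sequence, longer axes), so
    truth masks are nested over time.  Returns ``(per-day geometries or
    rendered scenes, truth TraitRecords)``.
    """
    if n_timepoints < 2:
        raise ValueError("need at least two timepoints")
    if not (0 < growth_factor <= 1):
        raise ValueError("growth_factor must be in (0, 1]")
    label = treatment_label or ("mock" if growth_factor == 1.0 else "treated")
    width_cm = params.root_width_px * scale

    days = np.arange(1, n_timepoints + 1)
    mult = np.where(days >= treatment_start, growth_factor, 1.0)
    lengths = params.initial_length + np.cumsum(params.primary_elong_rate * mult)

    # draw the full insertion sequence once, against the untreated horizon,
    # so treated and mock trajectories share the same underlying plant
    horizon = params.initial_length + params.primary_elong_rate * n_timepoints
    rng = np.random.default_rng(rng_seed)
    phase = rng.uniform(0, 2 * np.pi)
    insertions = _draw_insertions(params, horizon - params.lauz, rng)
    first_side = int(rng.integers(0, 2)) * 2 - 1
    angles = np.clip(rng.normal(params.branch_angle_deg, params.branch_angle_sd,
                                len(insertions)), 30.0, 85.0)

    # emergence day of each insertion: first day the axis covers s + lauz
    def emergence_day(s: float) -> int:
        covered = np.nonzero(lengths >= s + params.lauz)[0]
        return int(days[covered[0]]) if len(covered) else n_timepoints + 1

    e_days = np.array([emergence_day(s) for s in insertions])

    outputs, records = [], []
    render_kwargs = dict(render_kwargs or {})
    if render and "window_cm" not in render_kwargs:
        final = _assemble_day(params, phase, float(lengths[-1]), insertions,
                              e_days, angles, first_side, days[-1], mult,
                              rng_seed)
        p = np.concatenate(final.polylines) + [FRAME_CM[1] / 2.0, 0.5]
        m = render_kwargs.pop("crop_margin_cm", 2.0) or 2.0
        render_kwargs["window_cm"] = (p[:, 0].min() - m, max(p[:, 1].min() - m, 0),
                                      p[:, 0].max() + m, p[:, 1].max() + m)

    for d_i, day in enumerate(days):
        geom = _assemble_day(params, phase, float(lengths[d_i]), insertions,
                             e_days, angles, first_side, day, mult, rng_seed)
        if render:
            scene = render_scene(geom, scale=scale,
                                 rng_seed=rng_seed * 1000 + int(day) if rng_seed
                                 else int(day), **render_kwargs)
            outputs.append(scene)
        else:
            outputs.append(geom)
        records.extend(_truth_records(geom, plant_id, int(day), label,
                                      width_cm, scale))
    return outputs, records


def _assemble_day(params: PlantModel, phase: float, length: float,
                  insertions: np.ndarray, e_days: np.ndarray,
                  angles: np.ndarray, first_side: int, day: int,
                  mult: np.ndarray, rng_seed: int) -> PlantGeometry:
    primary = _primary_curve(params, length, phase)
    laterals: list[_GtLateral] = []
    side = first_side
    days = np.arange(1, len(mult) + 1)
    for i, s in enumerate(insertions):
        side = -side
        if s > length - params.lauz or e_days[i] > day:
            continue
        grown_days = ((days > e_days[i]) & (days <= day)
                      & (days <= e_days[i] + params.lateral_max_days))
        lat_len = float(params.lateral_elong_rate * mult[grown_days].sum())
        if params.lateral_length_rule is not None:
            lat_len = params.length_of(day - e_days[i])
        if lat_len <= 0:
            continue
        poly = _lateral_polyline(params, primary, phase, float(s), side,
                                 float(angles[i]), lat_len)
        laterals.append(_GtLateral(float(s), side, float(angles[i]),
                                   lat_len, poly))
    return PlantGeometry(primary, length, laterals, params.lauz,
                         params.root_width_px, rng_seed)


def _truth_records(geom: PlantGeometry, plant_id: str, day: int, label: str,
                   width_cm: float, scale: float) -> list[TraitRecord]:
    pts = np.concatenate(geom.polylines)
    depth = float(pts[:, 1].max() - pts[:, 1].min())
    total = geom.total_length
    topo = geom.truth_topology()
    local = measure_local_traits(topo)

    def rec(name: str, value: float, unit: str) -> TraitRecord:
        return TraitRecord(plant_id, day, label, "root", name, value, unit)

    out = [
        rec("projected_root_surface", total * width_cm, "cm2"),
        rec("root_system_depth", depth, "cm"),
        rec("primary_root_length", geom.primary_length, "cm"),
        rec("total_root_length", total, "cm"),
        rec("lauz", local.lauz, "cm"),
        rec("lateral_count", float(local.n_laterals), "count"),
        rec("root_biomass_proxy", total * width_cm ** 2, "cm3"),
    ]
    if local.lateral_density is not None:
        out.append(rec("lateral_root_density", local.lateral_density,
                       "count_per_cm"))
    return out
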