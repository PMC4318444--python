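# Methods

## Imaging model and segmentation

Photographs of hydroponic-rhizotron root systems are taken against a dark
background with indirect backlighting and deliberate slight
under-exposure: the fabric mesh all but disappears in brightness, while
the roots scatter light and appear as bright, near-achromatic ribbons.
Top-view rosette photographs show saturated green tissue on grey
hardware.  This drives the channel choice:

* **Shoot — Hue.** Pixels inside a green hue window (default 90°–150° of
  360°) with saturation ≥ 40/255 (achromatic pixels have meaningless
  hue), despeckled at 1000 px, largest component kept (one plant per
  frame).
* **Root — Value.** Hue cannot separate roots from mesh (both are
  grey-ish); brightness can.  Pipeline: Value channel → percentile
  contrast stretch (1, 99) → global Otsu threshold → despeckle (25 px) →
  fill 1-px holes.

Two numerical details matter:

* The threshold is computed on the *unclipped* affine stretch.  Roots
  occupy well under 1% of a frame, so they lie above the 99th percentile;
  saturating them (as the clipped display stretch does) folds the root
  mode into the background range and Otsu then splits the background
  hump instead.  The affine map is identical below the high percentile
  and preserves the ~30σ root/background separation.  If the percentile
  window is degenerate (noise-free background), the full min–max range is
  used instead.
* **Empty-frame guard.** Otsu always splits the histogram somewhere; on
  a frame without roots that split lands inside the background and
  selects tens of percent of the frame.  Roots are thin: any threshold
  capturing more than `max_foreground_frac` (default 10%) of the frame is
  treated as "nothing segmentable" and yields an empty mask with a
  warning.

Segmentation is fully deterministic; every mask carries its channel,
threshold and cleanup parameters as provenance.

## Global traits

Computed on the mask at its cm-per-pixel scale: projected area
(foreground count × scale²), bounding width/height (inclusive pixel
count; height of a root mask is reported as root-system depth),
convex-hull area, and for rosettes the maximum Feret diameter over hull
vertices (how one would put a ruler across the widest span).  Root traits
use all foreground components (thin roots fragment at mesh crossings;
dropping fragments would bias area low); shoot traits use the largest
component only.

The hull is computed on **pixel centers** by default, matching the
O(n²) gift-wrapping oracle used in the tests; note that for filled convex
shapes the center-hull is slightly *smaller* than the painted area (a
100×100 square has hull area 99²).  Where the containment property
projected ≤ hull ≤ width×height is wanted, `points="corners"` computes
the hull over pixel-square corners, which bounds the painted area from
above.  Both conventions differ by sub-pixel amounts at realistic organ
sizes.

## Root topology and local traits

The mask is thinned (Zhang's method), spurs shorter than 0.15 cm are
pruned, and the skeleton becomes an 8-connected pixel graph with edge
weights 1/√2 pixels.  The primary root is the maximum-arclength geodesic
from the seed node (nearest skeleton pixel to the seed holder, snap
radius 0.5 cm), ties broken toward greater depth.  Each branch component
hanging off the primary with arclength ≥ `min_lateral` (default 0.3 cm —
below the mesh-pitch scale, artifacts dominate) becomes one lateral;
deeper branching inside a component extends that lateral's longest path
rather than creating separate records.

Accuracy choices, each worth a sentence because the validation tolerances
are tight (LAUZ to 2 px-equivalents):

* **Arclength metric.** Raw 8-connected chain length (√2 per diagonal)
  overestimates oblique smooth curves by up to 8%.  Arclength is instead
  measured on the path resampled every 4 px (Euclidean polyline length),
  which is accurate to <0.5% at the curvatures that occur here.
* **Tip extension.** Thinning retracts endpoints by about half a root
  width — and on narrow diagonal ribbons Zhang thinning can erode tens of
  pixels from a free end.  When the source mask is available, terminal
  paths are continued along their local direction until they leave the
  mask.
* **Insertion refinement.** Thinning displaces junctions by a pixel or
  two.  Each insertion is re-estimated by intersecting the lateral's
  initial direction (least-squares line over its first pixels) with the
  primary polyline, to sub-pixel precision.

Local traits follow from the topology: LAUZ = primary arclength from the
apex to the most apical insertion (the whole primary when no laterals
exist); branched-zone length = primary length − LAUZ, so the partition
identity LAUZ + branched zone = primary length holds exactly by
construction; lateral density = lateral count / branched-zone length,
undefined (not zero) without laterals.  Density over the branched zone is
the standard RSA convention and is consistent with LAUZ being reported
separately; the whole-primary denominator is one division away if wanted.

Topologies serialize to RSML 1.0 (primary root element with nested
lateral roots, coordinates in cm).  Measured quantities that re-digitised
geometry cannot reproduce bit-exactly — primary length, insertion
arclengths, lateral lengths — are stored as RSML properties, making the
export/import round trip lossless to 10⁻⁶ cm; third-party RSML without
such properties falls back to projection onto the primary polyline.

## Synthetic scenes and ground truth

The generator emulates the imaging setup: a 33.5 × 25 cm frame at
0.1 mm/px, mesh grid at 0.707 mm pitch (0.5 mm² cells) rendered as a
faint additive grid (+3 grey levels) with bright 2×2 glints at 3% of
thread crossings, Gaussian sensor noise (σ = 4), radial vignetting (8%),
background level 30 (under-exposed: the frame mean stays well below
mid-grey), and roots as flat-capped ribbons (+130 grey levels, slight
warm tint so hue stays uninformative).  Under indirect backlighting the
real fabric is nearly invisible in brightness — its confounding is
specular glints and texture, which is what the renderer reproduces.  By
default the rendered window crops to the plant's bounding box + 2 cm, as
photographs are framed on the root system; the full frame is available.

The plant model (defaults chosen once, as a realistic adult plant under
daily imaging):

| parameter | default | meaning |
|---|---|---|
| `primary_length` | 18 cm | primary arclength at imaging (≈17 days at 1 cm/day from a 1 cm seedling) |
| `primary_elong_rate` | 1 cm/day | primary elongation |
| `waviness_amplitude` / `wavelength` | 0.2 / 5 cm | sinusoidal heading of the unit-speed primary curve |
| `lateral_rate` | 1.5 /cm | intensity of the insertion process |
| `lateral_min_gap` | 0.3 cm | hard-core spacing; gap = min_gap + Exp(μ) with mean exactly 1/rate |
| `lauz` | 2 cm | unbranched apical distance behind the tip |
| `lateral_elong_rate` | 0.4 cm/day | lateral elongation |
| `lateral_max_days` | 8 | determinate lateral growth duration |
| `branch_angle_deg` | 60 ± 4° | insertion angle off the local primary direction, clipped to [30°, 85°] |
| `root_width_px` | 3 | rendered ribbon width (0.3 mm) |

Lateral placement is a hard-core renewal process rather than pure
Poisson: real lateral primordia keep a minimum spacing, and arbitrarily
close insertions would merge at the skeleton junction, making exact
count recovery ill-posed.  The gap mean is chosen so the process
intensity equals `lateral_rate` exactly.  Insertion sides alternate
left/right (as Arabidopsis lateral files do) and branch angles are
redrawn (with widening spread) until each straight lateral keeps 0.5 mm
clearance from every other root — the mesh combs the system flat and
untangled, which is the apparatus's point.

Lateral length is day-quantized: elongation rate × whole days since
emergence (emergence when the tip has grown `lauz` past the insertion),
capped at `lateral_max_days` — the natural growth model for a
daily-photographed time course, with the acropetal consequence that more
basal laterals are longer.  Time courses share one underlying plant
(same waviness phase, same insertion sequence) across treatments; a
treatment multiplies every elongation rate by `growth_factor` from
`treatment_start` onward, so growth only adds material and truth masks
nest over time.  The `cd_like` preset models lateral-root inhibition
phenomenologically (emergence rate ×0.5, unbranched distance ×2, lateral
elongation ×0.5); it is a description of the observed pattern, not a
toxicity mechanism.

Ground truth is analytic: the unit-speed curve makes arclengths exact,
insertion positions and lateral lengths are known, and the truth mask is
the exact stroke raster before noise.  Stored truth traits are computed
from the truth topology by the same trait definitions, so recomputation
matches to 10⁻⁹.

**What the generator does not emulate** — and therefore what passing
tests do not establish about field data: root-width variation and
tapering, overlapping/crossing roots (real systems occasionally cross
even on mesh), second-order laterals as distinct organs, algal spots and
debris, uneven illumination beyond a radial vignette, perspective and
lens distortion, and plant-to-plant variation beyond primary length and
vigour.  Results on real photographs will degrade foremost where roots
cross (topology) and where illumination drifts (thresholding).

## Statistics

Two-sample comparisons use Welch's t-test (plain "t-test" reported in
such studies rarely guarantees equal variances; the pooled test is one
flag away), two-sided, per timepoint without multiple-testing correction
— matching the per-day significance-star readout — with a Holm option
available.  Degenerate zero-variance groups return t = 0, p = 1 (equal
means) or p = 0 (unequal) instead of NaN.  Trait correlations are Pearson
product-moment on per-plant pairs, undefined below three pairs or at zero
variance.

Validation sizes (chosen to keep each quantity's sampling error well
below its tolerance): 20 rendered scenes for segmentation/global traits,
50 noiseless plants for topology (30 for the density average), 100
simulated experiments for power and 1000 for type-I error, 30-plant
cohorts for the biomass–surface correlation.
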