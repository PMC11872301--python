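"""The measurement core: arch partition, curve fits, tooth gating, ACH.

Pipeline for one bitewing radiograph, in execution order:

1. fuse the two detectors' landmark sets (``fusion`` module);
2. fit a straight *partition line* through the ABCL segmentation-mask
   pixels — in a bitewing the maxillary and mandibular bone crests form
   two horizontal bands, so the ordinary least-squares line through all
   crest pixels runs between the arches;
3. split landmarks into upper (above the line) and lower;
4. fit one polynomial *arch curve* per (arch, landmark class);
5. union the two teeth segmentation masks and extract tooth instances
   as 8-connected components;
6. gate: a tooth is measurable only if its outline crosses both of its
   arch's curves (ABCL and CEJ) — teeth cut off at the image border or
   spurious blobs fail this test;
7. per tooth side (left/right flank), pair the nearest CEJ and ABCL
   landmarks inside a window around the flank column and report the
   Euclidean CEJ-ABCL distance as the alveolar crestal height (ACH),
   converted to mm and thresholded into a severity call.

All iteration orders are fixed (sorted by x, then y), so identical
inputs give bit-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw, ImageFont
from skimage import measure as skmeasure

from .core import (
    AchMeasurement,
    BinaryMask,
    Calibration,
    DegenerateGeometryError,
    DimensionError,
    Landmark,
    LandmarkClass,
    MaskLabel,
    PipelineConfig,
    Point2D,
    SITE_LEFT,
    SITE_RIGHT,
    logger,
    px_to_mm,
)

__all__ = [
    "PartitionLine",
    "ArchCurve",
    "ToothInstance",
    "AchMeasurement",
    "PipelineResult",
    "fit_partition_line",
    "partition_landmarks",
    "fit_arch_curve",
    "extract_tooth_instances",
    "merge_teeth_masks",
    "tooth_crosses_curves",
    "measure_tooth_ach",
    "classify_severity",
    "process_radiograph",
    "render_overlay",
]

ARCH_UPPER = "upper"
ARCH_LOWER = "lower"


@dataclass(frozen=True)
class PartitionLine:
    """Best-fit line y = slope * x + intercept separating the arches."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValueError("partition line coefficients must be finite")

    def y_at(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.slope * x + self.intercept


@dataclass(frozen=True)
class ArchCurve:
    """Polynomial y(x) fitted to one landmark class in one arch.

    ``coeffs`` are in ascending degree order; ``support`` is the x-range
    of the fitting points, outside which the curve is not evaluated.
    """

    arch: str
    cls: LandmarkClass
    coeffs: tuple[float, ...]
    degree: int
    support: tuple[float, float]

    def __post_init__(self) -> None:
        if self.arch not in (ARCH_UPPER, ARCH_LOWER):
            raise ValueError(f"arch must be '{ARCH_UPPER}' or '{ARCH_LOWER}'")
        if self.degree < 1 or len(self.coeffs) != self.degree + 1:
            raise ValueError("need len(coeffs) == degree + 1 with degree >= 1")
        if not self.support[1] > self.support[0]:
            raise ValueError("curve support must be non-degenerate")

    def __call__(self, x: float | np.ndarray) -> float | np.ndarray:
        return np.polynomial.polynomial.polyval(x, np.asarray(self.coeffs))


@dataclass
class ToothInstance:
    """A connected component of the teeth mask.

    ``pixels`` and ``outline`` are (N, 2) int arrays of (x, y); the
    outline is the set of foreground pixels with at least one background
    4-neighbour (the image border counts as background), sorted by
    (x, y).
    """

    tooth_id: int
    pixels: np.ndarray
    outline: np.ndarray
    x_min: int
    x_max: int
    area_px: int
    arch: str | None = None

    def __post_init__(self) -> None:
        if self.area_px != len(self.pixels):
            raise ValueError("area_px must equal the pixel count")
        if self.x_min > self.x_max:
            raise ValueError("x_min must be <= x_max")


@dataclass
class PipelineResult:
    """Everything :func:`process_radiograph` produces for one image."""

    measurements: list[AchMeasurement]
    partition_line: PartitionLine | None
    curves: dict[tuple[str, LandmarkClass], ArchCurve]
    teeth: list[ToothInstance] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Partition line and landmark split

def _as_xy(points: "BinaryMask | Sequence[Point2D] | np.ndarray") -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, BinaryMask):
        rows, cols = np.nonzero(points.grid)
        return cols.astype(float), rows.astype(float)
    arr = np.asarray(
        [(p.x, p.y) for p in points] if points and isinstance(points[0], Point2D) else points,
        dtype=float,
    )
    if arr.size == 0:
        return np.empty(0), np.empty(0)
    return arr[:, 0], arr[:, 1]


def fit_partition_line(abcl_mask_or_points: "BinaryMask | Sequence[Point2D]") -> PartitionLine:
    """OLS line y = a*x + b through ABCL foreground pixels (or points).

    Bitewings are landscape images whose crest pixels span both arches;
    regressing y on x places the line between the maxillary and
    mandibular crest bands.
    """
    x, y = _as_xy(abcl_mask_or_points)
    if len(x) < 2 or np.ptp(x) == 0:
        raise DegenerateGeometryError(
            f"partition line needs >= 2 points with >= 2 distinct x values, got {len(x)}"
        )
    slope, intercept = np.polyfit(x, y, 1)
    return PartitionLine(float(slope), float(intercept))


def partition_landmarks(
    landmarks: Sequence[Landmark], line: PartitionLine
) -> tuple[list[Landmark], list[Landmark]]:
    """Split landmarks into (upper, lower) by the partition line.

    y increases downward, so y <= line means maxillary (upper); a
    landmark exactly on the line goes to the upper arch (documented
    tie-break).
    """
    upper = [lm for lm in landmarks if lm.point.y <= line.y_at(lm.point.x)]
    lower = [lm for lm in landmarks if lm.point.y > line.y_at(lm.point.x)]
    return upper, lower


# ---------------------------------------------------------------------------
# Arch curves

def fit_arch_curve(
    points: Sequence[Point2D],
    arch: str,
    cls: LandmarkClass | str,
    degree: int,
) -> ArchCurve:
    """Least-squares polynomial y(x) of the requested degree.

    When there are fewer distinct x values than degree + 1, the degree
    is reduced to (distinct x count - 1) with a warning instead of
    failing; interpolating cases then reproduce the inputs exactly.
    """
    x, y = _as_xy(points)
    n_distinct = len(np.unique(x))
    if n_distinct < 2:
        raise DegenerateGeometryError(
            f"arch curve needs >= 2 distinct x values, got {n_distinct}"
        )
    eff_degree = min(degree, n_distinct - 1)
    if eff_degree < degree:
        logger.warning(
            "%s/%s curve: only %d distinct x values, reducing degree %d -> %d",
            arch, LandmarkClass(cls).value, n_distinct, degree, eff_degree,
        )
    coeffs = np.polynomial.polynomial.polyfit(x, y, eff_degree)
    return ArchCurve(
        arch=arch,
        cls=LandmarkClass(cls),
        coeffs=tuple(float(c) for c in coeffs),
        degree=eff_degree,
        support=(float(x.min()), float(x.max())),
    )


# ---------------------------------------------------------------------------
# Tooth instances

def _outline_mask(grid: np.ndarray) -> np.ndarray:
    # foreground pixel with >= 1 background 4-neighbour; off-image counts
    # as background, so blobs touching the border keep their border edge
    padded = np.pad(grid, 1)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return grid & ~interior

def extract_tooth_instances(teeth_mask: BinaryMask, min_tooth_area_px: int) -> list[ToothInstance]:
    """8-connected components of the teeth mask, area-filtered.

    Instances are sorted by x_min ascending (secondary key y_min, since
    upper and lower teeth can share a column range) and tooth_id is
    assigned in that order starting at 0.
    """
    if teeth_mask.label != MaskLabel.TEETH:
        raise ValueError(f"expected a teeth mask, got label {teeth_mask.label.value!r}")
    labels = skmeasure.label(teeth_mask.grid, connectivity=2)
    outline = _outline_mask(teeth_mask.grid)
    instances: list[tuple[int, int, ToothInstance]] = []
    for region in skmeasure.regionprops(labels):
        if region.area < min_tooth_area_px:
            continue
        coords = region.coords  # (row, col)
        pixels = np.column_stack((coords[:, 1], coords[:, 0])).astype(int)
        order = np.lexsort((pixels[:, 1], pixels[:, 0]))
        pixels = pixels[order]
        on_outline = outline[pixels[:, 1], pixels[:, 0]]
        inst = ToothInstance(
            tooth_id=-1,
            pixels=pixels,
            outline=pixels[on_outline],
            x_min=int(pixels[:, 0].min()),
            x_max=int(pixels[:, 0].max()),
            area_px=int(region.area),
        )
        instances.append((inst.x_min, int(pixels[:, 1].min()), inst))
    instances.sort(key=lambda t: (t[0], t[1]))
    out = []
    for tooth_id, (_, _, inst) in enumerate(instances):
        inst.tooth_id = tooth_id
        out.append(inst)
    logger.info("extracted %d tooth instances (min area %d px)", len(out), min_tooth_area_px)
    return out


def merge_teeth_masks(mask_1: BinaryMask, mask_2: BinaryMask) -> BinaryMask:
    """Pixel-wise union of the two teeth-segmentation masks."""
    if mask_1.shape != mask_2.shape:
        raise DimensionError(f"mask shapes differ: {mask_1.shape} vs {mask_2.shape}")
    return BinaryMask(mask_1.grid | mask_2.grid, MaskLabel.TEETH)


# ---------------------------------------------------------------------------
# Gate

def _crosses_one_curve(tooth: ToothInstance, curve: ArchCurve, tol_px: float) -> bool:
    lo, hi = curve.support
    if len(tooth.outline):
        ox = tooth.outline[:, 0].astype(float)
        oy = tooth.outline[:, 1].astype(float)
        in_support = (ox >= lo) & (ox <= hi)
        if in_support.any() and np.any(np.abs(oy[in_support] - curve(ox[in_support])) <= tol_px):
            return True
    # sign-change test: curve passes strictly between the tooth's min and
    # max row at some column (handles curves slicing through the interior)
    px = tooth.pixels
    cols, inverse = np.unique(px[:, 0], return_inverse=True)
    y_min = np.full(len(cols), np.iinfo(np.int64).max)
    y_max = np.full(len(cols), np.iinfo(np.int64).min)
    np.minimum.at(y_min, inverse, px[:, 1])
    np.maximum.at(y_max, inverse, px[:, 1])
    in_support = (cols >= lo) & (cols <= hi)
    if not in_support.any():
        return False
    cy = curve(cols[in_support].astype(float))
    return bool(np.any((cy > y_min[in_support]) & (cy < y_max[in_support])))


def tooth_crosses_curves(
    tooth: ToothInstance, abcl_curve: ArchCurve, cej_curve: ArchCurve, tol_px: float = 1.0
) -> bool:
    """True iff the tooth outline crosses BOTH arch curves.

    A curve is crossed when an outline pixel lies within ``tol_px`` of
    the curve inside its support, or the curve's y at some tooth column
    falls strictly between the tooth's min and max y there.
    """
    return _crosses_one_curve(tooth, abcl_curve, tol_px) and _crosses_one_curve(
        tooth, cej_curve, tol_px
    )


# ---------------------------------------------------------------------------
# Measurement

def classify_severity(ach_mm: float, threshold_mm: float, rule: str = "ge") -> bool:
    """Severity call for one site: ge -> severe iff ach >= threshold.

    Both conventions found in the clinical literature are supported;
    they disagree only when the measurement equals the threshold
    exactly.
    """
    if ach_mm < 0:
        raise ValueError(f"ach_mm must be >= 0, got {ach_mm}")
    if rule == "ge":
        return ach_mm >= threshold_mm
    if rule == "gt":
        return ach_mm > threshold_mm
    raise ValueError(f"severity rule must be 'ge' or 'gt', got {rule!r}")


def _nearest_in_window(
    landmarks: Sequence[Landmark],
    cls: LandmarkClass,
    ref_x: float,
    half_width: float,
    outline: np.ndarray,
) -> Landmark | None:
    """Nearest landmark of ``cls`` with x in [ref_x - w, ref_x + w].

    Nearest is measured as Euclidean distance to the tooth outline:
    true crestal landmarks sit on the tooth flank, so a spurious
    detection at an arbitrary row loses to an on-flank point even when
    its column happens to fall in the window. Ties break on |x - ref_x|,
    then (x, y).
    """
    best: tuple[float, float, float, float] | None = None
    best_lm: Landmark | None = None
    for lm in landmarks:
        if lm.cls != cls or abs(lm.point.x - ref_x) > half_width:
            continue
        if len(outline):
            d = float(
                np.min(np.hypot(outline[:, 0] - lm.point.x, outline[:, 1] - lm.point.y))
            )
        else:
            d = abs(lm.point.x - ref_x)
        key = (d, abs(lm.point.x - ref_x), lm.point.x, lm.point.y)
        if best is None or key < best:
            best, best_lm = key, lm
    return best_lm


def measure_tooth_ach(
    tooth: ToothInstance,
    landmarks_in_arch: Sequence[Landmark],
    cal: Calibration,
    config: PipelineConfig,
    image_id: str = "image",
) -> list[AchMeasurement]:
    """Measure ACH at the tooth's left and right flank (0-2 entries).

    For each side, the window spans fusion_radius_px columns either side
    of the flank column (x_min or x_max); the nearest CEJ and nearest
    ABCL landmark inside the window are paired and the Euclidean
    distance between them is the ACH. A side lacking either landmark
    emits nothing.
    """
    w = config.fusion_radius_px
    out: list[AchMeasurement] = []
    for site, ref_x in ((SITE_LEFT, float(tooth.x_min)), (SITE_RIGHT, float(tooth.x_max))):
        cej = _nearest_in_window(landmarks_in_arch, LandmarkClass.CEJ, ref_x, w, tooth.outline)
        abcl = _nearest_in_window(landmarks_in_arch, LandmarkClass.ABCL, ref_x, w, tooth.outline)
        if cej is None or abcl is None:
            logger.info(
                "%s tooth %d %s side: missing %s landmark, no measurement",
                image_id, tooth.tooth_id, site,
                "CEJ" if cej is None else "ABCL",
            )
            continue
        ach_px = cej.point.distance_to(abcl.point)
        ach_mm = px_to_mm(ach_px, cal)
        out.append(
            AchMeasurement(
                image_id=image_id,
                tooth_id=tooth.tooth_id,
                site=site,
                cej=cej.point,
                abcl=abcl.point,
                ach_px=ach_px,
                ach_mm=ach_mm,
                severe=classify_severity(ach_mm, config.severity_threshold_mm, config.severity_rule),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Full pipeline

def _assign_arch(tooth: ToothInstance, line: PartitionLine) -> str:
    above = int(np.sum(tooth.pixels[:, 1] <= line.y_at(tooth.pixels[:, 0].astype(float))))
    return ARCH_UPPER if 2 * above >= tooth.area_px else ARCH_LOWER


def process_radiograph(
    landmarks_a: Sequence[Landmark],
    landmarks_b: Sequence[Landmark],
    teeth_mask_1: BinaryMask,
    teeth_mask_2: BinaryMask,
    abcl_mask: BinaryMask,
    cal: Calibration,
    config: PipelineConfig,
    image_id: str = "image",
) -> PipelineResult:
    """Run the whole measurement pipeline on one radiograph.

    Stages with insufficient data degrade gracefully: a missing
    partition line or arch curve drops the affected arch's measurements
    with a log message rather than raising. Only structural errors
    (mask shape mismatch) raise.
    """
    from .fusion import FusionParams, fuse_landmarks  # local import avoids cycle

    teeth_mask = merge_teeth_masks(teeth_mask_1, teeth_mask_2)
    if abcl_mask.shape != teeth_mask.shape:
        raise DimensionError(
            f"ABCL mask shape {abcl_mask.shape} != teeth mask shape {teeth_mask.shape}"
        )

    fused = fuse_landmarks(landmarks_a, landmarks_b, FusionParams(config.fusion_radius_px))

    try:
        line = fit_partition_line(abcl_mask)
    except DegenerateGeometryError as exc:
        logger.warning("%s: cannot fit partition line (%s); no measurements", image_id, exc)
        return PipelineResult([], None, {}, [])

    upper, lower = partition_landmarks(fused, line)

    curves: dict[tuple[str, LandmarkClass], ArchCurve] = {}
    for arch, arch_landmarks in ((ARCH_UPPER, upper), (ARCH_LOWER, lower)):
        for cls in (LandmarkClass.ABCL, LandmarkClass.CEJ):
            pts = [lm.point for lm in arch_landmarks if lm.cls == cls]
            try:
                curves[(arch, cls)] = fit_arch_curve(pts, arch, cls, config.curve_degree)
            except DegenerateGeometryError as exc:
                logger.warning("%s: no %s/%s curve (%s)", image_id, arch, cls.value, exc)

    teeth = extract_tooth_instances(teeth_mask, config.min_tooth_area_px)
    arch_landmark_sets = {ARCH_UPPER: upper, ARCH_LOWER: lower}

    measurements: list[AchMeasurement] = []
    n_gated = 0
    for tooth in teeth:
        tooth.arch = _assign_arch(tooth, line)
        abcl_curve = curves.get((tooth.arch, LandmarkClass.ABCL))
        cej_curve = curves.get((tooth.arch, LandmarkClass.CEJ))
        if abcl_curve is None or cej_curve is None:
            logger.info("%s tooth %d: %s arch curves unavailable, skipped",
                        image_id, tooth.tooth_id, tooth.arch)
            continue
        if not tooth_crosses_curves(tooth, abcl_curve, cej_curve, config.crossing_tolerance_px):
            n_gated += 1
            logger.info("%s tooth %d: outline does not cross both curves, skipped",
                        image_id, tooth.tooth_id)
            continue
        measurements.extend(
            measure_tooth_ach(tooth, arch_landmark_sets[tooth.arch], cal, config, image_id)
        )
    logger.info(
        "%s: %d teeth, %d gated out, %d measurements",
        image_id, len(teeth), n_gated, len(measurements),
    )
    return PipelineResult(measurements, line, curves, teeth)


# ---------------------------------------------------------------------------
# Overlay rendering

_COLOR_SEVERE = (220, 40, 40)
_COLOR_NON_SEVERE = (40, 200, 80)
_COLOR_ABCL_CURVE = (250, 160, 30)
_COLOR_CEJ_CURVE = (60, 170, 250)
_COLOR_LINE = (120, 120, 250)


def render_overlay(
    image: np.ndarray,
    measurements: Sequence[AchMeasurement],
    curves: "dict[tuple[str, LandmarkClass], ArchCurve] | None" = None,
    line: PartitionLine | None = None,
) -> np.ndarray:
    """Superimpose measurements (and optional curves/line) on the image.

    Each measurement is a CEJ-to-ABCL segment labelled with its mm
    value; severe sites are red, non-severe green. Output is an RGB
    array of the input's H x W; rendering is deterministic.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("overlay input must be a 2-D grayscale raster")
    rgb = Image.fromarray(arr.astype(np.uint8), mode="L").convert("RGB")
    draw = ImageDraw.Draw(rgb)
    font = ImageFont.load_default()
    w = arr.shape[1]

    if line is not None:
        draw.line([(0, line.y_at(0.0)), (w - 1, line.y_at(float(w - 1)))],
                  fill=_COLOR_LINE, width=1)
    for curve in (curves or {}).values():
        xs = np.linspace(curve.support[0], curve.support[1], max(2, int(w / 4)))
        pts = [(float(x), float(curve(x))) for x in xs]
        color = _COLOR_ABCL_CURVE if curve.cls == LandmarkClass.ABCL else _COLOR_CEJ_CURVE
        draw.line(pts, fill=color, width=1)
    for m in measurements:
        color = _COLOR_SEVERE if m.severe else _COLOR_NON_SEVERE
        draw.line([(m.cej.x, m.cej.y), (m.abcl.x, m.abcl.y)], fill=color, width=2)
        mid = ((m.cej.x + m.abcl.x) / 2 + 3, (m.cej.y + m.abcl.y) / 2)
        draw.text(mid, f"{m.ach_mm:.1f}", fill=color, font=font)
    return np.asarray(rgb)
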