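"""Synthetic bitewing phantom scenes with exact ground-truth ACH.

No clinical imaging is bundled with the package, so all end-to-end
testing runs on phantoms: two arches of rounded-rectangle teeth placed
on a mild occlusal curve, with a cemento-enamel junction (CEJ) point on
each tooth flank and an alveolar bone crest (ABCL) point displaced
apically along the flank by a per-site bone-loss draw. Because the
flank is vertical, the Euclidean CEJ-ABCL distance equals the drawn
bone loss exactly, so every site has an exact, self-consistent
ground-truth ACH.

Teeth are geometric primitives, not anatomical crowns: the measurement
pipeline consumes only masks and point landmarks, so shape realism adds
nothing to correctness testing (see the methods note for what this does
and does not validate about clinical images).

The default bone-loss distribution is a 50/50 mixture of
Uniform(2, 4.5) and Uniform(5.5, 8) mm, straddling the 5 mm severity
threshold while leaving the boundary band empty so severity calls are
unambiguous unless a boundary case is explicitly requested. Default
geometry matches the 869 x 1200 working resolution of the pipeline;
phantom calibration defaults to 0.1 mm/px (a synthetic choice, not a
claim about real sensors).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    AchMeasurement,
    BinaryMask,
    MaskLabel,
    Point2D,
    SITE_LEFT,
    SITE_RIGHT,
    logger,
    write_measurements,
)
from .geometry import ARCH_LOWER, ARCH_UPPER, classify_severity

__all__ = [
    "PhantomSpecError",
    "PhantomSpec",
    "PhantomTooth",
    "TruthSite",
    "PhantomTruth",
    "draw_bone_loss",
    "generate_phantom",
    "truth_to_gold_csv",
]

_CROWN_CORNER_RADIUS_PX = 12


class PhantomSpecError(ValueError):
    """Raised when a phantom spec describes infeasible geometry."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic bitewing scene.

    ``bone_loss_mm`` may pin per-site losses explicitly (ordered by
    tooth then left/right site); when ``None``, losses are drawn from
    the severe/non-severe mixture controlled by ``severe_mix_p`` and
    the two uniform ranges.
    """

    image_shape: tuple[int, int] = (869, 1200)
    n_teeth_per_arch: int = 4
    tooth_width_px: int = 120
    tooth_height_px: int = 260
    arch_gap_px: int = 60
    cej_offset_px: int = 25
    occlusal_curve_amplitude_px: float = 20.0
    mm_per_px: float = 0.1
    severe_mix_p: float = 0.5
    bone_loss_range_non_severe_mm: tuple[float, float] = (2.0, 4.5)
    bone_loss_range_severe_mm: tuple[float, float] = (5.5, 8.0)
    bone_loss_mm: Sequence[float] | None = None
    severity_threshold_mm: float = 5.0
    severity_rule: str = "ge"
    seed: int = 0

    @property
    def n_sites(self) -> int:
        return 4 * self.n_teeth_per_arch

    def validate(self) -> None:
        h_img, w_img = self.image_shape
        if self.n_teeth_per_arch < 1:
            raise PhantomSpecError("need at least one tooth per arch")
        if self.mm_per_px <= 0:
            raise PhantomSpecError("mm_per_px must be > 0")
        if not 0.0 <= self.severe_mix_p <= 1.0:
            raise PhantomSpecError("severe_mix_p must lie in [0, 1]")
        gap = (w_img - self.n_teeth_per_arch * self.tooth_width_px) / (self.n_teeth_per_arch + 1)
        if gap <= 0:
            raise PhantomSpecError(
                f"{self.n_teeth_per_arch} teeth of width {self.tooth_width_px} px "
                f"overlap in a {w_img} px wide image"
            )
        if self.cej_offset_px <= _CROWN_CORNER_RADIUS_PX:
            raise PhantomSpecError(
                f"cej_offset_px must exceed the crown corner radius "
                f"({_CROWN_CORNER_RADIUS_PX} px) so the CEJ sits on a straight flank"
            )
        max_loss_px = self._max_loss_mm() / self.mm_per_px
        if self.cej_offset_px + max_loss_px >= self.tooth_height_px - 1:
            raise PhantomSpecError("tooth too short for the configured bone loss range")
        total_h = 2 * self.tooth_height_px + self.arch_gap_px + 2 * self.occlusal_curve_amplitude_px
        if total_h >= h_img:
            raise PhantomSpecError("arches do not fit vertically inside the image")
        if self.bone_loss_mm is not None:
            if len(self.bone_loss_mm) != self.n_sites:
                raise PhantomSpecError(
                    f"bone_loss_mm must list {self.n_sites} values, got {len(self.bone_loss_mm)}"
                )
            if any(v < 0 for v in self.bone_loss_mm):
                raise PhantomSpecError("bone_loss_mm values must be >= 0")

    def _max_loss_mm(self) -> float:
        if self.bone_loss_mm is not None:
            return max(self.bone_loss_mm, default=0.0)
        return max(self.bone_loss_range_non_severe_mm[1], self.bone_loss_range_severe_mm[1])


@dataclass
class PhantomTooth:
    tooth_id: int
    arch: str
    x_min: int
    x_max: int
    y_min: int
    y_max: int


@dataclass
class TruthSite:
    """Ground truth for one tooth site (one flank)."""

    tooth_id: int
    site: str
    cej: Point2D
    abcl: Point2D
    ach_mm: float
    severe: bool


@dataclass
class PhantomTruth:
    """Exact ground truth of a generated scene."""

    image_id: str
    mm_per_px: float
    teeth: list[PhantomTooth]
    sites: list[TruthSite]
    teeth_mask: BinaryMask
    abcl_mask: BinaryMask


def draw_bone_loss(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-site bone-loss draws (mm) from the configured mixture."""
    if spec.bone_loss_mm is not None:
        return np.asarray(spec.bone_loss_mm, dtype=float)
    severe = rng.uniform(size=spec.n_sites) < spec.severe_mix_p
    lo_ns, hi_ns = spec.bone_loss_range_non_severe_mm
    lo_s, hi_s = spec.bone_loss_range_severe_mm
    draws = rng.uniform(size=spec.n_sites)
    return np.where(severe, lo_s + draws * (hi_s - lo_s), lo_ns + draws * (hi_ns - lo_ns))


def _tooth_grid(spec: PhantomSpec, crown_at_bottom: bool) -> np.ndarray:
    """Boolean tooth template: rectangle with rounded crown corners."""
    h, w = spec.tooth_height_px, spec.tooth_width_px
    grid = np.ones((h, w), dtype=bool)
    r = _CROWN_CORNER_RADIUS_PX
    yy, xx = np.mgrid[0:r, 0:r]
    corner = (xx - (r - 1)) ** 2 + (yy - (r - 1)) ** 2 > r**2  # outside quarter disk
    if crown_at_bottom:
        grid[h - r:, :r] &= ~np.flipud(np.fliplr(corner))
        grid[h - r:, w - r:] &= ~np.flipud(corner)
    else:
        grid[:r, :r] &= ~corner
        grid[:r, w - r:] &= ~np.fliplr(corner)
    return grid


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Generate one bitewing scene and its exact ground truth.

    Returns the 8-bit grayscale image and a :class:`PhantomTruth` whose
    per-site ``ach_mm`` equals Euclidean(cej, abcl) * mm_per_px exactly.
    Fully deterministic given ``spec.seed``.
    """
    spec.validate()
    h_img, w_img = spec.image_shape
    rng = np.random.default_rng(spec.seed)
    loss_mm = draw_bone_loss(spec, rng)

    n = spec.n_teeth_per_arch
    w, h = spec.tooth_width_px, spec.tooth_height_px
    gap = (w_img - n * w) / (n + 1)
    y_mid = h_img / 2.0
    amp = spec.occlusal_curve_amplitude_px

    def curve_dev(x: float) -> float:
        return amp * ((x - w_img / 2.0) / (w_img / 2.0)) ** 2

    teeth_grid = np.zeros((h_img, w_img), dtype=bool)
    raw_teeth: list[tuple[str, int, int, int, int]] = []  # arch, x0, x1, y0, y1
    for arch in (ARCH_UPPER, ARCH_LOWER):
        for i in range(n):
            x0 = int(round(gap + i * (w + gap)))
            x1 = x0 + w - 1
            xc = (x0 + x1) / 2.0
            if arch == ARCH_UPPER:
                crown_y = int(round(y_mid - spec.arch_gap_px / 2.0 - curve_dev(xc)))
                y0, y1 = crown_y - h + 1, crown_y
                template = _tooth_grid(spec, crown_at_bottom=True)
            else:
                crown_y = int(round(y_mid + spec.arch_gap_px / 2.0 + curve_dev(xc)))
                y0, y1 = crown_y, crown_y + h - 1
                template = _tooth_grid(spec, crown_at_bottom=False)
            if y0 < 0 or y1 >= h_img:
                raise PhantomSpecError("tooth extends outside the image vertically")
            teeth_grid[y0:y1 + 1, x0:x1 + 1] |= template
            raw_teeth.append((arch, x0, x1, y0, y1))

    # tooth ids follow the instance-extraction convention: x_min ascending,
    # then y_min, so phantom truth joins with pipeline output on tooth_id
    raw_teeth.sort(key=lambda t: (t[1], t[3]))
    teeth = [
        PhantomTooth(tooth_id=i, arch=a, x_min=x0, x_max=x1, y_min=y0, y_max=y1)
        for i, (a, x0, x1, y0, y1) in enumerate(raw_teeth)
    ]

    abcl_grid = np.zeros_like(teeth_grid)
    sites: list[TruthSite] = []
    site_idx = 0
    for tooth in teeth:
        crown_y = tooth.y_max if tooth.arch == ARCH_UPPER else tooth.y_min
        apical = -1.0 if tooth.arch == ARCH_UPPER else 1.0
        cej_y = crown_y + apical * spec.cej_offset_px  # cej_offset toward apex
        for site, flank_x in ((SITE_LEFT, float(tooth.x_min)), (SITE_RIGHT, float(tooth.x_max))):
            loss_px = loss_mm[site_idx] / spec.mm_per_px
            cej = Point2D(flank_x, float(cej_y))
            abcl = Point2D(flank_x, float(cej_y + apical * loss_px))
            ach_mm = cej.distance_to(abcl) * spec.mm_per_px
            sites.append(
                TruthSite(
                    tooth_id=tooth.tooth_id,
                    site=site,
                    cej=cej,
                    abcl=abcl,
                    ach_mm=ach_mm,
                    severe=classify_severity(ach_mm, spec.severity_threshold_mm, spec.severity_rule),
                )
            )
            _stamp_disk(abcl_grid, abcl.x, abcl.y, radius=2)
            site_idx += 1

    image = rng.normal(30.0, 6.0, size=(h_img, w_img))
    image[teeth_grid] = 180.0 + rng.normal(0.0, 8.0, size=int(teeth_grid.sum()))
    image = np.clip(image, 0, 255).astype(np.uint8)

    truth = PhantomTruth(
        image_id=f"phantom-{spec.seed}",
        mm_per_px=spec.mm_per_px,
        teeth=teeth,
        sites=sites,
        teeth_mask=BinaryMask(teeth_grid, MaskLabel.TEETH),
        abcl_mask=BinaryMask(abcl_grid, MaskLabel.ABCL),
    )
    logger.info("generated %s: %d teeth, %d sites", truth.image_id, len(teeth), len(sites))
    return image, truth


def _stamp_disk(grid: np.ndarray, x: float, y: float, radius: int) -> None:
    h, w = grid.shape
    cx, cy = int(round(x)), int(round(y))
    for dy in range(-radius, radius + 1):
        for dx in range(-radius, radius + 1):
            if dx * dx + dy * dy <= radius * radius:
                px, py = cx + dx, cy + dy
                if 0 <= px < w and 0 <= py < h:
                    grid[py, px] = True


def truth_to_gold_csv(truth: PhantomTruth, path: str | Path) -> None:
    """Write per-site gold-standard rows in the measurement CSV schema."""
    measurements = [
        AchMeasurement(
            image_id=truth.image_id,
            tooth_id=s.tooth_id,
            site=s.site,
            cej=s.cej,
            abcl=s.abcl,
            ach_px=s.cej.distance_to(s.abcl),
            ach_mm=s.ach_mm,
            severe=s.severe,
        )
        for s in truth.sites
    ]
    write_measurements(measurements, path)
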