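"""Shared domain types, file I/O, calibration and configuration.

Coordinate convention used by every module: ``x`` is the 0-based pixel
column (increases rightward), ``y`` the 0-based pixel row (increases
downward, i.e. the maxillary arch sits at *smaller* y in a bitewing).
Landmark coordinates are continuous (sub-pixel positions are legal);
masks are integer rasters.

Calibration (mm per pixel) is a required input with no default: bitewing
sensors differ and silently guessing a pixel spacing would corrupt every
millimeter value downstream.
"""
from __future__ import annotations

import csv
import json
import logging
import math
import sys
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

logger = logging.getLogger("achkit")

__all__ = [
    "LandmarkClass",
    "LandmarkSource",
    "MaskLabel",
    "DegenerateGeometryError",
    "DimensionError",
    "Point2D",
    "Landmark",
    "BinaryMask",
    "Calibration",
    "PipelineConfig",
    "AchMeasurement",
    "SITE_LEFT",
    "SITE_RIGHT",
    "configure_logging",
    "read_landmarks",
    "write_landmarks",
    "read_measurements",
    "write_measurements",
    "read_mask",
    "write_mask",
    "read_image",
    "write_image",
    "px_to_mm",
]

SITE_LEFT = "left"
SITE_RIGHT = "right"


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


class LandmarkClass(str, Enum):
    """Anatomical class of a detected point."""

    ABCL = "ABCL"  # alveolar bone crestal level
    CEJ = "CEJ"  # cemento-enamel junction


class LandmarkSource(str, Enum):
    """Provenance of a landmark detection."""

    NET_A = "net_a"
    NET_B = "net_b"
    FUSED = "fused"
    ORACLE = "oracle"


class MaskLabel(str, Enum):
    TEETH = "teeth"
    ABCL = "abcl"


class DegenerateGeometryError(ValueError):
    """Raised when a fit has too few points or no x-spread."""


class DimensionError(ValueError):
    """Raised when raster shapes that must match do not."""


@dataclass(frozen=True, order=True)
class Point2D:
    """A continuous image-frame point (x = column, y = row)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Landmark:
    """A detected ABCL or CEJ point with detector confidence."""

    point: Point2D
    cls: LandmarkClass
    confidence: float
    source: LandmarkSource

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        if not isinstance(self.cls, LandmarkClass):
            raise ValueError(f"unknown landmark class {self.cls!r}")
        if not isinstance(self.source, LandmarkSource):
            raise ValueError(f"unknown landmark source {self.source!r}")


class BinaryMask:
    """A boolean H x W raster with a semantic label (teeth or ABCL)."""

    def __init__(self, grid: np.ndarray, label: MaskLabel):
        grid = np.asarray(grid)
        if grid.ndim != 2 or grid.shape[0] < 1 or grid.shape[1] < 1:
            raise ValueError(f"mask grid must be 2-D and non-empty, got shape {grid.shape}")
        self.grid = grid.astype(bool)
        self.label = MaskLabel(label)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.label == other.label and self.shape == other.shape and bool(
            np.array_equal(self.grid, other.grid)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BinaryMask(label={self.label.value}, shape={self.shape}, area={int(self.grid.sum())})"


@dataclass(frozen=True)
class Calibration:
    """Image calibration: millimeters per pixel, strictly positive."""

    mm_per_px: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mm_per_px) and self.mm_per_px > 0):
            raise ValueError(f"mm_per_px must be finite and > 0, got {self.mm_per_px}")


_SEVERITY_RULES = ("ge", "gt")


@dataclass
class PipelineConfig:
    """All tunables of the measurement pipeline.

    ``mm_per_px`` is mandatory. ``severity_threshold_mm`` defaults to the
    5 mm bone-loss convention; ``severity_rule`` selects whether a site
    exactly at threshold is severe (``ge``, the default) or not (``gt``).
    ``fusion_radius_px`` doubles as the dedup radius of the landmark
    fusion step and the half-width of the per-tooth side windows used to
    pair CEJ/ABCL landmarks; 30 px is half the 60 px annotation-box scale
    of typical crestal-landmark labels at bitewing resolution.
    """

    mm_per_px: float
    severity_threshold_mm: float = 5.0
    severity_rule: str = "ge"
    fusion_radius_px: float = 30.0
    curve_degree: int = 2
    min_tooth_area_px: int = 200
    crossing_tolerance_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        Calibration(self.mm_per_px)  # validates positivity
        if self.severity_threshold_mm <= 0:
            raise ValueError("severity_threshold_mm must be > 0")
        if self.severity_rule not in _SEVERITY_RULES:
            raise ValueError(f"severity_rule must be one of {_SEVERITY_RULES}")
        if self.fusion_radius_px <= 0:
            raise ValueError("fusion_radius_px must be > 0")
        if self.curve_degree < 1:
            raise ValueError("curve_degree must be >= 1")
        if self.min_tooth_area_px <= 0:
            raise ValueError("min_tooth_area_px must be > 0")
        if self.crossing_tolerance_px <= 0:
            raise ValueError("crossing_tolerance_px must be > 0")

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.mm_per_px)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config from YAML; keyword overrides win over file values.

        An empty file yields the same defaults as programmatic
        construction (mm_per_px must then come from an override).
        """
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        fields = {
            "mm_per_px": self.mm_per_px,
            "severity_threshold_mm": self.severity_threshold_mm,
            "severity_rule": self.severity_rule,
            "fusion_radius_px": self.fusion_radius_px,
            "curve_degree": self.curve_degree,
            "min_tooth_area_px": self.min_tooth_area_px,
            "crossing_tolerance_px": self.crossing_tolerance_px,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(fields))


@dataclass(frozen=True)
class AchMeasurement:
    """One tooth-site CEJ-to-ABCL distance with its severity call.

    ``site`` is "left" or "right" in the image frame, a proxy for
    mesial/distal (the true labels would require tooth numbering).
    """

    image_id: str
    tooth_id: int
    site: str
    cej: Point2D
    abcl: Point2D
    ach_px: float
    ach_mm: float
    severe: bool

    def __post_init__(self) -> None:
        if self.site not in (SITE_LEFT, SITE_RIGHT):
            raise ValueError(f"site must be '{SITE_LEFT}' or '{SITE_RIGHT}', got {self.site!r}")
        if self.ach_px < 0:
            raise ValueError("ach_px must be >= 0")


# ---------------------------------------------------------------------------
# Landmark file I/O

_LANDMARK_FIELDS = ("x", "y", "cls", "confidence", "source")


def _landmark_from_record(rec: dict, where: str) -> Landmark:
    missing = [k for k in _LANDMARK_FIELDS if k not in rec or rec[k] in (None, "")]
    if missing:
        raise ValueError(f"{where}: missing field(s) {missing}")
    try:
        x = float(rec["x"])
        y = float(rec["y"])
        conf = float(rec["confidence"])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{where}: non-numeric coordinate or confidence ({exc})") from exc
    try:
        cls = LandmarkClass(str(rec["cls"]))
    except ValueError:
        raise ValueError(f"{where}: unknown landmark class {rec['cls']!r}") from None
    try:
        source = LandmarkSource(str(rec["source"]))
    except ValueError:
        raise ValueError(f"{where}: unknown landmark source {rec['source']!r}") from None
    try:
        return Landmark(Point2D(x, y), cls, conf, source)
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from exc


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"format must be 'csv' or 'json', got {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValueError(f"cannot infer landmark file format from {path.name!r}; pass format=")


def read_landmarks(path: str | Path, format: str | None = None) -> list[Landmark]:
    """Read landmark detections from a CSV or JSON file.

    CSV needs a header row with columns x, y, cls, confidence, source;
    JSON is a list of objects with the same keys. Order is preserved.
    Malformed records raise ``ValueError`` naming the offending row.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(f"landmark file not found: {path}")
    landmarks: list[Landmark] = []
    if fmt == "csv":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            header_missing = [k for k in _LANDMARK_FIELDS if k not in reader.fieldnames]
            if header_missing:
                raise ValueError(f"{path.name}: header missing column(s) {header_missing}")
            for i, row in enumerate(reader):
                landmarks.append(_landmark_from_record(row, f"{path.name} row {i + 1}"))
    else:
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise ValueError(f"{path.name}: JSON landmark file must contain a list")
        for i, rec in enumerate(records):
            landmarks.append(_landmark_from_record(rec, f"{path.name} record {i}"))
    logger.info("read %d landmarks from %s", len(landmarks), path)
    return landmarks


def write_landmarks(landmarks: Sequence[Landmark], path: str | Path, format: str | None = None) -> None:
    """Write landmarks to CSV or JSON, preserving order (round-trips)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    records = [
        {
            "x": lm.point.x,
            "y": lm.point.y,
            "cls": lm.cls.value,
            "confidence": lm.confidence,
            "source": lm.source.value,
        }
        for lm in landmarks
    ]
    if fmt == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_LANDMARK_FIELDS))
            writer.writeheader()
            writer.writerows(records)
    else:
        path.write_text(json.dumps(records, indent=1))


# ---------------------------------------------------------------------------
# Measurement CSV I/O

_MEASUREMENT_COLUMNS = (
    "image_id",
    "tooth_id",
    "site",
    "cej_x",
    "cej_y",
    "abcl_x",
    "abcl_y",
    "ach_px",
    "ach_mm",
    "severe",
)


def write_measurements(measurements: Sequence[AchMeasurement], path: str | Path) -> None:
    """Write per-site measurements to CSV (floats to 6 decimals)."""
    rows = [
        {
            "image_id": m.image_id,
            "tooth_id": m.tooth_id,
            "site": m.site,
            "cej_x": f"{m.cej.x:.6f}",
            "cej_y": f"{m.cej.y:.6f}",
            "abcl_x": f"{m.abcl.x:.6f}",
            "abcl_y": f"{m.abcl.y:.6f}",
            "ach_px": f"{m.ach_px:.6f}",
            "ach_mm": f"{m.ach_mm:.6f}",
            "severe": "true" if m.severe else "false",
        }
        for m in measurements
    ]
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(_MEASUREMENT_COLUMNS))
        writer.writeheader()
        writer.writerows(rows)
    logger.info("wrote %d measurements to %s", len(rows), path)


def read_measurements(path: str | Path) -> list[AchMeasurement]:
    """Read a measurement CSV written by :func:`write_measurements`."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"image_id": str, "site": str, "severe": str})
    missing = [c for c in _MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    out: list[AchMeasurement] = []
    for i, row in df.iterrows():
        severe = str(row["severe"]).strip().lower()
        if severe not in ("true", "false"):
            raise ValueError(f"{path.name} row {i + 1}: severe must be true/false, got {row['severe']!r}")
        out.append(
            AchMeasurement(
                image_id=str(row["image_id"]),
                tooth_id=int(row["tooth_id"]),
                site=str(row["site"]),
                cej=Point2D(float(row["cej_x"]), float(row["cej_y"])),
                abcl=Point2D(float(row["abcl_x"]), float(row["abcl_y"])),
                ach_px=float(row["ach_px"]),
                ach_mm=float(row["ach_mm"]),
                severe=severe == "true",
            )
        )
    return out


# ---------------------------------------------------------------------------
# Raster I/O

def read_mask(path: str | Path, label: MaskLabel | str) -> BinaryMask:
    """Read a single-channel PNG mask (0 = background, >0 = foreground)."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("L"))
    return BinaryMask(arr > 0, MaskLabel(label))


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit PNG (0 background, 255 foreground)."""
    Image.fromarray(np.where(mask.grid, 255, 0).astype(np.uint8), mode="L").save(path)


def read_image(path: str | Path) -> np.ndarray:
    """Read a radiograph as an 8-bit grayscale array."""
    with Image.open(path) as img:
        return np.asarray(img.convert("L"))


def write_image(image: np.ndarray, path: str | Path) -> None:
    arr = np.asarray(image)
    mode = "RGB" if arr.ndim == 3 else "L"
    Image.fromarray(arr.astype(np.uint8), mode=mode).save(path)


# ---------------------------------------------------------------------------
# Calibration

def px_to_mm(d_px: float, cal: Calibration) -> float:
    """Convert a pixel distance to millimeters (linear scaling)."""
    if d_px < 0:
        raise ValueError(f"distance must be >= 0, got {d_px}")
    return d_px * cal.mm_per_px
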