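"""Fusion of landmark detections from two complementary detectors.

Two object-detection networks with different error profiles each emit a
set of crestal-landmark points for the same radiograph; the pipeline
uses both so each can cover the other's misses. Fusion takes the union
and removes near-duplicates by greedy non-maximum suppression: points
are visited in descending confidence and a point is dropped when a
kept point of the *same class* lies strictly closer than the dedup
radius. Ties are broken deterministically (first detector, then lower
x, then lower y), so fusion is bit-reproducible.

The default radius, 30 px, is half the 60 px box size conventionally
used to annotate crestal landmarks at bitewing resolution.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import Landmark, LandmarkSource, logger

__all__ = ["FusionParams", "fuse_landmarks"]


@dataclass(frozen=True)
class FusionParams:
    """Dedup radius (px) for same-class landmark suppression."""

    radius_px: float = 30.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be > 0")


def fuse_landmarks(
    dets_a: Sequence[Landmark],
    dets_b: Sequence[Landmark],
    params: FusionParams = FusionParams(),
) -> list[Landmark]:
    """Merge two detectors' landmark sets into one deduplicated set.

    Within each class, any pair of points closer than ``radius_px``
    collapses to the higher-confidence member (confidence tie: the
    ``dets_a`` member wins, then lower x, then lower y). Survivors are
    re-labelled ``source=fused`` and returned sorted by (x, y, class),
    so the output order does not depend on input order.
    """
    candidates = [(lm, 0) for lm in dets_a] + [(lm, 1) for lm in dets_b]
    candidates.sort(key=lambda c: (-c[0].confidence, c[1], c[0].point.x, c[0].point.y))

    kept: list[Landmark] = []
    for lm, _channel in candidates:
        suppressed = any(
            k.cls == lm.cls and k.point.distance_to(lm.point) < params.radius_px for k in kept
        )
        if not suppressed:
            kept.append(lm)
    fused = [Landmark(lm.point, lm.cls, lm.confidence, LandmarkSource.FUSED) for lm in kept]
    fused.sort(key=lambda lm: (lm.point.x, lm.point.y, lm.cls.value))
    logger.info(
        "fused %d + %d detections into %d landmarks (radius %.1f px)",
        len(dets_a), len(dets_b), len(fused), params.radius_px,
    )
    return fused
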