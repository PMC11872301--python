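"""Oracle detector: phantom ground truth -> noisy detector outputs.

The measurement pipeline is detector-agnostic: anything that provides
two landmark sets and three masks in the shared coordinate frame can
feed :func:`achkit.geometry.process_radiograph`. The oracle is the test
implementation of that contract — it converts phantom truth into the
outputs a pair of imperfect detection networks would produce:

* each true CEJ/ABCL point is independently dropped with
  ``dropout_rate``, otherwise jittered by N(0, sigma^2) per axis;
* Poisson(``false_positive_rate``) spurious landmarks land uniformly
  over the image with low confidence;
* the two landmark channels are drawn independently (distinct
  sub-seeds), the worst case for the fusion dedup logic;
* masks come from the truth geometry, with optional erosion of the
  teeth masks (the ABCL mask is small point-marks that erosion would
  annihilate, so it passes through unchanged).

True detections carry confidence 1.0, so the zero-noise limit emits the
truth points exactly and identically on both channels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    BinaryMask,
    Landmark,
    LandmarkClass,
    LandmarkSource,
    MaskLabel,
    Point2D,
)
from .phantom import PhantomTruth

__all__ = ["NoiseParams", "DetectionBundle", "oracle_detect"]

_FP_CONFIDENCE = (0.1, 0.6)


@dataclass(frozen=True)
class NoiseParams:
    """Detector imperfection model for the oracle."""

    jitter_sigma_px: float = 0.0
    dropout_rate: float = 0.0
    false_positive_rate: float = 0.0
    mask_erosion_px: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sigma_px < 0:
            raise ValueError("jitter_sigma_px must be >= 0")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be >= 0")
        if self.mask_erosion_px < 0:
            raise ValueError("mask_erosion_px must be >= 0")


@dataclass
class DetectionBundle:
    """One radiograph's worth of detector outputs."""

    landmarks_a: list[Landmark]
    landmarks_b: list[Landmark]
    teeth_mask_1: BinaryMask
    teeth_mask_2: BinaryMask
    abcl_mask: BinaryMask


def _detect_channel(
    truth: PhantomTruth,
    noise: NoiseParams,
    rng: np.random.Generator,
    source: LandmarkSource,
) -> list[Landmark]:
    h, w = truth.teeth_mask.shape
    out: list[Landmark] = []
    for site in truth.sites:
        for cls, pt in ((LandmarkClass.CEJ, site.cej), (LandmarkClass.ABCL, site.abcl)):
            # fixed draw count per landmark keeps the stream aligned
            # across dropout decisions
            u = rng.uniform()
            jx, jy = rng.normal(0.0, noise.jitter_sigma_px or 0.0, size=2)
            if u < noise.dropout_rate:
                continue
            x = float(np.clip(pt.x + jx, 0.0, w - 1.0))
            y = float(np.clip(pt.y + jy, 0.0, h - 1.0))
            out.append(Landmark(Point2D(x, y), cls, 1.0, source))
    for _ in range(int(rng.poisson(noise.false_positive_rate))):
        x = float(rng.uniform(0.0, w - 1.0))
        y = float(rng.uniform(0.0, h - 1.0))
        cls = LandmarkClass.CEJ if rng.uniform() < 0.5 else LandmarkClass.ABCL
        conf = float(rng.uniform(*_FP_CONFIDENCE))
        out.append(Landmark(Point2D(x, y), cls, conf, source))
    return out


def _eroded_teeth_mask(truth: PhantomTruth, erosion_px: int) -> BinaryMask:
    grid = truth.teeth_mask.grid
    if erosion_px > 0:
        grid = ndimage.binary_erosion(grid, iterations=erosion_px)
    return BinaryMask(grid.copy(), MaskLabel.TEETH)


def oracle_detect(truth: PhantomTruth, noise: NoiseParams) -> DetectionBundle:
    """Produce noisy dual-detector outputs for a phantom scene.

    Deterministic given ``noise.seed``; the two channels use distinct
    sub-seeds so their dropout, jitter and spurious landmarks are
    independent.
    """
    seq_a, seq_b = np.random.SeedSequence(noise.seed).spawn(2)
    landmarks_a = _detect_channel(truth, noise, np.random.default_rng(seq_a), LandmarkSource.NET_A)
    landmarks_b = _detect_channel(truth, noise, np.random.default_rng(seq_b), LandmarkSource.NET_B)
    return DetectionBundle(
        landmarks_a=landmarks_a,
        landmarks_b=landmarks_b,
        teeth_mask_1=_eroded_teeth_mask(truth, noise.mask_erosion_px),
        teeth_mask_2=_eroded_teeth_mask(truth, noise.mask_erosion_px),
        abcl_mask=BinaryMask(truth.abcl_mask.grid.copy(), MaskLabel.ABCL),
    )
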