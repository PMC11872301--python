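"""Agreement and accuracy scoring for severity calls and ACH ratings.

Two statistics families live here. Classification scoring compares
per-site severe/non-severe calls against a gold standard: pooled and
per-image accuracy, plus sensitivity on the severe class and
specificity (clinically, a missed severe site is the costly error).
The intraclass correlation coefficient (ICC) quantifies agreement of
two repeated continuous ACH ratings of the same sites — e.g. a rater
re-reading the same radiographs, or the pipeline re-run under an
independent noise realization.

The ICC form is the two-way, absolute-agreement, single-measurement
coefficient ICC(A,1) of McGraw & Wong: with n subjects rated k times,

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

where MSR, MSC, MSE are the subject, rater-occasion and residual mean
squares of the two-way layout. Absolute agreement is the right default
for repeated measurements by one rater because a constant bias between
occasions should count against reliability; the consistency form
ICC(C,1), which ignores such bias, is selectable.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .core import AchMeasurement, logger

__all__ = [
    "SeverityRecord",
    "EvaluationReport",
    "evaluate_classification",
    "match_records",
    "intraclass_correlation",
    "display_pct",
    "proportion_pct",
]


@dataclass(frozen=True)
class SeverityRecord:
    """Gold vs predicted severity for one tooth site."""

    image_id: str
    tooth_id: int
    site: str
    gold_severe: bool
    pred_severe: bool

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.image_id, self.tooth_id, self.site)


@dataclass
class EvaluationReport:
    """Pooled and per-image classification scores (percent scale)."""

    n_sites: int
    accuracy_pct: float
    sensitivity_severe_pct: float | None
    specificity_pct: float | None
    per_image: dict[str, tuple[int, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_severe_pct": self.sensitivity_severe_pct,
            "specificity_pct": self.specificity_pct,
            "per_image": {
                img: {"n": n, "accuracy_pct": acc} for img, (n, acc) in self.per_image.items()
            },
        }


def evaluate_classification(records: Sequence[SeverityRecord]) -> EvaluationReport:
    """Score severity calls against gold standard, pooled and per image.

    Sensitivity (severe class) and specificity are reported as ``None``
    when the gold standard contains no site of the relevant class.
    Raises on empty input and on duplicate (image, tooth, site) keys.
    """
    if not records:
        raise ValueError("evaluate_classification needs at least one record")
    keys = [r.key for r in records]
    if len(set(keys)) != len(keys):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ValueError(f"duplicate (image_id, tooth_id, site) keys: {dupes}")

    gold = np.array([r.gold_severe for r in records], dtype=bool)
    pred = np.array([r.pred_severe for r in records], dtype=bool)
    concordant = gold == pred

    n = len(records)
    accuracy = 100.0 * concordant.sum() / n
    n_severe = int(gold.sum())
    n_non_severe = n - n_severe
    sensitivity = 100.0 * (pred & gold).sum() / n_severe if n_severe else None
    specificity = 100.0 * (~pred & ~gold).sum() / n_non_severe if n_non_severe else None

    per_image: dict[str, tuple[int, float]] = {}
    for image_id in sorted({r.image_id for r in records}):
        sub = [c for r, c in zip(records, concordant) if r.image_id == image_id]
        per_image[image_id] = (len(sub), 100.0 * sum(sub) / len(sub))

    logger.info("evaluated %d sites: accuracy %.1f%%", n, accuracy)
    return EvaluationReport(n, accuracy, sensitivity, specificity, per_image)


def match_records(
    predictions: Sequence[AchMeasurement], gold: Sequence[AchMeasurement]
) -> list[SeverityRecord]:
    """Inner-join predictions with gold on (image_id, tooth_id, site)."""
    pred_by_key = {(m.image_id, m.tooth_id, m.site): m for m in predictions}
    if len(pred_by_key) != len(predictions):
        raise ValueError("duplicate keys in predictions")
    out: list[SeverityRecord] = []
    for g in gold:
        p = pred_by_key.get((g.image_id, g.tooth_id, g.site))
        if p is not None:
            out.append(
                SeverityRecord(g.image_id, g.tooth_id, g.site, g.severe, p.severe)
            )
    return out


def intraclass_correlation(
    ratings_1: Sequence[float], ratings_2: Sequence[float], form: str = "a1"
) -> float:
    """ICC of two repeated ratings of the same n subjects.

    ``form="a1"`` gives ICC(A,1) (absolute agreement, the default);
    ``form="c1"`` gives ICC(C,1) (consistency, bias-insensitive).
    Requires n >= 3 finite pairs and non-zero total variance.
    """
    if form not in ("a1", "c1"):
        raise ValueError(f"form must be 'a1' or 'c1', got {form!r}")
    r1 = np.asarray(ratings_1, dtype=float)
    r2 = np.asarray(ratings_2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("ratings must be two equal-length 1-D vectors")
    n = len(r1)
    if n < 3:
        raise ValueError(f"ICC needs at least 3 subjects, got {n}")
    if not (np.all(np.isfinite(r1)) and np.all(np.isfinite(r2))):
        raise ValueError("ratings must be finite")

    table = np.column_stack((r1, r2))  # n subjects x k occasions
    k = 2
    grand = table.mean()
    if np.allclose(table, grand):
        raise ValueError("zero total variance: ICC undefined")
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if form == "c1":
        return float((msr - mse) / (msr + (k - 1) * mse))
    return float((msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse)))


def display_pct(value: float) -> int:
    """Round a percentage half-up to an integer for display."""
    return int(Decimal(repr(float(value))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def proportion_pct(part: int, whole: int) -> float:
    """part / whole on the percent scale (e.g. survey completion)."""
    if whole <= 0 or part < 0 or part > whole:
        raise ValueError(f"need 0 <= part <= whole with whole > 0, got {part}/{whole}")
    return 100.0 * part / whole
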