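"""Navigation-line quality measures against ground truth.

Three measures per fitted line, summarised per row position:

* angle deviation (degrees): the acute angle between line directions,
  ``arccos(|d1 . d2|)`` with d = (-b, a) — symmetric and sign-invariant;
* horizontal distance deviation (pixels): mean over sampled heights of
  ``|x_pred(y) - x_truth(y)|`` where ``x(y) = -(b*y + c)/a``;
* anchor point fitting accuracy: the fraction of anchors within a
  perpendicular-distance tolerance of the fitted line (default 5 px, the
  RANSAC inlier threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .navline import AnchorPoint, LineModel


@dataclass(frozen=True)
class LineComparison:
    angle_deviation: float            # degrees, in [0, 90]
    horizontal_deviation: float       # pixels, >= 0
    anchor_fit_accuracy: float        # fraction in [0, 1]
    position: str                     # "left" | "middle" | "right"


@dataclass(frozen=True)
class MeasureSummary:
    mean: float
    std: float
    n: int
    flagged: bool = False  # fewer than 2 entries: std reported as 0


@dataclass(frozen=True)
class PositionSummary:
    """Per-position mean/std of each measure over a scene set."""

    angle: dict[str, MeasureSummary]
    horizontal: dict[str, MeasureSummary]
    anchor_accuracy: dict[str, MeasureSummary]


def _direction(line: LineModel) -> np.ndarray:
    return np.array([-line.b, line.a], dtype=float)


def angle_deviation(pred: LineModel, truth: LineModel) -> float:
    """Acute angle between the two line directions, in degrees."""
    d1, d2 = _direction(pred), _direction(truth)
    cosang = abs(float(d1 @ d2)) / (np.linalg.norm(d1) * np.linalg.norm(d2))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def horizontal_deviation(pred: LineModel, truth: LineModel,
                         heights: Sequence[float]) -> float:
    """Mean |x_pred(y) - x_truth(y)| over the sampled heights."""
    for name, line in (("pred", pred), ("truth", truth)):
        if abs(line.a) < 1e-12:
            raise ValueError(
                f"{name} line (a={line.a}, b={line.b}, c={line.c}) is "
                "horizontal; x(y) is undefined")
    y = np.asarray(heights, dtype=float)
    return float(np.mean(np.abs(pred.x_at(y) - truth.x_at(y))))


def anchor_fit_accuracy(anchors: Sequence[AnchorPoint], line: LineModel,
                        tol: float = 5.0) -> float:
    """Fraction of anchors with perpendicular distance <= tol."""
    if len(anchors) == 0:
        raise ValueError("anchor list must be non-empty")
    xs = np.array([a.x for a in anchors])
    ys = np.array([a.y for a in anchors])
    return float(np.mean(line.distance(xs, ys) <= tol))


def compare(pred: LineModel, truth: LineModel, anchors: Sequence[AnchorPoint],
            heights: Sequence[float], position: str,
            tol: float = 5.0) -> LineComparison:
    return LineComparison(
        angle_deviation=angle_deviation(pred, truth),
        horizontal_deviation=horizontal_deviation(pred, truth, heights),
        anchor_fit_accuracy=anchor_fit_accuracy(anchors, pred, tol=tol),
        position=position,
    )


def _summarise(values: list[float]) -> MeasureSummary:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return MeasureSummary(mean=float(arr.mean()), std=0.0, n=arr.size,
                              flagged=True)
    return MeasureSummary(mean=float(arr.mean()), std=float(arr.std(ddof=1)),
                          n=arr.size)


def summarize(comparisons: Iterable[LineComparison]) -> PositionSummary:
    """Sample mean and (n-1)-denominator std per measure per position."""
    comparisons = list(comparisons)
    if not comparisons:
        raise ValueError("no comparisons to summarise")
    by_pos: dict[str, list[LineComparison]] = {}
    for c in comparisons:
        by_pos.setdefault(c.position, []).append(c)
    angle, horiz, acc = {}, {}, {}
    for pos, items in by_pos.items():
        angle[pos] = _summarise([c.angle_deviation for c in items])
        horiz[pos] = _summarise([c.horizontal_deviation for c in items])
        acc[pos] = _summarise([c.anchor_fit_accuracy for c in items])
    return PositionSummary(angle=angle, horizontal=horiz, anchor_accuracy=acc)
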