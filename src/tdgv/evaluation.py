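"""Segment-level scoring of detector output, plus self-report utilities.

Scoring follows the study design rather than per-sample agreement: an
experimental segment counts as *marked* if the detector fired at least once
inside it — i.e. any detection event overlaps the half-open segment interval
[start, end). Marked task segments are true positives, marked no-task
segments false positives, and so on; accuracy, sensitivity and specificity
are computed from those segment counts as percentages.

Also here: the post-drive distraction-level score (difference of 1–7 focus
ratings with and without the secondary task) and the median-split helper used
to stratify participants by distraction level or baseline quality.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .detector import DetectionEvent
from .errors import DataError, UsageError
from .io import SegmentAnnotation

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "FocusRating",
    "POSITIVE_CONDITIONS",
    "event_overlaps_segment",
    "score_segments",
    "performance",
    "distraction_level",
    "median_split",
]

#: Conditions counted as "distraction present" by default.
POSITIVE_CONDITIONS = frozenset({"cognitive_task", "visual_task"})


@dataclass(frozen=True)
class ConfusionCounts:
    """Segment-level confusion counts (segments, not samples)."""

    true_pos: int = 0
    true_neg: int = 0
    false_pos: int = 0
    false_neg: int = 0

    def __post_init__(self) -> None:
        for name in ("true_pos", "true_neg", "false_pos", "false_neg"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.true_pos + self.true_neg + self.false_pos + self.false_neg

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.true_pos + other.true_pos,
            self.true_neg + other.true_neg,
            self.false_pos + other.false_pos,
            self.false_neg + other.false_neg,
        )


@dataclass(frozen=True)
class PerformanceReport:
    """Accuracy / sensitivity / specificity in percent.

    A metric whose denominator is zero (no positive or no negative segments
    scored) is reported as None rather than invented.
    """

    accuracy_pct: Optional[float]
    sensitivity_pct: Optional[float]
    specificity_pct: Optional[float]


@dataclass(frozen=True)
class FocusRating:
    """Post-drive self-reported focus on the 1–7 scale, with and without task."""

    focus_without_task: int
    focus_with_task: int

    def __post_init__(self) -> None:
        for name in ("focus_without_task", "focus_with_task"):
            v = getattr(self, name)
            if int(v) != v or not 1 <= v <= 7:
                raise DataError(f"{name} must be an integer in [1, 7], got {v!r}")


def event_overlaps_segment(event: DetectionEvent, segment: SegmentAnnotation) -> bool:
    """True if the (possibly zero-length) event touches [start, end).

    An event whose onset falls exactly at a segment's end belongs to the
    following segment only; an event is allowed to touch several segments.
    """
    return event.start_s < segment.end_s and event.end_s >= segment.start_s


def score_segments(
    events: Sequence[DetectionEvent],
    segments: Sequence[SegmentAnnotation],
    positive_conditions: Iterable[str] = POSITIVE_CONDITIONS,
    exclude_baseline: bool = True,
) -> ConfusionCounts:
    """Segment-level confusion counts under the marked-at-least-once rule.

    Segments with condition "baseline" are excluded by default: the threshold
    was calibrated on them, so scoring them would be circular.

    Raises
    ------
    UsageError
        If no segments remain to score.
    """
    positive = frozenset(positive_conditions)
    scored = [s for s in segments if not (exclude_baseline and s.condition == "baseline")]
    if not scored:
        raise UsageError("no segments to score")
    tp = tn = fp = fn = 0
    for seg in scored:
        marked = any(event_overlaps_segment(e, seg) for e in events)
        is_pos = seg.condition in positive
        if marked and is_pos:
            tp += 1
        elif marked:
            fp += 1
        elif is_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def _pct(num: int, den: int) -> Optional[float]:
    return None if den == 0 else 100.0 * num / den


def performance(counts: ConfusionCounts) -> PerformanceReport:
    """Accuracy, sensitivity and specificity in percent.

    Acc = (TP+TN)/(TP+TN+FP+FN) * 100, Sens = TP/(TP+FN) * 100,
    Spec = TN/(TN+FP) * 100.
    """
    if counts.total == 0:
        raise UsageError("cannot compute performance from zero scored segments")
    return PerformanceReport(
        accuracy_pct=_pct(counts.true_pos + counts.true_neg, counts.total),
        sensitivity_pct=_pct(counts.true_pos, counts.true_pos + counts.false_neg),
        specificity_pct=_pct(counts.true_neg, counts.true_neg + counts.false_pos),
    )


def distraction_level(rating: FocusRating) -> int:
    """Self-reported distraction = focus without task − focus with task.

    The expected range is 0 (not distracted) to 6 (very distracted); a
    negative value (more focused *with* the task) is returned as-is with a
    warning, since it usually flags a swapped or implausible rating.
    """
    level = rating.focus_without_task - rating.focus_with_task
    if level < 0:
        warnings.warn(
            f"negative distraction level ({level}): participant reported more focus "
            "with the secondary task than without",
            stacklevel=2,
        )
    return level


def median_split(values: Sequence[float]) -> tuple[list[int], list[int], float]:
    """Split indices at the sample median (midpoint-interpolated).

    Values strictly below the median go to the low group, strictly above to
    the high group; ties at the median are assigned to the low group. Returns
    ``(low_indices, high_indices, median)``.
    """
    if len(values) < 2:
        raise UsageError("median_split needs at least 2 values")
    arr = np.asarray(values, dtype=float)
    med = float(np.median(arr))
    low = [i for i, v in enumerate(arr) if v <= med]
    high = [i for i, v in enumerate(arr) if v > med]
    return low, high, med
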