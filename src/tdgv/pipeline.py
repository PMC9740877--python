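"""End-to-end synthetic experiments: simulate → calibrate → detect → score.

One drive-level helper plus a seed campaign. The convention throughout: the
first no-task segment of a drive is the calibration baseline, is excluded
from scoring, and the remaining segments are scored with the
marked-at-least-once rule.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .calibration import baseline_quality, calibrate_threshold
from .detector import DetectionEvent, DetectorConfig, TdgvTrace, compute_trace, events_from_trace
from .errors import UsageError
from .evaluation import ConfusionCounts, PerformanceReport, performance, score_segments
from .io import SegmentAnnotation
from .simulate import make_study2_default, simulate_drive

__all__ = ["DriveOutcome", "evaluate_drive", "evaluate_synthetic_drive", "detection_campaign"]


@dataclass(frozen=True)
class DriveOutcome:
    """Everything measured on one drive."""

    threshold_T: float
    quality_z: float
    counts: ConfusionCounts
    report: PerformanceReport
    events: tuple[DetectionEvent, ...]
    trace: Optional[TdgvTrace] = None


def evaluate_drive(
    stream,
    segments: Sequence[SegmentAnnotation],
    config: Optional[DetectorConfig] = None,
    keep_trace: bool = False,
) -> DriveOutcome:
    """Calibrate on the first no-task (or explicit baseline) segment, detect,
    and score the remaining segments.

    The trace is computed once; detection flags are re-derived from the
    calibrated threshold (the accumulator itself does not depend on T).
    """
    config = config or DetectorConfig()
    baseline = next((s for s in segments if s.condition == "baseline"), None)
    if baseline is None:
        baseline = next((s for s in segments if s.condition == "no_task"), None)
    if baseline is None:
        raise UsageError("no baseline or no_task segment to calibrate on")
    trace = compute_trace(stream, config)
    threshold = calibrate_threshold(trace, baseline)
    quality = baseline_quality(trace, baseline)
    flagged = trace.with_threshold(threshold)
    events = events_from_trace(flagged)
    scored_segments = [s for s in segments if s is not baseline]
    counts = score_segments(events, scored_segments)
    return DriveOutcome(
        threshold_T=threshold,
        quality_z=quality,
        counts=counts,
        report=performance(counts),
        events=tuple(events),
        trace=flagged if keep_trace else None,
    )


def evaluate_synthetic_drive(
    multiplier: float,
    seed: int,
    config: Optional[DetectorConfig] = None,
    rate_hz: float = 60.0,
    baseline_distracted: bool = False,
    keep_trace: bool = False,
) -> DriveOutcome:
    """Simulate one six-segment drive and evaluate it end to end."""
    schedule, models = make_study2_default(
        distraction_sd_multiplier=multiplier,
        seed=seed,
        rate_hz=rate_hz,
        baseline_distracted=baseline_distracted,
    )
    stream, segments = simulate_drive(schedule, models)
    return evaluate_drive(stream, segments, config=config, keep_trace=keep_trace)


def detection_campaign(
    multiplier: float,
    seeds: Sequence[int],
    config: Optional[DetectorConfig] = None,
    rate_hz: float = 60.0,
    baseline_distracted: bool = False,
) -> pd.DataFrame:
    """Per-seed drive metrics as a tidy DataFrame (one row per drive)."""
    rows = []
    for seed in seeds:
        out = evaluate_synthetic_drive(
            multiplier, seed, config=config, rate_hz=rate_hz,
            baseline_distracted=baseline_distracted,
        )
        rows.append(
            {
                "seed": seed,
                "multiplier": multiplier,
                "threshold_T": out.threshold_T,
                "quality_z": out.quality_z,
                "true_pos": out.counts.true_pos,
                "true_neg": out.counts.true_neg,
                "false_pos": out.counts.false_pos,
                "false_neg": out.counts.false_neg,
                "accuracy_pct": out.report.accuracy_pct,
                "sensitivity_pct": out.report.sensitivity_pct,
                "specificity_pct": out.report.specificity_pct,
            }
        )
    return pd.DataFrame(rows)
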