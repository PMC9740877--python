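"""Threshold calibration and baseline-quality diagnostics.

The detector fires when the accumulated TDGV change exceeds a threshold T
that is personal to a drive: T is the maximum accumulated change observed
during a designated undistracted *baseline* segment (by convention the first
driving segment without a secondary task). A perfectly regular baseline gives
T = 0, so any later variance increase triggers.

Because performance hinges on that baseline actually being calm, a
baseline-quality diagnostic is provided: the baseline maximum is z-scored
against the whole drive's accumulated-change series. High z means the
baseline already contained large variance changes — a distracted or
irregular baseline — and predicts degraded detection.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detector import TdgvTrace
from .errors import CalibrationError, ConfigError
from .io import SegmentAnnotation

__all__ = ["BaselineResult", "calibrate_threshold", "baseline_quality", "calibrate"]


@dataclass(frozen=True)
class BaselineResult:
    """Threshold and quality diagnostic derived from one baseline segment."""

    threshold_T: float
    quality_z: float
    baseline_span: SegmentAnnotation


def _baseline_mask(trace: TdgvTrace, baseline: SegmentAnnotation) -> np.ndarray:
    mask = (trace.t >= baseline.start_s) & (trace.t < baseline.end_s)
    if not mask.any():
        raise CalibrationError(
            f"baseline [{baseline.start_s}, {baseline.end_s}) contains no trace samples"
        )
    return mask


def calibrate_threshold(
    trace: TdgvTrace, baseline: SegmentAnnotation, statistic: str = "cum"
) -> float:
    """Detection threshold = maximum positive TDGV change over the baseline.

    ``statistic="cum"`` (default) takes the maximum of the accumulated change
    — the quantity the running detector compares against T, keeping threshold
    and statistic on one scale. ``statistic="delta"`` uses the raw per-sample
    derivative instead. Either way the result is floored at 0, so an
    identically flat baseline yields T = 0.
    """
    if statistic not in ("cum", "delta"):
        raise ConfigError(f"threshold statistic must be 'cum' or 'delta', got {statistic!r}")
    mask = _baseline_mask(trace, baseline)
    series = trace.cum if statistic == "cum" else trace.delta
    return max(0.0, float(np.max(series[mask])))


def baseline_quality(trace: TdgvTrace, baseline: SegmentAnnotation) -> float:
    """z-score of the baseline maximum against the whole drive.

    z = (max accumulated change in baseline − whole-drive mean) /
    whole-drive population SD of the accumulated change. Higher z = lower
    baseline quality (the baseline already looked like distraction).

    Raises
    ------
    CalibrationError
        If the whole-drive accumulator is constant (zero SD): the quality of
        a degenerate drive is undefined.
    """
    mask = _baseline_mask(trace, baseline)
    whole = np.asarray(trace.cum, dtype=float)
    sd = float(np.std(whole))  # population SD
    if sd == 0.0 or not math.isfinite(sd):
        raise CalibrationError("whole-drive accumulator has zero spread; quality undefined")
    return float((np.max(whole[mask]) - np.mean(whole)) / sd)


def calibrate(trace: TdgvTrace, baseline: SegmentAnnotation, statistic: str = "cum") -> BaselineResult:
    """Convenience wrapper: threshold plus quality for one baseline segment."""
    return BaselineResult(
        threshold_T=calibrate_threshold(trace, baseline, statistic=statistic),
        quality_z=baseline_quality(trace, baseline),
        baseline_span=baseline,
    )
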