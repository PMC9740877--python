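"""Synthetic AOI-labeled gaze drives with ground truth.

Dashboard glances are generated as an alternating renewal process: an
off-dashboard gap followed by an on-dashboard dwell, both drawn from
truncated normal distributions (a positive floor keeps intervals physical).
Attentive driving means low gap variance; "distraction" is modeled purely as
gap-variance inflation — the driver still checks the dashboard about as
often, but irregularly. That is exactly the signature the TDGV change
statistic is built to pick up, so these drives exercise the whole pipeline
(calibration, detection, scoring) without eye-tracker hardware.

The continuous glance timeline is discretized to samples at a fixed rate with
labels in {"dashboard", "none"}; alternating one-minute task/no-task segments
reproduce the layout of a short experimental drive.

All model parameters here are synthetic design choices, not measured values;
see docs/methods.md for what they do and do not emulate.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import ConfigError
from .io import GazeStream, SegmentAnnotation

__all__ = ["GlanceModel", "SegmentSpec", "DriveSchedule", "simulate_drive", "make_study2_default"]


@dataclass(frozen=True)
class GlanceModel:
    """Renewal-process parameters for one attention condition.

    Gaps (off-dashboard intervals) and dwells (on-dashboard glance durations)
    are truncated normal, lower-truncated at ``floor_s`` (0.2 s default — a
    shorter interval is not physiologically meaningful at ordinary sampling
    rates). ``gap_sd_s = 0`` degenerates to perfectly periodic glances.
    """

    gap_mean_s: float = 4.0
    gap_sd_s: float = 0.4
    glance_dur_mean_s: float = 0.6
    glance_dur_sd_s: float = 0.1
    floor_s: float = 0.2
    distribution: str = "truncnorm"

    def __post_init__(self) -> None:
        if not (self.gap_mean_s > 0 and self.glance_dur_mean_s > 0):
            raise ConfigError("interval means must be positive")
        if self.gap_sd_s < 0 or self.glance_dur_sd_s < 0:
            raise ConfigError("interval SDs must be non-negative")
        if not self.floor_s > 0:
            raise ConfigError("interval floor must be positive")
        if self.distribution != "truncnorm":
            raise ConfigError(f"unsupported distribution {self.distribution!r}")


@dataclass(frozen=True)
class SegmentSpec:
    """One scheduled segment: duration, condition label, glance-model key.

    The model key is separate from the condition so that ground-truth labels
    and generating behavior can be decoupled — e.g. to inject distracted gaze
    behavior into the calibration segment while it is still annotated (and
    used) as the undistracted baseline.
    """

    duration_s: float
    condition: str
    model: str

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ConfigError("segment duration must be positive")


@dataclass(frozen=True)
class DriveSchedule:
    """Ordered segments plus output sampling rate and master seed."""

    segments: tuple[SegmentSpec, ...]
    rate_hz: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ConfigError("schedule needs at least one segment")
        if not self.rate_hz > 0:
            raise ConfigError(f"rate_hz must be positive, got {self.rate_hz}")

    @property
    def total_duration_s(self) -> float:
        return float(sum(s.duration_s for s in self.segments))


def _draw_interval(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    if sd == 0.0:
        return max(mean, floor)
    a = (floor - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def simulate_drive(
    schedule: DriveSchedule, models: Mapping[str, GlanceModel]
) -> tuple[GazeStream, list[SegmentAnnotation]]:
    """Generate one drive: a sampled gaze stream plus exact annotations.

    Each segment consumes draws from its own RNG stream (spawned from the
    master seed by segment index), so two schedules sharing a prefix of
    segments share the gap realizations of that prefix. Within a segment the
    process alternates gap → dwell; a draw started inside a segment is never
    truncated at the segment boundary, it simply runs into the next segment.

    Identical (schedule, models) input reproduces the output exactly.
    """
    for seg in schedule.segments:
        if seg.model not in models:
            raise ConfigError(f"no glance model named {seg.model!r} for condition {seg.condition!r}")

    boundaries = np.cumsum([0.0] + [s.duration_s for s in schedule.segments])
    total = float(boundaries[-1])

    glance_on: list[float] = []
    glance_off: list[float] = []
    cursor = 0.0
    for k, seg in enumerate(schedule.segments):
        rng = np.random.default_rng(np.random.SeedSequence(schedule.seed, spawn_key=(k,)))
        model = models[seg.model]
        seg_end = float(boundaries[k + 1])
        while cursor < seg_end:
            cursor += _draw_interval(rng, model.gap_mean_s, model.gap_sd_s, model.floor_s)
            if cursor >= total:
                break
            dwell = _draw_interval(
                rng, model.glance_dur_mean_s, model.glance_dur_sd_s, model.floor_s
            )
            glance_on.append(cursor)
            glance_off.append(cursor + dwell)
            cursor += dwell

    n_samples = int(round(total * schedule.rate_hz))
    t = np.arange(n_samples, dtype=float) / schedule.rate_hz
    # sample k is on-dashboard iff k/rate falls inside a glance interval
    # [on, off); boundaries are resolved on the sample-index grid with a tiny
    # tolerance so grid-aligned glance times do not flip on float noise
    inside = np.zeros(n_samples, dtype=bool)
    eps = 1e-9
    for on, off in zip(glance_on, glance_off):
        i0 = max(0, int(np.ceil(on * schedule.rate_hz - eps)))
        i1 = min(n_samples, int(np.ceil(off * schedule.rate_hz - eps)))
        inside[i0:i1] = True
    aoi = np.where(inside, "dashboard", "none").astype(object)

    stream = GazeStream(
        t=t, aoi=aoi, valid=np.ones(n_samples, dtype=bool), rate_hz=schedule.rate_hz
    )
    annotations = [
        SegmentAnnotation(float(boundaries[k]), float(boundaries[k + 1]), seg.condition)
        for k, seg in enumerate(schedule.segments)
    ]
    return stream, annotations


def make_study2_default(
    distraction_sd_multiplier: float = 6.0,
    seed: int = 0,
    rate_hz: float = 60.0,
    segment_duration_s: float = 60.0,
    baseline_distracted: bool = False,
) -> tuple[DriveSchedule, dict[str, GlanceModel]]:
    """Six alternating one-minute segments, no-task first, at 60 Hz.

    The attentive model checks the dashboard every 4.0 ± 0.4 s with
    0.6 ± 0.1 s dwells; the distracted model inflates the gap SD by
    ``distraction_sd_multiplier`` (1 = null configuration: conditions are
    indistinguishable and detection performance is at chance).

    ``baseline_distracted=True`` makes the first (calibration) segment use
    the distracted glance model while keeping its no-task annotation — a
    corrupted-baseline drive for studying how baseline quality limits
    detection.
    """
    if not np.isfinite(distraction_sd_multiplier) or distraction_sd_multiplier < 1:
        raise ConfigError("distraction_sd_multiplier must be finite and >= 1")
    attentive = GlanceModel()
    distracted = replace(attentive, gap_sd_s=attentive.gap_sd_s * float(distraction_sd_multiplier))
    models = {"attentive": attentive, "distracted": distracted}

    segs = []
    for k in range(6):
        condition = "no_task" if k % 2 == 0 else "cognitive_task"
        model = "attentive" if k % 2 == 0 else "distracted"
        if k == 0 and baseline_distracted:
            model = "distracted"
        segs.append(SegmentSpec(segment_duration_s, condition, model))
    return DriveSchedule(segments=tuple(segs), rate_hz=rate_hz, seed=seed), models
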