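"""Streaming detector for cognitive distraction from dashboard-glance regularity.

The decision statistic is the *temporal dashboard gaze variance* (TDGV): the
population standard deviation of the last ``n`` gaps between successive
glances at a target AOI (the dashboard), tracked sample by sample. Attentive
driving produces regular dashboard checks, so the gap variance is low and
stable; under cognitive load the temporal control of this checking behavior
degrades and the variance inflates.

Per sample the detector maintains:

* a ring buffer of the last ``n`` inter-glance gaps, where the newest slot is
  *live* — it keeps growing with every off-target sample until the next
  glance freezes it;
* sigma(t), the population SD of the buffer contents;
* sigma_smooth(t), the mean of sigma over the trailing ``smooth_seconds``
  (m = round(smooth_seconds * rate_hz) samples) — smoothing suppresses the
  sample-level jitter that otherwise fragments detections;
* delta(t) = sigma_smooth(t) - sigma_smooth(t-1), a one-sample derivative;
* cum(t), delta accumulated while non-negative and reset to zero on the first
  negative derivative, so only variance *increases* are scored (a one-sided
  CUSUM-style accumulator);
* the flag cum(t) > T against a baseline-calibrated threshold T.

Window means and SDs use ``math.fsum`` (exactly rounded summation), so the
trace is reproducible bit-for-bit across the streaming path and the batch
re-computation in :mod:`tdgv.oracle`.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, DataError, UsageError
from .io import NO_AOI, GazeStream

__all__ = [
    "DetectorConfig",
    "GapWindow",
    "TdgvTrace",
    "DetectionEvent",
    "window_std",
    "smooth",
    "accumulate",
    "TdgvDetector",
    "effective_on_target",
    "compute_trace",
    "run_detector",
    "events_from_trace",
    "smoothing_samples",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of the TDGV change detector.

    Parameters
    ----------
    n : number of inter-glance gaps kept in the ring buffer (default 10).
    smooth_seconds : trailing horizon for the sigma moving average
        (default 2.0 s).
    threshold_T : detection threshold on the accumulated change statistic;
        ``None`` means *uncalibrated* — a trace can still be computed (for
        calibration) but detection is refused.
    target_aoi : AOI label whose glances are tracked (default "dashboard").
    invalid_policy : what an invalid-flagged sample counts as — "none"
        (off-target, the default) or "hold_last" (carry the previous AOI
        forward).
    normalize_per_second : when true, delta is divided by the sample period
        so the derivative is per second instead of per sample. Off by
        default: the statistic is constructed per sample and the calibrated
        threshold lives on the same scale either way.
    include_live_gap : when true (default, matching the statistic's original
        construction) the still-open gap participates in sigma, being
        rewritten in place on every off-target sample. This makes sigma
        sawtooth even under perfectly periodic glancing: each glance end
        resets the live gap to one sample period, far below the window mean.
        ``False`` restricts sigma to completed gaps, under which perfectly
        regular glancing idealizes to exactly zero variance (and zero
        accumulated change). See docs/methods.md for the consequences of
        each convention.
    """

    n: int = 10
    smooth_seconds: float = 2.0
    threshold_T: Optional[float] = None
    target_aoi: str = "dashboard"
    invalid_policy: str = "none"
    normalize_per_second: bool = False
    include_live_gap: bool = True

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise ConfigError(f"window size n must be an integer >= 2, got {self.n!r}")
        object.__setattr__(self, "n", int(self.n))
        if not self.smooth_seconds > 0:
            raise ConfigError(f"smooth_seconds must be > 0, got {self.smooth_seconds!r}")
        if self.threshold_T is not None:
            if not (math.isfinite(self.threshold_T) and self.threshold_T >= 0):
                raise ConfigError(
                    f"threshold_T must be a finite non-negative float or None, "
                    f"got {self.threshold_T!r}"
                )
        if self.invalid_policy not in ("none", "hold_last"):
            raise ConfigError(f"invalid_policy must be 'none' or 'hold_last', got {self.invalid_policy!r}")

    def with_threshold(self, threshold_T: float) -> "DetectorConfig":
        return replace(self, threshold_T=float(threshold_T))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DetectorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


def smoothing_samples(smooth_seconds: float, rate_hz: float) -> int:
    """m = round(smooth_seconds * rate_hz), at least 1 (half rounds up)."""
    return max(1, int(smooth_seconds * rate_hz + 0.5))


def window_std(gaps: Sequence[float]) -> float:
    """Population standard deviation of a gap window.

    Fewer than two entries give 0.0 by convention (a single gap carries no
    variance information; the statistic then starts from zero while the
    window fills).
    """
    vals = list(gaps)
    c = len(vals)
    if any(v < 0 for v in vals):
        raise DataError("negative gap duration in window — internal state corrupted")
    if c < 2:
        return 0.0
    mean = math.fsum(vals) / c
    return math.sqrt(math.fsum((v - mean) ** 2 for v in vals) / c)


def smooth(sigma_history: Sequence[float], m: int) -> float:
    """Mean of the most recent ``min(m, len)`` sigma values (startup shrinks)."""
    if m < 1:
        raise ConfigError(f"smoothing span m must be >= 1, got {m}")
    window = list(sigma_history)[-m:]
    if not window:
        return 0.0
    return math.fsum(window) / len(window)


def accumulate(delta: float, prev_cum: float) -> float:
    """One-sided accumulation: non-negative derivatives add up, a negative
    derivative resets the accumulator to zero."""
    if prev_cum < 0:
        raise DataError("accumulator must be non-negative")
    return prev_cum + delta if delta >= 0 else 0.0


@dataclass
class GapWindow:
    """Ring buffer of the last ``n`` inter-glance gap durations.

    ``slots[write_index]`` is the live gap: it is rewritten on every
    off-target sample as (current time - last on-target time) and is frozen
    when the next glance begins and the index advances (wrapping at ``n``,
    evicting the oldest gap). Unwritten slots hold NaN and are excluded from
    the standard deviation.
    """

    n: int
    slots: list[float]
    write_index: int = -1
    last_on_time: float = math.nan
    prev_on: bool = False
    live: bool = False

    @classmethod
    def empty(cls, n: int) -> "GapWindow":
        return cls(n=n, slots=[math.nan] * n)

    @property
    def filled(self) -> int:
        return sum(1 for v in self.slots if not math.isnan(v))

    def values(self, include_live: bool = True) -> list[float]:
        """Window contents; with ``include_live=False`` the slot currently
        being rewritten (the open gap) is excluded."""
        if include_live or not self.live:
            return [v for v in self.slots if not math.isnan(v)]
        return [
            v
            for i, v in enumerate(self.slots)
            if i != self.write_index and not math.isnan(v)
        ]

    def update(self, t: float, on_target: bool) -> None:
        """Advance the ring-buffer state machine by one sample."""
        if on_target:
            if not self.prev_on:
                self.write_index += 1
                if self.write_index >= self.n:
                    self.write_index = 0
            self.last_on_time = t
        else:
            if self.write_index >= 0:
                gap = t - self.last_on_time
                if gap < 0:
                    raise DataError("sample time precedes last glance time")
                self.slots[self.write_index] = gap
        self.prev_on = on_target
        self.live = (not on_target) and self.write_index >= 0

    def std(self) -> float:
        return window_std(self.values())


class TdgvDetector:
    """Incremental per-sample TDGV-change computation.

    Feed samples in time order via :meth:`step`; each call returns the
    ``(sigma, sigma_smooth, delta, cum)`` row for that sample. The window
    state is exposed as :attr:`window` for inspection.
    """

    def __init__(self, config: DetectorConfig, rate_hz: float) -> None:
        if not rate_hz > 0:
            raise ConfigError(f"rate_hz must be positive, got {rate_hz}")
        self.config = config
        self.rate_hz = float(rate_hz)
        self.m = smoothing_samples(config.smooth_seconds, rate_hz)
        self.window = GapWindow.empty(config.n)
        self._sigma_buf: list[float] = []  # trailing <= m sigma values
        self._prev_t: Optional[float] = None
        self._prev_smooth: Optional[float] = None
        self._cum = 0.0

    def step(self, t: float, on_target: bool) -> tuple[float, float, float, float]:
        if self._prev_t is not None and t <= self._prev_t:
            raise DataError(f"sample at t={t} not after previous sample at t={self._prev_t}")
        self.window.update(t, on_target)
        sigma = window_std(self.window.values(include_live=self.config.include_live_gap))

        self._sigma_buf.append(sigma)
        if len(self._sigma_buf) > self.m:
            self._sigma_buf.pop(0)
        sm = math.fsum(self._sigma_buf) / len(self._sigma_buf)

        if self._prev_smooth is None:
            delta = 0.0
        else:
            delta = sm - self._prev_smooth
            if self.config.normalize_per_second:
                delta *= self.rate_hz
        self._cum = accumulate(delta, self._cum)

        self._prev_t = t
        self._prev_smooth = sm
        return sigma, sm, delta, self._cum


@dataclass
class TdgvTrace:
    """Per-sample detector output aligned with the input stream."""

    t: np.ndarray
    sigma: np.ndarray
    sigma_smooth: np.ndarray
    delta: np.ndarray
    cum: np.ndarray
    distracted: np.ndarray
    threshold: Optional[float] = None

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "sigma": self.sigma,
                "sigma_smooth": self.sigma_smooth,
                "delta": self.delta,
                "cum": self.cum,
                "distracted": self.distracted,
            }
        )

    def with_threshold(self, threshold: float) -> "TdgvTrace":
        """Re-flag the trace against a new threshold (strict inequality)."""
        if not (math.isfinite(threshold) and threshold >= 0):
            raise ConfigError(f"threshold must be finite and >= 0, got {threshold!r}")
        return TdgvTrace(
            t=self.t,
            sigma=self.sigma,
            sigma_smooth=self.sigma_smooth,
            delta=self.delta,
            cum=self.cum,
            distracted=self.cum > threshold,
            threshold=float(threshold),
        )


@dataclass(frozen=True)
class DetectionEvent:
    """A maximal run of consecutive distraction-flagged samples.

    A single flagged sample yields a zero-length event (start == end);
    segment scoring only asks whether an event touches a segment, so event
    granularity cannot change scores.
    """

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise DataError("event end precedes start")


def effective_on_target(stream: GazeStream, config: DetectorConfig) -> np.ndarray:
    """Boolean per-sample on-target indicator after the invalid-sample policy.

    ``invalid_policy="none"`` maps invalid samples off-target;
    ``"hold_last"`` carries the last valid AOI forward (leading invalid
    samples count as off-target).
    """
    aoi = stream.aoi
    if config.invalid_policy == "hold_last":
        aoi = aoi.copy()
        last = NO_AOI
        for i in range(len(aoi)):
            if stream.valid[i]:
                last = aoi[i]
            else:
                aoi[i] = last
        on = aoi == config.target_aoi
    else:
        on = (aoi == config.target_aoi) & stream.valid
    return np.asarray(on, dtype=bool)


def compute_trace(stream: GazeStream, config: DetectorConfig) -> TdgvTrace:
    """Run the streaming statistic over a whole stream.

    Works with an uncalibrated config (``threshold_T=None``): the accumulator
    does not depend on the threshold, so calibration can consume this trace;
    the ``distracted`` flags are then all false and ``threshold`` is None.
    """
    on = effective_on_target(stream, config)
    det = TdgvDetector(config, stream.rate_hz)
    k = len(stream)
    sigma = np.empty(k)
    sm = np.empty(k)
    delta = np.empty(k)
    cum = np.empty(k)
    for i in range(k):
        sigma[i], sm[i], delta[i], cum[i] = det.step(float(stream.t[i]), bool(on[i]))
    if config.threshold_T is None:
        flags = np.zeros(k, dtype=bool)
    else:
        flags = cum > config.threshold_T
    return TdgvTrace(
        t=stream.t.copy(),
        sigma=sigma,
        sigma_smooth=sm,
        delta=delta,
        cum=cum,
        distracted=flags,
        threshold=config.threshold_T,
    )


def events_from_trace(trace: TdgvTrace) -> list[DetectionEvent]:
    """Collapse maximal runs of distracted samples into events."""
    flags = np.asarray(trace.distracted, dtype=bool)
    if not flags.any():
        return []
    edges = np.diff(flags.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        ends.append(len(flags) - 1)
    return [DetectionEvent(float(trace.t[a]), float(trace.t[b])) for a, b in zip(starts, ends)]


def run_detector(
    stream: GazeStream, config: DetectorConfig
) -> tuple[TdgvTrace, list[DetectionEvent]]:
    """Full detection pass: trace plus grouped detection events.

    Raises
    ------
    UsageError
        If ``config.threshold_T`` is None — calibrate first (see
        :func:`tdgv.calibration.calibrate_threshold`).
    """
    if config.threshold_T is None:
        raise UsageError(
            "detector threshold is uncalibrated; derive it from a baseline segment with "
            "tdgv.calibration.calibrate_threshold"
        )
    trace = compute_trace(stream, config)
    return trace, events_from_trace(trace)
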