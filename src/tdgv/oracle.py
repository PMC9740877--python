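"""Batch re-computation of the TDGV-change trace, independent of the
streaming state machine.

For every sample index the gap window is reconstructed from scratch out of
the glance-run structure of the stream (onset and end indices of maximal
on-target runs), with no state carried between samples:

* glance ``g`` writes ring slot ``g mod n``;
* a slot's frozen value is the time from the end of glance ``g`` to the last
  off-target sample before glance ``g+1`` begins;
* while a sample is off-target, the slot of the current glance holds the live
  gap (current time minus end of the current glance);
* while a sample is on-target (inside glance ``g``), that slot still holds
  the stale value written by glance ``g - n`` (if any): the index advances at
  glance onset but the slot is only rewritten on the next off-target sample.

Smoothing, differencing and one-sided accumulation are then applied to the
sigma series. Arithmetic matches :mod:`tdgv.detector` conventions
(population SD, exactly rounded sums), so agreement is expected to machine
precision.
"""
from __future__ import annotations

import math

import numpy as np

from .detector import DetectorConfig, TdgvTrace, smoothing_samples
from .io import GazeStream
from .detector import effective_on_target


def _run_structure(on: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Onset index and end index (inclusive) of each maximal on-target run."""
    on = np.asarray(on, dtype=bool)
    if len(on) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = np.diff(on.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if on[0]:
        starts = np.concatenate(([0], starts))
    if on[-1]:
        ends = np.concatenate((ends, [len(on) - 1]))
    return starts, ends


def _window_at(
    i: int,
    on_i: bool,
    g: int,
    t: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    frozen: list[float],
    n: int,
    include_live: bool,
) -> list[float]:
    """Gap-window contents at sample i, rebuilt from the run structure."""
    if g < 0:
        return []
    vals: list[float] = []
    for s in range(n):
        j = g - ((g - s) % n)  # newest glance <= g writing slot s
        if j < 0:
            continue
        if j < g:
            vals.append(frozen[j])
        elif on_i:
            # inside glance g: its slot still holds the value from glance g-n
            if g - n >= 0:
                vals.append(frozen[g - n])
        elif include_live:
            vals.append(float(t[i]) - float(t[ends[g]]))  # live gap
    return vals


def batch_oracle(stream: GazeStream, config: DetectorConfig) -> TdgvTrace:
    """Compute the full trace by per-sample reconstruction (no streaming state).

    Output contract is identical to
    :func:`tdgv.detector.compute_trace`; an empty stream yields an empty
    trace.
    """
    on = effective_on_target(stream, config)
    t = np.asarray(stream.t, dtype=float)
    k = len(t)
    n = config.n
    starts, ends = _run_structure(on)

    # frozen gap of glance g: last off sample before glance g+1 minus end of g
    frozen = [float(t[starts[g + 1] - 1] - t[ends[g]]) for g in range(len(starts) - 1)]

    # index of the current glance at each sample (-1 before the first onset)
    g_all = np.searchsorted(starts, np.arange(k), side="right") - 1

    sigma = np.empty(k)
    for i in range(k):
        vals = _window_at(
            i, bool(on[i]), int(g_all[i]), t, starts, ends, frozen, n,
            config.include_live_gap,
        )
        c = len(vals)
        if c < 2:
            sigma[i] = 0.0
        else:
            mean = math.fsum(vals) / c
            sigma[i] = math.sqrt(math.fsum((v - mean) ** 2 for v in vals) / c)

    m = smoothing_samples(config.smooth_seconds, stream.rate_hz)
    sm = np.empty(k)
    for i in range(k):
        lo = max(0, i - m + 1)
        sm[i] = math.fsum(sigma[lo : i + 1]) / (i + 1 - lo)

    delta = np.empty(k)
    cum = np.empty(k)
    scale = stream.rate_hz if config.normalize_per_second else 1.0
    prev_cum = 0.0
    for i in range(k):
        d = 0.0 if i == 0 else (sm[i] - sm[i - 1]) * scale
        prev_cum = prev_cum + d if d >= 0 else 0.0
        delta[i] = d
        cum[i] = prev_cum

    if config.threshold_T is None:
        flags = np.zeros(k, dtype=bool)
    else:
        flags = cum > config.threshold_T
    return TdgvTrace(
        t=t.copy(),
        sigma=sigma,
        sigma_smooth=sm,
        delta=delta,
        cum=cum,
        distracted=flags,
        threshold=config.threshold_T,
    )
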