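"""Shared fixtures: deterministic synthetic gaze streams."""
from __future__ import annotations

import numpy as np
import pytest

from tdgv.io import GazeStream


def make_random_stream(
    seed: int,
    length: int,
    rate_hz: float,
    p_on: float = 0.12,
    p_stay_on: float = 0.85,
    invalid_frac: float = 0.03,
) -> GazeStream:
    """Markov on/off AOI labels at a fixed rate, with a few invalid samples.

    The chain gives contiguous glances and gaps of realistic run lengths
    rather than per-sample coin flips.
    """
    rng = np.random.default_rng(seed)
    on = np.empty(length, dtype=bool)
    state = False
    for i in range(length):
        if state:
            state = rng.random() < p_stay_on
        else:
            state = rng.random() < p_on
        on[i] = state
    aoi = np.where(on, "dashboard", "none").astype(object)
    valid = rng.random(length) >= invalid_frac
    t = np.arange(length, dtype=float) / rate_hz
    return GazeStream(t=t, aoi=aoi, valid=valid, rate_hz=rate_hz)


@pytest.fixture
def hand_trace_stream() -> GazeStream:
    """1 Hz stream whose full detector trace was worked out by hand (n=2)."""
    labels = [
        "dashboard", "none", "none", "dashboard", "none",
        "none", "none", "dashboard", "none", "dashboard",
    ]
    return GazeStream(
        t=np.arange(10.0),
        aoi=np.array(labels, dtype=object),
        valid=np.ones(10, dtype=bool),
        rate_hz=1.0,
    )
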