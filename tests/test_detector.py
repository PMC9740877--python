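import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdgv.detector import (
    DetectionEvent,
    DetectorConfig,
    TdgvDetector,
    TdgvTrace,
    accumulate,
    compute_trace,
    events_from_trace,
    run_detector,
    smooth,
    smoothing_samples,
    window_std,
)
from tdgv.errors import ConfigError, DataError, UsageError
from tdgv.io import GazeStream

from conftest import make_random_stream

# Full hand-worked trace for the 1 Hz, n=2 fixture
# labels: on off off on off off off on off on  (on = dashboard)
HAND_SLOTS = [
    (0, [None, None]),
    (0, [1.0, None]),
    (0, [2.0, None]),   # live slot keeps growing while off target
    (1, [2.0, None]),   # new glance: index advances, 2.0 is frozen
    (1, [2.0, 1.0]),
    (1, [2.0, 2.0]),
    (1, [2.0, 3.0]),
    (0, [2.0, 3.0]),    # wrap at n=2: index back to slot 0
    (0, [1.0, 3.0]),    # oldest gap evicted by overwrite
    (1, [1.0, 3.0]),
]
HAND_SIGMA = [0.0, 0.0, 0.0, 0.0, 0.5, 0.0, 0.5, 0.5, 1.0, 1.0]
HAND_SMOOTH = [0.0, 0.0, 0.0, 0.0, 0.25, 0.25, 0.25, 0.5, 0.75, 1.0]
HAND_DELTA = [0.0, 0.0, 0.0, 0.0, 0.25, 0.0, 0.0, 0.25, 0.25, 0.25]
HAND_CUM = [0.0, 0.0, 0.0, 0.0, 0.25, 0.25, 0.25, 0.5, 0.75, 1.0]


class TestWindowStd:
    @pytest.mark.parametrize(
        "gaps,expected",
        [([2.0, 2.0, 2.0], 0.0), ([], 0.0), ([1.0, 3.0], 1.0), ([5.0], 0.0)],
    )
    def test_population_sd_with_small_window_conventions(self, gaps, expected):
        assert window_std(gaps) == expected

    def test_negative_gap_rejected(self):
        with pytest.raises(DataError):
            window_std([1.0, -0.5])

    @settings(derandomize=True, max_examples=60)
    @given(
        gaps=st.lists(st.floats(0.0, 100.0), min_size=2, max_size=10),
        c=st.floats(0.01, 50.0),
    )
    def test_scale_equivariance(self, gaps, c):
        scaled = window_std([c * g for g in gaps])
        assert scaled == pytest.approx(c * window_std(gaps), rel=1e-9, abs=1e-12)


class TestSmoothing:
    @pytest.mark.parametrize(
        "hist,m,expected",
        [([1.0, 1.0, 3.0, 3.0], 4, 2.0), ([5.0], 120, 5.0), ([2.5] * 7, 3, 2.5)],
    )
    def test_mean_of_recent_values_with_startup_shrink(self, hist, m, expected):
        assert smooth(hist, m) == expected

    def test_span_is_rounded_product_with_floor_one(self):
        assert smoothing_samples(2.0, 60.0) == 120
        assert smoothing_samples(2.0, 0.2) == 1
        assert smoothing_samples(2.0, 1.2) == 2  # 2.4 rounds down


class TestAccumulate:
    def test_hand_sequence(self):
        deltas = [0.1, 0.2, -0.05, 0.3]
        cum, out = 0.0, []
        for d in deltas:
            cum = accumulate(d, cum)
            out.append(cum)
        assert out == pytest.approx([0.1, 0.3, 0.0, 0.3])

    def test_all_negative_stays_zero(self):
        cum = 0.0
        for d in [-0.1, -0.2, -0.3]:
            cum = accumulate(d, cum)
            assert cum == 0.0

    def test_zero_delta_keeps_accumulator(self):
        assert accumulate(0.0, 0.4) == 0.4

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=50))
    def test_never_negative_and_resets_exactly(self, deltas):
        cum = 0.0
        for d in deltas:
            cum = accumulate(d, cum)
            assert cum >= 0.0
            if d < 0:
                assert cum == 0.0


class TestHandTrace:
    def test_window_states_match_hand_trace(self, hand_trace_stream):
        det = TdgvDetector(DetectorConfig(n=2), rate_hz=1.0)
        on = hand_trace_stream.aoi == "dashboard"
        for i in range(len(hand_trace_stream)):
            det.step(float(hand_trace_stream.t[i]), bool(on[i]))
            exp_idx, exp_slots = HAND_SLOTS[i]
            assert det.window.write_index == exp_idx, f"sample {i}"
            got = [None if math.isnan(v) else v for v in det.window.slots]
            assert got == exp_slots, f"sample {i}"

    def test_series_match_hand_trace(self, hand_trace_stream):
        tr = compute_trace(hand_trace_stream, DetectorConfig(n=2))
        assert list(tr.sigma) == HAND_SIGMA
        assert list(tr.sigma_smooth) == HAND_SMOOTH
        assert list(tr.delta) == HAND_DELTA
        assert list(tr.cum) == HAND_CUM


class TestStepEdgeCases:
    def _stream(self, labels, rate=1.0):
        return GazeStream(
            t=np.arange(len(labels), dtype=float) / rate,
            aoi=np.array(labels, dtype=object),
            valid=np.ones(len(labels), bool),
            rate_hz=rate,
        )

    def test_never_on_target_all_zero(self):
        s = self._stream(["none"] * 50)
        tr, events = run_detector(s, DetectorConfig(threshold_T=0.0))
        assert not tr.sigma.any() and not tr.cum.any() and events == []

    def test_entirely_on_target_all_zero(self):
        s = self._stream(["dashboard"] * 50)
        tr, events = run_detector(s, DetectorConfig(threshold_T=0.0))
        assert not tr.sigma.any() and not tr.cum.any() and events == []

    def test_out_of_order_sample_rejected(self):
        det = TdgvDetector(DetectorConfig(), rate_hz=10.0)
        det.step(0.0, True)
        with pytest.raises(DataError):
            det.step(0.0, False)

    def test_uncalibrated_run_rejected_with_pointer(self):
        s = self._stream(["dashboard", "none"] * 10)
        with pytest.raises(UsageError, match="calibrate"):
            run_detector(s, DetectorConfig())

    def test_window_capacity_never_exceeded(self):
        s = make_random_stream(seed=7, length=4000, rate_hz=30.0)
        cfg = DetectorConfig(n=5)
        det = TdgvDetector(cfg, rate_hz=30.0)
        on = (s.aoi == "dashboard") & s.valid
        for i in range(len(s)):
            det.step(float(s.t[i]), bool(on[i]))
            assert det.window.filled <= 5

    def test_invalid_policy_none_vs_hold_last(self):
        t = np.arange(4.0)
        aoi = np.array(["dashboard", "dashboard", "none", "none"], dtype=object)
        valid = np.array([True, False, True, True])
        s = GazeStream(t=t, aoi=aoi, valid=valid, rate_hz=1.0)
        from tdgv.detector import effective_on_target

        assert list(effective_on_target(s, DetectorConfig())) == [True, False, False, False]
        assert list(effective_on_target(s, DetectorConfig(invalid_policy="hold_last"))) == [
            True, True, False, False,
        ]


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 1},
            {"smooth_seconds": 0.0},
            {"threshold_T": -1.0},
            {"threshold_T": float("inf")},
            {"invalid_policy": "drop"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            DetectorConfig(**kwargs)

    def test_json_round_trip(self, tmp_path):
        cfg = DetectorConfig(n=7, smooth_seconds=1.5, threshold_T=0.3, target_aoi="speedo")
        p = tmp_path / "cfg.json"
        cfg.to_json(p)
        assert DetectorConfig.from_json(p) == cfg


class TestEvents:
    def _trace(self, cum, thr):
        k = len(cum)
        return TdgvTrace(
            t=np.arange(k, dtype=float),
            sigma=np.zeros(k),
            sigma_smooth=np.zeros(k),
            delta=np.zeros(k),
            cum=np.asarray(cum, dtype=float),
            distracted=np.asarray(cum) > thr,
            threshold=thr,
        )

    def test_runs_collapse_into_events(self):
        tr = self._trace([0, 1, 1, 0, 1, 0, 0, 1, 1, 1], 0.5)
        ev = events_from_trace(tr)
        assert ev == [
            DetectionEvent(1.0, 2.0),
            DetectionEvent(4.0, 4.0),  # single sample: zero-length event
            DetectionEvent(7.0, 9.0),
        ]

    def test_no_flags_no_events(self):
        assert events_from_trace(self._trace([0, 0, 0], 0.5)) == []

    def test_threshold_monotonicity_nested_detections(self):
        rng = np.random.default_rng(11)
        cum = np.abs(np.cumsum(rng.normal(size=500))) * 0.01
        prev = None
        for thr in np.linspace(0, cum.max(), 8):
            flagged = set(np.flatnonzero(cum > thr))
            if prev is not None:
                assert flagged <= prev
            prev = flagged
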