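# Methods

## Detection model

The detector treats dashboard glancing as a renewal-like process and watches
for loss of temporal regularity. Its only input is a per-sample AOI label at
a nominally fixed sampling rate; no fixation/saccade parsing, pupil data or
head pose is used. The state is a ring buffer of the last `n` inter-glance
gap durations (seconds). The buffer is driven by a small state machine:

- on an off→on transition of the target AOI, the write index advances
  (wrapping at `n`, evicting the oldest gap) and the glance timestamp starts
  updating with every on-target sample;
- on every off-target sample, the slot at the write index is rewritten with
  (current time − last on-target time) — the *live* gap;
- the slot freezes when the next glance begins.

Per sample the pipeline is: population SD of the buffer contents σ(t) → a
trailing moving average σ̄(t) over `smooth_seconds` → the one-sample
difference Δσ(t) → a one-sided accumulator that sums non-negative differences
and resets to zero on the first negative one → a strict comparison of the
accumulator against the threshold T.

Assumptions worth making explicit: samples arrive in strict time order at an
approximately constant rate (the smoothing span is converted to samples once,
m = round(`smooth_seconds` × `rate_hz`), minimum 1); only one AOI is the
detection target; distraction manifests as *increased* gap variance —
decreases are deliberately ignored by the one-sided accumulator; and the
drive begins with an undistracted baseline segment on which T is calibrated.

## The live-gap convention (and why there are two)

The construction above updates the open gap in place, so a gap that keeps
growing (eyes away from the dashboard for a long time) inflates σ in real
time — detection does not have to wait for the glance to return. That online
property has a price, and the package makes it explicit:

1. **Sawtooth.** At each glance end the live gap restarts near one sample
   period, far below the window mean, so σ jumps upward and then decays as
   the gap grows toward the mean. Even perfectly periodic glancing therefore
   produces a periodic σ with amplitude of order (gap mean)·√(n−1)/n — about
   1.2 s for 4 s gaps and n = 10 — and the accumulator repeatedly climbs to
   comparable values. Regular glancing is *not* mapped to zero signal; it is
   mapped to a stable repeating signal that the calibrated threshold must
   absorb.
2. **Cold-start coupling.** While the window is filling, σ rises from zero
   as slots are written; the two-slot stage (one frozen gap plus a live gap
   restarting near zero) yields the largest monotone rise of the whole drive,
   roughly (gap mean)/2 after smoothing. If the calibration segment is the
   first segment of the drive — as in the alternating-segment study design —
   T is dominated by this initialization transient rather than by behavior.

`DetectorConfig(include_live_gap=False)` restricts σ to completed gaps: the
slot currently being rewritten is excluded. Under that convention perfectly
periodic glancing gives σ ≡ 0 exactly (verified on a binary-exact sample
grid), a flat baseline calibrates to T = 0, and the cold-start artifact
disappears — at the cost of the online long-gap response. The default remains
`True`, matching the statistic's original per-datapoint construction; the
variant exists because the idealized "regularity ⇒ zero variance" picture,
and most intuition about the method, correspond to the completed-gap reading.
On the synthetic study preset (below) the difference is dramatic: a 100-seed
campaign yields mean segment accuracy 42.8% (sensitivity 4.7%) with the live
gap in σ versus 90.2% (sensitivity 98.3%, specificity 78.0%) with completed
gaps only — almost entirely attributable to the cold start living inside the
calibration segment.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `n` | 10 | glances | gap-window length; larger n smooths σ across more history but slows response and lengthens the fill transient (~n·(gap+dwell) seconds) |
| `smooth_seconds` | 2.0 | s | σ moving-average horizon; suppresses per-sample jitter, spreads (not removes) jumps slower than the glance period |
| `threshold_T` | uncalibrated | s | accumulator scale; derived per drive from the baseline maximum |
| `target_aoi` | `"dashboard"` | — | the tracked AOI |
| `invalid_policy` | `"none"` | — | invalid samples count as off-target; `"hold_last"` carries the previous AOI forward |
| `normalize_per_second` | off | — | divides Δσ by the sample period; off so the statistic matches its per-sample construction (T is then rate-dependent, which calibration absorbs) |
| `include_live_gap` | on | — | see above |

## Calibration and baseline quality

"Maximum change during the baseline" is read as the maximum of the
*accumulated* statistic Δσ_cum — the quantity the running detector compares
against T — so threshold and statistic share a scale. The raw-derivative
reading (`statistic="delta"`) is implemented behind a switch; it produces
thresholds on a per-sample scale that fire near-continuously and is kept only
for comparison. Whether the baseline interval itself is included in the
whole-drive normalization series of the quality z-score: it is (literal
whole-drive reading). The z-transform uses the population SD. Higher z means
lower baseline quality; under the default convention even clean drives score
z ≈ 6–8 because the baseline holds the global cold-start maximum, and
corrupted baselines push z higher still — the *ordering*, which is what the
diagnostic is for, is preserved under both conventions.

## Scoring conventions

Segments are half-open `[start, end)` so abutting one-minute segments
partition the drive. A segment is "marked" iff any detection event (a maximal
run of flagged samples; a single flagged sample is a zero-length event)
touches it; event granularity therefore cannot change scores, which a test
asserts by splitting events. Segments labeled `baseline`, and in the pipeline
the calibration segment itself, are excluded from scoring (scoring them would
be circular — the threshold is by construction not exceeded there). Metrics
with empty denominators are reported as undefined rather than 0 or 100. The
median split assigns ties at the median to the low group; the sample median
is midpoint-interpolated.

## Synthetic drives

The simulator emulates the alternating-segment study design: six 60 s
segments, no-task first, sampled at 60 Hz. Glances are an alternating renewal
process — off-dashboard gap, then on-dashboard dwell — with truncated-normal
intervals floored at 0.2 s (shorter intervals are not physiologically
meaningful). Attentive defaults: gaps 4.0 ± 0.4 s, dwells 0.6 ± 0.1 s —
plausible magnitudes for routine speedometer checks, chosen as synthetic
design values, not measurements. Distraction is modeled purely as gap-SD
inflation (default ×6), i.e. as loss of temporal regularity at an unchanged
checking rate; glance-rate or dwell changes are deliberately not modeled.
Each segment consumes its own RNG stream spawned from the master seed by
segment index, so schedules sharing a prefix share realizations, and
identical inputs reproduce output exactly. Intervals are never truncated at
segment boundaries; a draw is taken from the model of the segment in which it
starts. Glance times are continuous and are discretized to the sample grid
with a consistent tie rule (ceil with 1e-9 tolerance), which leaves ±1 sample
of boundary jitter on realized gaps.

What the simulator does **not** emulate: gaze coordinates and AOI geometry
noise, tracker dropouts in bursts, blinks, glances to third locations
(mirrors, infotainment), drifts in glance rate, or mind-wandering that is not
time-locked to segments. Passing tests on these drives show the detector
responds correctly to gap-variance inflation under clean conditions; they do
not certify field performance.

With the heavy distracted model (SD 2.4 s against a 4.0 s mean) the 0.2 s
floor truncates the gap distribution noticeably, so its realized SD runs
~11% below nominal; the SD-convergence test therefore uses the attentive
model, where truncation is negligible.

## Numerical choices

- Population SD everywhere (window σ, quality z): defined for a single
  element, no special case; a window with fewer than two values has σ = 0.
- Window means and SDs use exactly rounded summation (`math.fsum`) in both
  the streaming detector and the independent batch re-computation, so the
  equivalence check is bit-exact rather than tolerance-fitted; the two paths
  remain algorithmically independent (incremental state machine vs stateless
  per-sample reconstruction from the glance-run structure).
- Detection uses strict inequality (`cum > T`), so a flat drive never fires
  at the T = 0 it calibrates.
- The first sample's Δσ is 0; smoothing shrinks its window at startup.
- AOI containment is boundary-inclusive, first-declared-wins (shapely
  predicates); deterministic also for non-simple polygons.
- Problem sizes: unit tests use streams of 10–4,000 samples; the equivalence
  check runs 200 randomized streams of 100–20,000 samples at 10–120 Hz;
  detection campaigns use 50–100 drives of 21,600 samples each.

## Known limitations

- The statistic cannot distinguish cognitive from visual distraction; both
  disturb gap regularity.
- With the default convention, calibration on a drive-initial baseline is
  dominated by the detector's own fill transient (quantified above); a
  practical deployment should either discard a warm-up period before the
  baseline or use the completed-gap convention.
- Δσ is a per-sample difference, so trace magnitudes depend on the sampling
  rate unless `normalize_per_second` is enabled; thresholds are only
  transferable between recordings at one rate.
- Segment-level "marked at least once" scoring is maximally sensitive to
  single spurious samples crossing T; no minimum event duration is imposed.
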