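"""Gaze-stream, AOI and segment-annotation I/O.

The on-disk formats are deliberately plain text:

* gaze CSV — columns ``t,aoi,valid`` or ``t,x,y,valid`` (header required,
  UTF-8, ``.`` decimal); ``valid`` is optional and defaults to true.
* AOI JSON — ``{"aois": [{"name": ..., "polygon": [[x, y], ...]}, ...]}``.
* segments CSV — columns ``start_s,end_s,condition``.

Times are seconds as floats throughout. A gaze stream is stored columnar
(numpy arrays) because every downstream computation is per-sample over the
whole recording; :class:`GazeSample` exists for single-observation access.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .errors import ConfigError, DataError, FormatError

#: Recognised experimental-segment conditions. "baseline" marks the interval
#: used for threshold calibration; the task labels come from the alternating
#: drive design (undistracted driving vs. an auditory working-memory task vs.
#: a visual side task).
CONDITIONS = frozenset({"baseline", "no_task", "cognitive_task", "visual_task"})

#: Label assigned to gaze points that fall in no declared AOI.
NO_AOI = "none"


class GazeSample(NamedTuple):
    """One timestamped gaze observation classified into an area of interest."""

    t: float
    aoi: str
    valid: bool = True
    x: Optional[float] = None
    y: Optional[float] = None


@dataclass(frozen=True)
class AOIDefinition:
    """A named polygonal area of interest in screen/world plane units.

    Containment is boundary-inclusive and deterministic; polygons need not be
    convex and are not required to be simple.
    """

    name: str
    polygon: tuple[tuple[float, float], ...]
    _shape: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ConfigError(
                f"AOI {self.name!r}: polygon needs >= 3 vertices, got {len(self.polygon)}"
            )
        object.__setattr__(self, "polygon", tuple((float(x), float(y)) for x, y in self.polygon))
        object.__setattr__(self, "_shape", Polygon(self.polygon))

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive point-in-polygon test."""
        return bool(self._shape.intersects(Point(float(x), float(y))))


def classify_aoi(x: float, y: float, aois: Sequence[AOIDefinition]) -> str:
    """Classify a gaze point against an ordered list of AOIs.

    Returns the name of the *first* AOI (declaration order) whose polygon
    contains the point, with boundary points counting as inside; ``"none"``
    if no AOI contains it.

    Raises
    ------
    ConfigError
        If ``aois`` is empty.
    DataError
        If the coordinate is not finite.
    """
    if not aois:
        raise ConfigError("classify_aoi: empty AOI list")
    if not (np.isfinite(x) and np.isfinite(y)):
        raise DataError(f"classify_aoi: non-finite gaze point ({x}, {y})")
    for aoi in aois:
        if aoi.contains(x, y):
            return aoi.name
    return NO_AOI


@dataclass(frozen=True)
class SegmentAnnotation:
    """A labeled time interval of a drive.

    Intervals are half-open ``[start_s, end_s)`` so that abutting one-minute
    segments partition the drive without double counting.
    """

    start_s: float
    end_s: float
    condition: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start_s) and np.isfinite(self.end_s)):
            raise DataError(f"segment bounds must be finite, got [{self.start_s}, {self.end_s})")
        if not self.start_s < self.end_s:
            raise DataError(
                f"segment start must precede end, got [{self.start_s}, {self.end_s})"
            )
        if self.condition not in CONDITIONS:
            raise DataError(
                f"unknown segment condition {self.condition!r}; expected one of "
                f"{sorted(CONDITIONS)}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        """Half-open containment test for a time point."""
        return self.start_s <= t < self.end_s


@dataclass
class GazeStream:
    """An AOI-labeled gaze recording at a nominally fixed sampling rate.

    Attributes
    ----------
    t : float array, strictly increasing sample times in seconds.
    aoi : object array of AOI labels (``"none"`` when off all AOIs).
    valid : bool array, eye-tracker quality flag per sample.
    rate_hz : nominal sampling frequency; inferred from the median
        inter-sample spacing when not supplied.
    """

    t: np.ndarray
    aoi: np.ndarray
    valid: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.aoi = np.asarray(self.aoi, dtype=object)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.aoi) == len(self.valid)):
            raise DataError("GazeStream columns must share length")
        if len(self.t):
            if not np.all(np.isfinite(self.t)):
                bad = int(np.flatnonzero(~np.isfinite(self.t))[0])
                raise DataError(f"non-finite timestamp at row {bad}")
            if self.t[0] < 0:
                raise DataError("timestamps must be non-negative")
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                bad = int(np.flatnonzero(dt <= 0)[0]) + 1
                raise DataError(
                    f"timestamps must be strictly increasing; first violation at row {bad} "
                    f"(t={self.t[bad]!r} after t={self.t[bad - 1]!r})"
                )
        if not (np.isfinite(self.rate_hz) and self.rate_hz > 0):
            raise ConfigError(f"rate_hz must be positive, got {self.rate_hz}")
        self._check_rate_consistency()

    def _check_rate_consistency(self) -> None:
        if len(self.t) < 3:
            return
        med = float(np.median(np.diff(self.t)))
        if med <= 0:
            return
        implied = 1.0 / med
        if abs(implied - self.rate_hz) > 0.2 * self.rate_hz:
            warnings.warn(
                f"declared rate {self.rate_hz:g} Hz inconsistent with median sample "
                f"spacing ({implied:g} Hz implied)",
                stacklevel=3,
            )

    def __len__(self) -> int:
        return len(self.t)

    def __iter__(self) -> Iterator[GazeSample]:
        for t, aoi, valid in zip(self.t, self.aoi, self.valid):
            yield GazeSample(float(t), str(aoi), bool(valid))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "aoi": self.aoi, "valid": self.valid})

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0


def infer_rate_hz(t: np.ndarray) -> float:
    """Nominal sampling rate as 1 / median inter-sample spacing."""
    t = np.asarray(t, dtype=float)
    if len(t) < 2:
        raise DataError("cannot infer sampling rate from fewer than 2 samples")
    med = float(np.median(np.diff(t)))
    if med <= 0:
        raise DataError("cannot infer sampling rate: non-increasing timestamps")
    return 1.0 / med


def read_gaze_csv(
    path,
    schema: Optional[Mapping[str, str]] = None,
    aois: Optional[Sequence[AOIDefinition]] = None,
    rate_hz: Optional[float] = None,
) -> GazeStream:
    """Read an AOI-labeled gaze stream from CSV.

    Parameters
    ----------
    path : file path.
    schema : optional mapping from canonical names (``t``, ``aoi``, ``x``,
        ``y``, ``valid``) to the column names actually present; identity by
        default.
    aois : AOI geometry used to classify ``x, y`` points when no ``aoi``
        column is present.
    rate_hz : nominal sampling rate; inferred from the timestamps when
        omitted.

    Invalid-flagged rows are retained with ``valid=False``; how they are
    treated during detection is a detector-config policy, not an I/O one.
    """
    schema = dict(schema or {})
    col = lambda name: schema.get(name, name)  # noqa: E731
    # round_trip parsing so write->read reproduces timestamps bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    if col("t") not in df.columns:
        raise FormatError(f"{path}: missing time column {col('t')!r}")
    t = df[col("t")].to_numpy(dtype=float)

    if col("aoi") in df.columns:
        aoi = df[col("aoi")].astype(str).to_numpy(dtype=object)
    elif col("x") in df.columns and col("y") in df.columns:
        if not aois:
            raise FormatError(
                f"{path}: no {col('aoi')!r} column; supply AOI definitions to classify x,y"
            )
        xs = df[col("x")].to_numpy(dtype=float)
        ys = df[col("y")].to_numpy(dtype=float)
        aoi = np.array([classify_aoi(x, y, aois) for x, y in zip(xs, ys)], dtype=object)
    else:
        raise FormatError(
            f"{path}: need either an {col('aoi')!r} column or both {col('x')!r} and {col('y')!r}"
        )

    if col("valid") in df.columns:
        valid = df[col("valid")].astype(bool).to_numpy()
    else:
        valid = np.ones(len(df), dtype=bool)

    if rate_hz is None:
        rate_hz = infer_rate_hz(t)
    return GazeStream(t=t, aoi=aoi, valid=valid, rate_hz=float(rate_hz))


def write_gaze_csv(stream: GazeStream, path) -> None:
    """Write a gaze stream; round-trips timestamps and labels exactly
    (pandas emits full-precision ``repr`` floats)."""
    stream.to_frame().to_csv(path, index=False)


def read_aois_json(path) -> list[AOIDefinition]:
    """Read AOI definitions from ``{"aois": [{"name", "polygon"}, ...]}``."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    try:
        entries = payload["aois"]
        return [AOIDefinition(e["name"], tuple(map(tuple, e["polygon"]))) for e in entries]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed AOI JSON ({exc})") from exc


def write_aois_json(aois: Sequence[AOIDefinition], path) -> None:
    payload = {"aois": [{"name": a.name, "polygon": [list(v) for v in a.polygon]} for a in aois]}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def validate_segments(segments: Sequence[SegmentAnnotation]) -> list[SegmentAnnotation]:
    """Sort segments by start and reject overlapping intervals."""
    out = sorted(segments, key=lambda s: s.start_s)
    for a, b in zip(out, out[1:]):
        if b.start_s < a.end_s:
            raise DataError(
                f"overlapping segments: [{a.start_s}, {a.end_s}) and [{b.start_s}, {b.end_s})"
            )
    return out


def read_segments(path) -> list[SegmentAnnotation]:
    """Read a sorted, validated segment-annotation table from CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("start_s", "end_s", "condition"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    segs = [
        SegmentAnnotation(float(r.start_s), float(r.end_s), str(r.condition))
        for r in df.itertuples()
    ]
    return validate_segments(segs)


def write_segments(segments: Sequence[SegmentAnnotation], path) -> None:
    pd.DataFrame(
        {
            "start_s": [s.start_s for s in segments],
            "end_s": [s.end_s for s in segments],
            "condition": [s.condition for s in segments],
        }
    ).to_csv(path, index=False)
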