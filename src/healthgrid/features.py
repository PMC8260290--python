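"""Dimension expansion and gray-scale standardization of daily vitals.

Raw daily measurements (two blood-pressure/heart-rate sessions, weight,
body fat, two temperatures, and pedometer activity) are expanded into
derived cardiovascular indices and then mapped linearly onto 8-bit gray
values so they can be assembled into a health-map image.

The derived indices are the standard clinical ones:

* APP  (ambulatory pulse pressure)       = SP - DP            [mmHg]
* MAP  (mean arterial pressure)          = DP + (SP - DP)/3   [mmHg]
* ARPP (ambulatory rate-pressure product)= HR * SP            [mmHg*bpm]

Standardization maps each index's measurement range linearly to 0..255,
clamping out-of-range values (wearable spikes saturate rather than error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BloodPressureSession",
    "ActivitySummary",
    "DailyHealthRecord",
    "ExpandedSession",
    "ExpandedRecord",
    "StandardizationTable",
    "DEFAULT_TABLE",
    "expand_blood_pressure",
    "expand_activity",
    "expand_record",
    "standardize",
    "destandardize",
    "round_half_up",
    "read_records_csv",
    "write_records_csv",
]

SECONDS_PER_DAY = 86400.0

# Activity-expansion defaults; the pedometer protocol does not fix these,
# so they are explicit, configurable conventions.
DEFAULT_STRIDE_KM = 0.0007          # km per step
DEFAULT_FAST_CADENCE = 100          # steps/min counting as "fast motion"
DEFAULT_SLEEP_GAP_MIN = 20.0        # min without steps counting toward sleep
DEFAULT_NIGHT_WINDOW = (21.0, 9.0)  # local hours, wraps midnight


def round_half_up(value: float) -> int:
    """Round to nearest integer, halves away from zero (toward +inf for >=0)."""
    return int(math.floor(value + 0.5))


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BloodPressureSession:
    """One sphygmomanometer session: systolic, diastolic, heart rate."""

    sp: float  # mmHg
    dp: float  # mmHg
    hr: float  # bpm

    def __post_init__(self) -> None:
        if not self.dp < self.sp:
            raise ValueError(f"DP must be below SP (got SP={self.sp}, DP={self.dp})")
        if min(self.sp, self.dp, self.hr) < 0:
            raise ValueError("blood-pressure session values must be nonnegative")


@dataclass(frozen=True)
class ActivitySummary:
    """Pedometer six-tuple for one day."""

    step_num: int
    distance: float             # km
    fast_motion_time: float     # h
    fast_motion_distance: float  # km
    sleep_len: float            # h
    awake_len: float            # h

    def __post_init__(self) -> None:
        if self.step_num < 0:
            raise ValueError("step_num must be nonnegative")
        if self.sleep_len + self.awake_len > 24.0 + 1e-9:
            raise ValueError("sleep_len + awake_len cannot exceed 24 h")


@dataclass(frozen=True)
class DailyHealthRecord:
    """Raw daily measurements before expansion.

    Activity may be supplied either as raw step-event timestamps (seconds
    since 00:00) or as a precomputed :class:`ActivitySummary`.
    """

    session1: BloodPressureSession
    session2: BloodPressureSession
    weight: float   # kg
    fat: float      # percent
    temp1: float    # deg C
    temp2: float    # deg C
    activity: ActivitySummary | None = None
    step_events: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fat <= 100.0:
            raise ValueError(f"fat percent out of [0, 100]: {self.fat}")
        if self.activity is None and self.step_events is None:
            raise ValueError("record needs either activity summary or step events")


@dataclass(frozen=True)
class ExpandedSession:
    """Blood-pressure session plus its three derived indices."""

    sp: float
    dp: float
    hr: float
    app: float   # pulse pressure, mmHg
    map: float   # mean arterial pressure, mmHg
    arpp: float  # rate-pressure product, mmHg*bpm


@dataclass(frozen=True)
class ExpandedRecord:
    session1: ExpandedSession
    session2: ExpandedSession
    weight: float
    fat: float
    activity: ActivitySummary
    temp1: float
    temp2: float


# ---------------------------------------------------------------------------
# Standardization table
# ---------------------------------------------------------------------------

_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "weight": (0.0, 150.0),               # kg
    "fat": (0.0, 50.0),                   # percent
    "sp": (0.0, 250.0),                   # mmHg
    "dp": (0.0, 250.0),                   # mmHg
    "hr": (0.0, 200.0),                   # bpm
    "app": (0.0, 200.0),                  # mmHg
    "map": (0.0, 300.0),                  # mmHg
    "arpp": (0.0, 50000.0),               # mmHg*bpm
    "step_num": (0.0, 30000.0),           # count
    "distance": (0.0, 20.0),              # km
    "fast_motion_time": (0.0, 24.0),      # h
    "fast_motion_distance": (0.0, 20.0),  # km
    "sleep_len": (0.0, 24.0),             # h
    "awake_len": (0.0, 24.0),             # h
    "body_temperature": (30.0, 45.0),     # deg C
}


@dataclass(frozen=True)
class StandardizationTable:
    """Per-index (lo, hi) measurement ranges mapping linearly to gray 0..255."""

    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES)
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not hi > lo:
                raise ValueError(f"index {name!r}: hi must exceed lo ({lo}, {hi})")

    def __contains__(self, name: str) -> bool:
        return name in self.ranges

    def __getitem__(self, name: str) -> tuple[float, float]:
        try:
            return self.ranges[name]
        except KeyError:
            raise KeyError(f"unknown standardization index {name!r}") from None

    @classmethod
    def with_overrides(cls, overrides: Mapping[str, tuple[float, float]]) -> "StandardizationTable":
        ranges = dict(_DEFAULT_RANGES)
        for name, pair in overrides.items():
            ranges[name] = (float(pair[0]), float(pair[1]))
        return cls(ranges=ranges)


DEFAULT_TABLE = StandardizationTable()


def standardize(value: float, index: str, table: StandardizationTable = DEFAULT_TABLE) -> int:
    """Map a measurement to its 0..255 gray value.

    Values outside the index's range are clamped before scaling; the result
    is rounded half-up to an integer gray level.
    """
    lo, hi = table[index]
    clamped = min(max(float(value), lo), hi)
    gray = round_half_up(255.0 * (clamped - lo) / (hi - lo))
    return min(max(gray, 0), 255)


def destandardize(gray: int, index: str, table: StandardizationTable = DEFAULT_TABLE) -> float:
    """Inverse of :func:`standardize` on the gray lattice (exact round trip)."""
    if not 0 <= gray <= 255:
        raise ValueError(f"gray value out of [0, 255]: {gray}")
    lo, hi = table[index]
    return lo + gray / 255.0 * (hi - lo)


# ---------------------------------------------------------------------------
# Dimension expansion
# ---------------------------------------------------------------------------

def expand_blood_pressure(sp: float, dp: float, hr: float) -> tuple[float, float, float]:
    """Expand (SP, DP, HR) into (APP, MAP, ARPP).

    APP = SP - DP; MAP = DP + (SP - DP)/3; ARPP = HR * SP.
    """
    if dp > sp:
        raise ValueError(f"DP must not exceed SP (got SP={sp}, DP={dp})")
    if min(sp, dp, hr) < 0:
        raise ValueError("inputs must be nonnegative")
    app = sp - dp
    map_ = dp + (sp - dp) / 3.0
    arpp = hr * sp
    return app, map_, arpp


def expand_activity(
    step_events: Sequence[float],
    *,
    stride_km: float = DEFAULT_STRIDE_KM,
    fast_cadence: int = DEFAULT_FAST_CADENCE,
    sleep_gap_min: float = DEFAULT_SLEEP_GAP_MIN,
    night_window: tuple[float, float] = DEFAULT_NIGHT_WINDOW,
) -> ActivitySummary:
    """Expand raw step-event timestamps into the pedometer six-tuple.

    Parameters
    ----------
    step_events
        Nondecreasing timestamps in seconds since 00:00, all within one day.
    stride_km
        Distance credited per step.
    fast_cadence
        Minimum steps per clock minute for that minute to count as fast motion.
    sleep_gap_min
        A step-free gap at least this long (minutes) contributes its overlap
        with the night window to sleep time.
    night_window
        (start_hour, end_hour) local time; wraps midnight when start > end.

    Sleep is the total step-free-gap time inside the night window; awake time
    is the remainder of the 24 h day.
    """
    events = np.asarray(step_events, dtype=float)
    if events.size and (events.min() < 0.0 or events.max() >= SECONDS_PER_DAY):
        raise ValueError("step events must lie within one 24 h window [0, 86400)")
    if events.size and np.any(np.diff(events) < 0):
        raise ValueError("step events must be nondecreasing")

    step_num = int(events.size)
    distance = step_num * stride_km

    # Fast motion: clock-minute bins with cadence >= threshold.
    if step_num:
        minute_bins = np.bincount((events // 60.0).astype(int), minlength=1440)
        fast_mask = minute_bins >= fast_cadence
        fast_motion_time = float(fast_mask.sum()) / 60.0
        fast_motion_distance = float(minute_bins[fast_mask].sum()) * stride_km
    else:
        fast_motion_time = 0.0
        fast_motion_distance = 0.0

    # Night window as second-intervals (possibly wrapping midnight).
    start_h, end_h = night_window
    if start_h > end_h:
        night = [(0.0, end_h * 3600.0), (start_h * 3600.0, SECONDS_PER_DAY)]
    else:
        night = [(start_h * 3600.0, end_h * 3600.0)]

    # Step-free gaps (including the day edges) of at least sleep_gap_min.
    bounds = np.concatenate([[0.0], events, [SECONDS_PER_DAY]])
    gap_starts, gap_ends = bounds[:-1], bounds[1:]
    min_gap_s = sleep_gap_min * 60.0
    sleep_s = 0.0
    for g0, g1 in zip(gap_starts, gap_ends):
        if g1 - g0 < min_gap_s:
            continue
        for n0, n1 in night:
            sleep_s += max(0.0, min(g1, n1) - max(g0, n0))
    sleep_len = sleep_s / 3600.0
    awake_len = 24.0 - sleep_len

    return ActivitySummary(
        step_num=step_num,
        distance=distance,
        fast_motion_time=fast_motion_time,
        fast_motion_distance=fast_motion_distance,
        sleep_len=sleep_len,
        awake_len=awake_len,
    )


def _expand_session(s: BloodPressureSession) -> ExpandedSession:
    app, map_, arpp = expand_blood_pressure(s.sp, s.dp, s.hr)
    return ExpandedSession(sp=s.sp, dp=s.dp, hr=s.hr, app=app, map=map_, arpp=arpp)


def expand_record(record: DailyHealthRecord, **activity_kwargs) -> ExpandedRecord:
    """Expand a raw daily record into all derived indices.

    A precomputed activity summary on the record is passed through unchanged;
    otherwise the step events are expanded (``activity_kwargs`` forwarded to
    :func:`expand_activity`).
    """
    if record.activity is not None:
        activity = record.activity
    else:
        activity = expand_activity(record.step_events, **activity_kwargs)
    return ExpandedRecord(
        session1=_expand_session(record.session1),
        session2=_expand_session(record.session2),
        weight=record.weight,
        fat=record.fat,
        activity=activity,
        temp1=record.temp1,
        temp2=record.temp2,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "sp1", "dp1", "hr1", "sp2", "dp2", "hr2",
    "weight", "fat",
    "steps", "distance", "fast_time", "fast_dist", "sleep", "awake",
    "temp1", "temp2",
]


def _record_to_row(record: DailyHealthRecord) -> dict[str, float]:
    if record.activity is None:
        raise ValueError("CSV serialization requires an activity summary; expand first")
    a = record.activity
    s1, s2 = record.session1, record.session2
    return {
        "sp1": s1.sp, "dp1": s1.dp, "hr1": s1.hr,
        "sp2": s2.sp, "dp2": s2.dp, "hr2": s2.hr,
        "weight": record.weight, "fat": record.fat,
        "steps": a.step_num, "distance": a.distance,
        "fast_time": a.fast_motion_time, "fast_dist": a.fast_motion_distance,
        "sleep": a.sleep_len, "awake": a.awake_len,
        "temp1": record.temp1, "temp2": record.temp2,
    }


def write_records_csv(records: Sequence[DailyHealthRecord], path) -> None:
    """Write daily records as one CSV row per day with the documented header."""
    df = pd.DataFrame([_record_to_row(r) for r in records], columns=CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_records_csv(path) -> list[DailyHealthRecord]:
    """Read daily records from CSV (header must match :data:`CSV_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"record CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            DailyHealthRecord(
                session1=BloodPressureSession(sp=row.sp1, dp=row.dp1, hr=row.hr1),
                session2=BloodPressureSession(sp=row.sp2, dp=row.dp2, hr=row.hr2),
                weight=float(row.weight),
                fat=float(row.fat),
                temp1=float(row.temp1),
                temp2=float(row.temp2),
                activity=ActivitySummary(
                    step_num=int(row.steps),
                    distance=float(row.distance),
                    fast_motion_time=float(row.fast_time),
                    fast_motion_distance=float(row.fast_dist),
                    sleep_len=float(row.sleep),
                    awake_len=float(row.awake),
                ),
            )
        )
    return records
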