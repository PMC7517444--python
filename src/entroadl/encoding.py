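"""Minute-resolution symbolic encoding of activity logs.

Each location is assigned a unique positive odd integer code (toilet = 1,
bedroom-sleeping = 3, corridor = 5, living room = 7, kitchen = 9 when those
locations exist, further locations continuing 11, 13, ... in alphabetical
order).  A day becomes a length-1440 integer series: minute t carries the
code of the interval containing the instant HH:MM:00, repeated for the
duration of the stay; minutes covered by no interval repeat the last seen
code (carry-forward), or the dedicated out-of-home code before the first
interval of the day.  Hours and minutes are 0-based; windows half-open.

Sub-minute intervals that contain no minute-start instant do not appear in
the encoded series — dwell is effectively rounded to whole minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time, timedelta

import numpy as np

from .event_io import EventLog

__all__ = [
    "MINUTES_PER_DAY",
    "SAMPLES_PER_HOUR",
    "CodeMap",
    "EncodedSeries",
    "build_code_map",
    "encode_day",
    "encode_log",
    "slice_hour",
]

MINUTES_PER_DAY = 1440
SAMPLES_PER_HOUR = 60

#: Locations with conventional fixed codes, matched case-insensitively.
RESERVED_CODES = {
    "toilet": 1,
    "bedroom-sleeping": 3,
    "corridor": 5,
    "living room": 7,
    "kitchen": 9,
}


@dataclass(frozen=True)
class CodeMap:
    """Deterministic location -> odd-integer code assignment."""

    codes: dict[str, int]
    out_of_home_code: int

    def __post_init__(self) -> None:
        values = list(self.codes.values()) + [self.out_of_home_code]
        if len(set(values)) != len(values):
            raise ValueError(f"codes must be unique, got {values}")
        if any(v <= 0 or v % 2 == 0 for v in values):
            raise ValueError(f"codes must be positive odd integers, got {values}")

    def code_for(self, location: str) -> int:
        try:
            return self.codes[location]
        except KeyError:
            raise KeyError(f"unknown location {location!r}; known: "
                           f"{sorted(self.codes)}") from None

    def all_codes(self) -> set[int]:
        return set(self.codes.values()) | {self.out_of_home_code}


@dataclass(frozen=True)
class EncodedSeries:
    """One day's activity as a 1440-sample odd-integer symbol series."""

    day_index: int
    values: np.ndarray
    samples_per_hour: int = SAMPLES_PER_HOUR

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int64)
        if values.shape != (MINUTES_PER_DAY,):
            raise ValueError(
                f"encoded day must have exactly {MINUTES_PER_DAY} samples, "
                f"got shape {values.shape}"
            )
        object.__setattr__(self, "values", values)
        if self.day_index < 1:
            raise ValueError(f"day_index must be >= 1, got {self.day_index}")


def build_code_map(locations: set[str] | list[str]) -> CodeMap:
    """Assign odd-integer codes to a set of location labels.

    Locations with a conventional code (see RESERVED_CODES) receive it;
    all remaining locations receive the next unused odd numbers in
    alphabetical order.  The out-of-home code is the largest assigned + 2.
    """
    locations = sorted(set(locations))
    if not locations:
        raise ValueError("location set must be non-empty")
    codes: dict[str, int] = {}
    for loc in locations:
        reserved = RESERVED_CODES.get(loc.lower())
        if reserved is not None:
            codes[loc] = reserved
    used = set(codes.values())
    next_odd = 1
    for loc in locations:  # alphabetical (sorted above)
        if loc in codes:
            continue
        while next_odd in used:
            next_odd += 2
        codes[loc] = next_odd
        used.add(next_odd)
    return CodeMap(codes=codes, out_of_home_code=max(used) + 2)


def encode_day(log: EventLog, code_map: CodeMap, day_index: int) -> EncodedSeries:
    """Encode one calendar day of an EventLog as a 1440-sample series.

    Minute t takes the code of the interval containing the minute's start
    instant; uncovered minutes carry the last preceding code forward, with
    the out-of-home code before the first covered minute of the day.
    Intervals spanning midnight contribute to every day they touch.
    """
    if not 1 <= day_index <= log.n_days:
        raise ValueError(
            f"day_index {day_index} outside log span 1..{log.n_days}"
        )
    day_start = datetime.combine(log.day_date(day_index), time.min)
    values = np.full(MINUTES_PER_DAY, -1, dtype=np.int64)
    for event in log.events:
        if event.end <= day_start or event.start >= day_start + timedelta(days=1):
            continue
        code = code_map.code_for(event.location)
        # first minute whose start instant lies inside [event.start, event.end)
        first = max(0, _ceil_minute(event.start, day_start))
        last = min(MINUTES_PER_DAY, _ceil_minute(event.end, day_start))
        if first < last:
            values[first:last] = code
    # carry-forward fill; leading gap -> out-of-home
    current = code_map.out_of_home_code
    for t in range(MINUTES_PER_DAY):
        if values[t] == -1:
            values[t] = current
        else:
            current = values[t]
    return EncodedSeries(day_index=day_index, values=values)


def _ceil_minute(instant: datetime, day_start: datetime) -> int:
    """Index of the first minute-start at or after `instant` (day-relative)."""
    delta = (instant - day_start).total_seconds()
    return int(np.ceil(delta / 60.0))


def encode_log(log: EventLog, code_map: CodeMap | None = None) -> dict[int, EncodedSeries]:
    """Encode every day of the log; returns {day_index: EncodedSeries}."""
    if code_map is None:
        code_map = build_code_map(log.locations())
    return {d: encode_day(log, code_map, d) for d in range(1, log.n_days + 1)}


def slice_hour(series: EncodedSeries, hour: int) -> np.ndarray:
    """The contiguous 60-sample window [60*hour, 60*hour + 60)."""
    if not 0 <= hour <= 23:
        raise ValueError(f"hour must be in 0..23, got {hour}")
    lo = hour * series.samples_per_hour
    return series.values[lo : lo + series.samples_per_hour]
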