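"""Seeded simulator of single-resident ambient-sensor logs.

Emulates the statistical structure of a 65-day single-resident smart-home
recording: a stable daily routine (sleep with a brief nocturnal toilet
excursion, morning routine, meals, an afternoon outing, evening rest) with
minute-scale jitter, plus injected anomalous episodes of two kinds:

* ``visitor`` — a daytime hour of dense room-transition bursts accompanied
  by exactly one door open/close pair (the visit);
* ``irregular_sleep`` — nocturnal hours of transition bursts among bedroom,
  toilet, corridor and kitchen, with no door events;
* ``both`` — one visitor hour plus nocturnal sleep-burst hours on the same
  day;
* ``frequency_preserving`` — the morning-routine hour is re-ordered at
  one-minute granularity without changing its per-location minute totals,
  so symbol frequencies (hence Shannon entropy) are untouched while the
  transition structure (hence ordinal/template entropies) is scrambled.

Effect-size contract: every burst hour contains ~29+ within-hour location
transitions against at most ~4 on any normal hour, which makes the injected
anomalies separable by the template/ordinal measures at the max-over-normal
threshold.  The resident's own door use (outing and occasional evening
opening, 4-6 events/day) provides background door traffic so that door
events alone cannot mark a visit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from typing import Sequence

import numpy as np

from .event_io import (
    ABNORMAL,
    NORMAL,
    ActivityEvent,
    DoorEvent,
    EventLog,
    LabelSet,
)

__all__ = [
    "AnomalySpec",
    "SimConfig",
    "study_profile_anomalies",
    "study_profile_config",
    "frequency_preserving_config",
    "generate",
    "describe",
    "count_transitions",
]

LOC_BEDROOM = "Bedroom-sleeping"
LOC_TOILET = "Toilet"
LOC_CORRIDOR = "Corridor"
LOC_KITCHEN = "Kitchen"
LOC_DINING = "Dining room"
LOC_LIVING = "Living room"

#: Nominal daily schedule: (location or None for out-of-home, start minute).
#: The day ends at minute 1440.  At most 3-4 location transitions fall in
#: any one clock hour.
DEFAULT_SCHEDULE: tuple[tuple[str | None, int], ...] = (
    (LOC_BEDROOM, 0),
    (LOC_TOILET, 210),    # 03:30 nocturnal excursion
    (LOC_BEDROOM, 215),
    (LOC_TOILET, 480),    # 08:00 wake
    (LOC_CORRIDOR, 490),
    (LOC_KITCHEN, 492),
    (LOC_DINING, 525),
    (LOC_LIVING, 555),
    (LOC_KITCHEN, 720),   # 12:00 lunch
    (LOC_DINING, 750),
    (LOC_LIVING, 780),
    (LOC_CORRIDOR, 898),
    (None, 900),          # 15:00-17:00 out of the home
    (LOC_CORRIDOR, 1020),
    (LOC_KITCHEN, 1022),  # 17:00 dinner
    (LOC_DINING, 1065),
    (LOC_LIVING, 1095),
    (LOC_TOILET, 1350),   # 22:30
    (LOC_BEDROOM, 1360),
)

#: Morning-routine hour targeted by the frequency-preserving anomaly mode;
#: its schedule boundaries are frozen (no jitter) in that mode so the hour's
#: per-location minute totals are identical on every day.
FREQ_PRESERVING_HOUR = 8
_FREQ_FROZEN_BOUNDARIES = {480, 490, 492, 525}

VISITOR_CYCLE = (LOC_LIVING, LOC_CORRIDOR, LOC_KITCHEN)
SLEEP_CYCLE = (LOC_BEDROOM, LOC_TOILET, LOC_CORRIDOR, LOC_KITCHEN)

ANOMALY_KINDS = ("visitor", "irregular_sleep", "both", "frequency_preserving")


@dataclass(frozen=True)
class AnomalySpec:
    """One injected anomalous day."""

    day: int
    kind: str
    visitor_hour: int | None = None
    sleep_hours: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ANOMALY_KINDS:
            raise ValueError(f"unknown anomaly kind {self.kind!r}")
        if self.kind in ("visitor", "both") and self.visitor_hour is None:
            raise ValueError(f"day {self.day}: {self.kind} needs a visitor_hour")
        if self.kind in ("irregular_sleep", "both") and not self.sleep_hours:
            raise ValueError(f"day {self.day}: {self.kind} needs sleep_hours")
        hours = self.hours()
        if len(hours) != len(set(hours)):
            raise ValueError(f"day {self.day}: overlapping injected hours {hours}")
        if any(not 0 <= h <= 23 for h in hours):
            raise ValueError(f"day {self.day}: hour out of range in {hours}")

    def hours(self) -> tuple[int, ...]:
        if self.kind == "frequency_preserving":
            return (FREQ_PRESERVING_HOUR,)
        out: list[int] = []
        if self.visitor_hour is not None:
            out.append(self.visitor_hour)
        out.extend(self.sleep_hours)
        return tuple(sorted(out))


def study_profile_anomalies() -> tuple[AnomalySpec, ...]:
    """The packaged 9-day / 13-hour anomaly schedule of the default fixture:
    three visitor-only days, three irregular-sleep days, and three days with
    both causes (one of them carrying two nocturnal hours)."""
    return (
        AnomalySpec(16, "visitor", visitor_hour=9),
        AnomalySpec(25, "both", visitor_hour=13, sleep_hours=(3,)),
        AnomalySpec(29, "irregular_sleep", sleep_hours=(3,)),
        AnomalySpec(33, "visitor", visitor_hour=11),
        AnomalySpec(38, "irregular_sleep", sleep_hours=(2,)),
        AnomalySpec(42, "both", visitor_hour=10, sleep_hours=(2,)),
        AnomalySpec(49, "irregular_sleep", sleep_hours=(3,)),
        AnomalySpec(52, "visitor", visitor_hour=10),
        AnomalySpec(63, "both", visitor_hour=12, sleep_hours=(2, 4)),
    )


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; the seed fixes the output byte-for-byte."""

    n_days: int = 65
    anomalies: tuple[AnomalySpec, ...] = field(
        default_factory=study_profile_anomalies
    )
    seed: int = 42
    start_date: date = date(2020, 1, 1)
    boundary_jitter_seconds: int = 300
    burst_dwell_seconds: int = 120
    extra_evening_door_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        days = [a.day for a in self.anomalies]
        if len(days) != len(set(days)):
            raise ValueError(f"duplicate anomalous days: {sorted(days)}")
        bad = [d for d in days if not 1 <= d <= self.n_days]
        if bad:
            raise ValueError(f"anomalous days outside 1..{self.n_days}: {bad}")
        if self.burst_dwell_seconds < 60:
            raise ValueError("burst dwell must be >= 60 s (one encoded minute)")


def study_profile_config(
    seed: int = 42, n_days: int = 65, **overrides
) -> SimConfig:
    """65 days, 56 normal + 9 anomalous carrying 13 abnormal hours.

    A smaller ``n_days`` keeps only the anomalies that fit the span.
    """
    anomalies = tuple(a for a in study_profile_anomalies() if a.day <= n_days)
    return SimConfig(seed=seed, n_days=n_days, anomalies=anomalies, **overrides)


def frequency_preserving_config(
    seed: int = 42, n_days: int = 16, anomaly_days: Sequence[int] = (6, 12)
) -> SimConfig:
    """Small fixture whose anomalies permute dwell order inside the
    morning-routine hour without changing symbol frequencies."""
    return SimConfig(
        n_days=n_days,
        anomalies=tuple(
            AnomalySpec(d, "frequency_preserving") for d in anomaly_days
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(config: SimConfig) -> tuple[EventLog, LabelSet]:
    """Simulate the full activity + door log with ground-truth labels."""
    rng = np.random.default_rng(config.seed)
    freq_mode = any(a.kind == "frequency_preserving" for a in config.anomalies)
    anomalies = {a.day: a for a in config.anomalies}

    events: list[ActivityEvent] = []
    door_events: list[DoorEvent] = []
    day_labels: dict[int, str] = {}
    hour_labels: dict[tuple[int, int], str] = {}

    for day in range(1, config.n_days + 1):
        day_start = datetime.combine(
            config.start_date + timedelta(days=day - 1), time.min
        )
        intervals, day_doors = _normal_day(rng, config, freq_mode)
        spec = anomalies.get(day)
        if spec is not None:
            intervals, day_doors = _inject(rng, config, spec, intervals, day_doors)
        for start_s, end_s, loc in intervals:
            events.append(
                ActivityEvent(
                    day_start + timedelta(seconds=int(start_s)),
                    day_start + timedelta(seconds=int(end_s)),
                    loc,
                )
            )
        for t_s, action in day_doors:
            door_events.append(
                DoorEvent(day_start + timedelta(seconds=int(t_s)), action)
            )
        day_labels[day] = ABNORMAL if spec is not None else NORMAL
        injected = set(spec.hours()) if spec is not None else set()
        for hour in range(24):
            hour_labels[(day, hour)] = ABNORMAL if hour in injected else NORMAL

    log = EventLog(
        events=events,
        door_events=sorted(door_events),
        day_index_origin=config.start_date,
    )
    labels = LabelSet(day_labels=day_labels, hour_labels=hour_labels)
    return log, labels


def _normal_day(
    rng: np.random.Generator, config: SimConfig, freq_mode: bool
) -> tuple[list[tuple[int, int, str]], list[tuple[int, str]]]:
    """One jittered routine day: interval list (seconds) + door events."""
    jit = config.boundary_jitter_seconds
    bounds = [s * 60 for _, s in DEFAULT_SCHEDULE] + [1440 * 60]
    for i in range(1, len(bounds) - 1):
        nominal_min = DEFAULT_SCHEDULE[i][1]
        if freq_mode and nominal_min in _FREQ_FROZEN_BOUNDARIES:
            continue  # keep the morning-hour composition identical every day
        bounds[i] += int(rng.integers(-jit, jit + 1))
    for i in range(1, len(bounds)):
        bounds[i] = max(bounds[i], bounds[i - 1] + 60)

    intervals: list[tuple[int, int, str]] = []
    door: list[tuple[int, str]] = []
    for i, (loc, _) in enumerate(DEFAULT_SCHEDULE):
        start, end = bounds[i], bounds[i + 1]
        gap = int(rng.integers(5, 21))
        if loc is None:
            # outing: resident leaves and returns through the main door
            door.append((start, "open"))
            door.append((start + int(rng.integers(15, 40)), "close"))
            door.append((end - int(rng.integers(30, 60)), "open"))
            door.append((end - int(rng.integers(5, 15)), "close"))
            continue
        intervals.append((start, max(start + 60, end - gap), loc))
    if rng.random() < config.extra_evening_door_prob:
        t = 1230 * 60 + int(rng.integers(-1800, 1801))  # around 20:30
        door.append((t, "open"))
        door.append((t + int(rng.integers(20, 60)), "close"))
    return intervals, sorted(door)


def _clip(
    intervals: list[tuple[int, int, str]], w0: int, w1: int
) -> list[tuple[int, int, str]]:
    """Remove the window [w0, w1) from an interval list."""
    out: list[tuple[int, int, str]] = []
    for start, end, loc in intervals:
        if end <= w0 or start >= w1:
            out.append((start, end, loc))
            continue
        if start < w0:
            out.append((start, w0, loc))
        if end > w1:
            out.append((w1, end, loc))
    return out


def _burst(
    rng: np.random.Generator,
    config: SimConfig,
    w0: int,
    w1: int,
    cycle: Sequence[str],
) -> list[tuple[int, int, str]]:
    """Dense irregular transition burst filling [w0, w1): short random
    dwells, each in a random room different from the previous one.

    Aperiodicity matters: a strictly periodic room cycle would be highly
    self-similar and score LOW on the template measures.  Dwell lengths are
    drawn around config.burst_dwell_seconds but kept >= 70 s so every dwell
    covers at least one minute-grid point after the inter-event gap.
    """
    lo = max(70, config.burst_dwell_seconds - 50)
    hi = config.burst_dwell_seconds + 30
    out = []
    t = w0
    prev = None
    while t < w1:
        end = t + int(rng.integers(lo, hi + 1))
        if end + lo > w1:
            end = w1  # absorb a short remainder into the final dwell
        gap = int(rng.integers(3, 11))
        room = str(rng.choice([c for c in cycle if c != prev]))
        out.append((t, max(t + 60, end - gap), room))
        prev = room
        t = end
    return out


def _freq_preserving_hour(
    intervals: list[tuple[int, int, str]], w0: int, w1: int
) -> list[tuple[int, int, str]]:
    """Re-order the window's dwell at 1-minute granularity, preserving each
    location's minute total (greedy max-remaining interleave)."""
    minutes: dict[str, int] = {}
    for start, end, loc in intervals:
        lo, hi = max(start, w0), min(end, w1)
        if lo < hi:
            # minute-start sampling: count minute grid points in [lo, hi)
            first = -(-lo // 60)
            last = -(-hi // 60)
            if last > first:
                minutes[loc] = minutes.get(loc, 0) + (last - first)
    total = sum(minutes.values())
    order: list[str] = []
    prev = None
    remaining = dict(minutes)
    for _ in range(total):
        candidates = sorted(
            (loc for loc, c in remaining.items() if c > 0 and loc != prev),
            key=lambda loc: (-remaining[loc], loc),
        )
        if not candidates:  # forced repetition of the majority location
            candidates = sorted(
                (loc for loc, c in remaining.items() if c > 0),
                key=lambda loc: (-remaining[loc], loc),
            )
        loc = candidates[0]
        order.append(loc)
        remaining[loc] -= 1
        prev = loc
    out = _clip(intervals, w0, w1)
    base = -(-w0 // 60) * 60  # first minute-grid point in the window
    for i, loc in enumerate(order):
        out.append((base + i * 60, base + i * 60 + 55, loc))
    return out


def _inject(
    rng: np.random.Generator,
    config: SimConfig,
    spec: AnomalySpec,
    intervals: list[tuple[int, int, str]],
    door: list[tuple[int, str]],
) -> tuple[list[tuple[int, int, str]], list[tuple[int, str]]]:
    door = list(door)
    if spec.kind == "frequency_preserving":
        h = FREQ_PRESERVING_HOUR
        intervals = _freq_preserving_hour(intervals, h * 3600, (h + 1) * 3600)
    else:
        for h in spec.sleep_hours:
            w0, w1 = h * 3600, (h + 1) * 3600
            intervals = _clip(intervals, w0, w1) + _burst(
                rng, config, w0, w1, SLEEP_CYCLE
            )
        if spec.visitor_hour is not None:
            h = spec.visitor_hour
            w0, w1 = h * 3600, (h + 1) * 3600
            intervals = _clip(intervals, w0, w1) + _burst(
                rng, config, w0, w1, VISITOR_CYCLE
            )
            # exactly one open/close pair marking the visit, inside the hour
            door.append((w0 + 180 + int(rng.integers(0, 60)), "open"))
            door.append((w0 + 2820 + int(rng.integers(0, 180)), "close"))
    return sorted(intervals), sorted(door)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def count_transitions(window: np.ndarray) -> int:
    """Number of symbol changes between consecutive samples of a window."""
    arr = np.asarray(window)
    return int(np.sum(arr[1:] != arr[:-1]))


def describe(config: SimConfig) -> str:
    """Human-readable summary of a simulation configuration."""
    lines = [
        f"{config.n_days} days starting {config.start_date.isoformat()}, "
        f"seed {config.seed}",
        f"normal days: {config.n_days - len(config.anomalies)}, "
        f"anomalous days: {len(config.anomalies)} "
        f"({sum(len(a.hours()) for a in config.anomalies)} abnormal hours)",
    ]
    for a in sorted(config.anomalies, key=lambda a: a.day):
        lines.append(f"  day {a.day}: {a.kind} at hours {list(a.hours())}")
    return "\n".join(lines)
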