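"""Cause attribution for entropy-flagged hours via the main-door sensor.

A flagged hour co-occurring with door activity (open or close, treated
symmetrically) is attributed to a visitor; a flagged hour with no door
activity is an irregular pattern of the resident, reported as irregular
sleep in the day summary when it falls in the configured night window.
Door events alone never create an anomaly — only hours already flagged by
the entropy detector are labeled.

Visit intervals are bracketed inside each visitor hour by pairing door
events in order (first with second, third with fourth, ...); a trailing
unpaired event yields an open-ended interval flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Iterable, Sequence

from .detection import DetectionResult
from .event_io import DoorEvent, TIMESTAMP_FORMAT

__all__ = [
    "CAUSE_VISITOR",
    "CAUSE_IRREGULAR",
    "HourAttribution",
    "VisitInterval",
    "AttributionReport",
    "attribute_hours",
    "extract_visit_intervals",
]

CAUSE_VISITOR = "visitor"
CAUSE_IRREGULAR = "irregular_pattern"

#: Default night window (inclusive start hour, exclusive end hour, wrapping
#: midnight): non-visitor anomalies inside it are summarised as irregular sleep.
DEFAULT_NIGHT_WINDOW = (22, 7)


@dataclass(frozen=True)
class HourAttribution:
    day: int
    hour: int
    cause: str  # CAUSE_VISITOR or CAUSE_IRREGULAR
    door_events: tuple[DoorEvent, ...] = ()
    nocturnal: bool = False

    def to_dict(self) -> dict:
        return {
            "day": self.day,
            "hour": self.hour,
            "cause": self.cause,
            "nocturnal": self.nocturnal,
            "door_events": [
                {"time": e.time.strftime(TIMESTAMP_FORMAT), "action": e.action}
                for e in self.door_events
            ],
        }


@dataclass(frozen=True)
class VisitInterval:
    day: int
    start: datetime
    end: datetime | None  # None when the bracketing event is missing
    open_ended: bool = False

    def to_dict(self) -> dict:
        return {
            "day": self.day,
            "start": self.start.strftime(TIMESTAMP_FORMAT),
            "end": None if self.end is None else self.end.strftime(TIMESTAMP_FORMAT),
            "open_ended": self.open_ended,
        }


@dataclass
class AttributionReport:
    """Per-hour causes, per-day summaries and bracketed visit intervals."""

    hours: list[HourAttribution]
    day_summaries: dict[int, str]
    visits: list[VisitInterval]
    measure: str

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "hours": [h.to_dict() for h in self.hours],
            "day_summaries": {str(d): s for d, s in self.day_summaries.items()},
            "visits": [v.to_dict() for v in self.visits],
        }


def _in_night_window(hour: int, night_window: tuple[int, int]) -> bool:
    start, end = night_window
    if start <= end:
        return start <= hour < end
    return hour >= start or hour < end  # wraps midnight


def attribute_hours(
    result: DetectionResult,
    door_events: Sequence[DoorEvent],
    day_index_origin: date,
    measure: str = "FuzzyEn",
    tolerance_minutes: float = 0.0,
    night_window: tuple[int, int] = DEFAULT_NIGHT_WINDOW,
) -> AttributionReport:
    """Label each detected anomalous hour as visitor or irregular pattern.

    An hour is visitor-caused iff at least one door event falls inside
    [hour start - tolerance, hour end + tolerance].  The day summary is the
    union of its hour causes: ``visitor``, ``irregular_sleep`` (non-visitor
    hours in the night window), ``irregular_pattern`` (non-visitor daytime
    hours), or the ``..._and_visitor`` combinations.  An empty door log
    makes every anomaly an irregular pattern.
    """
    if measure not in result.anomalous_hours:
        raise ValueError(
            f"measure {measure!r} not present in detection result "
            f"(have {sorted(result.anomalous_hours)})"
        )
    tol = timedelta(minutes=tolerance_minutes)
    door_events = sorted(door_events)

    hours: list[HourAttribution] = []
    for day, hour in sorted(result.anomalous_hours[measure]):
        day_start = datetime.combine(
            day_index_origin + timedelta(days=day - 1), time.min
        )
        lo = day_start + timedelta(hours=hour) - tol
        hi = day_start + timedelta(hours=hour + 1) + tol
        inside = tuple(e for e in door_events if lo <= e.time < hi)
        cause = CAUSE_VISITOR if inside else CAUSE_IRREGULAR
        hours.append(
            HourAttribution(
                day=day,
                hour=hour,
                cause=cause,
                door_events=inside,
                nocturnal=_in_night_window(hour, night_window),
            )
        )

    day_summaries: dict[int, str] = {}
    for day in sorted({h.day for h in hours}):
        day_hours = [h for h in hours if h.day == day]
        has_visitor = any(h.cause == CAUSE_VISITOR for h in day_hours)
        irregular = [h for h in day_hours if h.cause == CAUSE_IRREGULAR]
        # nocturnal irregularity dominates the wording when both occur
        if any(h.nocturnal for h in irregular):
            base = "irregular_sleep"
        elif irregular:
            base = "irregular_pattern"
        else:
            base = None
        if base and has_visitor:
            day_summaries[day] = f"{base}_and_visitor"
        elif base:
            day_summaries[day] = base
        else:
            day_summaries[day] = CAUSE_VISITOR

    visits = extract_visit_intervals(door_events, hours)
    return AttributionReport(
        hours=hours, day_summaries=day_summaries, visits=visits, measure=measure
    )


def extract_visit_intervals(
    door_events: Sequence[DoorEvent],
    attributed_hours: Iterable[HourAttribution],
) -> list[VisitInterval]:
    """Bracket visits inside visitor-attributed hours.

    Within each such hour the supporting door events are paired in order
    (1st with 2nd, 3rd with 4th, ...); a trailing unpaired event becomes an
    open-ended interval.
    """
    visits: list[VisitInterval] = []
    for hour in attributed_hours:
        if hour.cause != CAUSE_VISITOR:
            continue
        events = sorted(hour.door_events)
        for i in range(0, len(events) - 1, 2):
            visits.append(
                VisitInterval(
                    day=hour.day, start=events[i].time, end=events[i + 1].time
                )
            )
        if len(events) % 2 == 1:
            visits.append(
                VisitInterval(
                    day=hour.day, start=events[-1].time, end=None, open_ended=True
                )
            )
    return visits
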