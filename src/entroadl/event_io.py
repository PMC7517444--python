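"""Reading, validating and writing ambient-sensor event logs.

Three on-disk record kinds, all plain CSV (comma-separated, UTF-8, header
required, timestamps ``YYYY-MM-DD HH:MM:SS``):

* activity log — ``start_time,end_time,activity``: one row per dwelling
  interval derived from PIR occupancy (which room the resident was in, and
  for how long);
* door log — ``time,action``: main-door entry sensor events, ``action`` in
  {``open``, ``close``};
* labels — ``day,hour,label``: ground-truth normal/abnormal annotations at
  day level (``hour`` empty) and hour level.

The single-resident assumption makes simultaneous locations meaningless, so
overlapping activity intervals are rejected rather than clipped.  Gaps
between intervals are allowed (resident out of home, or sensors silent) and
are resolved downstream by the encoder.  Day 1 is the first calendar date in
the log; day boundaries are midnight-to-midnight.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ActivityEvent",
    "DoorEvent",
    "EventLog",
    "LabelSet",
    "LogFormatError",
    "LogValidationError",
    "read_activity_log",
    "read_door_log",
    "read_labels",
    "write_activity_log",
    "write_door_log",
    "write_labels",
    "write_report",
    "read_report",
]

TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S"

DOOR_ACTIONS = ("open", "close")

NORMAL = "normal"
ABNORMAL = "abnormal"


class LogFormatError(ValueError):
    """A file could not be parsed (bad header, malformed timestamp...)."""


class LogValidationError(ValueError):
    """Parsed records violate an invariant (overlap, end <= start...)."""


def _parse_timestamp(text: str, path: Path, line_no: int) -> datetime:
    try:
        return datetime.strptime(text.strip(), TIMESTAMP_FORMAT)
    except ValueError as exc:
        raise LogFormatError(
            f"{path}, line {line_no}: malformed timestamp {text!r} "
            f"(expected {TIMESTAMP_FORMAT.replace('%', '')!r} form)"
        ) from exc


@dataclass(frozen=True, order=True)
class ActivityEvent:
    """One sensor-derived dwelling interval: the resident was at `location`
    during [start, end)."""

    start: datetime
    end: datetime
    location: str

    def __post_init__(self) -> None:
        if not self.location:
            raise LogValidationError("ActivityEvent.location must be non-empty")
        if self.start >= self.end:
            raise LogValidationError(
                f"ActivityEvent end must be after start: "
                f"{self.start} >= {self.end} ({self.location})"
            )

    @property
    def duration_seconds(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass(frozen=True, order=True)
class DoorEvent:
    """A main-door entry-sensor event."""

    time: datetime
    action: str

    def __post_init__(self) -> None:
        if self.action not in DOOR_ACTIONS:
            raise LogValidationError(
                f"DoorEvent action must be one of {DOOR_ACTIONS}, "
                f"got {self.action!r}"
            )


@dataclass
class EventLog:
    """A validated, chronologically sorted collection of activity intervals
    and door events for one dwelling.

    ``day_index_origin`` is the calendar date of day 1 (the first date
    covered by the log); days are indexed 1-based, midnight to midnight.
    """

    events: list[ActivityEvent]
    door_events: list[DoorEvent] = field(default_factory=list)
    day_index_origin: date | None = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events)
        self.door_events = sorted(self.door_events)
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.start < prev.end:
                raise LogValidationError(
                    "overlapping activity intervals: "
                    f"[{prev.start} .. {prev.end}] {prev.location!r} and "
                    f"[{cur.start} .. {cur.end}] {cur.location!r}"
                )
        if self.day_index_origin is None and self.events:
            self.day_index_origin = self.events[0].start.date()

    @property
    def n_days(self) -> int:
        """Number of calendar days spanned, from day_index_origin through the
        last instant covered by any event."""
        if not self.events:
            return 0
        last = max(self.events[-1].end, self.events[-1].start)
        # an interval ending exactly at midnight does not open a new day
        last_date = (last - timedelta(seconds=1)).date()
        return (last_date - self.day_index_origin).days + 1

    def day_date(self, day_index: int) -> date:
        if self.day_index_origin is None:
            raise LogValidationError("empty log has no day origin")
        return self.day_index_origin + timedelta(days=day_index - 1)

    def locations(self) -> set[str]:
        return {e.location for e in self.events}


@dataclass
class LabelSet:
    """Ground-truth normal/abnormal annotations.

    ``day_labels`` maps day index -> label; ``hour_labels`` maps
    (day index, hour 0-23) -> label.  Every labeled hour's day must itself be
    labeled, and an abnormal day must contain at least one abnormal hour.
    """

    day_labels: dict[int, str]
    hour_labels: dict[tuple[int, int], str]

    def __post_init__(self) -> None:
        for label in list(self.day_labels.values()) + list(self.hour_labels.values()):
            if label not in (NORMAL, ABNORMAL):
                raise LogValidationError(f"unknown label {label!r}")
        for (day, hour) in self.hour_labels:
            if day not in self.day_labels:
                raise LogValidationError(
                    f"hour label for day {day} hour {hour} but day {day} unlabeled"
                )
            if not 0 <= hour <= 23:
                raise LogValidationError(f"hour out of range: {hour}")
        for day, label in self.day_labels.items():
            if label == ABNORMAL:
                if not any(
                    d == day and lab == ABNORMAL
                    for (d, _), lab in self.hour_labels.items()
                ):
                    raise LogValidationError(
                        f"abnormal day {day} has no abnormal hour in ground truth"
                    )

    def normal_days(self) -> list[int]:
        return sorted(d for d, lab in self.day_labels.items() if lab == NORMAL)

    def abnormal_days(self) -> list[int]:
        return sorted(d for d, lab in self.day_labels.items() if lab == ABNORMAL)

    def abnormal_hours(self) -> list[tuple[int, int]]:
        return sorted(k for k, lab in self.hour_labels.items() if lab == ABNORMAL)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _open_csv(path: str | Path, expected_header: Sequence[str]):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    handle = path.open(newline="", encoding="utf-8")
    reader = csv.reader(handle)
    try:
        header = next(reader)
    except StopIteration:
        handle.close()
        raise LogFormatError(f"{path}: empty file, header row required")
    if [h.strip().lower() for h in header] != list(expected_header):
        handle.close()
        raise LogFormatError(
            f"{path}: expected header {','.join(expected_header)!r}, "
            f"got {','.join(header)!r}"
        )
    return path, handle, reader


def read_activity_log(path: str | Path) -> EventLog:
    """Read an activity-interval CSV into a validated, sorted EventLog.

    Raises LogFormatError for malformed rows (naming the line) and
    LogValidationError for ordering/overlap violations.
    """
    path, handle, reader = _open_csv(path, ("start_time", "end_time", "activity"))
    events: list[ActivityEvent] = []
    with handle:
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise LogFormatError(
                    f"{path}, line {line_no}: expected 3 fields, got {len(row)}"
                )
            start = _parse_timestamp(row[0], path, line_no)
            end = _parse_timestamp(row[1], path, line_no)
            location = row[2].strip()
            if not location:
                raise LogFormatError(f"{path}, line {line_no}: empty activity label")
            if start >= end:
                raise LogValidationError(
                    f"{path}, line {line_no}: end_time {row[1].strip()!r} is not "
                    f"after start_time {row[0].strip()!r}"
                )
            events.append(ActivityEvent(start, end, location))
    return EventLog(events=events)


def read_door_log(path: str | Path) -> list[DoorEvent]:
    """Read a door-sensor CSV into a sorted list of DoorEvent."""
    path, handle, reader = _open_csv(path, ("time", "action"))
    events: list[DoorEvent] = []
    with handle:
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 2:
                raise LogFormatError(
                    f"{path}, line {line_no}: expected 2 fields, got {len(row)}"
                )
            time = _parse_timestamp(row[0], path, line_no)
            action = row[1].strip().lower()
            if action not in DOOR_ACTIONS:
                raise LogFormatError(
                    f"{path}, line {line_no}: unknown door action {action!r} "
                    f"(expected one of {DOOR_ACTIONS})"
                )
            events.append(DoorEvent(time, action))
    return sorted(events)


def read_labels(path: str | Path) -> LabelSet:
    """Read a ground-truth label CSV (day-level rows have an empty hour)."""
    path, handle, reader = _open_csv(path, ("day", "hour", "label"))
    day_labels: dict[int, str] = {}
    hour_labels: dict[tuple[int, int], str] = {}
    with handle:
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise LogFormatError(
                    f"{path}, line {line_no}: expected 3 fields, got {len(row)}"
                )
            try:
                day = int(row[0])
            except ValueError:
                raise LogFormatError(
                    f"{path}, line {line_no}: bad day index {row[0]!r}"
                ) from None
            label = row[2].strip().lower()
            if row[1].strip() == "":
                day_labels[day] = label
            else:
                try:
                    hour = int(row[1])
                except ValueError:
                    raise LogFormatError(
                        f"{path}, line {line_no}: bad hour {row[1]!r}"
                    ) from None
                hour_labels[(day, hour)] = label
    return LabelSet(day_labels=day_labels, hour_labels=hour_labels)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_activity_log(log: EventLog, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["start_time", "end_time", "activity"])
        for event in log.events:
            writer.writerow(
                [
                    event.start.strftime(TIMESTAMP_FORMAT),
                    event.end.strftime(TIMESTAMP_FORMAT),
                    event.location,
                ]
            )


def write_door_log(events: Iterable[DoorEvent], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["time", "action"])
        for event in sorted(events):
            writer.writerow([event.time.strftime(TIMESTAMP_FORMAT), event.action])


def write_labels(labels: LabelSet, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["day", "hour", "label"])
        for day in sorted(labels.day_labels):
            writer.writerow([day, "", labels.day_labels[day]])
        for day, hour in sorted(labels.hour_labels):
            writer.writerow([day, hour, labels.hour_labels[(day, hour)]])


def write_report(report: Mapping | object, path: str | Path) -> None:
    """Serialise an attribution report (or any report mapping) to JSON.

    Accepts either a plain mapping or an object with a ``to_dict`` method;
    the document round-trips losslessly through :func:`read_report`.
    """
    if hasattr(report, "to_dict"):
        payload = report.to_dict()
    else:
        payload = report
    with Path(path).open("w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_report(path: str | Path) -> dict:
    with Path(path).open(encoding="utf-8") as handle:
        return json.load(handle)
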