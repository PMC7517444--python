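"""Two-stage max-over-normal-days anomaly detection.

Stage one computes each measure on the full 1440-sample day vectors,
calibrates a per-measure daily threshold as the maximum value over the
labeled normal days, and flags every day whose value strictly exceeds it.
Stage two recomputes the measures on 60-sample hourly windows, calibrates
an hourly threshold as the maximum over all hourly windows of the normal
days (a single scalar per measure), and — within the flagged days only —
flags every hour strictly above it.

Strict ``>`` everywhere: a calibration day can tie its own maximum but can
never flag itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .encoding import EncodedSeries, slice_hour
from .entropy import MEASURES, EntropyParams, compute_measure

__all__ = [
    "EntropyProfile",
    "ThresholdModel",
    "DetectionResult",
    "compute_profile",
    "calibrate",
    "detect",
]

ALL_MEASURES = tuple(MEASURES)


@dataclass
class EntropyProfile:
    """Per-measure entropy values on daily and hourly windows.

    ``daily``: DataFrame indexed by day, one column per measure.
    ``hourly``: DataFrame indexed by (day, hour), one column per measure.
    """

    daily: pd.DataFrame
    hourly: pd.DataFrame
    params: EntropyParams

    def __post_init__(self) -> None:
        days = list(self.daily.index)
        if days != list(range(min(days), max(days) + 1)):
            raise ValueError(f"daily profile has gaps in its day coverage: {days}")
        expected = {(d, h) for d in days for h in range(24)}
        if set(self.hourly.index) != expected:
            raise ValueError("hourly profile grid incomplete")

    @property
    def measures(self) -> tuple[str, ...]:
        return tuple(self.daily.columns)

    @property
    def days(self) -> list[int]:
        return list(self.daily.index)


@dataclass
class ThresholdModel:
    """Per-measure maxima over the normal-day calibration set."""

    daily: dict[str, float]
    hourly: dict[str, float]
    calibration_days: list[int]


@dataclass
class DetectionResult:
    """Flagged days and hours per measure."""

    anomalous_days: dict[str, set[int]]
    anomalous_hours: dict[str, set[tuple[int, int]]]
    thresholds: ThresholdModel | None = None

    def __post_init__(self) -> None:
        for measure, hours in self.anomalous_hours.items():
            days = self.anomalous_days.get(measure, set())
            stray = {(d, h) for d, h in hours if d not in days}
            if stray:
                raise ValueError(
                    f"{measure}: anomalous hours outside anomalous days: {stray}"
                )


def compute_profile(
    series_by_day: Mapping[int, EncodedSeries] | Sequence[EncodedSeries],
    params: EntropyParams | None = None,
    measures: Iterable[str] = ALL_MEASURES,
) -> EntropyProfile:
    """Evaluate the chosen measures on every day (1440 samples) and every
    hourly window (60 samples) of the encoded dataset."""
    params = params or EntropyParams()
    measures = list(measures)
    unknown = [m for m in measures if m not in MEASURES]
    if unknown:
        raise ValueError(f"unknown measures: {unknown}")
    if not isinstance(series_by_day, Mapping):
        series_by_day = {s.day_index: s for s in series_by_day}
    days = sorted(series_by_day)
    if not days:
        raise ValueError("no encoded days to profile")
    if days != list(range(days[0], days[-1] + 1)):
        raise ValueError(f"missing days in input: have {days}")

    daily_rows = {}
    hourly_rows = {}
    for day in days:
        series = series_by_day[day]
        daily_rows[day] = {
            m: compute_measure(m, series.values, params) for m in measures
        }
        for hour in range(24):
            window = slice_hour(series, hour)
            hourly_rows[(day, hour)] = {
                m: compute_measure(m, window, params) for m in measures
            }
    daily = pd.DataFrame.from_dict(daily_rows, orient="index").loc[days, measures]
    daily.index.name = "day"
    hourly = pd.DataFrame.from_dict(hourly_rows, orient="index").loc[:, measures]
    hourly.index = pd.MultiIndex.from_tuples(hourly.index, names=["day", "hour"])
    return EntropyProfile(daily=daily, hourly=hourly, params=params)


def calibrate(profile: EntropyProfile, normal_days: Iterable[int]) -> ThresholdModel:
    """Thresholds = per-measure maxima of the normal days.

    daily threshold: max daily value over the calibration days;
    hourly threshold: max over all 24 x |calibration days| hourly windows.
    """
    normal_days = sorted(set(normal_days))
    if not normal_days:
        raise ValueError("calibration requires at least one normal day")
    missing = [d for d in normal_days if d not in profile.daily.index]
    if missing:
        raise ValueError(f"calibration days missing from profile: {missing}")
    daily = profile.daily.loc[normal_days].max().to_dict()
    hourly_sub = profile.hourly.loc[
        profile.hourly.index.get_level_values("day").isin(normal_days)
    ]
    hourly = hourly_sub.max().to_dict()
    return ThresholdModel(
        daily={k: float(v) for k, v in daily.items()},
        hourly={k: float(v) for k, v in hourly.items()},
        calibration_days=normal_days,
    )


def detect(
    profile: EntropyProfile,
    thresholds: ThresholdModel,
    scan_all_hours: bool = False,
) -> DetectionResult:
    """Flag days strictly above the daily threshold, then hours strictly
    above the hourly threshold within those days.

    ``scan_all_hours=True`` lifts the day gate and scans every hour of every
    day (exploratory use).
    """
    anomalous_days: dict[str, set[int]] = {}
    anomalous_hours: dict[str, set[tuple[int, int]]] = {}
    for measure in profile.measures:
        if measure not in thresholds.daily or measure not in thresholds.hourly:
            raise ValueError(f"thresholds missing for measure {measure!r}")
        day_thr = thresholds.daily[measure]
        hour_thr = thresholds.hourly[measure]
        flagged_days = {
            int(d) for d, v in profile.daily[measure].items() if v > day_thr
        }
        candidate_days = set(profile.days) if scan_all_hours else flagged_days
        flagged_hours = {
            (int(d), int(h))
            for (d, h), v in profile.hourly[measure].items()
            if d in candidate_days and v > hour_thr
        }
        if scan_all_hours:
            # keep the day/hour containment invariant
            flagged_days = flagged_days | {d for d, _ in flagged_hours}
        anomalous_days[measure] = flagged_days
        anomalous_hours[measure] = flagged_hours
    return DetectionResult(
        anomalous_days=anomalous_days,
        anomalous_hours=anomalous_hours,
        thresholds=thresholds,
    )
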