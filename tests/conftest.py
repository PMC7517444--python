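"""Shared fixtures: the worked-example day, the packaged synthetic
fixtures, and the entropy profiles derived from them."""

from __future__ import annotations

from datetime import datetime

import pytest

import entroadl as e
from entroadl import synthetic as syn


def _ts(text: str) -> datetime:
    return datetime.strptime(text, "%Y-%m-%d %H:%M:%S")


@pytest.fixture(scope="session")
def table2_hour_events() -> list[e.ActivityEvent]:
    """The worked-example hour: bedroom 5', corridor 1', toilet 4',
    corridor 1', living room 49' from 12:00, then kitchen 6'."""
    rows = [
        ("2020-01-01 12:00:00", "2020-01-01 12:05:00", "Bedroom-sleeping"),
        ("2020-01-01 12:05:00", "2020-01-01 12:06:00", "Corridor"),
        ("2020-01-01 12:06:00", "2020-01-01 12:10:00", "Toilet"),
        ("2020-01-01 12:10:00", "2020-01-01 12:11:00", "Corridor"),
        ("2020-01-01 12:11:00", "2020-01-01 13:00:00", "Living room"),
        ("2020-01-01 13:00:00", "2020-01-01 13:06:00", "Kitchen"),
    ]
    return [e.ActivityEvent(_ts(a), _ts(b), loc) for a, b, loc in rows]


@pytest.fixture(scope="session")
def table2_day_log(table2_hour_events) -> e.EventLog:
    """A full day that is constant (living room) except for the
    worked-example hour."""
    events = [
        e.ActivityEvent(
            _ts("2020-01-01 00:00:00"), _ts("2020-01-01 12:00:00"), "Living room"
        ),
        *table2_hour_events,
        e.ActivityEvent(
            _ts("2020-01-01 13:06:00"), _ts("2020-01-02 00:00:00"), "Living room"
        ),
    ]
    return e.EventLog(events=events)


@pytest.fixture(scope="session")
def study_fixture():
    """The packaged 65-day fixture: (log, labels) at the fixed seed."""
    return syn.generate(syn.study_profile_config(seed=42))


@pytest.fixture(scope="session")
def study_series(study_fixture):
    log, _ = study_fixture
    return e.encode_log(log)


@pytest.fixture(scope="session")
def fuzzyen_profile(study_series):
    return e.compute_profile(study_series, e.EntropyParams(), ["FuzzyEn"])


@pytest.fixture(scope="session")
def small_fixture():
    """A short dataset (20 days, one visitor day) for multi-measure tests."""
    log, labels = syn.generate(syn.study_profile_config(seed=7, n_days=20))
    series = e.encode_log(log)
    return log, labels, series


@pytest.fixture(scope="session")
def small_profile_all(small_fixture):
    _, _, series = small_fixture
    return e.compute_profile(series, e.EntropyParams(), list(e.MEASURES))
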