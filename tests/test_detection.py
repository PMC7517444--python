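"""Threshold calibration and the two-stage day/hour detection logic."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

import entroadl as e
from entroadl.detection import DetectionResult, EntropyProfile, ThresholdModel


def _profile_from_values(daily: dict, hourly_base: float = 0.0) -> EntropyProfile:
    """Single-measure profile with given daily values and flat hourly grid."""
    days = sorted(daily)
    daily_df = pd.DataFrame({"FuzzyEn": [daily[d] for d in days]}, index=days)
    daily_df.index.name = "day"
    idx = pd.MultiIndex.from_tuples(
        [(d, h) for d in days for h in range(24)], names=["day", "hour"]
    )
    hourly_df = pd.DataFrame({"FuzzyEn": hourly_base}, index=idx)
    return EntropyProfile(daily=daily_df, hourly=hourly_df, params=e.EntropyParams())


class TestComputeProfile:
    def test_constant_day_gives_zero_everywhere(self):
        log = e.EventLog(
            events=[
                e.ActivityEvent(
                    datetime(2020, 1, 1), datetime(2020, 1, 2), "Living room"
                )
            ]
        )
        series = e.encode_log(log)
        profile = e.compute_profile(series, e.EntropyParams(), list(e.MEASURES))
        assert np.allclose(profile.daily.to_numpy(), 0.0)
        assert np.allclose(profile.hourly.to_numpy(), 0.0)

    def test_worked_example_hour_dominates_a_constant_day(self, table2_day_log):
        series = e.encode_log(table2_day_log)
        profile = e.compute_profile(
            series, e.EntropyParams(), ["ShEn", "FuzzyEn", "PerEn"]
        )
        for measure in ("ShEn", "FuzzyEn"):
            hourly = profile.hourly[measure]
            busy = hourly.loc[(1, 12)]
            others = hourly.drop(index=(1, 12))
            assert busy > others.max()
        # PerEn at m=2 only distinguishes rises from falls (ties rank as
        # rises), and both the busy hour and the 13:00 kitchen hour contain
        # exactly one fall, so the busy hour ties rather than dominates
        peren = profile.hourly["PerEn"]
        assert peren.loc[(1, 12)] >= peren.drop(index=(1, 12)).max()

    def test_missing_day_gap_rejected(self, table2_day_log):
        series = e.encode_log(table2_day_log)
        series[3] = e.EncodedSeries(day_index=3, values=series[1].values)
        with pytest.raises(ValueError, match="missing"):
            e.compute_profile(series, e.EntropyParams(), ["ShEn"])

    def test_unknown_measure_rejected(self, table2_day_log):
        series = e.encode_log(table2_day_log)
        with pytest.raises(ValueError):
            e.compute_profile(series, e.EntropyParams(), ["NotAMeasure"])


class TestCalibrate:
    def test_daily_threshold_is_max_over_normal_days(self):
        profile = _profile_from_values({1: 1.0, 2: 1.2, 3: 0.9})
        model = e.calibrate(profile, [1, 2, 3])
        assert model.daily["FuzzyEn"] == pytest.approx(1.2)

    def test_single_normal_day(self):
        profile = _profile_from_values({1: 0.7, 2: 2.0}, hourly_base=0.3)
        model = e.calibrate(profile, [1])
        assert model.daily["FuzzyEn"] == pytest.approx(0.7)
        assert model.hourly["FuzzyEn"] == pytest.approx(0.3)
        assert model.calibration_days == [1]

    def test_empty_calibration_set_rejected(self):
        profile = _profile_from_values({1: 1.0})
        with pytest.raises(ValueError):
            e.calibrate(profile, [])

    def test_thresholds_match_an_independent_fold(self, fuzzyen_profile, study_fixture):
        _, labels = study_fixture
        normal = labels.normal_days()
        model = e.calibrate(fuzzyen_profile, normal)
        expected_daily = max(fuzzyen_profile.daily.loc[d, "FuzzyEn"] for d in normal)
        expected_hourly = max(
            fuzzyen_profile.hourly.loc[(d, h), "FuzzyEn"]
            for d in normal
            for h in range(24)
        )
        assert model.daily["FuzzyEn"] == pytest.approx(expected_daily)
        assert model.hourly["FuzzyEn"] == pytest.approx(expected_hourly)


class TestDetect:
    def test_all_values_at_or_below_threshold_gives_empty_result(self):
        profile = _profile_from_values({1: 1.0, 2: 1.0}, hourly_base=0.5)
        model = ThresholdModel(
            daily={"FuzzyEn": 1.0}, hourly={"FuzzyEn": 0.5}, calibration_days=[1, 2]
        )
        result = e.detect(profile, model)
        assert result.anomalous_days["FuzzyEn"] == set()
        assert result.anomalous_hours["FuzzyEn"] == set()

    def test_value_exactly_at_threshold_is_not_flagged(self):
        profile = _profile_from_values({1: 1.0, 2: 1.2})
        model = ThresholdModel(
            daily={"FuzzyEn": 1.2}, hourly={"FuzzyEn": 0.0}, calibration_days=[2]
        )
        assert e.detect(profile, model).anomalous_days["FuzzyEn"] == set()

    def test_no_calibration_day_is_self_flagged(self, fuzzyen_profile, study_fixture):
        _, labels = study_fixture
        model = e.calibrate(fuzzyen_profile, labels.normal_days())
        result = e.detect(fuzzyen_profile, model)
        assert not set(labels.normal_days()) & result.anomalous_days["FuzzyEn"]

    def test_raising_thresholds_never_adds_flags(self, fuzzyen_profile, study_fixture):
        _, labels = study_fixture
        model = e.calibrate(fuzzyen_profile, labels.normal_days())
        base = e.detect(fuzzyen_profile, model)
        raised = ThresholdModel(
            daily={k: v + 0.05 for k, v in model.daily.items()},
            hourly={k: v + 0.05 for k, v in model.hourly.items()},
            calibration_days=model.calibration_days,
        )
        higher = e.detect(fuzzyen_profile, raised)
        assert higher.anomalous_days["FuzzyEn"] <= base.anomalous_days["FuzzyEn"]
        assert higher.anomalous_hours["FuzzyEn"] <= base.anomalous_hours["FuzzyEn"]

    def test_detection_is_pure(self, fuzzyen_profile, study_fixture):
        _, labels = study_fixture
        model = e.calibrate(fuzzyen_profile, labels.normal_days())
        r1 = e.detect(fuzzyen_profile, model)
        r2 = e.detect(fuzzyen_profile, model)
        assert r1.anomalous_days == r2.anomalous_days
        assert r1.anomalous_hours == r2.anomalous_hours

    def test_hours_confined_to_flagged_days_unless_scanning_all(self):
        profile = _profile_from_values({1: 1.0, 2: 2.0}, hourly_base=0.5)
        model = ThresholdModel(
            daily={"FuzzyEn": 1.5}, hourly={"FuzzyEn": 0.4}, calibration_days=[1]
        )
        gated = e.detect(profile, model)
        assert gated.anomalous_days["FuzzyEn"] == {2}
        assert {d for d, _ in gated.anomalous_hours["FuzzyEn"]} == {2}
        full = e.detect(profile, model, scan_all_hours=True)
        assert {d for d, _ in full.anomalous_hours["FuzzyEn"]} == {1, 2}

    def test_result_invariant_hours_within_days(self):
        with pytest.raises(ValueError):
            DetectionResult(
                anomalous_days={"FuzzyEn": {1}},
                anomalous_hours={"FuzzyEn": {(2, 5)}},
            )
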