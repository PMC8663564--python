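import numpy as np
import pandas as pd
import pytest

import practicecurve as pc
from practicecurve.data_model import (ConfigurationError, InputDataError,
                                      UsageError, build_units,
                                      cohort_from_records)
from practicecurve.data_model import TestRecord as Record

from conftest import make_unit


def toy_csv(tmp_path, rows, name="toy.csv",
            header="floodlightOpenId,testName,handUsed,testStartedAt,"
                   "testMetricName,testResultMetricValue,age"):
    path = tmp_path / name
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


SDMT_ROWS = [
    "p1,e-SDMT,,2020-01-01,correctResponses,30,44",
    "p1,e-SDMT,,2020-01-08,correctResponses,34,44",
    "p1,e-SDMT,,2020-01-15,correctResponses,36,44",
]


class TestLoadCohort:
    def test_weekly_series_is_indexed_in_weeks(self, tmp_path):
        cohort = pc.load_cohort(toy_csv(tmp_path, SDMT_ROWS))
        assert len(cohort.units) == 1
        u = cohort.units[0]
        assert list(u.rep_index) == [1, 2, 3]
        assert np.allclose(u.t_weeks, [0.0, 1.0, 2.0])
        assert np.allclose(u.values, [30, 34, 36])
        assert cohort.participants["p1"] == 44.0

    def test_cutoff_date_drops_later_records(self, tmp_path):
        cohort = pc.load_cohort(toy_csv(tmp_path, SDMT_ROWS),
                                cutoff_date="2020-01-08")
        assert cohort.units[0].n_reps == 2

    def test_missing_mandatory_column_is_configuration_error(self, tmp_path):
        path = toy_csv(tmp_path, ["p1,e-SDMT,2020-01-01,30"],
                       header="floodlightOpenId,testName,testStartedAt,"
                              "testResultMetricValue")
        with pytest.raises(ConfigurationError, match="testMetricName"):
            pc.load_cohort(path)

    def test_no_parseable_rows_is_input_error(self, tmp_path):
        path = toy_csv(tmp_path, ["p1,NotATest,,2020-01-01,foo,30,"])
        with pytest.raises(InputDataError):
            pc.load_cohort(path)

    def test_malformed_rows_are_counted_not_fatal(self, tmp_path):
        rows = SDMT_ROWS + ["p1,e-SDMT,,not-a-date,correctResponses,31,",
                            "p1,e-SDMT,,2020-02-01,correctResponses,oops,"]
        cohort = pc.load_cohort(toy_csv(tmp_path, rows))
        assert cohort.units[0].n_reps == 3
        assert cohort.meta["n_rows_dropped"] == 2

    def test_hand_grouped_tests_split_units_and_normalize_labels(self, tmp_path):
        rows = [
            "p1,FingerPinching,LEFT,2020-01-01,successfulPinches,10,",
            "p1,FingerPinching,right,2020-01-03,successfulPinches,12,",
            "p1,FingerPinching,Left,2020-01-05,successfulPinches,14,",
            "p1,FingerPinching,both,2020-01-07,successfulPinches,99,",
        ]
        cohort = pc.load_cohort(toy_csv(tmp_path, rows))
        ids = {u.unit_id: u.n_reps for u in cohort.units}
        assert ids == {"p1/left": 2, "p1/right": 1}

    def test_repetition_index_independent_of_row_order(self, tmp_path):
        shuffled = [SDMT_ROWS[2], SDMT_ROWS[0], SDMT_ROWS[1]]
        a = pc.load_cohort(toy_csv(tmp_path, SDMT_ROWS, "a.csv"))
        b = pc.load_cohort(toy_csv(tmp_path, shuffled, "b.csv"))
        assert np.array_equal(a.units[0].values, b.units[0].values)
        assert np.array_equal(a.units[0].t_weeks, b.units[0].t_weeks)

    def test_same_timestamp_ties_keep_input_order(self):
        ts = pd.Timestamp("2020-01-01 12:00")
        recs = [Record("p", "UTurn", "none", ts, v) for v in (5.0, 7.0, 6.0)]
        (unit,) = build_units(recs)
        assert list(unit.values) == [5.0, 7.0, 6.0]


class TestNormalizedRoundTrip:
    def test_write_then_read_preserves_units_exactly(self, tmp_path):
        cfg = pc.study_config("FingerPinching", n_units=6)
        cohort, _ = pc.simulate_cohort(cfg, seed=5)
        path = tmp_path / "cohort.csv"
        cohort.write_csv(path)
        back = pc.Cohort.read_csv(path)
        assert sorted(u.unit_id for u in back.units) == \
            sorted(u.unit_id for u in cohort.units)
        orig = {u.unit_id: u for u in cohort.units}
        for u in back.units:
            o = orig[u.unit_id]
            assert np.array_equal(u.values, o.values)
            assert np.array_equal(u.t_weeks, o.t_weeks)
            assert list(u.rep_index) == list(o.rep_index)


class TestCorrectSdmt:
    def _cohort(self, values, baselines):
        recs = [
            Record("p1", "e-SDMT", "none",
                       pd.Timestamp("2020-01-01") + pd.Timedelta(days=7 * i),
                       v, sdmt_baseline_correct=b)
            for i, (v, b) in enumerate(zip(values, baselines))
        ]
        return cohort_from_records(recs)

    def test_identity_ratio(self):
        out = pc.correct_sdmt(self._cohort([40.0], [40.0]))
        assert out.units[0].values[0] == 1.0

    def test_zero_baseline_record_dropped_and_counted(self):
        out = pc.correct_sdmt(self._cohort([40.0, 30.0], [0.0, 60.0]))
        assert out.meta["sdmt_records_dropped"] == 1
        u = out.units[0]
        assert u.n_reps == 1 and u.values[0] == 0.5
        assert u.t_weeks[0] == 0.0  # clock restarts at surviving first record

    def test_second_application_refused(self):
        once = pc.correct_sdmt(self._cohort([40.0], [40.0]))
        with pytest.raises(UsageError):
            pc.correct_sdmt(once)

    def test_requires_esdmt_units(self):
        cohort = pc.Cohort([make_unit([1, 2, 3], test="UTurn")])
        with pytest.raises(UsageError):
            pc.correct_sdmt(cohort)

    def test_baseline_rows_joined_from_long_format(self, tmp_path):
        rows = [
            "p1,e-SDMT,,2020-01-01,correctResponses,30,",
            "p1,e-SDMT,,2020-01-01,baselineCorrectResponses,60,",
            "p1,e-SDMT,,2020-01-08,correctResponses,40,",
            "p1,e-SDMT,,2020-01-08,baselineCorrectResponses,50,",
        ]
        path = tmp_path / "sdmt.csv"
        path.write_text(
            "floodlightOpenId,testName,handUsed,testStartedAt,"
            "testMetricName,testResultMetricValue,age\n" + "\n".join(rows))
        corrected = pc.correct_sdmt(pc.load_cohort(path))
        assert np.allclose(corrected.units[0].values, [0.5, 0.8])


class TestRegistry:
    def test_static_balance_is_the_only_lower_better_test(self):
        lower = [s.name for s in pc.TEST_SPECS.values()
                 if s.direction is pc.Direction.LOWER_BETTER]
        assert lower == ["StaticBalance"]

    def test_dexterity_tests_are_the_only_hand_grouped_tests(self):
        by_hand = {s.name for s in pc.TEST_SPECS.values() if s.hand_grouped}
        assert by_hand == {"FingerPinching", "DrawAShape"}

    def test_min_intervals_follow_app_constraints(self):
        days = {name: s.min_interval_days for name, s in pc.TEST_SPECS.items()}
        assert days["e-SDMT"] == 7
        assert days["FingerPinching"] == days["DrawAShape"] == 2
        assert days["TwoMinuteWalk"] == days["UTurn"] == days["StaticBalance"] == 1
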