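"""Cohort eligibility, outcome windows and thresholds, cascade tables."""

import numpy as np
import pandas as pd
import pytest

import labcascade as lc
from labcascade.cascade import (Thresholds, Windows, assign_first_test,
                                build_cohort, classify_control,
                                classify_diagnosis, classify_retention,
                                flag_hiv, flag_tb)

TH, WIN = Thresholds(), Windows()


def with_pid(df):
    out = df.copy()
    out["patient_id"] = out["true_patient_id"]
    return out


class TestFirstTest:
    def test_earliest_diabetes_lab_wins(self, records_factory):
        df = with_pid(records_factory([
            {"specimen_date": "2013-06-01", "test_type": "HbA1c"},
            {"specimen_date": "2013-05-01", "test_type": "FPG", "result_value": 5.0},
        ]))
        first = assign_first_test(df)
        assert first.loc[0, "test_type"] == "FPG"
        assert first.loc[0, "specimen_date"] == pd.Timestamp("2013-05-01")

    def test_same_day_tie_prefers_hba1c(self, records_factory):
        df = with_pid(records_factory([
            {"specimen_date": "2013-05-01", "test_type": "RPG", "result_value": 12.0},
            {"specimen_date": "2013-05-01", "test_type": "HbA1c"},
        ]))
        assert assign_first_test(df).loc[0, "test_type"] == "HbA1c"

    def test_patient_without_diabetes_test_absent(self, records_factory):
        df = with_pid(records_factory([
            {"test_type": "CD4", "result_value": 300},
        ]))
        assert assign_first_test(df).empty


class TestEligibility:
    @pytest.mark.parametrize("date,dob,included", [
        ("2011-12-31", "1970-06-15", False),   # before the window
        ("2015-03-31", "1985-03-31", True),    # last day, exactly 30
        ("2013-06-01", "1983-07-01", False),   # age 29 at first test
        ("2012-01-01", "1982-01-01", True),    # first day, age 30
    ])
    def test_window_and_age_boundaries(self, records_factory, date, dob, included):
        df = with_pid(records_factory([{"specimen_date": date, "dob": dob}]))
        cohort, _ = build_cohort(assign_first_test(df), WIN)
        assert (len(cohort) == 1) is included

    def test_missing_dob_logged(self, records_factory):
        df = with_pid(records_factory([{"dob": pd.NaT}]))
        cohort, excl = build_cohort(assign_first_test(df), WIN)
        assert cohort.empty and excl["missing_dob"] == 1


def _cohort_for(records):
    rec = with_pid(records)
    cohort, _ = build_cohort(assign_first_test(rec), WIN)
    return rec, cohort


class TestDiagnosis:
    @pytest.mark.parametrize("test_type,value,diagnosed", [
        ("HbA1c", 6.5, True), ("HbA1c", 6.4, False),
        ("FPG", 7.0, True), ("FPG", 6.9, False),
        ("RPG", 11.1, True), ("RPG", 11.0, False),
    ])
    def test_thresholds_at_or_above(self, records_factory, test_type, value, diagnosed):
        rec, cohort = _cohort_for(records_factory([
            {"test_type": test_type, "result_value": value}]))
        dx = classify_diagnosis(rec, cohort, TH, WIN)
        assert bool(dx.loc[0, "diagnosed"]) is diagnosed
        if diagnosed:
            assert dx.loc[0, "diagnostic_used"] == test_type

    def test_window_mode_allows_later_diagnosis(self, records_factory):
        rec, cohort = _cohort_for(records_factory([
            {"specimen_date": "2013-01-15", "result_value": 6.0},
            {"specimen_date": "2014-01-15", "result_value": 8.0},
        ]))
        dx_window = classify_diagnosis(rec, cohort, TH, WIN, mode="window")
        dx_first = classify_diagnosis(rec, cohort, TH, WIN, mode="first")
        assert bool(dx_window.loc[0, "diagnosed"])
        assert dx_window.loc[0, "diagnosis_date"] == pd.Timestamp("2014-01-15")
        assert not bool(dx_first.loc[0, "diagnosed"])

    def test_lab_beyond_horizon_does_not_diagnose(self, records_factory):
        rec, cohort = _cohort_for(records_factory([
            {"specimen_date": "2013-01-15", "result_value": 6.0},
            {"specimen_date": "2015-01-16", "result_value": 9.0},  # day 731
        ]))
        dx = classify_diagnosis(rec, cohort, TH, WIN)
        assert not bool(dx.loc[0, "diagnosed"])


def _dx_frame(date="2013-01-15"):
    return pd.DataFrame({"patient_id": ["p0"],
                         "diagnosis_date": [pd.Timestamp(date)]})


class TestRetentionAndControl:
    @pytest.mark.parametrize("offset,retained", [
        (5, False),     # inside the one-month exclusion
        (30, False),    # exactly 30 days: still excluded (half-open)
        (31, True),     # first qualifying day
        (730, True),    # horizon boundary inclusive
        (731, False),   # past the horizon
    ])
    def test_window_boundaries_day_exact(self, records_factory, offset, retained):
        date = pd.Timestamp("2013-01-15") + pd.Timedelta(days=offset)
        rec = with_pid(records_factory([
            {"specimen_date": "2013-01-15", "result_value": 8.0},
            {"specimen_date": str(date.date()), "result_value": 8.5},
        ]))
        out = classify_retention(rec, _dx_frame(), WIN)
        assert bool(out.loc[0, "retained_dm"]) is retained

    def test_any_lab_retention_broader_than_diabetes(self, records_factory):
        rec = with_pid(records_factory([
            {"specimen_date": "2013-01-15", "result_value": 8.0},
            {"specimen_date": "2013-06-01", "test_type": "creatinine",
             "result_value": 90.0},
        ]))
        out = classify_retention(rec, _dx_frame(), WIN)
        assert not bool(out.loc[0, "retained_dm"])
        assert bool(out.loc[0, "retained_any"])

    def test_retention_requires_diagnosis_date(self, records_factory):
        rec = with_pid(records_factory([{}]))
        undiag = pd.DataFrame({"patient_id": ["p0"], "diagnosis_date": [pd.NaT]})
        with pytest.raises(ValueError, match="diagnos"):
            classify_retention(rec, undiag, WIN)

    @pytest.mark.parametrize("test_type,value,controlled", [
        ("HbA1c", 6.9, True), ("HbA1c", 7.0, False),
        ("FPG", 7.9, True), ("FPG", 8.0, False),
        ("RPG", 9.9, True), ("RPG", 10.0, False),
    ])
    def test_control_strictly_below(self, records_factory, test_type, value, controlled):
        rec = with_pid(records_factory([
            {"specimen_date": "2013-01-15", "result_value": 8.0},
            {"specimen_date": "2013-06-01", "test_type": test_type,
             "result_value": value},
        ]))
        out = classify_control(rec, _dx_frame(), TH, WIN)
        assert bool(out.loc[0, "controlled"]) is controlled


class TestComorbidityFlags:
    def test_cd4_years_before_first_test_counts(self, records_factory):
        rec, cohort = _cohort_for(records_factory([
            {"specimen_date": "2013-01-15"},
            {"specimen_date": "2008-03-01", "test_type": "CD4",
             "result_value": 350},
        ]))
        assert flag_hiv(rec, cohort, WIN).iloc[0] == "PLWH"

    def test_negative_rapid_test_does_not_count(self, records_factory):
        rec, cohort = _cohort_for(records_factory([
            {"specimen_date": "2013-01-15"},
            {"specimen_date": "2013-02-01", "test_type": "HIV_test",
             "result_value": 0.0, "result_positive": False},
        ]))
        assert flag_hiv(rec, cohort, WIN).iloc[0] == "PLWOH"

    def test_viral_load_outside_lookahead_excluded(self, records_factory):
        rec, cohort = _cohort_for(records_factory([
            {"specimen_date": "2013-01-15"},
            {"specimen_date": "2015-01-17", "test_type": "HIV_VL",  # +732 d
             "result_value": 1000},
        ]))
        assert flag_hiv(rec, cohort, WIN).iloc[0] == "PLWOH"

    @pytest.mark.parametrize("offset,status", [
        (-100, "TB+"), (183, "TB+"), (200, "TB-"), (-184, "TB-"),
    ])
    def test_tb_window_six_months_either_side(self, records_factory, offset, status):
        date = pd.Timestamp("2013-06-01") + pd.Timedelta(days=offset)
        rec, cohort = _cohort_for(records_factory([
            {"specimen_date": "2013-06-01"},
            {"specimen_date": str(date.date()), "test_type": "TB_assay",
             "result_value": 0.0, "result_positive": True},
        ]))
        assert flag_tb(rec, cohort, WIN).iloc[0] == status

    def test_tb_positivity_mode(self, records_factory):
        rec, cohort = _cohort_for(records_factory([
            {"specimen_date": "2013-06-01"},
            {"specimen_date": "2013-07-01", "test_type": "TB_assay",
             "result_value": 0.0, "result_positive": False},
        ]))
        assert flag_tb(rec, cohort, WIN).iloc[0] == "TB+"
        assert flag_tb(rec, cohort, WIN, require_positive=True).iloc[0] == "TB-"


class TestCascadeTable:
    def test_monotone_counts_every_stratum(self, cascade_rows):
        table = lc.build_cascade_table(cascade_rows)
        assert (table["n_controlled"] <= table["n_retained_dm"]).all()
        assert (table["n_retained_dm"] <= table["n_diagnosed"]).all()
        assert (table["n_diagnosed"] <= table["n_tested"]).all()

    def test_pipeline_recovers_configured_fractions(self, small_cohort, cascade_rows):
        cfg, _records, truth = small_cohort
        merged = cascade_rows.merge(truth.patients, on="patient_id",
                                    suffixes=("", "_true"))
        assert (merged["diagnosed"] == merged["diagnosed_true"]).all()
        assert (merged["retained_dm"] == merged["retained"]).all()
        assert (merged["controlled"] == merged["controlled_true"]).all()

    def test_empty_stratum_reports_absent_proportions(self, records_factory):
        rows, _ = lc.build_cascade(with_pid(records_factory([
            {"result_value": 5.0}])))
        table = lc.build_cascade_table(rows, stratifiers=("overall",))
        assert table.loc[0, "n_diagnosed"] == 0
        assert np.isnan(table.loc[0, "p_retained"])

    def test_standardized_columns_present_with_weights(self, cascade_rows):
        table = lc.build_cascade_table(cascade_rows, weights=lc.load_weights())
        overall = table[table["stratifier"] == "overall"].iloc[0]
        assert 0 < overall["std_p_diagnosed"] < 1


class TestTrendSummary:
    def test_only_hba1c_events_full_share(self, records_factory):
        rec = records_factory([{"specimen_date": d}
                               for d in ("2013-01-05", "2013-04-05",
                                         "2013-07-05", "2013-10-05")])
        counts, shares = lc.testing_trend_summary(rec)
        assert shares["hba1c_share"] == 1.0
        assert len(counts) == 4 and (counts["n_events"] == 1).all()

    def test_shares_computed_event_level(self, records_factory):
        rec = records_factory([
            {"test_type": "HbA1c"},
            {"test_type": "HbA1c"},
            {"test_type": "FPG", "facility_type": "clinic", "result_value": 5.0},
            {"test_type": "RPG", "result_value": 6.0},
        ])
        _counts, shares = lc.testing_trend_summary(rec)
        assert shares["hba1c_share"] == pytest.approx(0.5)
        assert shares["clinic_glucose_share"] == pytest.approx(0.5)
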