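import pandas as pd
import pytest

from trajmine.event_model import (MissingColumnError, age_decade,
                                  apply_code_mapping, build_timelines,
                                  read_events, truncate_code)

from conftest import WINDOW, make_cohort


def _write(tmp_path, text, name="events.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadEvents:
    def test_well_formed_file_loads_every_row(self, tmp_path):
        p = _write(tmp_path, "patient_id,code,domain,date\n"
                             "p1,I10,diagnosis,2015-01-01\n"
                             "p1,E11,diagnosis,2015-02-01\n"
                             "p2,IMG1,procedure,2016-03-04\n")
        df, report = read_events(p)
        assert len(df) == 3 and report.n_dropped == 0

    def test_malformed_date_row_is_dropped_and_counted(self, tmp_path):
        p = _write(tmp_path, "patient_id,code,domain,date\n"
                             "p1,I10,diagnosis,2015-01-01\n"
                             "p1,E11,diagnosis,not-a-date\n"
                             "p2,I10,diagnosis,2016-03-04\n"
                             "p2,E78,diagnosis,2017-05-06\n")
        df, report = read_events(p)
        assert len(df) == 3 and report.n_bad_date == 1

    def test_missing_code_column_is_named_in_error(self, tmp_path):
        p = _write(tmp_path, "patient_id,domain,date\np1,diagnosis,2015-01-01\n")
        with pytest.raises(MissingColumnError, match="code"):
            read_events(p)

    def test_empty_file_is_an_error(self, tmp_path):
        p = _write(tmp_path, "patient_id,code,domain,date\n")
        with pytest.raises(ValueError, match="empty"):
            read_events(p)


class TestTruncateCode:
    @pytest.mark.parametrize("code,domain,outcomes,expected", [
        ("E78.5", "diagnosis", frozenset(), "E78"),
        ("E11.9", "diagnosis", frozenset(), "E11"),
        ("G30.0", "diagnosis", frozenset({"G30.0"}), "G30.0"),
        ("IMG4028", "procedure", frozenset(), "IMG4028"),
        ("drugA", "medication", frozenset(), "drugA"),
    ])
    def test_icd_category_with_outcome_exception(self, code, domain,
                                                 outcomes, expected):
        assert truncate_code(code, domain, outcomes) == expected

    @pytest.mark.parametrize("code", ["E78.5", "I10", "F03.90", "AB", "X99.99"])
    def test_idempotent_and_never_longer(self, code):
        once = truncate_code(code, "diagnosis", frozenset())
        assert truncate_code(once, "diagnosis", frozenset()) == once
        assert len(once) <= len(code)


class TestBuildTimelines:
    DEMO = [("p1", "F", "White", "1950-06-01")]

    def test_keeps_first_occurrence_only(self):
        cohort, _ = make_cohort(
            [("p1", "I10", "diagnosis", "2014-01-01"),
             ("p1", "I10", "diagnosis", "2016-05-05")], self.DEMO)
        assert len(cohort.events) == 1
        assert cohort.events["date"].iloc[0] == pd.Timestamp("2014-01-01")

    def test_lab_keeps_first_abnormal_and_drops_normals(self):
        cohort, _ = make_cohort(
            [("p1", "LAB1", "lab", "2015-01-01", False),
             ("p1", "LAB1", "lab", "2015-01-30", True)], self.DEMO)
        assert len(cohort.events) == 1
        assert cohort.events["date"].iloc[0] == pd.Timestamp("2015-01-30")

    def test_normal_only_lab_vanishes(self):
        cohort, _ = make_cohort(
            [("p1", "LAB1", "lab", "2015-01-01", False)], self.DEMO)
        assert len(cohort.events) == 0 and cohort.n_patients == 1

    def test_missing_race_excluded_and_counted(self):
        cohort, report = make_cohort(
            [("p1", "I10", "diagnosis", "2015-01-01"),
             ("p2", "I10", "diagnosis", "2015-01-01")],
            [("p1", "F", "White", "1950-06-01"),
             ("p2", "M", None, "1960-01-01")])
        assert cohort.n_patients == 1
        assert report.incomplete_demographics == 1

    def test_under_age_excluded_after_demographic_check(self):
        _, report = make_cohort(
            [("p1", "I10", "diagnosis", "2015-01-01")],
            [("p1", "F", "White", "2005-01-01")])
        assert report.under_age == 1 and report.n_included == 0

    def test_missing_demographics_row_is_counted_not_fatal(self):
        cohort, report = make_cohort(
            [("ghost", "I10", "diagnosis", "2015-01-01")] , self.DEMO)
        assert "ghost" not in cohort.demographics.index
        assert report.incomplete_demographics == 1

    def test_exclusion_accounting_balances(self):
        _, report = make_cohort(
            [("p1", "I10", "diagnosis", "2015-01-01"),
             ("p4", "I10", "diagnosis", "2015-01-01")],
            [("p1", "F", "White", "1950-06-01"),
             ("p2", "M", "", "1960-01-01"),
             ("p3", "F", "Black", "2010-01-01")])
        assert report.counts_balance
        assert (report.n_input_patients ==
                report.n_included + report.incomplete_demographics
                + report.under_age)

    def test_same_day_truncation_collision_keeps_smallest_original(self):
        cohort, _ = make_cohort(
            [("p1", "E11.9", "diagnosis", "2015-01-01"),
             ("p1", "E11.3", "diagnosis", "2015-01-01")], self.DEMO)
        assert list(cohort.events["code"]) == ["E11"]

    def test_outside_window_events_dropped(self):
        cohort, _ = make_cohort(
            [("p1", "I10", "diagnosis", "2001-01-01"),
             ("p1", "E78", "diagnosis", "2015-01-01")], self.DEMO)
        assert list(cohort.events["code"]) == ["E78"]

    def test_idempotence_on_own_output(self):
        cohort, _ = make_cohort(
            [("p1", "E11.9", "diagnosis", "2015-01-01"),
             ("p1", "I10", "diagnosis", "2014-02-03"),
             ("p1", "I10", "diagnosis", "2018-02-03")], self.DEMO)
        again, _ = build_timelines(cohort.events,
                                   cohort.demographics.reset_index(),
                                   WINDOW)
        pd.testing.assert_frame_equal(cohort.events, again.events)


class TestAgeDecade:
    @pytest.mark.parametrize("age_days,expected", [
        (int(67.9 * 365.25), 6),     # 67.9 years
        (int(20.0 * 365.25), 2),     # exact decade boundary
        (int(80.0 * 365.25), 8),
        (int(18.0 * 365.25), 1),
    ])
    def test_floor_convention(self, age_days, expected):
        at = pd.Timestamp("2020-06-15")
        assert age_decade(at - pd.Timedelta(days=age_days), at) == expected

    def test_unresolvable_age_is_an_error(self):
        with pytest.raises(ValueError):
            age_decade(pd.NaT, pd.Timestamp("2020-01-01"))


class TestCodeMapping:
    def _events(self):
        df = pd.DataFrame({
            "patient_id": ["p1", "p1", "p1"],
            "code": ["drugA", "drugB", "E11.9"],
            "domain": ["medication", "medication", "diagnosis"],
            "date": pd.to_datetime(["2015-01-01", "2015-06-01", "2015-03-01"]),
            "abnormal": [True, True, True],
        })
        return df

    def test_mapped_group_collapses_to_earliest_date(self):
        mapping = {"drugA": "class1", "drugB": "class1"}
        demo = pd.DataFrame([("p1", "F", "White", "1950-06-01")],
                            columns=["patient_id", "sex", "race", "birth_date"])
        demo["birth_date"] = pd.to_datetime(demo["birth_date"])
        cohort, _ = build_timelines(self._events(), demo, WINDOW,
                                    code_mapping=mapping)
        meds = cohort.events[cohort.events["domain"] == "medication"]
        assert list(meds["code"]) == ["class1"]
        assert meds["date"].iloc[0] == pd.Timestamp("2015-01-01")

    def test_empty_mapping_is_identity(self):
        out, n_unmapped = apply_code_mapping(self._events(), {})
        pd.testing.assert_frame_equal(out, self._events())
        assert n_unmapped == 0

    def test_unmapped_medications_pass_through_counted(self):
        out, n_unmapped = apply_code_mapping(self._events(), {"drugA": "c1"})
        assert n_unmapped == 1
        assert set(out["code"]) == {"c1", "drugB", "E11.9"}

    def test_diagnosis_codes_unaffected(self):
        out, _ = apply_code_mapping(self._events(), {"E11.9": "nope"})
        assert "E11.9" in set(out["code"])
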