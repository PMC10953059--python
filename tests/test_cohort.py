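import numpy as np
import pandas as pd
import pytest

from multimorbidity.cohort import (
    OutcomeDataError,
    check_eligibility,
    consultation_rate_table,
    derive_cancer,
    derive_consultation_rate,
    derive_death,
    eligibility_table,
    gp_coverage_end,
    merge_spells,
)
from multimorbidity.pipeline import analyse_study

from conftest import make_records

BL = pd.Timestamp("2008-06-01")
STUDY_END = pd.Timestamp("2016-07-10")


def _spells(*pairs):
    return pd.DataFrame(
        [(pd.Timestamp(a), pd.Timestamp(b)) for a, b in pairs], columns=["start", "end"]
    )


def _cohort(pids, baselines=None):
    baselines = baselines or [BL] * len(pids)
    return pd.DataFrame({"patient_id": pids, "index_date": baselines})


class TestEligibility:
    def test_single_covering_spell(self):
        spells = _spells((BL - pd.Timedelta(days=400), BL + pd.Timedelta(days=200)))
        assert check_eligibility(spells, BL)

    @pytest.mark.parametrize("gap, expected", [(90, True), (91, False)])
    def test_gap_boundary(self, gap, expected):
        end1 = BL - pd.Timedelta(days=200)
        start2 = end1 + pd.Timedelta(days=gap + 1)  # gap = start2 - end1 - 1
        spells = _spells(
            (BL - pd.Timedelta(days=900), end1),
            (start2, BL + pd.Timedelta(days=400)),
        )
        assert check_eligibility(spells, BL) is expected

    def test_short_history_ineligible(self):
        spells = _spells((BL - pd.Timedelta(days=200), BL + pd.Timedelta(days=400)))
        assert not check_eligibility(spells, BL)

    def test_insufficient_followup_ineligible(self):
        spells = _spells((BL - pd.Timedelta(days=900), BL + pd.Timedelta(days=100)))
        assert not check_eligibility(spells, BL)

    def test_no_spells_is_false_not_error(self):
        assert not check_eligibility(_spells(), BL)

    def test_partition(self, small_study):
        table = eligibility_table(small_study.registration, small_study.cohort)
        assert len(table) == len(small_study.cohort)
        assert table["eligible"].isin([True, False]).all()

    def test_bridged_coverage_end(self):
        end1 = BL + pd.Timedelta(days=300)
        spells = _spells(
            (BL - pd.Timedelta(days=900), end1),
            (end1 + pd.Timedelta(days=50), BL + pd.Timedelta(days=900)),
        )
        assert gp_coverage_end(spells, BL) == BL + pd.Timedelta(days=900)
        assert len(merge_spells(spells)) == 1


class TestDeathOutcome:
    def test_event_within_study(self):
        deaths = pd.DataFrame({"patient_id": ["p1"],
                               "date_of_death": [BL + pd.Timedelta(days=400)]})
        out = derive_death(deaths, _cohort(["p1"]), STUDY_END)
        assert out.loc[0, "event"] == 1
        assert out.loc[0, "time_days"] == 400

    def test_no_death_censored_at_study_end(self):
        out = derive_death(pd.DataFrame(columns=["patient_id", "date_of_death"]),
                           _cohort(["p1"]), STUDY_END)
        assert out.loc[0, "event"] == 0
        assert out.loc[0, "time_days"] == (STUDY_END - BL).days

    def test_death_after_study_end_censored(self):
        deaths = pd.DataFrame({"patient_id": ["p1"],
                               "date_of_death": [STUDY_END + pd.Timedelta(days=10)]})
        out = derive_death(deaths, _cohort(["p1"]), STUDY_END)
        assert out.loc[0, "event"] == 0
        assert out.loc[0, "time_days"] == (STUDY_END - BL).days

    def test_death_before_baseline_is_data_error(self):
        deaths = pd.DataFrame({"patient_id": ["p1"],
                               "date_of_death": [BL - pd.Timedelta(days=1)]})
        with pytest.raises(OutcomeDataError, match="p1"):
            derive_death(deaths, _cohort(["p1"]), STUDY_END)


class TestCancerOutcome:
    def test_nmsc_excluded_first_qualifying_event_used(self):
        cancers = pd.DataFrame(
            {
                "patient_id": ["p1", "p1"],
                "diagnosis_date": [BL + pd.Timedelta(days=365), BL + pd.Timedelta(days=730)],
                "site_code": ["C44", "C18"],  # NMSC first, colon later
            }
        )
        out = derive_cancer(cancers, _cohort(["p1"]), STUDY_END)
        assert out.loc[0, "event"] == 1
        assert out.loc[0, "time_days"] == 730

    def test_prevalent_cancer_retained_and_flagged(self):
        cancers = pd.DataFrame(
            {"patient_id": ["p1"], "diagnosis_date": [BL - pd.Timedelta(days=365)],
             "site_code": ["C50"]}
        )
        out = derive_cancer(cancers, _cohort(["p1"]), STUDY_END)
        assert len(out) == 1
        assert out.loc[0, "event"] == 0
        assert bool(out.loc[0, "prior_cancer_flag"])

    def test_exclude_prevalent_drops_patient(self):
        cancers = pd.DataFrame(
            {"patient_id": ["p1"], "diagnosis_date": [BL - pd.Timedelta(days=365)],
             "site_code": ["C50"]}
        )
        out = derive_cancer(cancers, _cohort(["p1", "p2"]), STUDY_END,
                            exclude_prevalent=True)
        assert list(out["patient_id"]) == ["p2"]

    def test_competing_censoring_at_death(self):
        death_dates = pd.Series([BL + pd.Timedelta(days=100)], index=["p1"])
        out = derive_cancer(
            pd.DataFrame(columns=["patient_id", "diagnosis_date", "site_code"]),
            _cohort(["p1"]), STUDY_END, death_dates=death_dates,
        )
        assert out.loc[0, "time_days"] == 100

    def test_unclassifiable_site_code_is_error(self):
        cancers = pd.DataFrame(
            {"patient_id": ["p1"], "diagnosis_date": [BL + pd.Timedelta(days=10)],
             "site_code": ["999"]}
        )
        with pytest.raises(OutcomeDataError, match="999"):
            derive_cancer(cancers, _cohort(["p1"]), STUDY_END)


class TestConsultationRate:
    def test_same_day_dedup(self):
        end = BL + pd.Timedelta(days=730)
        recs = make_records(
            [("p1", "2009-01-05", "9N11.", "diagnosis")] * 3
            + [("p1", "2009-08-01", "9N11.", "diagnosis")]
        )
        rate = derive_consultation_rate(recs, BL, end)
        assert rate == pytest.approx(2 / (730 / 365.25))
        assert rate == pytest.approx(1.0, rel=2e-3)

    def test_zero_records(self):
        assert derive_consultation_rate(make_records([]), BL, BL + pd.Timedelta(days=730)) == 0.0

    def test_ten_days_over_two_years(self):
        end = BL + pd.Timedelta(days=730)
        recs = make_records(
            [("p1", BL + pd.Timedelta(days=30 * (i + 1)), "9N11.", "diagnosis")
             for i in range(10)]
        )
        assert derive_consultation_rate(recs, BL, end) == pytest.approx(5.0, rel=2e-3)

    def test_non_positive_followup_is_error(self):
        with pytest.raises(OutcomeDataError):
            derive_consultation_rate(make_records([]), BL, BL)

    def test_records_outside_window_ignored(self):
        end = BL + pd.Timedelta(days=730)
        recs = make_records(
            [("p1", BL, "9N11.", "diagnosis"),  # on baseline: excluded
             ("p1", end + pd.Timedelta(days=5), "9N11.", "diagnosis")]
        )
        assert derive_consultation_rate(recs, BL, end) == 0.0

    def test_table_matches_scalar(self):
        end = BL + pd.Timedelta(days=730)
        recs = make_records(
            [("p1", "2009-01-05", "9N11.", "diagnosis"),
             ("p1", "2009-01-05", "9N11.", "diagnosis"),
             ("p2", "2009-02-01", "9N11.", "diagnosis")]
        )
        fe = pd.Series([end, end], index=["p1", "p2"])
        table = consultation_rate_table(recs, _cohort(["p1", "p2"]), fe)
        for pid in ("p1", "p2"):
            scalar = derive_consultation_rate(recs[recs["patient_id"] == pid], BL, end)
            got = table.set_index("patient_id").loc[pid, "consult_rate"]
            assert got == pytest.approx(scalar)


class TestAnalysisTable:
    def test_summary_partition_and_conservation(self, eventful_study):
        at = analyse_study(eventful_study)
        s = at.summary.set_index("group")
        assert (
            s.loc["no_conditions", "n"] + s.loc["one_condition", "n"]
            + s.loc["multimorbid", "n"] == s.loc["whole_cohort", "n"]
        )
        assert (
            s.loc[["no_conditions", "one_condition", "multimorbid"], "deaths"].sum()
            == s.loc["whole_cohort", "deaths"]
        )

    def test_event_times_bounded_by_study_end(self, eventful_study):
        at = analyse_study(eventful_study)
        recs = at.records
        max_days = (pd.Timestamp(eventful_study.config.study_end)
                    - recs["index_date"]).dt.days
        assert (recs["time_death_days"] <= max_days).all()
        assert (recs["time_cancer_days"] <= max_days).all()

    def test_ineligible_patients_absent(self, eventful_study):
        at = analyse_study(eventful_study)
        elig = eligibility_table(eventful_study.registration, eventful_study.cohort)
        ineligible = set(elig.loc[~elig["eligible"], "patient_id"])
        assert not (set(at.records["patient_id"]) & ineligible)

    def test_prevalent_cancer_sensitivity_shrinks_cohort(self, eventful_study):
        full = analyse_study(eventful_study)
        sens = analyse_study(eventful_study, exclude_prevalent_cancer=True)
        n_prior = int(full.records["prior_cancer_flag"].sum())
        assert len(sens.records) == len(full.records) - n_prior
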