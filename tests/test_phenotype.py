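import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multimorbidity.codemap import Codelist, Domain, Framework
from multimorbidity.conditions import CONDITIONS
from multimorbidity.phenotype import (
    Ever,
    CodeSet,
    LastNTests,
    RecentRx,
    RuleConfigError,
    Within,
    build_condition_matrix,
    compile_rules,
    evaluate_condition,
)
from multimorbidity.synthdata import SynthConfig, plant_conditions

from conftest import make_records

INDEX = pd.Timestamp("2008-06-01")

DIAG = CodeSet(Domain.DIAGNOSIS, frozenset({"H33.."}))
RX = CodeSet(Domain.PRESCRIPTION, frozenset({"0301010"}))
TEST = CodeSet(Domain.TEST, frozenset({"451E."}))


class TestCompileRules:
    def test_fixture_config_compiles_all_conditions(self, rules):
        assert set(rules) == set(CONDITIONS)

    def test_missing_condition_is_named(self, codelists):
        config = {"conditions": {"hypertension": {"ever": {"codelist": "hypertension_diag"}}}}
        with pytest.raises(RuleConfigError, match="diabetes"):
            compile_rules(config, codelists)

    def test_zero_window_rejected(self, codelists):
        config = {"conditions": {"migraine": {
            "rx_recent": {"codelist": "migraine_rx", "min_count": 4, "window_months": 0}}}}
        with pytest.raises(RuleConfigError, match="window_months"):
            compile_rules(config, codelists, required_conditions=("migraine",))

    def test_dangling_codelist_reference(self, codelists):
        config = {"conditions": {"migraine": {"ever": {"codelist": "no_such_list"}}}}
        with pytest.raises(RuleConfigError, match="no_such_list"):
            compile_rules(config, codelists, required_conditions=("migraine",))

    def test_unknown_logic_keyword(self, codelists):
        config = {"conditions": {"migraine": {"sometimes": {"codelist": "migraine_rx"}}}}
        with pytest.raises(RuleConfigError, match="sometimes"):
            compile_rules(config, codelists, required_conditions=("migraine",))


class TestEvaluateCondition:
    def test_ever_prior_event(self):
        recs = make_records([("p", "2005-01-01", "H33..", "diagnosis")])
        assert evaluate_condition(Ever(DIAG), recs, INDEX) == 1

    def test_index_day_record_excluded(self):
        recs = make_records([("p", INDEX, "H33..", "diagnosis")])
        assert evaluate_condition(Ever(DIAG), recs, INDEX) == 0

    def test_no_records_gives_zero(self):
        recs = make_records([])
        assert evaluate_condition(Ever(DIAG), recs, INDEX) == 0

    @pytest.mark.parametrize(
        "values_by_date, expected",
        [
            ([("2006-01-01", 72), ("2007-01-01", 55), ("2008-01-01", 50)], 1),
            ([("2006-01-01", 55), ("2007-01-01", 72)], 0),
            ([("2007-01-01", 50)], 0),  # fewer than n tests: insufficient evidence
        ],
    )
    def test_last_two_egfr_below_60(self, values_by_date, expected):
        rule = LastNTests(TEST, n=2, threshold=60, direction="below")
        recs = make_records(
            [("p", d, "451E.", "test", v) for d, v in values_by_date]
        )
        assert evaluate_condition(rule, recs, INDEX) == expected

    def test_same_day_tests_straddling_threshold_not_met(self):
        rule = LastNTests(TEST, n=2, threshold=60, direction="below")
        recs = make_records(
            [
                ("p", "2007-01-01", "451E.", "test", 50),
                ("p", "2008-01-01", "451E.", "test", 55),
                ("p", "2008-01-01", "451E.", "test", 65),  # same day, above threshold
            ]
        )
        assert evaluate_condition(rule, recs, INDEX) == 0

    def test_rx_recent_counts_window(self):
        rule = RecentRx(RX, min_count=2, window_months=12)
        inside = [("p", "2008-01-10", "0301010", "prescription"),
                  ("p", "2008-03-10", "0301010", "prescription")]
        outside = [("p", "2006-01-10", "0301010", "prescription")]
        assert evaluate_condition(rule, make_records(inside), INDEX) == 1
        assert evaluate_condition(rule, make_records(inside[:1] + outside), INDEX) == 0

    def test_within_window_boundary(self):
        rule = Within(DIAG, years=5)
        lower = INDEX - pd.Timedelta(days=round(5 * 365.25))
        assert evaluate_condition(
            rule, make_records([("p", lower, "H33..", "diagnosis")]), INDEX) == 1
        assert evaluate_condition(
            rule, make_records([("p", lower - pd.Timedelta(days=1), "H33..", "diagnosis")]),
            INDEX) == 0

    def test_combinators(self, rules, codelists):
        # asthma = diagnosis ever AND a prescription in the last year
        asthma = rules["asthma"]
        diag_code = sorted(codelists["asthma_diag"].codes)[0]
        rx_code = sorted(codelists["asthma_rx"].codes)[0]
        diag = make_records([("p", "2001-05-01", diag_code, "diagnosis")])
        rx_row = pd.DataFrame(
            [("p", pd.Timestamp("2008-03-01"), rx_code, "BNF", "prescription", np.nan)],
            columns=diag.columns,
        )
        assert evaluate_condition(asthma, diag, INDEX) == 0
        assert evaluate_condition(asthma, pd.concat([diag, rx_row]), INDEX) == 1


class TestConditionMatrix:
    def test_patient_without_records_gets_zero_row(self, rules):
        cohort = pd.DataFrame({"patient_id": ["p1"], "index_date": [INDEX]})
        matrix = build_condition_matrix(cohort, make_records([]), rules)
        assert matrix.indicators.shape == (1, 37)
        assert matrix.indicators.to_numpy().sum() == 0

    def test_column_prevalence(self, rules, codelists):
        code = sorted(codelists["hypertension_diag"].codes)[0]
        cohort = pd.DataFrame({"patient_id": ["p1", "p2"], "index_date": [INDEX, INDEX]})
        recs = make_records([("p1", "2005-01-01", code, "diagnosis")])
        matrix = build_condition_matrix(cohort, recs, rules)
        assert matrix.prevalence()["hypertension"] == 0.5

    def test_record_order_invariance(self, rules, small_study):
        cohort = small_study.cohort.head(50)
        recs = pd.concat([small_study.clinical, small_study.scripts], ignore_index=True)
        shuffled = recs.sample(frac=1, random_state=1).reset_index(drop=True)
        m1 = build_condition_matrix(cohort, recs, rules)
        m2 = build_condition_matrix(cohort, shuffled, rules)
        pd.testing.assert_frame_equal(m1.indicators, m2.indicators)

    def test_scalar_and_vector_paths_agree(self, rules, small_study):
        cohort = small_study.cohort.head(30)
        recs = pd.concat([small_study.clinical, small_study.scripts], ignore_index=True)
        matrix = build_condition_matrix(cohort, recs, rules)
        baselines = dict(zip(cohort["patient_id"], cohort["index_date"]))
        for pid in cohort["patient_id"]:
            mine = recs[recs["patient_id"] == pid]
            for cid in ("hypertension", "asthma", "chronic_kidney_disease",
                        "anxiety_depression", "migraine"):
                assert (
                    evaluate_condition(rules[cid], mine, baselines[pid])
                    == matrix.indicators.loc[pid, cid]
                )

    def test_undated_records_excluded_not_fatal(self, rules):
        cohort = pd.DataFrame({"patient_id": ["p1"], "index_date": [INDEX]})
        recs = make_records(
            [("p1", "2005-01-01", "B011.", "diagnosis"),
             ("p1", "2005-02-01", "B011.", "diagnosis")]
        )
        recs.loc[1, "date"] = pd.NaT
        matrix = build_condition_matrix(cohort, recs, rules)
        assert matrix.indicators.loc["p1", "hypertension"] == 1


@settings(max_examples=40, derandomize=True, deadline=None)
@given(extra_day_offset=st.integers(min_value=1, max_value=2000))
def test_adding_matching_record_is_monotone(extra_day_offset):
    """For cumulative rules an extra matching record can never clear the flag."""
    recs = make_records([("p", "2005-01-01", "H33..", "diagnosis")])
    extra = make_records(
        [("p", INDEX - pd.Timedelta(days=extra_day_offset), "H33..", "diagnosis")]
    )
    both = pd.concat([recs, extra], ignore_index=True)
    for rule in (Ever(DIAG), Within(DIAG, years=6)):
        before = evaluate_condition(rule, recs, INDEX)
        after = evaluate_condition(rule, both, INDEX)
        assert after >= before


def test_planted_prevalence_recovery_binomial_tolerance():
    """Observed column prevalence converges to the planted probability."""
    cfg = SynthConfig(n_patients=10_000, seed=5)
    matrix = plant_conditions(cfg, np.random.default_rng(5))
    n = cfg.n_patients
    for cid, p in cfg.condition_prevalence.items():
        se = np.sqrt(p * (1 - p) / n)
        assert abs(matrix[cid].mean() - p) <= max(3 * se, 2 / n), cid
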