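import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multimorbidity.validate import (
    ConcordanceUndefined,
    calibration_deciles,
    concordance_continuous,
    followup_sweep,
    harrell_c,
    pair_counts,
    pair_counts_brute,
    subgroup_concordance,
    truncate_horizon,
)
from multimorbidity.pipeline import analyse_study


def _c(time, event, score):
    conc, disc, tied = pair_counts(time, event, score)
    return (conc + 0.5 * tied) / (conc + disc + tied)


class TestCensoredConcordance:
    def test_worked_four_subject_example(self):
        time, event, score = [2, 4, 5, 7], [1, 1, 0, 1], [0.9, 0.4, 0.7, 0.1]
        assert pair_counts_brute(time, event, score) == (4, 1, 0)
        assert harrell_c(score, time, event).c == pytest.approx(0.8)

    def test_perfect_score(self):
        time = np.arange(1.0, 40.0)
        assert harrell_c(-time, time, np.ones_like(time, bool)).c == 1.0

    def test_perfectly_reversed_score(self):
        time = np.arange(1.0, 40.0)
        assert harrell_c(time, time, np.ones_like(time, bool)).c == 0.0

    def test_constant_score_is_half(self):
        time = np.arange(1.0, 20.0)
        res = harrell_c(np.zeros_like(time), time, np.ones_like(time, bool))
        assert res.c == 0.5

    def test_no_events_is_undefined_signal(self):
        with pytest.raises(ConcordanceUndefined):
            harrell_c([1.0, 2.0], [1.0, 2.0], [False, False])

    def test_time_tie_with_single_event_is_usable(self):
        # event at t ranks before the censored subject at the same t
        counts = pair_counts_brute([3.0, 3.0], [True, False], [2.0, 1.0])
        assert counts == (1, 0, 0)
        assert pair_counts([3.0, 3.0], [True, False], [2.0, 1.0]) == counts

    def test_tied_event_times_unusable(self):
        assert pair_counts_brute([3.0, 3.0], [True, True], [2.0, 1.0]) == (0, 0, 0)

    def test_horizon_truncation_recodes_late_events(self):
        t, e = truncate_horizon([2.0, 7.0], [True, True], 5.0)
        assert list(t) == [2.0, 5.0]
        assert list(e) == [True, False]

    def test_positive_time_required(self):
        with pytest.raises(ValueError):
            harrell_c([1.0], [0.0], [True])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_fast_kernel_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 120))
    time = rng.choice(np.arange(1, 15), n).astype(float)
    event = rng.random(n) < 0.6
    score = rng.choice(np.arange(8), n).astype(float)
    assert pair_counts(time, event, score) == pair_counts_brute(time, event, score)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_negating_scores_flips_concordance(seed):
    rng = np.random.default_rng(seed)
    n = 40
    time = rng.choice(np.arange(1, 25), n).astype(float)
    event = rng.random(n) < 0.5
    score = rng.normal(size=n)  # continuous: no score ties
    if not event.any():
        return
    assert _c(time, event, -score) == pytest.approx(1 - _c(time, event, score))


@settings(max_examples=40, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_monotone_transform_invariance(seed):
    rng = np.random.default_rng(seed)
    n = 40
    time = rng.choice(np.arange(1, 25), n).astype(float)
    event = rng.random(n) < 0.5
    score = rng.normal(size=n)
    if not event.any():
        return
    base = pair_counts(time, event, score)
    assert pair_counts(time, event, np.exp(score)) == base
    assert pair_counts(time, event, 3 * score + 7) == base


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_agrees_with_lifelines_on_tie_free_times(seed):
    """Independent library cross-check where tie conventions coincide."""
    from lifelines.utils import concordance_index

    rng = np.random.default_rng(seed)
    n = 100
    time = rng.permutation(np.arange(1, n + 1)).astype(float)  # distinct times
    event = rng.random(n) < 0.5
    score = rng.normal(size=n)
    if not event.any():
        return
    # lifelines expects higher prediction = longer survival, hence -score
    assert _c(time, event, score) == pytest.approx(
        concordance_index(time, -score, event), abs=1e-12
    )


class TestContinuousConcordance:
    def test_perfect_agreement(self):
        r = np.array([1.0, 4.0, 2.0, 9.0])
        assert concordance_continuous(r, r, n_boot=0).c == 1.0

    def test_three_subject_trace(self):
        res = concordance_continuous([1, 2, 3], [10, 30, 20], n_boot=0)
        assert res.c == pytest.approx(2 / 3)
        assert res.n_usable_pairs == 3

    def test_tied_rates_are_unusable(self):
        res = concordance_continuous([1, 2, 3], [5, 5, 9], n_boot=0)
        assert res.n_usable_pairs == 2

    def test_fewer_than_two_subjects_undefined(self):
        with pytest.raises(ConcordanceUndefined):
            concordance_continuous([1.0], [1.0])

    def test_bootstrap_se_is_seeded(self):
        rng = np.random.default_rng(0)
        s, r = rng.normal(size=80), rng.exponential(size=80)
        a = concordance_continuous(s, r, n_boot=50, random_state=3)
        b = concordance_continuous(s, r, n_boot=50, random_state=3)
        assert a.se == b.se


class TestCalibration:
    def test_event_conservation(self):
        rng = np.random.default_rng(1)
        pred = rng.uniform(0.01, 0.3, 500)
        events = (rng.random(500) < pred).astype(float)
        cal = calibration_deciles(pred, events)
        assert cal.total_events == events.sum()
        assert cal.table["n"].sum() == 500

    def test_constant_score_observed_rr_one(self):
        rng = np.random.default_rng(2)
        events = (rng.random(1000) < 0.1).astype(float)
        cal = calibration_deciles(np.ones(1000), events)
        filled = cal.table.dropna(subset=["observed_rr"])
        assert np.allclose(filled["observed_rr"], 1.0)

    def test_identity_when_predicted_equals_generating_risk(self):
        rng = np.random.default_rng(3)
        n = 20_000
        pred = rng.uniform(0.02, 0.4, n)
        events = (rng.random(n) < pred).astype(float)
        cal = calibration_deciles(pred, events)
        overall = events.mean()
        for _, row in cal.table.iterrows():
            p_dec = row["mean_predicted_rr"] * pred.mean()
            se = np.sqrt(p_dec * (1 - p_dec) / row["n"]) / overall
            assert abs(row["observed_rr"] - row["mean_predicted_rr"]) <= 4 * se

    def test_no_events_undefined(self):
        with pytest.raises(ConcordanceUndefined):
            calibration_deciles(np.arange(20.0), np.zeros(20))


class TestSubgroups:
    def _table(self, rng, n, informative_in_men=False):
        sex = (rng.random(n) < 0.5).astype(int)
        age = rng.uniform(40, 70, n)
        risk = rng.normal(size=n)
        score = np.where(sex == 1, risk, rng.normal(size=n)) if informative_in_men else risk
        rate = 0.02 * np.exp(risk)
        time = np.minimum(rng.exponential(1 / rate), 10.0)
        event = time < 10.0
        time = np.maximum(time, 1e-3)
        return pd.DataFrame(
            {"sex": sex, "age": age, "score": score, "time": time, "event": event}
        )

    def test_single_sex_cohort_matches_whole(self):
        rng = np.random.default_rng(4)
        t = self._table(rng, 400)
        men = t[t["sex"] == 1].reset_index(drop=True)
        results = subgroup_concordance(men, "score", "time", "event", horizons=[5])
        labels = {r.subgroup for r in results}
        assert "female" not in labels
        whole = harrell_c(men["score"], men["time"], men["event"], horizon_years=5)
        male = next(r for r in results if r.subgroup == "male")
        assert male.c == pytest.approx(whole.c)

    def test_sex_specific_signal_detected(self):
        rng = np.random.default_rng(5)
        t = self._table(rng, 3000, informative_in_men=True)
        results = subgroup_concordance(t, "score", "time", "event", horizons=[5])
        by = {r.subgroup: r.c for r in results}
        assert by["male"] > by["female"] + 0.05

    def test_subgroup_sizes_partition_cohort(self):
        rng = np.random.default_rng(6)
        t = self._table(rng, 500)
        results = subgroup_concordance(t, "score", "time", "event", horizons=[5])
        n_by = {r.subgroup: r.n_included for r in results}
        assert n_by["male"] + n_by["female"] == len(t)
        bands = [v for k, v in n_by.items() if k.startswith("male_")]
        assert sum(bands) == n_by["male"]


@pytest.fixture(scope="module")
def analysis(eventful_study):
    return analyse_study(eventful_study).records


class TestFollowupSweep:
    def test_grid_complete(self, analysis):
        models = {m: f"score_{m}" for m in ("general", "mortality", "hospital", "count")}
        sweep = followup_sweep(analysis, models)
        assert len(sweep) == 4 * (10 + 10 + 8)
        assert not sweep["c"].isna().any()

    def test_deterministic(self, analysis):
        models = {"general": "score_general"}
        a = followup_sweep(analysis, models)
        b = followup_sweep(analysis, models)
        pd.testing.assert_frame_equal(a, b)

    def test_horizon_rows_match_direct_oracle(self, analysis):
        sweep = followup_sweep(analysis, {"general": "score_general"}, outcomes=("death",))
        row = sweep[(sweep["horizon"] == 1)].iloc[0]
        t, e = truncate_horizon(
            analysis["time_death_years"], analysis["event_death"], 1.0
        )
        conc, disc, tied = pair_counts_brute(t, e, analysis["score_general"].to_numpy())
        assert row["c"] == pytest.approx((conc + 0.5 * tied) / (conc + disc + tied))

    def test_rate_capped_and_coverage_filtered(self, analysis):
        models = {"general": "score_general"}
        sweep = followup_sweep(analysis, models)
        rate = sweep[sweep["outcome"] == "rate"]
        assert rate["horizon"].max() == 8
        n5 = rate[rate["horizon"] == 5]["n"].iloc[0]
        assert n5 == (analysis["gp_coverage_years"] >= 5).sum()
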