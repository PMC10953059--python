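"""Cohort eligibility and outcome derivation with explicit censoring rules.

Eligibility requires continuous primary-care registration around the
baseline assessment: after merging registration spells separated by at
most 90 days, a single merged interval must cover from 365 days before
baseline to 183 days after.  Three outcomes are derived per patient:

* **death** — time from baseline to death, administratively censored at
  the study end date;
* **cancer diagnosis** — time to the first non-melanoma-skin-cancer-
  excluded (non-NMSC) registry diagnosis strictly after baseline,
  censored at death or study end.  Patients with a cancer diagnosis
  before baseline are retained by default (they remain at risk of
  subsequent cancers) and flagged, with an option to exclude them as a
  sensitivity analysis;
* **consultation rate** — distinct calendar days bearing a clinical
  record, divided by years of available follow-up (duplicate same-day
  records never inflate the numerator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
ELIGIBILITY_DAYS_BEFORE = 365
ELIGIBILITY_DAYS_AFTER = 183
MAX_REGISTRATION_GAP_DAYS = 90
#: ICD-10 prefix identifying non-melanoma skin cancer in the default dialect.
DEFAULT_NMSC_PREFIXES = ("C44",)


class OutcomeDataError(ValueError):
    """Inconsistent registry/outcome inputs (e.g. death before baseline)."""


def merge_spells(spells: pd.DataFrame, max_gap_days: int = MAX_REGISTRATION_GAP_DAYS) -> pd.DataFrame:
    """Merge one patient's registration spells, bridging short gaps.

    Registration intervals are inclusive of both endpoints; the gap
    between consecutive spells is ``start_next - end_prev - 1`` days.
    Gaps of up to ``max_gap_days`` (90 by default) are bridged; longer
    gaps break continuity.
    """
    if spells.empty:
        return spells.copy()
    s = spells.sort_values("start").reset_index(drop=True)
    merged = [[s.loc[0, "start"], s.loc[0, "end"]]]
    for _, row in s.iloc[1:].iterrows():
        gap = (row["start"] - merged[-1][1]).days - 1
        if gap <= max_gap_days:
            merged[-1][1] = max(merged[-1][1], row["end"])
        else:
            merged.append([row["start"], row["end"]])
    return pd.DataFrame(merged, columns=["start", "end"])


def check_eligibility(spells: pd.DataFrame, baseline) -> bool:
    """True iff one merged spell covers [baseline-365 d, baseline+183 d]."""
    if spells.empty:
        return False
    baseline = pd.Timestamp(baseline)
    lo = baseline - pd.Timedelta(days=ELIGIBILITY_DAYS_BEFORE)
    hi = baseline + pd.Timedelta(days=ELIGIBILITY_DAYS_AFTER)
    merged = merge_spells(spells)
    return bool(((merged["start"] <= lo) & (merged["end"] >= hi)).any())


def gp_coverage_end(spells: pd.DataFrame, baseline) -> pd.Timestamp | None:
    """End of the merged registration interval containing the baseline date."""
    if spells.empty:
        return None
    baseline = pd.Timestamp(baseline)
    merged = merge_spells(spells)
    hit = merged[(merged["start"] <= baseline) & (merged["end"] >= baseline)]
    if hit.empty:
        return None
    return hit["end"].max()


def eligibility_table(registration: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-patient eligibility flag and GP-coverage end for a whole cohort.

    ``registration`` holds spells (patient_id, start, end); ``cohort``
    holds (patient_id, index_date).  Patients with no spells are
    ineligible, not errors.
    """
    reg = registration.copy()
    reg["patient_id"] = reg["patient_id"].astype(str)
    if (reg["start"] > reg["end"]).any():
        raise OutcomeDataError("registration spell with start > end")
    by_patient = dict(tuple(reg.groupby("patient_id")))
    rows = []
    for pid, baseline in zip(cohort["patient_id"].astype(str), cohort["index_date"]):
        spells = by_patient.get(pid, pd.DataFrame(columns=["start", "end"]))
        rows.append(
            {
                "patient_id": pid,
                "eligible": check_eligibility(spells, baseline),
                "gp_coverage_end": gp_coverage_end(spells, baseline),
            }
        )
    out = pd.DataFrame(rows)
    logger.info("eligibility: %d / %d patients eligible", int(out["eligible"].sum()), len(out))
    return out


def derive_death(
    deaths: pd.DataFrame, cohort: pd.DataFrame, study_end
) -> pd.DataFrame:
    """Death outcome per cohort patient.

    Returns (patient_id, event, time_days, death_date); time is measured
    from baseline and censored at ``study_end``.  A recorded death before
    baseline is a data error naming the patients.
    """
    study_end = pd.Timestamp(study_end)
    d = deaths.copy()
    d["patient_id"] = d["patient_id"].astype(str)
    if d["patient_id"].duplicated().any():
        raise OutcomeDataError("multiple death records for one patient")
    death_map = d.set_index("patient_id")["date_of_death"]
    out = cohort[["patient_id", "index_date"]].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    out["death_date"] = pd.to_datetime(out["patient_id"].map(death_map))
    early = out[out["death_date"].notna() & (out["death_date"] < out["index_date"])]
    if len(early):
        raise OutcomeDataError(
            f"death before baseline for patient(s): {early['patient_id'].tolist()[:10]}"
        )
    event = out["death_date"].notna() & (out["death_date"] <= study_end)
    end = out["death_date"].where(event, study_end)
    out["event"] = event.astype(int)
    out["time_days"] = (end - out["index_date"]).dt.days
    out.loc[~event, "death_date"] = pd.NaT
    return out[["patient_id", "event", "time_days", "death_date"]]


def _is_nmsc(site_codes: pd.Series, nmsc_prefixes=DEFAULT_NMSC_PREFIXES) -> pd.Series:
    s = site_codes.astype(str).str.strip().str.upper()
    return s.str.startswith(tuple(p.upper() for p in nmsc_prefixes))


def derive_cancer(
    cancers: pd.DataFrame,
    cohort: pd.DataFrame,
    study_end,
    death_dates: pd.Series | None = None,
    exclude_prevalent: bool = False,
    nmsc_prefixes=DEFAULT_NMSC_PREFIXES,
    known_prefixes: tuple[str, ...] = ("C", "D"),
) -> pd.DataFrame:
    """Cancer-diagnosis outcome per cohort patient.

    The event is the earliest non-NMSC registry diagnosis strictly after
    baseline and at or before ``study_end``, with competing censoring at
    death.  Any non-NMSC diagnosis on or before baseline sets
    ``prior_cancer_flag``; such patients are retained unless
    ``exclude_prevalent`` is set (sensitivity analysis).  Site codes not
    matching a recognisable prefix raise a configuration error naming the
    code.
    """
    study_end = pd.Timestamp(study_end)
    c = cancers.copy()
    c["patient_id"] = c["patient_id"].astype(str)
    site = c["site_code"].astype(str).str.strip().str.upper()
    unknown = c[~site.str.startswith(tuple(known_prefixes))]
    if len(unknown):
        raise OutcomeDataError(
            f"unclassifiable cancer site code(s): {sorted(set(unknown['site_code']))[:10]}"
        )
    c = c[~_is_nmsc(c["site_code"], nmsc_prefixes)]

    out = cohort[["patient_id", "index_date"]].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    out = out.set_index("patient_id")

    merged = c.assign(index_date=c["patient_id"].map(out["index_date"]))
    merged = merged[merged["index_date"].notna()]
    prior = merged[merged["diagnosis_date"] <= merged["index_date"]]
    out["prior_cancer_flag"] = out.index.isin(prior["patient_id"])
    post = merged[
        (merged["diagnosis_date"] > merged["index_date"])
        & (merged["diagnosis_date"] <= study_end)
    ]
    first = post.groupby("patient_id")["diagnosis_date"].min()
    out["cancer_date"] = pd.to_datetime(first.reindex(out.index))

    if death_dates is not None:
        dd = death_dates.copy()
        dd.index = dd.index.astype(str)
        out["death_date"] = pd.to_datetime(dd.reindex(out.index))
    else:
        out["death_date"] = pd.NaT

    event = out["cancer_date"].notna()
    censor = out[["death_date"]].assign(study_end=study_end).min(axis=1)
    end = out["cancer_date"].where(event, censor)
    out["event"] = event.astype(int)
    out["time_days"] = (end - out["index_date"]).dt.days

    out = out.reset_index()
    if exclude_prevalent:
        n0 = len(out)
        out = out[~out["prior_cancer_flag"]].reset_index(drop=True)
        logger.info("excluded %d patients with prevalent cancer", n0 - len(out))
    return out[["patient_id", "event", "time_days", "cancer_date", "prior_cancer_flag"]]


def derive_consultation_rate(
    clinical: pd.DataFrame, baseline, followup_end
) -> float:
    """Consultation rate (per year) for one patient.

    Counts distinct calendar days bearing at least one clinical record in
    ``(baseline, followup_end]`` and divides by years of follow-up
    (days / 365.25).  Zero records is a valid rate of 0; non-positive
    follow-up is an error.
    """
    baseline, followup_end = pd.Timestamp(baseline), pd.Timestamp(followup_end)
    days = (followup_end - baseline).days
    if days <= 0:
        raise OutcomeDataError("non-positive follow-up period")
    d = pd.to_datetime(clinical["date"])
    in_window = d[(d > baseline) & (d <= followup_end)]
    n_days = in_window.dt.normalize().nunique()
    return float(n_days) / (days / DAYS_PER_YEAR)


def consultation_rate_table(
    clinical: pd.DataFrame, cohort: pd.DataFrame, followup_end: pd.Series
) -> pd.DataFrame:
    """Vectorised consultation rate for a whole cohort.

    ``followup_end`` is a per-patient Series (indexed by patient_id):
    min(death, end of bridged GP registration, study end).
    """
    out = cohort[["patient_id", "index_date"]].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    fe = followup_end.copy()
    fe.index = fe.index.astype(str)
    out["followup_end"] = out["patient_id"].map(fe)
    days = (out["followup_end"] - out["index_date"]).dt.days
    if (days <= 0).any():
        bad = out.loc[days <= 0, "patient_id"].tolist()[:10]
        raise OutcomeDataError(f"non-positive follow-up for patient(s): {bad}")

    rec = clinical.copy()
    rec["patient_id"] = rec["patient_id"].astype(str)
    rec = rec.merge(out[["patient_id", "index_date", "followup_end"]], on="patient_id")
    rec = rec[(rec["date"] > rec["index_date"]) & (rec["date"] <= rec["followup_end"])]
    n_days = (
        rec.assign(day=rec["date"].dt.normalize())
        .drop_duplicates(["patient_id", "day"])
        .groupby("patient_id")
        .size()
    )
    out["consult_day_count"] = out["patient_id"].map(n_days).fillna(0).astype(int)
    out["followup_years"] = days / DAYS_PER_YEAR
    out["consult_rate"] = out["consult_day_count"] / out["followup_years"]
    return out[["patient_id", "consult_day_count", "followup_years", "consult_rate"]]


@dataclass
class AnalysisTable:
    """Per-patient analysis records plus a cohort summary by condition count."""

    records: pd.DataFrame
    summary: pd.DataFrame


def assemble_analysis_table(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    death: pd.DataFrame,
    cancer: pd.DataFrame,
    consultation: pd.DataFrame,
    condition_count: pd.Series,
    demographics: pd.DataFrame | None = None,
    gp_coverage_end: pd.Series | None = None,
) -> AnalysisTable:
    """Join scores and outcomes into one analysis record per eligible patient.

    ``scores`` is the long-format score table; it is pivoted to one column
    per (model, variant).  Patients present in scores but missing from any
    outcome table raise a consistency error.  The summary stratifies
    counts and outcome measures by 0 / 1 / >1 conditions.
    """
    base = cohort[["patient_id", "index_date"]].copy()
    base["patient_id"] = base["patient_id"].astype(str)

    wide = scores.copy()
    wide["patient_id"] = wide["patient_id"].astype(str)
    wide["col"] = "score_" + wide["model_id"].astype(str) + np.where(
        wide["variant"] == "short", "_short", ""
    )
    wide = wide.pivot_table(index="patient_id", columns="col", values="value")

    out = base.merge(wide, left_on="patient_id", right_index=True, how="left")
    for name, table, cols in (
        ("death", death, {"event": "event_death", "time_days": "time_death_days"}),
        ("cancer", cancer, {"event": "event_cancer", "time_days": "time_cancer_days",
                            "prior_cancer_flag": "prior_cancer_flag"}),
        ("consultation", consultation,
         {"consult_rate": "consult_rate", "consult_day_count": "consult_day_count",
          "followup_years": "followup_years"}),
    ):
        t = table.copy()
        t["patient_id"] = t["patient_id"].astype(str)
        missing = set(out["patient_id"]) - set(t["patient_id"])
        if missing and name != "consultation":
            raise OutcomeDataError(
                f"patient(s) scored but missing from {name} outcomes: {sorted(missing)[:10]}"
            )
        out = out.merge(
            t[["patient_id", *cols]].rename(columns=cols), on="patient_id", how="left"
        )
    cc = condition_count.copy()
    cc.index = cc.index.astype(str)
    out["n_conditions"] = out["patient_id"].map(cc)
    if out["n_conditions"].isna().any():
        raise OutcomeDataError("patients missing from the condition matrix")
    if demographics is not None:
        demo = demographics.copy()
        demo["patient_id"] = demo["patient_id"].astype(str)
        out = out.merge(demo[["patient_id", "age", "sex"]], on="patient_id", how="left")
    if gp_coverage_end is not None:
        gce = gp_coverage_end.copy()
        gce.index = gce.index.astype(str)
        out["gp_coverage_years"] = (
            out["patient_id"].map(gce) - out["index_date"]
        ).dt.days / DAYS_PER_YEAR

    out["time_death_years"] = out["time_death_days"] / DAYS_PER_YEAR
    out["time_cancer_years"] = out["time_cancer_days"] / DAYS_PER_YEAR

    return AnalysisTable(records=out, summary=cohort_summary(out))


def cohort_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics stratified by 0 / 1 / >1 conditions."""
    groups = {
        "whole_cohort": records,
        "no_conditions": records[records["n_conditions"] == 0],
        "one_condition": records[records["n_conditions"] == 1],
        "multimorbid": records[records["n_conditions"] > 1],
    }
    rows = []
    for label, grp in groups.items():
        row = {"group": label, "n": len(grp)}
        if "event_death" in grp:
            row["deaths"] = int(grp["event_death"].sum()) if len(grp) else 0
        if "event_cancer" in grp:
            row["cancers"] = int(grp["event_cancer"].sum()) if len(grp) else 0
        if "consult_rate" in grp and len(grp):
            row["median_consult_rate"] = float(grp["consult_rate"].median())
        rows.append(row)
    return pd.DataFrame(rows)
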