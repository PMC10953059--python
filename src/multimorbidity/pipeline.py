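"""End-to-end convenience: from raw study tables to the analysis table.

Chains the pipeline stages in the order a validation study runs them:
eligibility filtering, condition ascertainment at baseline, score
computation, outcome derivation with censoring, and assembly of one
analysis record per eligible patient.
"""

from __future__ import annotations

import pandas as pd

from .cohort import (
    assemble_analysis_table,
    consultation_rate_table,
    derive_cancer,
    derive_death,
    eligibility_table,
)
from .phenotype import build_condition_matrix
from .score import score_table
from .synthdata import SyntheticStudy


def analyse_study(
    study: SyntheticStudy,
    rules=None,
    weights=None,
    exclude_prevalent_cancer: bool = False,
    variant: str = "full",
):
    """Run the whole validation pipeline on one study bundle.

    Returns an :class:`~multimorbidity.cohort.AnalysisTable` whose records
    carry the scores (``score_general`` etc.), outcome times/flags and
    follow-up metadata needed by the validation module.
    """
    if rules is None:
        from .fixtures import load_fixture_rules
        rules = load_fixture_rules()
    if weights is None:
        from .fixtures import load_fixture_weights
        weights = load_fixture_weights()

    study_end = pd.Timestamp(study.config.study_end)
    elig = eligibility_table(study.registration, study.cohort)
    cohort = study.cohort.merge(elig, on="patient_id")
    eligible = cohort[cohort["eligible"]].reset_index(drop=True)

    records = pd.concat([study.clinical, study.scripts], ignore_index=True)
    matrix = build_condition_matrix(eligible, records, rules)
    scores = score_table(matrix, weights, study.demographics, variant=variant)

    death = derive_death(study.deaths, eligible, study_end)
    death_dates = death.set_index("patient_id")["death_date"]
    cancer = derive_cancer(
        study.cancers, eligible, study_end,
        death_dates=death_dates, exclude_prevalent=exclude_prevalent_cancer,
    )
    if exclude_prevalent_cancer:
        keep = set(cancer["patient_id"])
        eligible = eligible[eligible["patient_id"].isin(keep)].reset_index(drop=True)
        scores = scores[scores["patient_id"].isin(keep)]
        death = death[death["patient_id"].isin(keep)]
        matrix.indicators = matrix.indicators.loc[sorted(keep)]

    gp_end = eligible.set_index("patient_id")["gp_coverage_end"]
    followup_end = pd.concat([death_dates.reindex(gp_end.index), gp_end], axis=1)
    followup_end = followup_end.assign(study_end=study_end).min(axis=1)
    consult = consultation_rate_table(study.clinical, eligible, followup_end)

    return assemble_analysis_table(
        eligible, scores, death, cancer, consult,
        matrix.condition_count, study.demographics, gp_end,
    )
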