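"""Registry of the 37 long-term conditions used by the multimorbidity scores.

The Cambridge Multimorbidity Score family is defined over a fixed panel of
37 chronic conditions curated for UK primary-care records (the
CPRD@Cambridge condition set).  Every downstream structure — codelists,
phenotyping rules, indicator matrices, score weights — is keyed by these
identifiers, so they live in one place.
"""

from __future__ import annotations

CONDITIONS: tuple[str, ...] = (
    "painful_condition",
    "hypertension",
    "anxiety_depression",
    "hearing_loss",
    "irritable_bowel_syndrome",
    "asthma",
    "diabetes",
    "coronary_heart_disease",
    "chronic_kidney_disease",
    "thyroid_disorder",
    "cancer",
    "atrial_fibrillation",
    "constipation",
    "stroke_tia",
    "copd",
    "connective_tissue_disorder",
    "diverticular_disease",
    "heart_failure",
    "dementia",
    "epilepsy",
    "schizophrenia_bipolar",
    "psoriasis_eczema",
    "inflammatory_bowel_disease",
    "migraine",
    "blindness",
    "peripheral_vascular_disease",
    "parkinsons",
    "anorexia_bulimia",
    "alcohol_problem",
    "substance_misuse",
    "chronic_liver_disease",
    "prostate_disorder",
    "glaucoma",
    "learning_disability",
    "multiple_sclerosis",
    "bronchiectasis",
    "chronic_sinusitis",
)

N_CONDITIONS = len(CONDITIONS)

assert N_CONDITIONS == 37
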