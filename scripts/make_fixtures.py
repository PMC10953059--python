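"""Regenerate the packaged fixture data (codelists, lookup, rules, weights).

All fixture content is synthetic: code strings follow the *shape* of Read
v2 / CTV3 / BNF codes but are fabricated, and the score weights are fixed
plausible values, NOT the development-study coefficients (which are not
redistributed here).  Deterministic: running this script always produces
identical files.
"""

from __future__ import annotations

import csv
from pathlib import Path

import yaml

import sys

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
from multimorbidity.conditions import CONDITIONS  # noqa: E402

DATA = Path(__file__).resolve().parents[1] / "src" / "multimorbidity" / "data"
DATA.mkdir(parents=True, exist_ok=True)

# conditions ascertained purely from prescriptions (no diagnosis list)
RX_ONLY = {"painful_condition", "migraine", "constipation"}
# conditions with a prescription list alongside the diagnosis list
RX_ALSO = {
    "anxiety_depression", "asthma", "epilepsy", "psoriasis_eczema",
    "irritable_bowel_syndrome",
}
TEST_ONLY = {"chronic_kidney_disease"}

GENERAL_WEIGHTS = {
    "painful_condition": 0.65, "hypertension": 0.08, "anxiety_depression": 0.50,
    "hearing_loss": 0.15, "irritable_bowel_syndrome": 0.21, "asthma": 0.19,
    "diabetes": 0.75, "coronary_heart_disease": 0.74, "chronic_kidney_disease": 0.53,
    "thyroid_disorder": 0.06, "cancer": 1.53, "atrial_fibrillation": 1.08,
    "constipation": 1.12, "stroke_tia": 0.80, "copd": 1.05,
    "connective_tissue_disorder": 0.44, "diverticular_disease": 0.26,
    "heart_failure": 1.96, "dementia": 2.50, "epilepsy": 0.92,
    "schizophrenia_bipolar": 0.47, "psoriasis_eczema": 0.24,
    "inflammatory_bowel_disease": 0.30, "migraine": 0.36, "blindness": 0.77,
    "peripheral_vascular_disease": 0.74, "parkinsons": 1.45,
    "anorexia_bulimia": 0.35, "alcohol_problem": 0.68, "substance_misuse": 1.10,
    "chronic_liver_disease": 1.42, "prostate_disorder": 0.42, "glaucoma": 0.21,
    "learning_disability": 0.60, "multiple_sclerosis": 0.89,
    "bronchiectasis": 0.52, "chronic_sinusitis": 0.07,
}

NOTES = (
    "synthetic fixture weights - fixed plausible values, not the development-study "
    "coefficients; age term: continuous years at baseline; sex coded 0=female 1=male"
)


def diag_codes(i: int) -> list[str]:
    return [f"{chr(65 + i % 26)}{i:02d}{j}." for j in range(1, 4)]


def rx_codes(k: int) -> list[str]:
    return [f"04{k:02d}0{j}00" for j in range(1, 4)]


def main() -> None:
    # ---- codelists ----------------------------------------------------
    diag_rows, rx_rows = [], []
    rx_index = 0
    for i, cid in enumerate(CONDITIONS):
        if cid not in RX_ONLY | TEST_ONLY:
            for code in diag_codes(i):
                diag_rows.append((code, cid))
        if cid in RX_ONLY | RX_ALSO:
            for code in rx_codes(rx_index):
                rx_rows.append((code, cid))
            rx_index += 1
    with open(DATA / "codelists_diagnosis_read2.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "condition_id"])
        w.writerows(diag_rows)
    with open(DATA / "codelists_prescription_bnf.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "condition_id"])
        w.writerows(rx_rows)
    with open(DATA / "codelists_test_read2.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "condition_id"])
        for code in ("451E.", "451F.", "451G."):
            w.writerow([code, "chronic_kidney_disease"])

    # ---- Read2 -> CTV3 lookup (plus overrides) ------------------------
    lookup_rows, override_rows = [], []
    for idx, (code, cid) in enumerate(diag_rows):
        if idx % 11 == 10:
            continue  # deliberately unmapped, exercised by the audit
        lookup_rows.append((code, "READ2", f"Y{code[:4]}"))
        if code.endswith("1."):
            lookup_rows.append((code, "READ2", f"Z{code[:4]}"))  # one-to-many
    # overrides: manual correction for two codes (one otherwise unmapped)
    override_rows.append((diag_rows[10][0], f"Q{diag_rows[10][0][:4]}"))
    override_rows.append((diag_rows[0][0], f"Q{diag_rows[0][0][:4]}"))
    with open(DATA / "lookup_read2_ctv3.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_code", "source_framework", "target_code"])
        w.writerows(lookup_rows)
    with open(DATA / "overrides_read2_ctv3.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_code", "target_code"])
        w.writerows(override_rows)

    # ---- phenotyping rules --------------------------------------------
    rules: dict[str, dict] = {}
    for cid in CONDITIONS:
        if cid == "chronic_kidney_disease":
            rules[cid] = {"last_n_tests": {
                "codelist": "egfr_test", "n": 2, "threshold": 60, "direction": "below"}}
        elif cid in RX_ONLY:
            rules[cid] = {"rx_recent": {
                "codelist": f"{cid}_rx", "min_count": 4, "window_months": 12}}
        elif cid == "anxiety_depression":
            rules[cid] = {"any_of": [
                {"within": {"codelist": f"{cid}_diag", "years": 5}},
                {"rx_recent": {"codelist": f"{cid}_rx", "min_count": 4,
                               "window_months": 12}},
            ]}
        elif cid == "irritable_bowel_syndrome":
            rules[cid] = {"any_of": [
                {"ever": {"codelist": f"{cid}_diag"}},
                {"rx_recent": {"codelist": f"{cid}_rx", "min_count": 4,
                               "window_months": 12}},
            ]}
        elif cid in ("asthma", "epilepsy"):
            rules[cid] = {"all_of": [
                {"ever": {"codelist": f"{cid}_diag"}},
                {"rx_recent": {"codelist": f"{cid}_rx", "min_count": 1,
                               "window_months": 12}},
            ]}
        elif cid == "psoriasis_eczema":
            rules[cid] = {"all_of": [
                {"ever": {"codelist": f"{cid}_diag"}},
                {"rx_recent": {"codelist": f"{cid}_rx", "min_count": 4,
                               "window_months": 12}},
            ]}
        elif cid in ("anorexia_bulimia", "substance_misuse"):
            rules[cid] = {"within": {"codelist": f"{cid}_diag", "years": 5}}
        else:
            rules[cid] = {"ever": {"codelist": f"{cid}_diag"}}
    with open(DATA / "rules.yaml", "w") as fh:
        yaml.safe_dump({"conditions": rules}, fh, sort_keys=False)

    # ---- score weights -------------------------------------------------
    rows = []
    for i, cid in enumerate(CONDITIONS):
        g = GENERAL_WEIGHTS[cid]
        mort = round(0.85 * g + 0.02 * ((i * 7) % 5), 3)
        hosp = round(0.60 * g + 0.015 * ((i * 3) % 7), 3)
        rows.append(("general", cid, g))
        rows.append(("mortality", cid, mort))
        rows.append(("hospital", cid, hosp))
    rows.append(("mortality", "age", 0.083))
    rows.append(("mortality", "sex", 0.25))
    rows.append(("hospital", "age", 0.031))
    rows.append(("hospital", "sex", 0.12))
    mort_by_cond = {
        cid: next(r[2] for r in rows if r[0] == "mortality" and r[1] == cid)
        for cid in CONDITIONS
    }
    short = sorted(CONDITIONS, key=lambda c: -mort_by_cond[c])[:20]
    for cid in short:
        rows.append(("short_subset", cid, 1))
    with open(DATA / "weights_fixture.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["model_id", "term", "coefficient", "notes"])
        for model, term, coef in rows:
            w.writerow([model, term, coef, NOTES])
    print(f"fixtures written to {DATA}")


if __name__ == "__main__":
    main()
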