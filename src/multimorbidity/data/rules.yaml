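conditions:
  painful_condition:
    rx_recent:
      codelist: painful_condition_rx
      min_count: 4
      window_months: 12
  hypertension:
    ever:
      codelist: hypertension_diag
  anxiety_depression:
    any_of:
    - within:
        codelist: anxiety_depression_diag
        years: 5
    - rx_recent:
        codelist: anxiety_depression_rx
        min_count: 4
        window_months: 12
  hearing_loss:
    ever:
      codelist: hearing_loss_diag
  irritable_bowel_syndrome:
    any_of:
    - ever:
        codelist: irritable_bowel_syndrome_diag
    - rx_recent:
        codelist: irritable_bowel_syndrome_rx
        min_count: 4
        window_months: 12
  asthma:
    all_of:
    - ever:
        codelist: asthma_diag
    - rx_recent:
        codelist: asthma_rx
        min_count: 1
        window_months: 12
  diabetes:
    ever:
      codelist: diabetes_diag
  coronary_heart_disease:
    ever:
      codelist: coronary_heart_disease_diag
  chronic_kidney_disease:
    last_n_tests:
      codelist: egfr_test
      n: 2
      threshold: 60
      direction: below
  thyroid_disorder:
    ever:
      codelist: thyroid_disorder_diag
  cancer:
    ever:
      codelist: cancer_diag
  atrial_fibrillation:
    ever:
      codelist: atrial_fibrillation_diag
  constipation:
    rx_recent:
      codelist: constipation_rx
      min_count: 4
      window_months: 12
  stroke_tia:
    ever:
      codelist: stroke_tia_diag
  copd:
    ever:
      codelist: copd_diag
  connective_tissue_disorder:
    ever:
      codelist: connective_tissue_disorder_diag
  diverticular_disease:
    ever:
      codelist: diverticular_disease_diag
  heart_failure:
    ever:
      codelist: heart_failure_diag
  dementia:
    ever:
      codelist: dementia_diag
  epilepsy:
    all_of:
    - ever:
        codelist: epilepsy_diag
    - rx_recent:
        codelist: epilepsy_rx
        min_count: 1
        window_months: 12
  schizophrenia_bipolar:
    ever:
      codelist: schizophrenia_bipolar_diag
  psoriasis_eczema:
    all_of:
    - ever:
        codelist: psoriasis_eczema_diag
    - rx_recent:
        codelist: psoriasis_eczema_rx
        min_count: 4
        window_months: 12
  inflammatory_bowel_disease:
    ever:
      codelist: inflammatory_bowel_disease_diag
  migraine:
    rx_recent:
      codelist: migraine_rx
      min_count: 4
      window_months: 12
  blindness:
    ever:
      codelist: blindness_diag
  peripheral_vascular_disease:
    ever:
      codelist: peripheral_vascular_disease_diag
  parkinsons:
    ever:
      codelist: parkinsons_diag
  anorexia_bulimia:
    within:
      codelist: anorexia_bulimia_diag
      years: 5
  alcohol_problem:
    ever:
      codelist: alcohol_problem_diag
  substance_misuse:
    within:
      codelist: substance_misuse_diag
      years: 5
  chronic_liver_disease:
    ever:
      codelist: chronic_liver_disease_diag
  prostate_disorder:
    ever:
      codelist: prostate_disorder_diag
  glaucoma:
    ever:
      codelist: glaucoma_diag
  learning_disability:
    ever:
      codelist: learning_disability_diag
  multiple_sclerosis:
    ever:
      codelist: multiple_sclerosis_diag
  bronchiectasis:
    ever:
      codelist: bronchiectasis_diag
  chronic_sinusitis:
    ever:
      codelist: chronic_sinusitis_diag
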