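"""Synthetic primary-care cohort generation with known ground truth.

Real coded primary-care extracts cannot be redistributed, so every stage
of the pipeline is exercised against cohorts generated here from known
generative models:

* demographics shaped like a mid-life population cohort (ages 40–70 at a
  baseline assessment dated 2006–2010, study end 2016-07-10);
* conditions planted per patient from configurable prevalences (printed
  cohort prevalences are used where available for the common
  conditions); an optional shared latent factor (Gaussian copula) induces
  comorbidity clustering without disturbing the marginal prevalences,
  since real conditions do not occur independently;
* coded records engineered to *satisfy* each planted condition's
  phenotyping rule, plus deliberate near-miss decoys that must NOT
  satisfy it (one prescription where four are required, a low eGFR
  followed by a normal one, events dated on or after baseline) — so
  phenotyping can be checked for exact recovery of the planted matrix;
* survival outcomes drawn from exponential proportional-hazards models
  with known prognostic indices, administratively censored at study end;
* overdispersed consultation-day counts (negative binomial, log-mean
  linear in the condition count), emitted as dated records with
  deliberate same-day duplicates to exercise the dedup rule.

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .codemap import Domain
from .conditions import CONDITIONS
from .phenotype import (
    AllOf, AnyOf, ConditionRule, Ever, LastNTests, RecentRx, Within,
    DAYS_PER_MONTH, DAYS_PER_YEAR,
)

logger = logging.getLogger(__name__)

#: Default per-condition baseline prevalences.  The common conditions use
#: the values reported for a UK mid-life cohort with linked primary-care
#: records (painful condition 16.8%, hypertension 16.5%,
#: anxiety/depression 9.7%, IBS 6.1%, CKD 2.5%, dementia ~0.015%); the
#: remainder are plausible round figures for such a cohort.
DEFAULT_PREVALENCE: dict[str, float] = {
    "painful_condition": 0.168,
    "hypertension": 0.165,
    "anxiety_depression": 0.097,
    "hearing_loss": 0.055,
    "irritable_bowel_syndrome": 0.061,
    "asthma": 0.060,
    "diabetes": 0.045,
    "coronary_heart_disease": 0.030,
    "chronic_kidney_disease": 0.025,
    "thyroid_disorder": 0.035,
    "cancer": 0.045,
    "atrial_fibrillation": 0.012,
    "constipation": 0.012,
    "stroke_tia": 0.015,
    "copd": 0.012,
    "connective_tissue_disorder": 0.020,
    "diverticular_disease": 0.025,
    "heart_failure": 0.005,
    "dementia": 0.00015,
    "epilepsy": 0.006,
    "schizophrenia_bipolar": 0.004,
    "psoriasis_eczema": 0.022,
    "inflammatory_bowel_disease": 0.008,
    "migraine": 0.012,
    "blindness": 0.001,
    "peripheral_vascular_disease": 0.005,
    "parkinsons": 0.001,
    "anorexia_bulimia": 0.002,
    "alcohol_problem": 0.010,
    "substance_misuse": 0.003,
    "chronic_liver_disease": 0.003,
    "prostate_disorder": 0.020,
    "glaucoma": 0.010,
    "learning_disability": 0.0005,
    "multiple_sclerosis": 0.003,
    "bronchiectasis": 0.002,
    "chronic_sinusitis": 0.009,
}

#: Neutral clinical code used for consultation-day records; deliberately
#: outside every fixture codelist so consultations never flip a condition.
CONSULTATION_CODE = "9N11."


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort generator (defaults = study conditions)."""

    n_patients: int = 1000
    seed: int = 0
    condition_prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    #: Pairwise latent correlation of a shared comorbidity factor (Gaussian
    #: copula); 0 = independent conditions.  Marginal prevalences are
    #: preserved exactly for any value.
    comorbidity_correlation: float = 0.0
    #: expected number of near-miss decoy conditions per patient
    decoy_mean: float = 1.0

    # study window and demographics
    baseline_start: str = "2006-03-01"
    baseline_end: str = "2010-10-01"
    study_end: str = "2016-07-10"
    age_min: float = 40.0
    age_max: float = 70.0
    age_center: float = 57.0
    male_fraction: float = 0.463

    # registration-gap process
    p_registration_gap: float = 0.05  # disqualifying gap (>90 d) near baseline
    p_bridgeable_gap: float = 0.05    # short gap (<=90 d), still eligible
    p_short_history: float = 0.02     # registered < 1 year before baseline
    p_early_deregistration: float = 0.35

    # exponential PH survival models (hazards per person-year at reference)
    death_base_hazard: float = 0.003
    death_age_coef: float = 0.083
    death_sex_coef: float = 0.25
    death_condition_coef: Mapping[str, float] | None = None  # default: fixture mortality betas
    cancer_base_hazard: float = 0.009
    cancer_age_coef: float = 0.045
    cancer_sex_coef: float = 0.10
    cancer_condition_coef: Mapping[str, float] | None = None  # default: 0.25 x mortality betas
    p_prevalent_cancer: float = 0.05
    p_nmsc: float = 0.03

    # negative-binomial consultation model: annual mean = base * exp(slope * n_conditions)
    consult_base_rate: float = 5.5
    consult_slope: float = 0.25
    consult_dispersion: float = 2.0
    consult_duplicate_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for cid, p in self.condition_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {cid} outside [0, 1]")
        for h in (self.death_base_hazard, self.cancer_base_hazard):
            if h <= 0:
                raise ValueError("baseline hazards must be > 0")


@dataclass
class SyntheticStudy:
    """Everything one simulated study produces, in pipeline-ready tables."""

    clinical: pd.DataFrame      # coded-record dialect (diagnosis/test events)
    scripts: pd.DataFrame       # coded-record dialect (prescriptions)
    registration: pd.DataFrame  # patient_id, start, end, provider
    demographics: pd.DataFrame  # patient_id, age, sex
    cohort: pd.DataFrame        # patient_id, index_date
    deaths: pd.DataFrame        # patient_id, date_of_death
    cancers: pd.DataFrame       # patient_id, diagnosis_date, site_code
    matrix_true: pd.DataFrame   # planted condition indicators (ground truth)
    config: SynthConfig


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def _coefs(config: SynthConfig, outcome: str) -> dict[str, float]:
    if outcome == "death":
        if config.death_condition_coef is not None:
            return dict(config.death_condition_coef)
        from .fixtures import load_fixture_weights
        return dict(load_fixture_weights()["mortality"].condition_weight)
    if config.cancer_condition_coef is not None:
        return dict(config.cancer_condition_coef)
    from .fixtures import load_fixture_weights
    mort = load_fixture_weights()["mortality"].condition_weight
    return {c: 0.25 * b for c, b in mort.items()}


def true_prognostic_index(
    matrix: pd.DataFrame, demographics: pd.DataFrame, config: SynthConfig,
    outcome: str = "death",
) -> pd.Series:
    """The generating-model linear predictor per patient (age centred)."""
    betas = _coefs(config, outcome)
    if outcome == "death":
        a, s = config.death_age_coef, config.death_sex_coef
    else:
        a, s = config.cancer_age_coef, config.cancer_sex_coef
    demo = demographics.set_index("patient_id").loc[matrix.index]
    w = pd.Series({c: betas[c] for c in CONDITIONS}, dtype=float)
    return (
        matrix[list(CONDITIONS)] @ w
        + a * (demo["age"] - config.age_center)
        + s * demo["sex"]
    )


# ---------------------------------------------------------------------------
# planting

def plant_conditions(config: SynthConfig, rng) -> pd.DataFrame:
    """Draw the ground-truth condition matrix from the configured prevalences.

    With ``comorbidity_correlation`` ρ > 0, conditions share a latent
    per-patient factor through a Gaussian copula: condition i is present
    iff ``sqrt(ρ)·u + sqrt(1-ρ)·e_i < Φ⁻¹(p_i)``, which keeps every
    marginal prevalence exactly ``p_i`` while clustering conditions in
    the same patients.
    """
    rng = _rng(rng)
    n = config.n_patients
    patients = pd.Index([f"P{i:06d}" for i in range(n)], name="patient_id")
    p = np.array([config.condition_prevalence.get(c, 0.0) for c in CONDITIONS])
    rho = config.comorbidity_correlation
    if rho > 0:
        from scipy.stats import norm

        thresholds = norm.ppf(np.clip(p, 1e-12, 1 - 1e-12))
        u = rng.standard_normal(n)[:, None]
        e = rng.standard_normal((n, len(CONDITIONS)))
        z = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * e
        x = (z < thresholds[None, :]).astype(np.int8)
    else:
        x = (rng.random((n, len(CONDITIONS))) < p).astype(np.int8)
    return pd.DataFrame(x, index=patients, columns=list(CONDITIONS))


def _draw_demographics(config: SynthConfig, rng, patients: pd.Index) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(patients)
    age = rng.uniform(config.age_min, config.age_max, n).round(1)
    sex = (rng.random(n) < config.male_fraction).astype(int)
    start = pd.Timestamp(config.baseline_start)
    span = (pd.Timestamp(config.baseline_end) - start).days
    baseline = start + pd.to_timedelta(rng.integers(0, span + 1, n), unit="D")
    demographics = pd.DataFrame({"patient_id": patients, "age": age, "sex": sex})
    cohort = pd.DataFrame({"patient_id": patients, "index_date": baseline})
    return demographics, cohort


def _registration_for(config: SynthConfig, rng, baseline: pd.Timestamp) -> list[tuple]:
    study_end = pd.Timestamp(config.study_end)
    u = rng.random()
    if u < config.p_short_history:
        reg_start = baseline - pd.Timedelta(days=int(rng.integers(100, 300)))
    else:
        reg_start = baseline - pd.Timedelta(days=int(rng.integers(550, 2900)))
    if rng.random() < config.p_early_deregistration:
        max_days = max(201, (study_end - baseline).days)
        reg_end = baseline + pd.Timedelta(days=int(rng.integers(200, max_days + 1)))
        reg_end = min(reg_end, study_end)
    else:
        reg_end = study_end

    v = rng.random()
    if v < config.p_registration_gap:
        gap = int(rng.integers(91, 181))
    elif v < config.p_registration_gap + config.p_bridgeable_gap:
        gap = int(rng.integers(20, 91))
    else:
        gap = 0
    if gap and reg_start < baseline - pd.Timedelta(days=320):
        break_end = baseline - pd.Timedelta(days=int(rng.integers(150, 320)))
        next_start = break_end + pd.Timedelta(days=gap + 1)
        return [(reg_start, break_end), (next_start, reg_end)]
    return [(reg_start, reg_end)]


# ---------------------------------------------------------------------------
# record emission per rule

def _pick_code(codeset, rng) -> str:
    return str(rng.choice(sorted(codeset.codes)))


def _emit(out: dict, patient_id: str, date: pd.Timestamp, code: str,
          domain: Domain, value=np.nan) -> None:
    stream = out["scripts"] if domain is Domain.PRESCRIPTION else out["clinical"]
    stream.append((patient_id, date, code, domain.value, value))


def _emit_satisfy(node, pid: str, baseline: pd.Timestamp, rng, out: dict) -> None:
    if isinstance(node, AllOf):
        for child in node.children:
            _emit_satisfy(child, pid, baseline, rng, out)
        return
    if isinstance(node, AnyOf):
        _emit_satisfy(node.children[int(rng.integers(len(node.children)))],
                      pid, baseline, rng, out)
        return
    if isinstance(node, Ever):
        date = baseline - pd.Timedelta(days=int(rng.integers(30, 3650)))
        _emit(out, pid, date, _pick_code(node.codeset, rng), node.codeset.domain)
        return
    if isinstance(node, Within):
        window = round(node.years * DAYS_PER_YEAR)
        date = baseline - pd.Timedelta(days=int(rng.integers(10, max(11, window - 10))))
        _emit(out, pid, date, _pick_code(node.codeset, rng), node.codeset.domain)
        return
    if isinstance(node, RecentRx):
        window = round(node.window_months * DAYS_PER_MONTH)
        days = rng.choice(np.arange(1, max(node.min_count + 1, window - 10)),
                          size=node.min_count, replace=False)
        for d in days:
            _emit(out, pid, baseline - pd.Timedelta(days=int(d)),
                  _pick_code(node.codeset, rng), node.codeset.domain)
        return
    if isinstance(node, LastNTests):
        days = np.sort(rng.choice(np.arange(30, 1500), size=node.n, replace=False))
        for d in days:
            if node.direction == "below":
                value = float(rng.uniform(node.threshold - 35, node.threshold - 5))
            else:
                value = float(rng.uniform(node.threshold + 5, node.threshold + 35))
            _emit(out, pid, baseline - pd.Timedelta(days=int(d)),
                  _pick_code(node.codeset, rng), node.codeset.domain, round(value, 1))
        return
    raise TypeError(f"unknown rule node {node!r}")


def _emit_decoy(node, pid: str, baseline: pd.Timestamp, rng, out: dict) -> None:
    """Emit near-miss records guaranteed NOT to satisfy ``node``."""
    if isinstance(node, AllOf):
        # violate the first conjunct, satisfy the rest
        _emit_decoy(node.children[0], pid, baseline, rng, out)
        for child in node.children[1:]:
            _emit_satisfy(child, pid, baseline, rng, out)
        return
    if isinstance(node, AnyOf):
        for child in node.children:
            _emit_decoy(child, pid, baseline, rng, out)
        return
    if isinstance(node, Ever):
        # on the index day (strictly-prior boundary) or after it
        offset = 0 if rng.random() < 0.3 else int(rng.integers(1, 120))
        _emit(out, pid, baseline + pd.Timedelta(days=offset),
              _pick_code(node.codeset, rng), node.codeset.domain)
        return
    if isinstance(node, Within):
        window = round(node.years * DAYS_PER_YEAR)
        date = baseline - pd.Timedelta(days=window + int(rng.integers(30, 400)))
        _emit(out, pid, date, _pick_code(node.codeset, rng), node.codeset.domain)
        return
    if isinstance(node, RecentRx):
        window = round(node.window_months * DAYS_PER_MONTH)
        if node.min_count > 1:
            days = rng.choice(np.arange(1, window - 10), size=node.min_count - 1,
                              replace=False)
            for d in days:
                _emit(out, pid, baseline - pd.Timedelta(days=int(d)),
                      _pick_code(node.codeset, rng), node.codeset.domain)
        else:
            date = baseline - pd.Timedelta(days=window + int(rng.integers(30, 200)))
            _emit(out, pid, date, _pick_code(node.codeset, rng), node.codeset.domain)
        return
    if isinstance(node, LastNTests):
        sign = -1.0 if node.direction == "below" else 1.0
        if node.n > 1 and rng.random() < 0.5:
            # insufficient evidence: n-1 qualifying tests only
            days = np.sort(rng.choice(np.arange(30, 1500), size=node.n - 1, replace=False))
            for d in days:
                value = node.threshold + sign * float(rng.uniform(5, 35))
                _emit(out, pid, baseline - pd.Timedelta(days=int(d)),
                      _pick_code(node.codeset, rng), node.codeset.domain, round(value, 1))
        else:
            # qualifying result superseded by a normal one
            d_old = int(rng.integers(400, 1500))
            d_new = int(rng.integers(30, 399))
            bad = node.threshold + sign * float(rng.uniform(5, 35))
            good = node.threshold - sign * float(rng.uniform(5, 35))
            _emit(out, pid, baseline - pd.Timedelta(days=d_old),
                  _pick_code(node.codeset, rng), node.codeset.domain, round(bad, 1))
            _emit(out, pid, baseline - pd.Timedelta(days=d_new),
                  _pick_code(node.codeset, rng), node.codeset.domain, round(good, 1))
        return
    raise TypeError(f"unknown rule node {node!r}")


# ---------------------------------------------------------------------------
# main operations

def generate_ehr(
    config: SynthConfig,
    rules: Mapping[str, ConditionRule] | None = None,
) -> SyntheticStudy:
    """Generate coded records, registration spells and demographics.

    Records are constructed so that phenotyping recovers the planted
    condition matrix exactly: every planted condition gets rule-
    satisfying records, and decoy conditions get near-miss records that
    must evaluate to 0.  Deterministic given ``config.seed``.
    """
    if rules is None:
        from .fixtures import load_fixture_rules
        rules = load_fixture_rules()
    rng = np.random.default_rng(config.seed)
    matrix = plant_conditions(config, rng)
    patients = matrix.index
    demographics, cohort = _draw_demographics(config, rng, patients)
    baselines = dict(zip(cohort["patient_id"], cohort["index_date"]))

    out = {"clinical": [], "scripts": []}
    reg_rows = []
    cond_list = list(CONDITIONS)
    mat = matrix.to_numpy()
    for row, pid in enumerate(patients):
        baseline = baselines[pid]
        for start, end in _registration_for(config, rng, baseline):
            reg_rows.append((pid, start, end, "TPP"))
        planted = np.flatnonzero(mat[row])
        for k in planted:
            _emit_satisfy(rules[cond_list[k]].rule, pid, baseline, rng, out)
        n_decoys = int(rng.poisson(config.decoy_mean))
        if n_decoys:
            unplanted = np.flatnonzero(mat[row] == 0)
            chosen = rng.choice(unplanted, size=min(n_decoys, len(unplanted)),
                                replace=False)
            for k in chosen:
                _emit_decoy(rules[cond_list[k]].rule, pid, baseline, rng, out)

    cols = ["patient_id", "date", "code", "domain", "value"]
    clinical = pd.DataFrame(out["clinical"], columns=cols)
    scripts = pd.DataFrame(out["scripts"], columns=cols)
    for frame, fw in ((clinical, "READ2"), (scripts, "BNF")):
        frame["framework"] = fw
    registration = pd.DataFrame(reg_rows, columns=["patient_id", "start", "end", "provider"])
    logger.info(
        "generated EHR: %d patients, %d clinical records, %d prescriptions",
        len(patients), len(clinical), len(scripts),
    )
    return SyntheticStudy(
        clinical=clinical[["patient_id", "date", "code", "framework", "domain", "value"]],
        scripts=scripts[["patient_id", "date", "code", "framework", "domain", "value"]],
        registration=registration,
        demographics=demographics,
        cohort=cohort,
        deaths=pd.DataFrame(columns=["patient_id", "date_of_death"]),
        cancers=pd.DataFrame(columns=["patient_id", "diagnosis_date", "site_code"]),
        matrix_true=matrix,
        config=config,
    )


def simulate_survival_outcomes(
    matrix: pd.DataFrame,
    demographics: pd.DataFrame,
    cohort: pd.DataFrame,
    config: SynthConfig,
    rng,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw death and cancer registry tables from exponential PH models.

    Event times are exponential with rate ``base_hazard * exp(PI)`` per
    person-year; events falling after the study end are simply absent
    from the registries (administrative censoring).  Cancer diagnoses
    after death are suppressed; a fraction of patients get a prevalent
    (pre-baseline) cancer record and/or an NMSC record to exercise the
    outcome-derivation rules.
    """
    rng = _rng(rng)
    study_end = pd.Timestamp(config.study_end)
    baselines = cohort.set_index("patient_id")["index_date"].loc[matrix.index]

    death_rows, cancer_rows = [], []
    non_nmsc_sites = np.array(["C18", "C34", "C50", "C61"])
    for outcome, base in (("death", config.death_base_hazard),
                          ("cancer", config.cancer_base_hazard)):
        pi = true_prognostic_index(matrix, demographics, config, outcome)
        rate = base * np.exp(pi.to_numpy(dtype=float))
        # anything beyond the study window is censored; cap to keep dates finite
        t_years = np.minimum(rng.exponential(1.0 / rate), 100.0)
        if outcome == "death":
            death_t = t_years
        else:
            cancer_t = t_years

    for i, pid in enumerate(matrix.index):
        baseline = baselines.loc[pid]
        d_date = baseline + pd.Timedelta(days=max(1, round(death_t[i] * DAYS_PER_YEAR)))
        died = d_date <= study_end
        if died:
            death_rows.append((pid, d_date))
        c_date = baseline + pd.Timedelta(days=max(1, round(cancer_t[i] * DAYS_PER_YEAR)))
        if c_date <= study_end and (not died or c_date <= d_date):
            cancer_rows.append((pid, c_date, str(rng.choice(non_nmsc_sites))))
        if rng.random() < config.p_prevalent_cancer:
            prev_date = baseline - pd.Timedelta(days=int(rng.integers(200, 3650)))
            cancer_rows.append((pid, prev_date, str(rng.choice(non_nmsc_sites))))
        if rng.random() < config.p_nmsc:
            limit = min(d_date, study_end)
            span = (limit - baseline).days
            if span > 1:
                nm_date = baseline + pd.Timedelta(days=int(rng.integers(1, span)))
                cancer_rows.append((pid, nm_date, "C44"))

    deaths = pd.DataFrame(death_rows, columns=["patient_id", "date_of_death"])
    cancers = pd.DataFrame(cancer_rows, columns=["patient_id", "diagnosis_date", "site_code"])
    return deaths, cancers


def simulate_consultations(
    matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    config: SynthConfig,
    rng,
    followup_end: pd.Series | None = None,
) -> pd.DataFrame:
    """Emit dated consultation records from a negative-binomial day-count model.

    The expected number of consultation *days* per year is
    ``base * exp(slope * n_conditions)``; day counts are negative
    binomial (dispersion ``consult_dispersion``), the days are sampled
    without replacement from the follow-up window, and a fraction of days
    receive a deliberate duplicate record (same day, second row), which
    the rate outcome must ignore.
    """
    rng = _rng(rng)
    study_end = pd.Timestamp(config.study_end)
    baselines = cohort.set_index("patient_id")["index_date"].loc[matrix.index]
    n_cond = matrix.sum(axis=1).to_numpy(dtype=float)
    k = config.consult_dispersion
    rows = []
    for i, pid in enumerate(matrix.index):
        baseline = baselines.loc[pid]
        end = study_end
        if followup_end is not None and pid in followup_end.index:
            end = min(end, followup_end.loc[pid])
        span = (end - baseline).days
        if span <= 0:
            continue
        years = span / DAYS_PER_YEAR
        mean = config.consult_base_rate * np.exp(config.consult_slope * n_cond[i]) * years
        m = int(rng.negative_binomial(k, k / (k + mean)))
        m = min(m, span)
        if m == 0:
            continue
        days = rng.choice(np.arange(1, span + 1), size=m, replace=False)
        for d in days:
            date = baseline + pd.Timedelta(days=int(d))
            rows.append((pid, date, CONSULTATION_CODE, "READ2", "diagnosis", np.nan))
            if rng.random() < config.consult_duplicate_frac:
                rows.append((pid, date, CONSULTATION_CODE, "READ2", "diagnosis", np.nan))
    return pd.DataFrame(
        rows, columns=["patient_id", "date", "code", "framework", "domain", "value"]
    )


def generate_study(config: SynthConfig) -> SyntheticStudy:
    """Full bundle: EHR + consultations + survival registries, one seed."""
    study = generate_ehr(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    deaths, cancers = simulate_survival_outcomes(
        study.matrix_true, study.demographics, study.cohort, config, rng
    )
    consult = simulate_consultations(study.matrix_true, study.cohort, config, rng)
    clinical = pd.concat([study.clinical, consult], ignore_index=True)
    return replace(study, clinical=clinical, deaths=deaths, cancers=cancers)


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write the bundle as the CSV dialects the pipeline consumes.

    Every file starts with a provenance comment recording the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"# synthetic cohort, seed={study.config.seed}, n={study.config.n_patients}\n"
    tables = {
        "clinical.csv": study.clinical,
        "scripts.csv": study.scripts,
        "registration.csv": study.registration,
        "demographics.csv": study.demographics,
        "cohort.csv": study.cohort,
        "deaths.csv": study.deaths,
        "cancers.csv": study.cancers,
        "matrix_true.csv": study.matrix_true.reset_index(),
    }
    for name, frame in tables.items():
        path = out_dir / name
        with open(path, "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False, date_format="%Y-%m-%d")
    logger.info("synthetic study written to %s", out_dir)


# ---------------------------------------------------------------------------
# analytic oracles for the exponential PH model

def expected_event_fraction(pi, base_hazard: float, horizon_years: float) -> float:
    """Closed-form expected event fraction by ``horizon_years``.

    Exponential survival with rate ``base_hazard * exp(PI)``:
    P(event by t) averaged over the supplied PI sample.
    """
    pi = np.asarray(pi, dtype=float)
    return float(np.mean(1.0 - np.exp(-base_hazard * np.exp(pi) * horizon_years)))


def expected_harrell_c(
    pi, base_hazard: float, horizon_years: float, chunk: int = 512
) -> float:
    """Population concordance of the true PI under the generating model.

    For exponential PH with administrative censoring at the horizon, a
    pair with linear predictors (a, b) is usable with probability
    ``1 - exp(-s·τ)`` where ``s = λ(e^a + e^b)``, and — because the
    minimum's identity is independent of the minimum's value — the
    subject with the larger predictor dies first with probability
    ``e^max / (e^a + e^b)``.  Averaging both over all pairs of the
    supplied PI sample gives the large-n concordance by numerical
    integration, independently of any simulated realisation.
    """
    pi = np.asarray(pi, dtype=float)
    lam = base_hazard * np.exp(pi)
    n = len(pi)
    num = 0.0
    den = 0.0
    for start in range(0, n, chunk):
        a = lam[start:start + chunk, None]
        pa = pi[start:start + chunk, None]
        s = a + lam[None, :]
        p_usable = 1.0 - np.exp(-s * horizon_years)
        p_conc = np.where(
            pa == pi[None, :], 0.5, np.maximum(a, lam[None, :]) / s
        )
        # mask the diagonal and the lower triangle (each unordered pair once)
        cols = np.arange(n)[None, :]
        rows = np.arange(start, min(start + chunk, n))[:, None]
        upper = cols > rows
        num += float((p_conc * p_usable * upper).sum())
        den += float((p_usable * upper).sum())
    return num / den
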