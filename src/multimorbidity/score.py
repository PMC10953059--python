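"""Multimorbidity score computation from the condition-indicator matrix.

Three weighted scores plus a comparator are supported:

* **general** — a weighted linear sum of the 37 condition indicators
  (no demographic terms), developed against a weighted combination of
  outcomes;
* **mortality** and **hospital** — prognostic indices of Cox
  proportional-hazards models, ``PI = Σ β_i x_i + β_age·age + β_sex·sex``,
  used in validation as rank scores without their baseline hazard;
* **unweighted count** — the plain number of conditions present.

Each weighted model also has a *short* variant restricted to the 20 most
influential conditions.  Coefficients are never estimated here: they are
inputs, loaded from a weights table.  Age enters as continuous years at
baseline; sex is coded 0 = female, 1 = male (recorded in the weights
file's provenance notes so an alternative coding can be swapped in as
data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import CONDITIONS
from .phenotype import ConditionMatrix

logger = logging.getLogger(__name__)

WEIGHTED_MODELS = ("general", "mortality", "hospital")
MODELS = WEIGHTED_MODELS + ("count",)
AGE_TERM = "age"
SEX_TERM = "sex"
SHORT_SUBSET_MODEL = "short_subset"


class WeightsError(ValueError):
    """Malformed or incomplete score-weights table."""


@dataclass(frozen=True)
class ScoreWeights:
    """Coefficients of one score model over the condition panel."""

    model_id: str
    condition_weight: dict[str, float]
    age_coef: float = 0.0
    sex_coef: float = 0.0
    short_subset: tuple[str, ...] = ()
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in CONDITIONS if c not in self.condition_weight]
        if missing:
            raise WeightsError(
                f"{self.model_id}: missing coefficient(s) for {', '.join(missing)}"
            )
        unknown = [c for c in self.condition_weight if c not in CONDITIONS]
        if unknown:
            raise WeightsError(f"{self.model_id}: unknown condition term(s) {unknown}")
        if self.short_subset:
            bad = [c for c in self.short_subset if c not in CONDITIONS]
            if bad:
                raise WeightsError(f"short subset has unknown condition(s) {bad}")

    def weights_vector(self, variant: str = "full") -> pd.Series:
        """Coefficients as a Series over the condition set for a variant.

        The short variant keeps only the 20-condition subset's terms;
        indicators outside the subset contribute nothing.
        """
        w = pd.Series({c: self.condition_weight[c] for c in CONDITIONS}, dtype=float)
        if variant == "short":
            if not self.short_subset:
                raise WeightsError(f"{self.model_id}: no short subset defined")
            w[~w.index.isin(self.short_subset)] = 0.0
        elif variant != "full":
            raise WeightsError(f"unknown variant {variant!r}")
        return w


def load_weights(path: str | Path) -> dict[str, ScoreWeights]:
    """Load score weights from a (model_id, term, coefficient[, notes]) CSV.

    Terms are condition ids plus ``age`` / ``sex`` for the Cox models;
    rows with ``model_id = short_subset`` enumerate the 20-condition short
    list.  Missing condition terms raise an error naming them; non-numeric
    coefficients and unknown model ids are rejected.
    """
    frame = pd.read_csv(path, dtype=str, comment="#")
    missing = {"model_id", "term", "coefficient"} - set(frame.columns)
    if missing:
        raise WeightsError(f"{path}: missing column(s) {sorted(missing)}")
    coefs = pd.to_numeric(frame["coefficient"], errors="coerce")
    bad = frame[coefs.isna()]
    if len(bad):
        raise WeightsError(
            f"{path}: non-numeric coefficient(s) for {bad['term'].tolist()}"
        )
    frame = frame.assign(coefficient=coefs)
    known = set(WEIGHTED_MODELS) | {SHORT_SUBSET_MODEL}
    unknown = set(frame["model_id"]) - known
    if unknown:
        raise WeightsError(f"{path}: unknown model id(s) {sorted(unknown)}")

    subset_rows = frame[frame["model_id"] == SHORT_SUBSET_MODEL]
    short_subset = tuple(subset_rows["term"])
    provenance = ""
    if "notes" in frame.columns:
        notes = frame["notes"].dropna().unique()
        provenance = "; ".join(notes)

    out: dict[str, ScoreWeights] = {}
    for model_id in WEIGHTED_MODELS:
        rows = frame[frame["model_id"] == model_id]
        if rows.empty:
            continue
        terms = dict(zip(rows["term"], rows["coefficient"]))
        age = float(terms.pop(AGE_TERM, 0.0))
        sex = float(terms.pop(SEX_TERM, 0.0))
        out[model_id] = ScoreWeights(
            model_id=model_id,
            condition_weight={k: float(v) for k, v in terms.items()},
            age_coef=age,
            sex_coef=sex,
            short_subset=short_subset,
            provenance=provenance,
        )
    if not out:
        raise WeightsError(f"{path}: no model rows found")
    logger.info("loaded weights for models %s (short subset: %d conditions)",
                sorted(out), len(short_subset))
    return out


def _indicator_frame(matrix: ConditionMatrix | pd.DataFrame) -> pd.DataFrame:
    ind = matrix.indicators if isinstance(matrix, ConditionMatrix) else matrix
    missing = [c for c in CONDITIONS if c not in ind.columns]
    if missing:
        raise ValueError(f"indicator matrix missing condition column(s) {missing}")
    return ind[list(CONDITIONS)]


def general_cms(
    matrix: ConditionMatrix | pd.DataFrame,
    weights: ScoreWeights,
    variant: str = "full",
) -> pd.Series:
    """Weighted linear sum of the condition indicators (no demographics)."""
    if weights.model_id != "general":
        raise WeightsError(f"expected general weights, got {weights.model_id}")
    ind = _indicator_frame(matrix)
    return ind @ weights.weights_vector(variant)


def cox_prognostic_index(
    matrix: ConditionMatrix | pd.DataFrame,
    age_years: pd.Series,
    sex: pd.Series,
    weights: ScoreWeights,
    variant: str = "full",
) -> pd.Series:
    """Prognostic index of a Cox-type score: Σ β_i x_i + β_age·age + β_sex·sex."""
    if weights.model_id not in ("mortality", "hospital"):
        raise WeightsError(f"expected a Cox model, got {weights.model_id}")
    ind = _indicator_frame(matrix)
    age = pd.to_numeric(age_years.reindex(ind.index), errors="coerce")
    sx = pd.to_numeric(sex.reindex(ind.index), errors="coerce")
    bad = ind.index[age.isna() | sx.isna()]
    if len(bad):
        raise ValueError(f"missing age/sex for patient(s): {list(bad[:10])}")
    return ind @ weights.weights_vector(variant) + weights.age_coef * age + weights.sex_coef * sx


def unweighted_count(
    matrix: ConditionMatrix | pd.DataFrame, subset: tuple[str, ...] | None = None
) -> pd.Series:
    """Plain count of conditions present, optionally over the short subset."""
    ind = _indicator_frame(matrix)
    if subset is not None:
        ind = ind[list(subset)]
    return ind.sum(axis=1)


def score_table(
    matrix: ConditionMatrix | pd.DataFrame,
    weights: dict[str, ScoreWeights],
    demographics: pd.DataFrame | None = None,
    models: tuple[str, ...] = MODELS,
    variant: str = "full",
) -> pd.DataFrame:
    """Compute several scores at once, long format.

    ``demographics`` (patient_id, age, sex) is required for the Cox
    models.  Returns columns (patient_id, model_id, variant, value).
    """
    ind = _indicator_frame(matrix)
    age = sex = None
    if demographics is not None:
        demo = demographics.copy()
        demo["patient_id"] = demo["patient_id"].astype(str)
        demo = demo.set_index("patient_id")
        age, sex = demo["age"], demo["sex"]
    parts = []
    for model in models:
        if model == "count":
            subset = None
            if variant == "short":
                any_w = next(iter(weights.values()), None)
                subset = any_w.short_subset if any_w else None
            values = unweighted_count(ind, subset)
        elif model == "general":
            values = general_cms(ind, weights["general"], variant)
        elif model in ("mortality", "hospital"):
            if age is None:
                raise ValueError(f"model {model} requires demographics (age, sex)")
            values = cox_prognostic_index(ind, age, sex, weights[model], variant)
        else:
            raise WeightsError(f"unknown model {model!r}")
        parts.append(
            pd.DataFrame(
                {
                    "patient_id": values.index,
                    "model_id": model,
                    "variant": variant,
                    "value": values.to_numpy(dtype=float),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def relative_risk_transform(pi: pd.Series) -> pd.Series:
    """Map a prognostic index to relative risk exp(PI)/mean(exp(PI)).

    A rank-preserving convenience for calibration displays; no baseline
    hazard (hence no absolute risk) is implied.
    """
    e = np.exp(pi.astype(float))
    return e / e.mean()
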