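"""Rule-based ascertainment of chronic conditions from coded records.

A condition is deemed present at an *index date* (the study baseline) when
the patient's coded history satisfies that condition's rule.  Four rule
archetypes cover the condition set:

``ever``
    at least one matching diagnosis record strictly before the index date
    (e.g. hypertension, diabetes);
``within``
    a matching record inside a look-back window ``[index - years, index)``;
``rx_recent``
    at least ``min_count`` matching prescriptions inside a recent window
    (e.g. regular analgesics for a painful condition, migraine therapy);
``last_n_tests``
    the ``n`` most recent test results before the index date all beyond a
    threshold — the chronic-kidney-disease pattern, where the last two
    eGFR results must both be below 60 mL/min/1.73m².

Rules may be combined with ``all_of`` / ``any_of``.  "Before the index
date" is strict throughout: records dated on the index day never
contribute, so a baseline score cannot use same-day information.  Exact
per-condition parameters are configuration, not code; the package ships a
fixture configuration following the published condition-definition
archetypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd
import yaml

from .codemap import Codelist, Domain
from .conditions import CONDITIONS

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0


class RuleConfigError(ValueError):
    """Invalid phenotyping rule configuration."""


@dataclass(frozen=True)
class CodeSet:
    """The codes (within one record domain) a rule leaf matches against."""

    domain: Domain
    codes: frozenset[str]


@dataclass(frozen=True)
class Ever:
    codeset: CodeSet


@dataclass(frozen=True)
class Within:
    codeset: CodeSet
    years: float


@dataclass(frozen=True)
class RecentRx:
    codeset: CodeSet
    min_count: int
    window_months: float


@dataclass(frozen=True)
class LastNTests:
    codeset: CodeSet
    n: int
    threshold: float
    direction: str  # "below" | "above"


@dataclass(frozen=True)
class AllOf:
    children: tuple


@dataclass(frozen=True)
class AnyOf:
    children: tuple


RuleNode = Union[Ever, Within, RecentRx, LastNTests, AllOf, AnyOf]


@dataclass(frozen=True)
class ConditionRule:
    condition_id: str
    rule: RuleNode


@dataclass
class ConditionMatrix:
    """Per-patient binary indicators for the condition panel at index date."""

    indicators: pd.DataFrame  # index: patient_id; columns: condition ids; values 0/1
    index_date: pd.Series  # index: patient_id

    @property
    def patients(self) -> pd.Index:
        return self.indicators.index

    @property
    def condition_count(self) -> pd.Series:
        return self.indicators.sum(axis=1)

    def prevalence(self) -> pd.Series:
        return self.indicators.mean(axis=0)


# ---------------------------------------------------------------------------
# rule compilation

_LEAF_KEYS = {"ever", "within", "rx_recent", "last_n_tests"}
_COMBINATOR_KEYS = {"all_of", "any_of"}


def _resolve_codeset(
    spec: Mapping, codelists: Mapping[str, Codelist], context: str
) -> CodeSet:
    names = spec.get("codelists")
    if names is None:
        name = spec.get("codelist")
        if name is None:
            raise RuleConfigError(f"{context}: no codelist reference")
        names = [name]
    lists = []
    for name in names:
        if name not in codelists:
            raise RuleConfigError(f"{context}: unknown codelist {name!r}")
        lists.append(codelists[name])
    domains = {cl.domain for cl in lists}
    if len(domains) != 1:
        raise RuleConfigError(f"{context}: referenced codelists span multiple domains")
    codes = frozenset().union(*(cl.codes for cl in lists))
    return CodeSet(domain=domains.pop(), codes=codes)


def _parse_node(
    node: Mapping, codelists: Mapping[str, Codelist], context: str
) -> RuleNode:
    if not isinstance(node, Mapping) or len(node) != 1:
        raise RuleConfigError(f"{context}: rule node must have exactly one keyword")
    (key, spec), = node.items()
    if key in _COMBINATOR_KEYS:
        if not isinstance(spec, list) or not spec:
            raise RuleConfigError(f"{context}: {key} needs a non-empty list of sub-rules")
        children = tuple(
            _parse_node(child, codelists, f"{context}.{key}[{i}]")
            for i, child in enumerate(spec)
        )
        return AllOf(children) if key == "all_of" else AnyOf(children)
    if key not in _LEAF_KEYS:
        raise RuleConfigError(f"{context}: unknown logic keyword {key!r}")
    cs = _resolve_codeset(spec, codelists, context)
    if key == "ever":
        return Ever(cs)
    if key == "within":
        years = float(spec.get("years", 0))
        if years <= 0:
            raise RuleConfigError(f"{context}: within.years must be > 0")
        return Within(cs, years)
    if key == "rx_recent":
        min_count = int(spec.get("min_count", 0))
        window = float(spec.get("window_months", 0))
        if min_count < 1:
            raise RuleConfigError(f"{context}: rx_recent.min_count must be >= 1")
        if window <= 0:
            raise RuleConfigError(f"{context}: rx_recent.window_months must be > 0")
        if cs.domain is not Domain.PRESCRIPTION:
            raise RuleConfigError(f"{context}: rx_recent requires prescription codelists")
        return RecentRx(cs, min_count, window)
    n = int(spec.get("n", 0))
    if n < 1:
        raise RuleConfigError(f"{context}: last_n_tests.n must be >= 1")
    direction = str(spec.get("direction", "below"))
    if direction not in ("below", "above"):
        raise RuleConfigError(f"{context}: direction must be 'below' or 'above'")
    return LastNTests(cs, n, float(spec["threshold"]), direction)


def compile_rules(
    config: Mapping | str | Path,
    codelists: Mapping[str, Codelist],
    required_conditions: tuple[str, ...] = CONDITIONS,
) -> dict[str, ConditionRule]:
    """Validate a rule configuration against the available codelists.

    ``config`` is a mapping (or a YAML file path) with a ``conditions``
    table keyed by condition id.  Every required condition must be
    present; gaps are reported by name.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    table = config.get("conditions")
    if not isinstance(table, Mapping):
        raise RuleConfigError("rule config must contain a 'conditions' mapping")
    missing = [c for c in required_conditions if c not in table]
    if missing:
        raise RuleConfigError(f"rule config missing condition(s): {', '.join(missing)}")
    rules: dict[str, ConditionRule] = {}
    for cid in required_conditions:
        rules[cid] = ConditionRule(cid, _parse_node(table[cid], codelists, cid))
    extra = [c for c in table if c not in rules]
    if extra:
        logger.info("rule config has %d extra condition(s) ignored: %s", len(extra), extra)
    return rules


# ---------------------------------------------------------------------------
# evaluation

def _last_n_ok(
    dates: np.ndarray, values: np.ndarray, n: int, threshold: float, direction: str
) -> bool:
    """Apply the last-n-tests rule to one patient's matching test results.

    Tests sharing the most recent calendar days are taken together (their
    within-day order is undefined); if the collected set straddles the
    threshold the rule is not met.  Fewer than ``n`` recorded tests is
    insufficient evidence, hence False.
    """
    if len(values) < n:
        return False
    order = np.argsort(dates, kind="stable")
    dates, values = dates[order], values[order]
    taken: list[float] = []
    pos = len(dates)
    while pos > 0 and len(taken) < n:
        day = dates[pos - 1]
        while pos > 0 and dates[pos - 1] == day:
            taken.append(values[pos - 1])
            pos -= 1
    arr = np.asarray(taken, dtype=float)
    return bool(np.all(arr < threshold) if direction == "below" else np.all(arr > threshold))


def _match(records: pd.DataFrame, cs: CodeSet) -> pd.DataFrame:
    mask = (records["domain"] == cs.domain.value) & records["code"].isin(cs.codes)
    return records[mask]


def evaluate_condition(
    rule: ConditionRule | RuleNode, records: pd.DataFrame, index_date
) -> int:
    """Evaluate one condition rule for one patient's records at an index date.

    Absence of records is never an error; it simply yields 0.
    """
    node = rule.rule if isinstance(rule, ConditionRule) else rule
    index_date = pd.Timestamp(index_date)
    return int(_eval_scalar(node, records, index_date))


def _eval_scalar(node: RuleNode, records: pd.DataFrame, index_date: pd.Timestamp) -> bool:
    if isinstance(node, AllOf):
        return all(_eval_scalar(c, records, index_date) for c in node.children)
    if isinstance(node, AnyOf):
        return any(_eval_scalar(c, records, index_date) for c in node.children)
    sub = _match(records, node.codeset)
    sub = sub[sub["date"].notna()]
    dates = sub["date"]
    if isinstance(node, Ever):
        return bool((dates < index_date).any())
    if isinstance(node, Within):
        lower = index_date - pd.Timedelta(days=round(node.years * DAYS_PER_YEAR))
        return bool(((dates >= lower) & (dates < index_date)).any())
    if isinstance(node, RecentRx):
        lower = index_date - pd.Timedelta(days=round(node.window_months * DAYS_PER_MONTH))
        return int(((dates >= lower) & (dates < index_date)).sum()) >= node.min_count
    sub = sub[(dates < index_date) & sub["value"].notna()]
    return _last_n_ok(
        sub["date"].to_numpy(), sub["value"].to_numpy(dtype=float),
        node.n, node.threshold, node.direction,
    )


def _eval_vector(
    node: RuleNode, records: pd.DataFrame, patients: pd.Index
) -> pd.Series:
    """Vectorised rule evaluation over all cohort patients.

    ``records`` must already carry an ``index_date`` column (the patient's
    baseline) alongside the normal record columns.
    """
    if isinstance(node, AllOf):
        out = _eval_vector(node.children[0], records, patients)
        for child in node.children[1:]:
            out &= _eval_vector(child, records, patients)
        return out
    if isinstance(node, AnyOf):
        out = _eval_vector(node.children[0], records, patients)
        for child in node.children[1:]:
            out |= _eval_vector(child, records, patients)
        return out
    sub = _match(records, node.codeset)
    base = pd.Series(False, index=patients)
    if not len(sub):
        return base
    d, i = sub["date"], sub["index_date"]
    if isinstance(node, Ever):
        hit = sub.loc[d < i, "patient_id"].unique()
        base[base.index.isin(hit)] = True
        return base
    if isinstance(node, Within):
        lower = i - pd.Timedelta(days=round(node.years * DAYS_PER_YEAR))
        hit = sub.loc[(d >= lower) & (d < i), "patient_id"].unique()
        base[base.index.isin(hit)] = True
        return base
    if isinstance(node, RecentRx):
        lower = i - pd.Timedelta(days=round(node.window_months * DAYS_PER_MONTH))
        counts = sub.loc[(d >= lower) & (d < i)].groupby("patient_id").size()
        hit = counts[counts >= node.min_count].index
        base[base.index.isin(hit)] = True
        return base
    sub = sub[(d < i) & sub["value"].notna()]
    for pid, grp in sub.groupby("patient_id"):
        if _last_n_ok(
            grp["date"].to_numpy(), grp["value"].to_numpy(dtype=float),
            node.n, node.threshold, node.direction,
        ):
            if pid in base.index:
                base[pid] = True
    return base


def build_condition_matrix(
    cohort: pd.DataFrame,
    records: pd.DataFrame,
    rules: Mapping[str, ConditionRule],
) -> ConditionMatrix:
    """Assemble the per-patient condition-indicator matrix at index date.

    ``cohort`` needs ``patient_id`` and ``index_date`` columns; every
    cohort patient gets a row (all zeros when they have no qualifying
    records).  Records of patients outside the cohort are ignored; records
    without a valid date are excluded with a logged count.  The result is
    independent of the input record ordering.
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    if cohort["patient_id"].duplicated().any():
        raise ValueError("cohort contains duplicate patient ids")
    index_date = pd.Series(
        pd.to_datetime(cohort["index_date"]).to_numpy(),
        index=pd.Index(cohort["patient_id"].astype(str), name="patient_id"),
    )
    patients = index_date.index

    recs = records.copy()
    recs["patient_id"] = recs["patient_id"].astype(str)
    n_undated = int(recs["date"].isna().sum())
    if n_undated:
        logger.warning("excluded %d undated records before evaluation", n_undated)
    recs = recs[recs["date"].notna()]
    recs = recs[recs["patient_id"].isin(patients)]
    recs = recs.assign(index_date=recs["patient_id"].map(index_date))

    cols = {}
    for cid, crule in rules.items():
        cols[cid] = _eval_vector(crule.rule, recs, patients).astype(np.int8)
    indicators = pd.DataFrame(cols, index=patients)

    n_no_records = int((~patients.isin(recs["patient_id"])).sum())
    logger.info(
        "condition matrix: %d patients (%d with no records); prevalence: %s",
        len(patients), n_no_records,
        {c: round(float(v), 4) for c, v in indicators.mean(axis=0).items()},
    )
    return ConditionMatrix(indicators=indicators, index_date=index_date)
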