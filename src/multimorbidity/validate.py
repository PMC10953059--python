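"""Discrimination and calibration statistics for risk-score validation.

The central statistic is the concordance (Harrell's C for censored
outcomes): among *usable* pairs — pairs where the subject with the
smaller follow-up time had the event — the probability that that subject
also carries the higher score, with tied scores counting one half.
C = 0.5 means no discrimination, C = 1 perfect discrimination.

Two conventions are implemented over one O(n log n) Fenwick-tree kernel:

* :func:`harrell_c` — censored event outcomes, with optional horizon
  truncation (events after ``horizon_years`` are recoded as censored at
  the horizon, so discrimination can be swept over 1–10-year windows);
* :func:`concordance_continuous` — fully observed non-negative outcomes
  such as annual consultation rates, where a pair is usable iff the
  outcomes differ.

An O(n²) all-pairs oracle (:func:`pair_counts_brute`) implements the same
conventions independently and is used for verification, never for
production-size inputs.

Calibration is assessed by score deciles: observed relative risk
(decile event proportion over the overall proportion) against mean
predicted relative risk, with ``exp(PI)`` as the predicted risk of
Cox-type scores and the raw score otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
AGE_BANDS = ((40, 50), (50, 60), (60, 70))
RATE_MAX_HORIZON = 8  # consultation rate analysed up to 8 years of follow-up


class ConcordanceUndefined(ValueError):
    """No usable pairs (e.g. no events): the statistic does not exist."""


@dataclass
class ConcordanceResult:
    c: float
    se: float
    ci95: tuple[float, float]
    n_included: int
    n_usable_pairs: int
    horizon_years: int | None = None
    outcome: str = ""
    subgroup: str = "all"

    def __post_init__(self) -> None:
        if not (0.0 <= self.c <= 1.0):
            raise ValueError(f"concordance {self.c} outside [0, 1]")


@dataclass
class CalibrationTable:
    """Decile-level observed vs predicted relative risk."""

    table: pd.DataFrame  # columns: decile, n, mean_predicted_rr, observed_rr, observed_events
    outcome: str = ""

    @property
    def total_events(self) -> float:
        return float(self.table["observed_events"].sum())


# ---------------------------------------------------------------------------
# pair-counting kernels

class _Fenwick:
    __slots__ = ("n", "tree")

    def __init__(self, n: int) -> None:
        self.n = n
        self.tree = np.zeros(n + 1, dtype=np.int64)

    def add(self, i: int) -> None:  # 0-based rank
        i += 1
        t = self.tree
        while i <= self.n:
            t[i] += 1
            i += i & -i

    def prefix(self, i: int) -> int:  # count of inserted ranks < i (0-based)
        s = 0
        t = self.tree
        while i > 0:
            s += t[i]
            i -= i & -i
        return int(s)


def pair_counts(time, event, score) -> tuple[int, int, int]:
    """(concordant, discordant, score-tied) over usable pairs, O(n log n).

    A pair is usable iff the smaller time belongs to an event; when two
    times tie with exactly one event, the event is ranked first and the
    pair is usable.  Tied event times (both events) and tied censored
    times are unusable.  Concordant means the earlier-event subject has
    the strictly higher score.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    score = np.asarray(score, dtype=float)
    if not (len(time) == len(event) == len(score)):
        raise ValueError("time, event and score must have equal length")
    n = len(time)
    if n < 2:
        return 0, 0, 0
    _, rank = np.unique(score, return_inverse=True)
    n_ranks = int(rank.max()) + 1
    order = np.lexsort((np.arange(n), -time))  # time descending, stable
    tree = _Fenwick(n_ranks)
    in_tree = 0
    conc = disc = tied = 0
    i = 0
    while i < n:
        j = i
        t0 = time[order[i]]
        while j < n and time[order[j]] == t0:
            j += 1
        group = order[i:j]
        ev_ranks = rank[group[event[group]]]
        cen_ranks = np.sort(rank[group[~event[group]]])
        for r in ev_ranks:
            lt = tree.prefix(r)
            le = tree.prefix(r + 1)
            conc += lt
            tied += le - lt
            disc += in_tree - le
            if len(cen_ranks):
                lt2 = int(np.searchsorted(cen_ranks, r, side="left"))
                le2 = int(np.searchsorted(cen_ranks, r, side="right"))
                conc += lt2
                tied += le2 - lt2
                disc += len(cen_ranks) - le2
        for r in rank[group]:
            tree.add(int(r))
        in_tree += len(group)
        i = j
    return int(conc), int(disc), int(tied)


def pair_counts_brute(time, event, score) -> tuple[int, int, int]:
    """All-pairs O(n²) reference implementation of the same pair rules."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    score = np.asarray(score, dtype=float)
    n = len(time)
    conc = disc = tied = 0
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                if event[i] == event[j]:
                    continue  # two events or two censored at the same time
                a, b = (i, j) if event[i] else (j, i)  # event ranked first
            elif time[i] < time[j]:
                if not event[i]:
                    continue
                a, b = i, j
            else:
                if not event[j]:
                    continue
                a, b = j, i
            if score[a] > score[b]:
                conc += 1
            elif score[a] < score[b]:
                disc += 1
            else:
                tied += 1
    return conc, disc, tied


def _c_from_counts(conc: int, disc: int, tied: int) -> tuple[float, int]:
    usable = conc + disc + tied
    if usable == 0:
        raise ConcordanceUndefined("no usable pairs")
    return (conc + 0.5 * tied) / usable, usable


def _hanley_mcneil_se(c: float, n_pos: int, n_neg: int) -> float:
    """Asymptotic SE approximation for a concordance-type statistic.

    Treats the statistic as an AUC over n_pos event and n_neg non-event
    subjects (Hanley–McNeil form).  Documented approximation; swappable.
    """
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    q1 = c / (2 - c)
    q2 = 2 * c * c / (1 + c)
    var = (
        c * (1 - c) + (n_pos - 1) * (q1 - c * c) + (n_neg - 1) * (q2 - c * c)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def _ci(c: float, se: float) -> tuple[float, float]:
    if np.isnan(se):
        return (float("nan"), float("nan"))
    return (max(0.0, c - 1.96 * se), min(1.0, c + 1.96 * se))


def truncate_horizon(time, event, horizon: float) -> tuple[np.ndarray, np.ndarray]:
    """Recode events after ``horizon`` as censored at the horizon."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    out_t = np.minimum(time, horizon)
    out_e = event & (time <= horizon)
    return out_t, out_e


def harrell_c(
    scores,
    times,
    events,
    horizon_years: int | None = None,
    outcome: str = "",
    subgroup: str = "all",
) -> ConcordanceResult:
    """Censored concordance, optionally truncated at a follow-up horizon.

    ``times`` are positive follow-up times in years; ``events`` flags
    observed events.  With ``horizon_years`` set, events beyond the
    horizon are recoded censored at the horizon before counting pairs.
    Raises :class:`ConcordanceUndefined` when there are no usable pairs.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times <= 0):
        raise ValueError("follow-up times must be positive")
    if horizon_years is not None:
        if not 1 <= horizon_years <= 10:
            raise ValueError("horizon_years must be in 1..10")
        times, events = truncate_horizon(times, events, float(horizon_years))
    conc, disc, tied = pair_counts(times, events, scores)
    c, usable = _c_from_counts(conc, disc, tied)
    n_pos = int(events.sum())
    se = _hanley_mcneil_se(c, n_pos, len(times) - n_pos)
    return ConcordanceResult(
        c=float(c), se=se, ci95=_ci(c, se),
        n_included=len(times), n_usable_pairs=usable,
        horizon_years=horizon_years, outcome=outcome, subgroup=subgroup,
    )


def concordance_continuous(
    scores,
    rates,
    n_boot: int = 200,
    random_state: int = 0,
    outcome: str = "rate",
    subgroup: str = "all",
) -> ConcordanceResult:
    """Concordance between scores and a fully observed non-negative outcome.

    Usable pairs are those with distinct outcome values; tied scores
    count one half.  The standard error comes from a seeded nonparametric
    bootstrap (``n_boot`` resamples; 0 skips the bootstrap and reports
    NaN).
    """
    scores = np.asarray(scores, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if len(scores) < 2:
        raise ConcordanceUndefined("fewer than two subjects")
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")

    def _c(s, r):
        # higher rate = "earlier event": every subject an event, time = -rate
        conc, disc, tied = pair_counts(-r, np.ones(len(r), dtype=bool), s)
        return _c_from_counts(conc, disc, tied)

    c, usable = _c(scores, rates)
    se = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(random_state)
        reps = []
        n = len(scores)
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            try:
                reps.append(_c(scores[idx], rates[idx])[0])
            except ConcordanceUndefined:
                continue
        if len(reps) >= 2:
            se = float(np.std(reps, ddof=1))
    return ConcordanceResult(
        c=float(c), se=se, ci95=_ci(c, se),
        n_included=len(scores), n_usable_pairs=usable,
        horizon_years=None, outcome=outcome, subgroup=subgroup,
    )


# ---------------------------------------------------------------------------
# calibration

def calibration_deciles(
    predicted_risk,
    outcome,
    outcome_label: str = "",
) -> CalibrationTable:
    """Observed vs predicted relative risk across score deciles.

    ``predicted_risk`` should be ``exp(PI)`` for Cox-type scores and the
    raw score for general/count scores.  ``outcome`` may be binary events
    at a horizon or a non-negative continuous outcome; observed relative
    risk is the decile mean over the overall mean.  Decile boundaries
    come from the empirical distribution with ties kept together in the
    lower decile, so heavy ties can give unequal decile sizes — sizes are
    reported, never rebalanced.
    """
    pred = np.asarray(predicted_risk, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if len(pred) != len(y):
        raise ValueError("predicted_risk and outcome must have equal length")
    if len(pred) < 10:
        raise ValueError("calibration requires at least 10 subjects")
    overall_y = y.mean()
    if overall_y == 0:
        raise ConcordanceUndefined("no observed events: relative risk undefined")
    overall_pred = pred.mean()
    edges = np.quantile(pred, np.linspace(0.1, 0.9, 9))
    decile = np.digitize(pred, edges, right=True) + 1  # ties -> lower decile
    rows = []
    for d in range(1, 11):
        mask = decile == d
        n = int(mask.sum())
        rows.append(
            {
                "decile": d,
                "n": n,
                "mean_predicted_rr": float(pred[mask].mean() / overall_pred) if n else np.nan,
                "observed_rr": float(y[mask].mean() / overall_y) if n else np.nan,
                "observed_events": float(y[mask].sum()),
            }
        )
    return CalibrationTable(table=pd.DataFrame(rows), outcome=outcome_label)


# ---------------------------------------------------------------------------
# subgroups and sweeps

def _age_band_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def subgroup_concordance(
    table: pd.DataFrame,
    score_col: str,
    time_col: str,
    event_col: str,
    horizons=range(1, 11),
    outcome: str = "",
) -> list[ConcordanceResult]:
    """Concordance by sex and 10-year age band across horizons.

    Bands are [40,50), [50,60) and [60,70]; subgroups partition the
    cohort.  Empty subgroups (or subgroups with no usable pairs) are
    skipped with a log entry.
    """
    results: list[ConcordanceResult] = []
    sexes = {"female": table["sex"] == 0, "male": table["sex"] == 1}
    bands = {}
    for lo, hi in AGE_BANDS:
        upper_ok = table["age"] <= hi if (lo, hi) == AGE_BANDS[-1] else table["age"] < hi
        bands[_age_band_label(lo, hi)] = (table["age"] >= lo) & upper_ok
    groups = {}
    for s_label, s_mask in sexes.items():
        groups[s_label] = s_mask
        for b_label, b_mask in bands.items():
            groups[f"{s_label}_{b_label}"] = s_mask & b_mask
    for label, mask in groups.items():
        sub = table[mask]
        if sub.empty:
            logger.info("subgroup %s empty; skipped", label)
            continue
        for h in horizons:
            try:
                results.append(
                    harrell_c(
                        sub[score_col], sub[time_col], sub[event_col],
                        horizon_years=h, outcome=outcome, subgroup=label,
                    )
                )
            except ConcordanceUndefined:
                logger.info("subgroup %s horizon %d: no usable pairs; skipped", label, h)
    return results


def followup_sweep(
    table: pd.DataFrame,
    models: dict[str, str],
    outcomes=("death", "cancer", "rate"),
    horizons=range(1, 11),
    rate_max_horizon: int = RATE_MAX_HORIZON,
    n_boot_rate: int = 0,
) -> pd.DataFrame:
    """Concordance for every (model, outcome, horizon), long format.

    ``models`` maps model id to its score column in ``table``.  Death and
    cancer use horizon-truncated censored concordance (columns
    ``time_<outcome>_years`` / ``event_<outcome>``); the consultation
    rate uses the continuous convention, capped at ``rate_max_horizon``
    years and restricted per horizon to members with continuous GP
    coverage to the end of the period (``gp_coverage_years``).  Horizon
    recoding always restarts from the master table, so the sweep is
    order-independent and deterministic.
    """
    rows = []
    for model_id, col in models.items():
        for outcome in outcomes:
            if outcome == "rate":
                hs = [h for h in horizons if h <= rate_max_horizon]
            else:
                hs = list(horizons)
            for h in hs:
                try:
                    if outcome == "rate":
                        sub = table[table["gp_coverage_years"] >= h] if "gp_coverage_years" in table else table
                        sub = sub[sub["consult_rate"].notna() & sub[col].notna()]
                        res = concordance_continuous(
                            sub[col], sub["consult_rate"], n_boot=n_boot_rate,
                            outcome=outcome,
                        )
                    else:
                        sub = table[table[col].notna()]
                        res = harrell_c(
                            sub[col], sub[f"time_{outcome}_years"], sub[f"event_{outcome}"],
                            horizon_years=h, outcome=outcome,
                        )
                except ConcordanceUndefined:
                    logger.info("%s/%s horizon %d: no usable pairs; cell skipped",
                                model_id, outcome, h)
                    continue
                rows.append(
                    {
                        "model": model_id,
                        "outcome": outcome,
                        "horizon": h,
                        "subgroup": "all",
                        "c": res.c,
                        "se": res.se,
                        "ci_low": res.ci95[0],
                        "ci_high": res.ci95[1],
                        "n": res.n_included,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# optional plots

def plot_calibration(cal: CalibrationTable, path=None, ax=None):
    """Decile calibration plot (observed vs predicted relative risk)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    t = cal.table
    ax.plot(t["mean_predicted_rr"], t["observed_rr"], "o-", label="deciles")
    lim = max(t["mean_predicted_rr"].max(), t["observed_rr"].max()) * 1.05
    ax.plot([0, lim], [0, lim], "--", color="grey", label="identity")
    ax.set_xlabel("predicted relative risk")
    ax.set_ylabel("observed relative risk")
    ax.set_title(cal.outcome)
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_concordance_sweep(sweep: pd.DataFrame, outcome: str, path=None, ax=None):
    """Concordance over follow-up horizons, one line per model."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    sub = sweep[sweep["outcome"] == outcome]
    for model, grp in sub.groupby("model"):
        ax.errorbar(
            grp["horizon"], grp["c"],
            yerr=1.96 * grp["se"].fillna(0), label=model, marker="o", capsize=2,
        )
    ax.axhline(0.5, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("follow-up horizon (years)")
    ax.set_ylabel("concordance")
    ax.set_title(outcome)
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
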