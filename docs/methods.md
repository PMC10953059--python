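# Methods

This note documents the models, conventions and numerical choices behind
the package, and what its synthetic cohorts do and do not show about
real primary-care data.

## Condition ascertainment

A condition is present at the index date (study baseline) when the
patient's coded records satisfy that condition's rule.  Four archetypes
cover the 37-condition panel, combinable with `all_of` / `any_of`:

| archetype | meaning | example |
|---|---|---|
| `ever` | ≥ 1 matching diagnosis strictly before index | hypertension, diabetes |
| `within(y)` | matching record in `[index − y years, index)` | recent eating-disorder code |
| `rx_recent(k, m)` | ≥ k matching prescriptions in the last m months | regular analgesics, migraine therapy |
| `last_n_tests(n, θ, dir)` | the n latest test results all beyond θ | last two eGFR < 60 (CKD) |

Conventions, all deliberate:

- **Strictly prior.** Records dated on the index day never contribute, so
  a baseline score cannot use same-day information.
- **Calendar arithmetic.** Years convert at 365.25 d, months at
  365.25/12 ≈ 30.44 d; windows are closed below, open above.
- **Insufficient evidence.** `last_n_tests` with fewer than n recorded
  results yields 0.  Tests sharing the most recent calendar days are
  taken together (within-day order is undefined); if the collected set
  straddles the threshold the rule is not met.
- **Undated records** are excluded before evaluation, with a logged count.
- Exact per-condition parameters are configuration (`data/rules.yaml`),
  not code.  The shipped configuration follows the published archetypes;
  per-condition parameter fidelity to the original clinical definitions
  is a property of the configuration a user supplies, not asserted by
  the engine.

The matrix builder evaluates rules vectorised over the cohort; a scalar
recursive evaluator exists independently and the test suite asserts the
two paths agree, along with order-invariance and monotonicity
(adding a matching record never clears a cumulative flag).

## Codelist mapping

Mapping between coding frameworks is *sensitive*: a one-to-many lookup
entry contributes all its targets, and target codes reached from more
than one source are flagged for manual review rather than collapsed
silently — over-inclusion followed by human pruning is the intended
workflow.  Every source code lands in the audit with exactly one status
(`mapped`, `unmapped`, `manual_override`); an override table wins over
the lookup on conflict.  Codes compare exactly after trimming
surrounding whitespace, case preserved (Read/CTV3 are case-sensitive).

## Scores

- general: `Σ w_i x_i`; mortality/hospital: `Σ β_i x_i + β_age·age + β_sex·sex`.
- Age enters as continuous years at baseline, not banded; sex is coded
  0 = female, 1 = male.  Both conventions live in the weights file's
  notes so an alternative coding ships as data, not code.
- No baseline hazard is applied: validation uses the prognostic index as
  a rank score, for which any age centring is an additive constant and
  irrelevant.  For calibration displays an optional transform
  `exp(PI)/mean(exp(PI))` maps a Cox index to relative risk.
- The repository's weights file is a **synthetic fixture** (fixed,
  plausible magnitudes, labelled as such in every row); it exists so the
  pipeline is testable.  Published coefficients load from the same CSV
  layout `(model_id, term, coefficient, notes)`, with
  `short_subset` rows enumerating the 20-condition variant.

## Eligibility and outcomes

- Eligibility: after merging registration spells whose gap
  (`start_next − end_prev − 1` days, endpoints inclusive) is ≤ 90 days,
  one merged interval must cover baseline − 365 d to baseline + 183 d.
  A 90-day gap is bridged; 91 days breaks continuity.
- Death: time from baseline, administratively censored at the study end
  date; a death before baseline is a data error, never silently fixed.
- Cancer: first non-NMSC registry diagnosis strictly after baseline,
  competing censoring at death.  NMSC is identified by a configurable
  site-code prefix list (ICD-10 `C44` by default).  Patients with
  pre-baseline cancer are retained and flagged (they remain at risk of
  subsequent cancers); `exclude_prevalent` removes them as a sensitivity
  analysis.
- Consultation rate: distinct calendar days bearing a clinical record in
  `(baseline, follow-up end]`, divided by years (days/365.25).
  Duplicate same-day records never inflate the numerator.  The follow-up
  denominator ends at min(death, end of bridged GP registration, study
  end); a variant ignoring deregistration can be had by passing a
  different `followup_end`.

## Concordance

One O(n log n) Fenwick-tree kernel counts (concordant, discordant,
score-tied) pairs; `C = (concordant + ½·tied) / usable`.  Pair rules:

- a pair is usable iff the smaller follow-up time belongs to an event;
- tied times with exactly one event are usable with the event ranked
  first; tied event times and tied censored times are unusable;
- tied scores count ½.

Horizon truncation recodes events after h years as censored at h, always
starting from the master table, so sweeps over 1–10 years are
order-independent.  The continuous convention (consultation rate) treats
every subject as an event and pairs with equal outcomes as unusable,
implemented through the same kernel with time = −rate.  An O(n²)
all-pairs oracle implements the identical rules independently; the test
suite asserts exact agreement on random instances with censoring and
heavy ties (and cross-checks against lifelines' `concordance_index` on
tie-free instances, where conventions coincide).

Uncertainty: the censored C uses a Hanley–McNeil-type asymptotic
variance approximation over events/non-events — a documented,
swappable choice, since a packaged survival routine's exact influence
formula is not reproduced here; the continuous C uses a seeded
nonparametric bootstrap (default 200 resamples; sweeps default to
skipping it for speed and report NaN).  CIs are 1.96·SE, clipped to
[0, 1].

## Calibration

Subjects are ranked into deciles by predicted risk (`exp(PI)` for Cox
scores, the raw score otherwise), with quantile boundaries from the
empirical distribution and ties kept together in the lower decile —
heavily tied scores (the count) therefore give unequal decile sizes,
which are reported, never rebalanced.  Observed relative risk is the
decile outcome mean over the overall mean; events are conserved across
deciles by construction.  With zero observed events the quantity is
undefined and signalled as such (an exception, not a number).
Subgroup analyses partition by sex and 10-year age bands [40,50),
[50,60), [60,70]; empty subgroups are skipped with a log entry.

## Synthetic cohorts

The generator emulates the shape of a UK mid-life cohort with linked
primary-care records: ages uniform 40–70 (mean ≈ 55 rather than the
recruited cohort's 57 — a simplification), 46.3% male, baseline dates
2006–2010, study end 2016-07-10.  Default per-condition prevalences use
published cohort values where printed (painful condition 16.8%,
hypertension 16.5%, anxiety/depression 9.7%, IBS 6.1%, CKD 2.5%,
dementia ≈ 0.015%) and plausible round figures elsewhere.

Conditions are planted independently by default.  Because the real
cohort shows strong comorbidity clustering (about half of patients are
condition-free even though the prevalences sum to ≈ 1), a latent-factor
Gaussian copula option correlates conditions while preserving every
marginal exactly; `comorbidity_correlation ≈ 0.3` reproduces the
≈ 51% / 26% / 23% split of none / one / multiple conditions.

For each planted condition the generator emits records that satisfy the
rule, and for a Poisson number of unplanted conditions per patient it
emits *near-miss decoys* guaranteed to fail it: events on or after the
index day, one prescription short of the required count, a qualifying
eGFR superseded by a normal one, conjunctions with one violated
conjunct.  End-to-end tests assert that phenotyping recovers the planted
matrix *exactly* — decoys included — at n = 2,000.

Survival outcomes are exponential proportional hazards,
rate = λ₀·exp(PI) per person-year with the configured true coefficients
(fixture mortality betas by default, age centred at 57), administrative
censoring at study end; event times are capped at 100 years before date
conversion, far beyond any study window.  Defaults λ₀ = 0.003 /y (death)
and 0.009 /y (cancer) give roughly the 1.8% 5-year mortality and 5%
5-year cancer incidence of the emulated cohort.  Consultation-day counts
are negative binomial (dispersion 2) with annual mean
5.5·exp(0.25·n_conditions), sampled onto distinct calendar days with
deliberate same-day duplicates; registration histories include
bridgeable (≤ 90 d) and disqualifying (> 90 d) gaps and early
deregistration to exercise the eligibility and coverage rules.

Two independent oracles check the simulation: the closed-form
exponential event fraction, and a numerically integrated population
concordance — for a pair with predictors (a, b), usable with probability
`1 − exp(−λ(eᵃ+eᵇ)τ)` and concordant with probability
`e^max(a,b)/(eᵃ+eᵇ)`, averaged over all pairs of the PI sample.  At
n = 5,000 the simulated C at a 5-year horizon matches this oracle within
±0.02 averaged over 20 seeds.

What passing these tests shows: the machinery is internally consistent
and recovers known truth under its own generative assumptions.  What it
does not show: performance on real records, where coding is incomplete
and erroneous, condition definitions are clinically subtler, hazards are
non-exponential and age-varying, and cohort selection (e.g. healthy
volunteering) shifts prevalences — none of which the generator models.

## Problem sizes and budgets

Test and acceptance computations are sized to run comfortably on one
CPU: oracle-equivalence checks use 100 random instances at n ≤ 200;
analytic-limit and no-information checks use n = 10,000 over 5 seeds;
end-to-end recovery runs at n = 2,000; the PH-concordance check uses 20
seeds at n = 5,000; calibration identity uses n = 20,000.  The full
suite completes in well under a minute beyond the simulation-heavy
checks; the acceptance script runs in seconds.
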