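# Methods

## Phenotyping algorithm

A patient's treatment episode is the maximal run of antidepressant /
augmentation-agent supply coverage starting at the index date in which
consecutive covered intervals are separated by at most `episode_gap_days`
(default 180 — chosen to be self-consistent with the switch-failure
ceiling; the episode boundary itself is a design decision, since "the
current depressive episode" has no operational definition in claims).
Fills after the first larger gap belong to a later episode and are ignored.

Within the episode, lines of therapy are segmented by drug-start events
(first dispensing per drug; refills and dose changes never open a line).
The regimen start date is Day 1 throughout, so a drug starting on Day k has
gap = k − 1 days. A new drug against the current regimen is classified:

| supply overlap on start date | condition           | classification        |
|---|---|---|
| yes | Day 1–14                  | same regimen (combination) |
| yes | Day ≥ 15                  | augmentation failure  |
| no  | 29 ≤ gap ≤ 180 (inclusive)| switch failure        |
| no  | otherwise                 | new line, no failure  |

Both window boundaries are inclusive named constants
(`SWITCH_FAIL_MIN_GAP_DAYS`, `SWITCH_FAIL_MAX_GAP_DAYS`,
`AUGMENT_FAIL_MIN_DAY`) and are tested on both sides. An early or late
switch still opens a new line (the prior one carries `failure_mode=none`);
an augmentation-class drug starting after the regimen's supply has lapsed
can neither augment nor found a line and is ignored. TRD requires ≥ 3
regimens with lines 1 and 2 each dose-adequate *and* ended by a failure;
line 3 needs no adequacy assessment — its initiation completes the
definition.

Dose adequacy: at least one antidepressant in the line has a fill
*dispensed within the line's date span* at or above its drug-specific
minimum daily dose (boundary inclusive; titration counts). Supply carried
into a line from an earlier fill contributes coverage but not adequacy.
The shipped minimum-dose table is an implementer default in the spirit of
guideline minimal therapeutic doses and is replaceable via YAML; it is a
configuration artifact, not a clinical reference.

## Cohort rules

Month-denominated protocol windows are day-exact: 6 months = 183 days,
12 months = 365, 24 months = 730 (all config-overridable). The accrual
window defaults to 2013-01-01..2014-09-30, with a shorter ..2013-09-30
variant available (`StudyWindows.with_abstract_index_window`), because the
two appear interchangeably in study summaries of this design. The
"second compliant fill" rule is implemented as: a second antidepressant
dispensing begins no more than 30 days after the first fill's supply ends —
the coverage-gap reading of an ambiguous protocol sentence — and is applied
uniformly across diagnosis categories. ICD matching is prefix-based on
normalized codes (dots stripped, uppercase). When several depression codes
fall in the ±30-day window, the category comes from the claim nearest the
index date, ties broken 296.X > 300.X > 309.X > 311.X.

The Elixhauser score counts distinct comorbidity categories (not weighted)
with ≥ 1 matching baseline code, range 0–30. The shipped 30-category prefix
map is the classic enumeration minus the depression category (which every
cohort member carries by construction) and is replaceable configuration.

## Matching

The caliper is applied on the probability scale (width 0.02, inclusive,
with a 1e-9 float tolerance), matching without replacement, variable ratio
1..4 per case. Greedy output depends on case order, so the order is fixed:
descending propensity score, ties by patient id; control-distance ties
break by control id. A published analysis of this design reports fewer
than ratio×cases controls, which is why variable ratio — not strict 1:4 —
is the default. An independent post-hoc checker re-verifies every matching
invariant after each run.

## Outcome models

* Counts: log-link negative-binomial GLM on the TRD indicator plus the
  baseline value of the outcome. The NB2 dispersion is estimated by the
  Cameron–Trivedi auxiliary OLS regression on Poisson residuals and plugged
  into the NB family — deterministic and robust at the sample sizes used;
  dispersion ≈ 0 falls back to the Poisson fit.
* Costs: log-link gamma GLM (linear-normal OLS as sensitivity). Exact
  zero costs are shifted up by half the smallest positive cost observed
  (count reported in the result) because the gamma family needs positive
  support; the handling is config-free and logged rather than silent.
* Adjusted means use recycled predictions: predict for the whole matched
  sample with the TRD indicator toggled to 1 and to 0, then average. This
  is one of several possible "adjusted mean difference" operationalizations
  and is flagged as an interpretation.
* Bootstrap: percentile 2.5/97.5 over patient-level resamples stratified
  by arm (both follow-up years of a patient move together, respecting the
  matched structure and within-patient correlation). A resample on which
  the estimator fails is redrawn and counted; more than 10% failures
  aborts. Fixed seed ⇒ identical bounds.
* Binary use: GEE logistic with exchangeable working correlation
  (independence available) and robust sandwich variance, on TRD, year,
  TRD×year, baseline outcome, and Elixhauser; the year-1 OR is
  exp(β_TRD), the year-2 OR exp(β_TRD + β_interaction) with a delta-method
  CI. The working-correlation choice is a design decision; the sensitivity
  structure is one flag away.
* Costs by diagnosis category use the linear-normal family within each of
  296.X/300.X/309.X/311.X; subgroups with < 2 patients in either arm are
  skipped with a recorded reason.
* Costs can be restated to a reference year through a per-calendar-year
  multiplier table (identity by default); no price index is bundled.

Decedents are retained: enrollment is required only through the death
date, their claims are truncated at death, and they contribute the
outcomes they accrued.

## Synthetic data generator

Drug histories are assembled from eight parameterized templates — two TRD
(switch→switch, augment→switch) and six targeted non-TRD failures
(single line; two lines; switch too early, gap 15–28; switch too late,
episode break > 180 days; inadequate dose on line 1; inadequate dose on
line 2) — with transition gaps drawn uniformly inside the relevant windows,
so the classifier's acceptance surface is exercised at its exact
boundaries. The final line's drug keeps refilling through the end of
follow-up, so each follow-up year carries claims to which annual costs can
be attached.

Outcome truth per patient-year: annual total cost ~ Gamma(shape 1.5,
mean $8,000), the mean multiplied by `cost_effect_ratio` (default 1.4) for
TRD-trajectory patients; outpatient visits ~ NB2(mean 8, dispersion 0.8),
mean multiplied by `utilization_effect_ratio` (default 1.35); any-ED and
any-hospitalization ~ Bernoulli with base probabilities 0.20 / 0.10 and
per-year odds ratios (1.7, 1.4) for the TRD arm. Scripted prevalence
defaults to 13%. The distributional parameters for costs and visits are
free generator choices documented here, not literature claims; the
prevalence, demographic mix (62% female, mean age ≈ 39–40) and the
direction/rough magnitude of baseline covariate imbalance (anxiety 45% vs
27%, PTSD 5% vs 2%, etc.) are chosen to be realistic for a commercially
insured depression cohort. Confounding is on by default so that matching
has real work to do; `confounded=False` gives exchangeable arms. Annual
costs are drawn directly and distributed across that year's claims
(15% pharmacy share, 15% member out-of-pocket share) because the models
consume annual aggregates — the per-claim amounts have no independent
meaning. A configurable fraction dies during follow-up (flagged, claims
truncated) and a disenrollment stress fraction (default 0) breaks follow-up
coverage deliberately, flagged in ground truth.

What the generator does **not** emulate: disease progression, plan-design
and geographic heterogeneity, coding noise and miscoding, claim-level cost
structure, psychotherapy treatment lines, seasonality. Passing tests
therefore demonstrate the algorithmic and statistical machinery is correct
under the stated data-generating process, not that the pipeline is robust
to real-world claims messiness.

## Verification scales and numerical choices

Test problem sizes are package choices balancing statistical resolution
against runtime: label-recovery and matching-invariant checks run on
600–3,500-patient bundles; effect recovery runs one full pipeline at
n = 5,000 (cost and visit ratios asserted within 10%; per-year ORs pooled
across the two binary outcomes by geometric mean — they share the same
injected truth, and pooling halves the variance at ~660 matched cases —
asserted within 15% with per-outcome direction checks); bootstrap type-I
error uses 200 null replicates of 120 patients per arm with 300 resamples
each, asserted within the binomial envelope [0.025, 0.085] around the
nominal 0.05. Gamma-vs-linear sign agreement is asserted on datasets with
injected effects in both directions; under exactly null data the adjusted
difference is numerically near zero and its sign is not meaningful. The
end-to-end determinism check runs the pipeline twice at n = 350 and
compares report files byte for byte.

## Known limitations

* The episode boundary (180-day coverage gap) and the refill-compliance
  reading are interpretations of under-specified protocol language; both
  are config-overridable and flagged above.
* The dose table and Elixhauser map are documented defaults, not validated
  clinical references.
* Matching is greedy; optimal (network-flow) matching, coarsened exact
  matching and weighting are out of scope.
* No indirect/work-loss costs, no two-part hurdle cost models, no
  high-dimensional covariate selection.
* Cross-episode TRD carryover and psychotherapy-based lines are not
  modelled, and overlapping same-drug fills are not dose-averaged.
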