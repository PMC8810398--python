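# Methods

This note documents the models, conventions and numerical choices behind
`opiomort`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Study frame and date conventions

The study window is Jan 1 2001 – Oct 30 2018, divided into six three-year
calendar bins (2001–03 … 2016–18).  All date arithmetic is at day
resolution.  Two conventions are applied everywhere and are load-bearing
for the exactness guarantees:

* **Half-open intervals** `[start, end)`.  A timescale boundary falling on
  the exit day produces no zero-length cell, and no day is counted twice.
* **Feb 29 → Mar 1**: a birthday or anniversary of a Feb 29 date falls on
  Mar 1 in non-leap years, so cut sequences are total and deterministic.

Person-time in years is days / 365.25.  "12 months" of washout is exactly
365 days — unambiguous and testable, at the cost of drifting one day from
calendar-month arithmetic across leap years.

## Cohort construction

An exposed person enters at the **latest** of: study start, registration
plus washout, first exposure record.  (The three candidates only make
sense combined by a maximum: any earlier choice would defeat the washout.)
Entry requires exact age (days/365.25) in [18, 65).  Exit is the earlier
of death and the administrative end; the administrative end precedes the
death-data horizon by six months because drug-related deaths and suicides
are registered late, which would otherwise depress recent rates.

Matching pools contain registry members of the same sex and practice,
registered at least 365 days before the entry date, alive at entry, with
no exposure record on or before the entry date, and born within 3.0 years
(closed caliper, in days/365.25) of the exposed member.  Three comparators
are drawn uniformly **with replacement** — a pool of one yields the same
person three times; a person may serve many sets; each draw is a separate
follow-up unit ("member").  Comparators inherit the exposed member's entry
date (exposure density sampling, which aligns comparison person-time in
calendar time).  Two decisions the design leaves open:

* a comparator who later acquires an exposure record is censored as a
  comparator at that date (and may separately enter as exposed);
* exposure exactly *on* the entry date excludes a candidate — under the
  censoring rule such a comparator would contribute zero follow-up;
* an empty pool keeps the exposed member (their person-time still counts)
  with a logged warning; dropping them would bias exposed rates downward
  for hard-to-match strata.

## Lexis expansion

Follow-up is cut at every period start, birthday, and third anniversary of
entry strictly inside (entry, exit).  Cells carry completed age in years
at cell start (matching the generator's hazard resolution; a continuous
age would make exact cross-checks against the piecewise simulator
impossible), the period bin, the completed three-year time-since-entry
band, and person-time.  The death sits in the chronologically last cell of
the member, and only when death caused the exit.  Conservation is exact:
cell days sum to (exit − entry) days per member, and the test suite checks
the expansion cell-by-cell against a day-walk oracle that classifies every
single follow-up day.

## Cause grouping

Underlying-cause ICD-10 codes are classified by longest-prefix match
against a codelist shipped as replaceable data: the ONS drug-poisoning
definition (F11–F16, F18–F19, X40–X44, X60–X64, X85, Y10–Y14) plus
conventional chapter/block prefixes for the disease groups.  Drug
poisoning takes precedence over everything — an intentional
self-poisoning by narcotics is drug poisoning, never suicide.  Codes
matching nothing fall through to "other" and still count toward all-cause
mortality, so the exclusive labels plus "other" partition the deaths
exactly.  The precise ONS code-set edition varies over time; users with a
definitive list can supply their own file (`icd10_prefix, group, subgroup,
exclusive_label`).

## SMR estimation

Comparison-group rates are tabulated by age band × sex × period bin.  The
age-band width is 5 years (18–22, 23–27, …) by default and configurable;
5-year bands are the conventional compromise between residual confounding
by age and empty-stratum noise.  A stratum with zero comparison
person-time has an *undefined* (not zero) rate; exposed person-time in
such strata contributes zero expected deaths and is logged, which is
conservative (it can only pull the SMR up, and the logged person-time
makes the approximation auditable).

Confidence intervals are percentile bootstrap with the **matched set** as
resampling unit: weights from a with-replacement resample of sets multiply
both the comparison deaths/person-time (hence the stratum rates) and the
exposed person-time and observed deaths, so the uncertainty of the
expected count — dominant for rare causes — is propagated.  Quantiles use
numpy's linear interpolation (inclusive).  Resamples with zero expected
deaths are excluded from the quantiles with a warning; if all resamples
degenerate, the estimator raises naming the cause, while the pipeline
wrapper reports the observed count with an undefined SMR.

## Poisson rate models and marginal standardisation

Per-cause cells are aggregated by covariate pattern (exposure × age × sex
× period × tse band) before fitting — aggregation leaves the Poisson
likelihood unchanged and shrinks the design by orders of magnitude.  Age
enters centred at 35 (near the cohort's median entry age; the centring
constant is fixed so coefficients are comparable across runs) with a
quadratic term; period and tse are categorical with the first level as
reference; interactions of exposure with period and tse allow the exposed
and comparison trends to differ.  Empty or collinear design columns are
dropped with a warning before fitting; the optimisation is statsmodels'
IRLS (tolerance ~1e-8), and non-convergence raises.

Marginal rates are g-computation: predictions over the exposed cohort's
person-time-weighted covariate patterns with the axis variable (period
bin, or age) overridden, averaged, × 100 000.  Confidence intervals use
the delta method on the weighted mean of predicted rates, applied on the
log scale so bounds stay positive; a matched-set bootstrap would be the
alternative and the delta method was chosen as the default for speed and
determinism.  On a saturated model this standardisation reduces exactly
to direct standardisation (tested).  Deaths with causes outside the
exclusive classification count in all-cause fits only.

## Ageing counterfactual

`rate(year) = Σ_a w_a(year) · rate(a)` over single years of age 18–64,
with modelled rates interpolated linearly between evaluated ages and an
error if the structure puts weight outside the modelled support.  The
projection is exactly linear in the rates and invariant to the structure
under flat rates.  Because the underlying survey microdata are not
redistributable, the default structure is **synthetic**: for each year a
truncated normal over ages 18–64 (sd 9 years; the mean may drift outside
the support, truncation keeps the weights inside) whose mean is solved by
bisection so the under-40 mass interpolates the anchors — 89% in 2001,
52% in 2018 — to machine precision (tests require 0.5 points).  Any
year × age × weight file can replace it.

## The synthetic registry generator

Deaths arise from competing cause-specific hazards, piecewise constant on
single years of age × period bins (the resolution of the Lexis engine, so
closed-form checks are exact), log-linear-plus-quadratic in age with
additive period, sex (male vs female) and exposure effects on the log
scale.  One total-hazard exponential draw per person locates the death
piece; the cause is drawn proportionally to the cause-specific hazards in
that piece; the death day is uniform-exponential within the piece.
Exposure is an onset *date* (uniform over an onset window), so washout,
delayed entry and comparator censoring at later exposure are all
exercised.  All streams are explicit `numpy` generators seeded per stage;
identical configuration and seed reproduce the registry byte for byte.

The default study configuration encodes the descriptive profile of the
population it emulates: 69% male, entry-age median in the mid-30s,
exposure prevalence 25%, and cause-specific reference rates, age slopes,
period effects and exposure rate ratios chosen so the exposed group shows
drug poisoning as the leading cause (~1/3 of deaths) with a post-2010-12
rise, liver disease peaking around 2010–12 then declining, COPD roughly
doubling across the period with a steep age gradient, and an all-cause
SMR in the high single digits.  Tests never assert these anchors; they
assert recovery of whatever ground truth a configuration declares.

What the generator does **not** emulate — and hence what passing tests do
not show about real registries: deprivation, ethnicity, smoking and BMI
confounding; practice-level heterogeneity beyond the practice identifier;
differential calendar trends between exposed and comparison groups
(period effects are shared, because the hazard has no exposure × period
interaction); recording artefacts in the washout period; and
cause-of-death misclassification (codes are generated to round-trip the
classifier exactly).

## Problem sizes and test design

Calibration tests run at n = 20 000 with 3-Monte-Carlo-SE bands (rate
calibration, competing-cause shares, crude rate-ratio recovery, null SMR
calibration over 10 replicates with 1000-resample intervals, and recovery
of an 8-fold all-cause exposure rate ratio by both the SMR and the GLM
coefficient).  The Wald-coverage check for the exposure coefficient uses
100 replicates of n = 1 500 over a 2001–2007 window with constant hazard
and entry dates built directly (matching is not what that invariant
tests).  Oracle-equivalence checks (day-walk expected deaths, cell-level
Lexis agreement) run on cohorts of ≤ 50 people where the brute force is
exact and fast.  The shared demonstration fixture is n = 6 000.  All
hypothesis-based property tests run derandomised.

## Known limitations

* SMR strata use the six calendar bins (consistent with the Lexis cuts);
  single calendar years would be an alternative reading.
* The delta-method CIs for marginal rates are model-based; rare causes at
  small n can produce very wide (occasionally infinite) upper bounds.
* The competing-risk additivity of cause-specific fitted counts to the
  all-cause fit is approximate (tested at 2% on simulated data), not an
  identity.
* Age–period–cohort effects are not separately identifiable; the window
  boundaries chosen for expansion can influence the apparent split.
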