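# Methods

## Data model

The analysis operates on four tables: `persons` (birth, optional death,
source join/leave dates), `events` (dated, typed MS-qualifying records),
`pregnancies` (first day of last menstrual period, LMP, to pregnancy end),
and a source profile. The profile carries everything source-specific:
population regime (`childbearing_age` or `pregnant_only`), study span, an
optional historical lookback whose events count for identification only,
four availability flags (inpatient, outpatient/other and primary-care
diagnoses; medication data), and the pregnancy-window margins. Code lists
are deliberately out of scope: mapping ICD/ATC codes to the five event
categories is the caller's responsibility, because the algorithms operate on
categories, not codes. Prescribed and dispensed medicines are represented
identically, as the sources treat them as interchangeable components.

All dates are ISO-8601 calendar dates; intervals are closed `[start, end]`
and day counts inclusive (`end − start + 1`), which makes the 365-day
eligibility phrasing exact. Anniversaries of Feb 29 births fall on Feb 28 in
non-leap years.

## Cohort construction

Childbearing-age sources: entry = latest of {source join, 15th birthday,
source study start, 2005-01-01}; exit = earliest of {source leave, death,
day before the 50th birthday, source study end, 2019-12-31}. Exit the day
before the 50th birthday keeps every in-study day at age ≤ 49. Eligibility
requires ≥ 365 consecutive fully covered days, implemented as any 365-day
span (the rule names no calendar anchor).

Pregnant-only sources: a pregnancy qualifies when it lies completely inside
the study period and the woman is aged 15–49 throughout. Each qualifying
pregnancy opens a window `[LMP − pre_margin, end + post_margin]`; "3 months"
is fixed at 90 days and "2.5 months" at 76 days so results are reproducible
(both are profile-configurable; the France-shaped preset uses pre 76 /
post 0, the Spain- and Finland-shaped presets 90/90). Overlapping windows
merge. Coverage = observed days / follow-up days, where follow-up spans
first window start to last window end. Margins may extend windows outside
the study period, but events only count for identification within the
source's own bounds.

## Identification

The five rules and the 30-day diagnosis-separation constraint are evaluated
under "exists a satisfying selection" semantics: a woman is identified on
the earliest date `t` such that some set of distinct events dated ≤ `t`
meets the rule, where any two diagnoses in the set must be ≥ 30 days apart.
Distinct means distinct (date, category) pairs — same-day repeats of one
category collapse, as they are most plausibly administrative duplicates.
The 30-day rule binds diagnosis–diagnosis pairs only; pairs involving a DMT
need only be distinct. MS3 carries no within-one-year constraint. MS4's
two-diagnosis branch enforces the 30-day separation for consistency, with a
flag to disable it for sensitivity analyses.

Because each criterion is monotone in the event set, the implementation
walks event dates in order and tests satisfiability of the prefix with a
counting argument (the maximum number of pairwise-separated diagnoses comes
from greedy earliest-first selection, which is optimal for this
interval-scheduling structure). The test suite checks this implementation
against an independent brute-force oracle that enumerates every candidate
selection, on tens of thousands of random streams.

Events in a historical lookback count toward identification; an
identification date before cohort entry simply makes the woman prevalent
from entry. Status is absorbing to end of follow-up.

## Prevalence

Average point prevalence (childbearing-age regime) averages monthly ratios
over the month-firsts inside both the requested period and the source's
study span; months with an empty denominator are skipped. The Wilson
interval for this average is a design choice the estimator itself does not
dictate: we use effective counts `n_eff` = mean monthly denominator and
`k_eff = p̂ · n_eff`. This reduces to the ordinary Wilson interval when the
cohort is static and guarantees the interval contains the reported estimate
even when denominators drift across months (a literal mean-numerator /
mean-denominator pairing does not, because a mean of ratios is not a ratio
of means).

Period prevalence (pregnant-only regime) counts anyone whose observation
windows touch the period in the denominator and those identified on or
before the period's last day (inclusive) in the numerator. For age strata,
point-prevalence membership is age on the day; period-prevalence membership
requires at least one day in the period on which the woman is both observed
and in the age group. Age is completed years; groups are closed intervals.

Summary metrics over a whole source: per-algorithm case counts, percentages
of the study population (reported half-away-from-zero to 2 dp), maximum
relative difference `100·(max − min)/max` (1 dp), and pairwise overlap
shares `100·|A∩B|/|A|`. Exported cells with 1–4 cases are masked
(numerator, estimate and CI suppressed; zero and ≥ 5 pass through), while
unrounded, unmasked values are retained internally.

## Synthetic sources

The generator emulates what the analysis needs and nothing more:

- Birth dates uniform over 1957–2003, joining at birth, a small exponential
  leave hazard (default 0.005/year), no deaths by default.
- MS assignment by an age-prevalence curve evaluated at each woman's age at
  the study midpoint. The default curve rises 40 → 360 per 100,000 from the
  youngest to the oldest group, mirroring the age gradient of real female
  populations; the exact levels are arbitrary and claim no match to any
  actual population.
- Age at onset ~ Normal(29, 7) clipped to [10, age at study midpoint], so
  every simulated case is prevalent during follow-up and a flat curve makes
  "true prevalence" well-defined for recovery experiments.
- From onset, each event category is a homogeneous Poisson process (defaults:
  inpatient 0.3, outpatient 0.8, primary care 0.8, MS-specific DMT 1.5,
  non-specific DMT 0.3 per person-year) — the simplest process with tunable
  expected counts. Non-MS women receive false positives at 0.0002 (diagnoses)
  and 0.0001 (DMT) per person-year, emulating miscoding and off-label use.
- Pregnancies: Poisson 0.08 per fertile in-study woman-year, gestation
  Normal(280, 14) days clipped to [180, 310], overlapping episodes dropped.
- Availability masking removes event categories the profile lacks, dates
  outside the identification span, and — for pregnant-only sources — events
  outside the margin-extended pregnancy windows. Generation itself never
  depends on the availability flags, so one underlying stream can be masked
  under several profiles to isolate the availability effect.

One seeded numpy Generator drives everything in a fixed vectorized draw
order: a fixed seed reproduces output byte for byte. (Per-woman substreams
would additionally make output invariant under person reordering; that was
traded away for roughly two orders of magnitude in speed across the
100-replicate recovery study, and reordering stability is not a property the
analysis relies on.)

What passing tests show — and do not. The generator produces stationary
event rates, independent women, perfectly classified event categories and
exact dates. Real sources have coding drift, care-seeking correlation,
regional coding habits and ETL artefacts; recovery and containment results
here validate the estimator and rule implementations, not the rules'
clinical accuracy in any real database (which the design cannot validate
without chart review).

## Problem sizes and numerics

Default problem sizes: pipeline examples use 20,000 women; the recovery
study uses 100 replicates of 50,000 women at a flat 300 per 100,000 with
false positives off and default (generous) event rates; the availability
gradient uses 30,000 women at a flat 1,000 per 100,000. These sizes give
~150–300 expected cases per run, enough for stable counts while keeping the
whole suite fast on one CPU.

Wilson intervals special-case `k = 0` (lower bound exactly 0) and `k = n`
(upper exactly 1) to avoid floating-point fuzz at the boundaries; elsewhere
the closed form is used directly with `z = Φ⁻¹(0.975)`. Ratios are never
rounded internally; report rounding is half-away-from-zero at export only.

## Known limitations

- One join/leave spell per person; no multi-enrolment histories.
- Pregnancy episodes are inputs; no inference of pregnancies from care
  events.
- No age-standardisation, trend modelling, or pooling across sources.
- The published sources' absolute prevalence values are not reproducible
  here (their raw data are access-restricted); only count-derived summary
  metrics and simulation-based properties are.
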