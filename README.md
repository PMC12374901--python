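# msprev

Rule-based identification of multiple sclerosis (MS) in administrative
healthcare data, and estimation of MS prevalence among women of childbearing
age (15–49) and among pregnant women — with a synthetic-source generator so
the whole analysis runs end to end without access-restricted patient data.

MS is usually diagnosed during a woman's childbearing years, and studying MS
medication use in pregnancy requires first finding the women with MS inside
heterogeneous national and regional health databases. No single record is
definitive: sources differ in which components they observe (inpatient,
outpatient and primary-care diagnoses; dispensings or prescriptions of
disease-modifying therapies, DMTs), and some sources only observe women
around their pregnancies. `msprev` implements the standard family of
phenotyping rules used for this problem and the prevalence estimators
matched to each source regime, for epidemiologists working with event-level
extracts of such databases.

## The algorithms

A woman's qualifying events fall into five categories: diagnoses recorded in
inpatient, outpatient/other, or primary care, and DMT records split into
MS-specific (MS is the only indication) and non-specific. Five nested and
overlapping rules classify her as an MS case:

| rule | criterion |
|------|-----------|
| MS1  | ≥ 1 MS diagnosis (any setting) **or** ≥ 1 MS-specific DMT |
| MS2  | MS1 **and** one further event among diagnoses and any DMT |
| MS3  | MS2 **and** one further such event (three distinct events) |
| MS4  | ≥ 1 inpatient diagnosis **or** ≥ 2 outpatient/primary-care diagnoses |
| MS5  | ≥ 2 MS diagnoses (any setting) |

When a rule uses two or more diagnoses they must be pairwise ≥ 30 days
apart. The identification date is the day the criteria are first met (for
MS5, the date of the second diagnosis), and case status is absorbing until
the end of follow-up. Case sets are nested — MS3 ⊆ MS2 ⊆ MS1 and
MS5 ⊆ MS4 ⊆ MS1 — so the spread between the rules' counts measures how much
a source's observable components and follow-up length matter.

## The estimators

For sources covering all women of childbearing age, the **average point
prevalence** over a period averages the monthly ratios

p̂ = mean over month-firsts *d* of  (cases identified on or before *d* and in
study on *d*) / (women in study on *d*).

For pregnant-only sources, whose pregnancy-anchored windows cannot pin down
diagnosis timing, the **period prevalence** is

p̂ = (women observed in the period and identified by its end) / (women
observed at any time in the period).

Both are reported per 100,000 with 95% Wilson score intervals
((k + z²/2)/(n + z²) ± z√(k(n−k)/n + z²/4)/(n + z²)), stratified by
calendar period (2005–2009, 2010–2014, 2015–2019, clipped to each source's
span) and age group (15–24, 25–29, 30–34, 35–39, 40–49). Exported cells
with 1–4 cases are masked, following small-cell disclosure rules.

## Worked example

`examples/prevalence_pipeline.py` simulates a Norway-shaped source (all
components observable, 2008–2019) for 20,000 women and runs the full
pipeline:

```
Eligible women: 18926
Cases per algorithm: {'MS1': 86, 'MS2': 45, 'MS3': 45, 'MS4': 59, 'MS5': 45}
Maximum relative difference between two algorithms: 47.7%

MS1 average point prevalence by period (per 100,000, Wilson 95% CI):
  2008-2009                216.3 (153.0-305.6)
  2010-2014                293.1 (217.3-395.2)
  2015-2019                372.4 (284.6-487.2)
  2008-2019 (overall)      313.3 (234.3-418.9)
```

The rising trend across periods is the lookback effect: early in the study
there has been little time to observe the events that reveal a prevalent
case. The other examples cover single-stream identification
(`identify_cases.py`), the pregnant-only regime with its short windows and
wider between-algorithm spread (`pregnancy_limited_source.py`), raw
synthetic tables (`simulate_source.py`), and summary metrics computed from
the six European sources' published case counts
(`published_count_summary.py`).

A thin CLI wraps the same pipeline: `msprev simulate`, `msprev run`,
`msprev report` (see `msprev --help`).

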