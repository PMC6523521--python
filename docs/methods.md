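# Methods

## Model structure

The cohort model tracks the fraction of a CABG cohort across twelve
mutually exclusive health states: `CABG` (procedure day), `ICU_MV`,
`ICU`, `PROLONGED_MV`, `GW` (general ward), `GW_SSI`/`GW_DSWI`
(inpatient infection-care extensions), `OUT_SSI` (outpatient infection
episode), `OUT_DSWI_READMIT` (readmission for deep sternal wound
infection), `HOME`, `CARE_HOME`, and the absorbing `DECEASED`. Cycles
are daily through day 90 and quarterly (91.3 days) thereafter, to a
40-year horizon (about 250 cycles). The cohort enters at `CABG`, which
is never re-entered; repeat CABG procedures are out of scope.

Routine stay times are exact means rather than geometric exit rates, so
the inpatient pathway uses fixed-duration (tunnel) scheduling: 0.5 days
ventilated in the ICU, 1 further ICU day, then general ward to day 8.
Fractional durations are handled by fractional day-occupancy, so a
half-day on mechanical ventilation is represented exactly. A 10.6%
branch requires prolonged mechanical ventilation, inserting extra
ICU+MV days (calibrated below). Discharge splits 74.5% home / 25.5%
care home; the care home carries no extra cost by default
(`care_home_extra_annual`, configurable).

### Infection branches

Cumulative 90-day SSI incidence under reusable leads is 5.49% (the 2014
Medicare rate). The single-patient-use arm applies an odds ratio of
0.74 through the odds transform, giving 4.12%. Onset windows follow the
switch-cohort split — 1.8 : 2.1 : 1.7 (index admission : by day 30 : by
day 90) — as a multinomial over SSI cases, independent of device.
40.75% of SSIs are DSWIs.

* **Index-onset SSIs** extend the index stay by 13.3 days (24 days for
  DSWI), billed at the general-ward per-diem plus the −$158/day SSI
  adjustment (infections lengthen stays but lower the mean daily cost).
* **Post-discharge DSWIs** are readmitted: a $23,586 admission payment
  plus a 24-day inpatient episode billed at the same adjusted ward
  per-diem. Treating the payment as covering the entire stay would cap
  the achievable incremental saving far below what the printed SSI
  parameters imply; modelling the episode days explicitly is what makes
  DSWIs — as observed — the dominant cost driver. Readmission days are
  not counted in the index length of stay.
* **Other post-discharge SSIs** are outpatient episodes: a one-time
  $2,583 cost and 21 days (configurable) of utility decrement.

Post-discharge onsets are placed at the midpoint of their window.
Because no first-year quantity is discounted, within-window timing has
no effect on any aggregate output; midpoints simply keep each pathway's
schedule deterministic and the engine fast enough for the PSA.

### Mortality

In-hospital death follows a constant daily hazard over inpatient days,
with a hazard ratio of 2.0 (`ssi_death_hazard_ratio`) on SSI-care days
— hospital-acquired infection roughly doubles in-hospital mortality in
the cardiac-surgery literature. The hazard is calibrated by root
finding so that cumulative index-admission mortality in the reusable
arm equals 2.7%, and the same hazard applies to both arms; the
single-patient-use arm therefore realizes slightly lower mortality
through its smaller SSI burden. This produces the "survival paradox":
the extra survivors accrue routine care costs in later years, which is
why the 40-year saving is a little below the 1-year saving.

After discharge, background mortality follows a Gompertz annual
probability `q(age) = q0 · 2^((age − 73) / 8.5)` with `q0 = 0.045` —
roughly a 1.8× standardized mortality ratio over the 2016 US life table
at age 73, consistent with the ~50% 10-year survival reported for
elderly CABG cohorts. This is a package default, not a published model
input; it is configurable (`bg_mortality_q0`,
`bg_mortality_doubling_years`) and matters mainly for the 40-year cost
and QALY levels.

### Risk-factor adjustment

Population rates are printed for the whole cohort, while relative risks
attach to subgroups (DSWI: RR 6.45 for morbid obesity, 1.71 for
diabetes; in-hospital death: RR 1.64 for morbid obesity). The engine
recovers the reference ("average patient") rate by solving
`Σ w_g · min(1, r · RR_g) = population rate` by bisection, with
subgroup weights from independent prevalences, and re-applies it to the
scenario's cohort mix. At the default composition this is an exact
identity, so the adjustment only moves results when a scenario changes
the cohort (e.g. 10% diabetes).

### Costs, utilities, discounting

Per-diems: ICU $2,536/day, mechanical ventilation $756/day on top of
the ICU rate (used for both the initial ventilated half-day and
prolonged-MV days), general ward calibrated (below). One-time costs:
CABG $10,244, leads $9.08 (rECG) or $15 (spECG) per use. Monitoring
alarms (97.9 false + 40.9 leads-off per 100 patient-days, relative
risks 0.81/0.71 with spECG) accrue nurse time at 1.5 minutes per alarm
(`nurse_min_per_alarm`, a package default) and $58/hour over monitored
days, capped at 8. Survivors accrue future (standard) care from year 2
onward at $4,673.1/year minus $92.29 per elapsed year — the first model
year is the acute episode, whose costs are carried entirely by the
daily-phase states; the years-2+ annuity is the long-term follow-up
cost.

Utilities (EQ-5D scale): procedure day 0.741; ICU 0.402 with a −0.39
decrement while ventilated; ward 0.52; SSI care −0.198. After
discharge, utility ramps linearly from 0.741 to the 0.85 baseline over
the first year and stays there. Costs and QALYs are discounted at 3.5%
per year after year 1 (`discount_factor` is 1 within year 1); no
half-cycle correction is applied by default (a `CycleSchedule` flag
enables it).

## Calibration

Two quantities are not published inputs and are pinned to published
outputs, once, with the results frozen into the defaults:

* **Prolonged-MV extra ICU days** — closed form
  `(2.3 − 1.5)/0.106 = 7.5472` days, anchoring the mean ICU stay at 2.3
  days (`calibrate_pmv_extra_days`).
* **General-ward per-diem** — bisection on the 1-year rECG cost total
  of $35,539 gives $2,589.03/day (`calibrate_gw_daily_cost`). This is
  an *effective* per-diem: it bundles every acute-phase cost not listed
  elsewhere (pharmacy, diagnostics, physician fees, non-DSWI
  readmissions), which is why it exceeds the bare ICU room rate.

With these two values the model reproduces, without further fitting: a
1-year saving of $473, a 40-year saving of $446, a QALY gain of 0.0066,
a 40-year rECG total of $65,351, a mean stay of 8.98 days, and a
leads-off alarm reduction of ~93.9 per 100 patients.

## Probabilistic sensitivity analysis

Every non-fixed parameter is sampled independently per draw by
inverse CDF on a truncated distribution: normal for most parameters,
log-normal for relative risks and the SSI odds ratio. Truncation
intervals are the explicit variance ranges where given, else
value ± 1.96 SD, intersected with hard bounds (probabilities stay in
[0, 1], durations non-negative; signed parameters such as the −$158/day
adjustment keep their sign only through their sampling interval). A
uniform draw of 0 maps to the lower bound and 1 to the upper bound.
The odds ratio's log-SD comes from its printed CI,
σ = (ln 0.89 − ln 0.62)/3.92; single-spread relative risks use the
analogous ±1.96 SD bounds on the natural scale.

Two spreads are package defaults because no published value exists: the
90-day SSI rate uses its binomial standard error at n = 2,167 (0.0049),
and the calibrated ward per-diem uses a 10% SD (comparable to the
printed ICU per-diem range). Percentage-valued single-number spreads
are read as percentage points; the ventilation-utility range is
(−0.59, −0.09).

One uniform per parameter per draw is consumed in the documented
registry order from a single seeded generator, so results are exactly
reproducible and insensitive to evaluation order; invalid draws are
resampled (at most 10 times) with logging. Both arms share each draw's
parameters; the in-hospital hazard is recalibrated to the sampled
mortality target inside every draw. Summaries report mean, median and
the empirical 2.5–97.5 percentile range, labelled a credible interval —
model results are not normally distributed — plus the fraction of draws
in which spECG dominates, and the cost-effectiveness plane export flips
the cost sign so savings plot downward against a $25,000/QALY line.

## Synthetic claims generator

The generator emulates the 18-facility switch cohort: Poisson facility
sizes matching the 2,167/3,235 arm totals, a logistic risk model with
normal facility intercepts (SD 0.2 on the log-odds scale, an
engineering default that makes stratified and crude estimators
distinguishable), a device odds ratio applied on the log-odds scale,
and intercepts centred by Gauss–Hermite quadrature so the marginal
reusable-arm rate equals 5.49% in expectation. Onset windows are
multinomial and device-independent; flags are cumulative by
construction. It does **not** simulate patient covariates, ICD-9 code
noise, billing amounts, secular trends, or facility-size skew — so
passing recovery tests demonstrates estimator correctness under the
assumed risk model, not robustness to real claims-data pathologies
(coding drift, confounded switch timing, non-exchangeable facilities).

## Numerical choices

* Bisection tolerances: reference-rate solver 1e-12; in-hospital hazard
  1e-14; ward per-diem $0.001 on the per-diem (≪ $1 on the target).
* Trace conservation is asserted at 1e-9 per cycle row; violations
  raise rather than warn.
* Degenerate inputs: zero SSI rate, zero DSWI share, and zero mortality
  are exact limits (tested against closed forms); zero-margin claims
  tables raise; a 0.5 continuity correction with a warning handles
  zero cells in odds-ratio tables.
* Quarterly cycles use 91.3/365.25 years; the last cycle is not
  stretched to land exactly on the horizon (the schedule ends within
  one cycle of 40 years).

## Known limitations

* The ward per-diem and prolonged-MV duration are calibrated, not
  observed; alternative decompositions of the same 1-year total would
  shift the scenario-level cost split (but not the calibration anchors).
* Cohort fractions, not individuals: risk factors apply to the average
  patient, and event counts are expectations.
* The device effect enters only through the 90-day SSI odds ratio and
  alarm rates; no effect on onset timing or severity mix is modelled.
* Background mortality is a two-parameter Gompertz approximation, not a
  full life table (a configurable table would be a natural extension).
* The claims layer reports counts, rates and stratified odds ratios
  only — no regression adjustment or interrupted-time-series analysis.
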