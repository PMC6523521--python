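# ecgcea

Cost-effectiveness modelling of single-patient-use ECG cable and lead
systems (spECG) versus reusable leads (rECG) for monitoring coronary
artery bypass graft (CABG) patients.

Reusable ECG leads are frequently contaminated and have been linked to
surgical site infections (SSIs) after CABG; Medicare claims from
facilities that switched devices show about a 26% reduction in the odds
of a 90-day SSI with single-patient-use leads (OR 0.74, 95% CI
0.62–0.89). This package asks the payer's question: given that effect,
a $15 vs $9.08 per-use price difference, and the cost and
quality-of-life burden of SSIs and deep sternal wound infections
(DSWIs), is switching worth it?

It is written for health-economics and outcomes-research analysts and
provides:

* **claims statistics** — rates, percent reductions, crude and
  Mantel–Haenszel odds ratios (Robins–Breslow–Greenland CIs), Pearson
  chi-square tests, odds↔probability transforms, and two-proportion
  sample size, operating on per-procedure claims tables;
* **a synthetic claims generator** — facility-stratified cohorts with a
  known device odds ratio, baseline 90-day SSI risk, and onset-window
  split, so every estimator is testable without Medicare access;
* **a Markov cohort model** of post-CABG care — daily cycles to day 91
  and quarterly (91.3-day) cycles to 40 years, tunnel-state inpatient
  scheduling, SSI/DSWI branches, risk-factor adjustment, and 3.5%
  annual discounting after year 1;
* **probabilistic sensitivity analysis** — 2,000 seeded draws with
  inverse-CDF sampling from truncated normal/log-normal distributions,
  credible intervals, dominance fractions, and cost-effectiveness-plane
  export;
* **a scenario grid** with ICER / dominance classification.

The model's core quantity is the incremental comparison
ΔC = C_rECG − C_spECG and ΔE = E_spECG − E_rECG (QALYs). When
ΔC > 0 and ΔE > 0 the single-patient-use strategy *dominates*; otherwise
an ICER = ΔC/ΔE (USD per QALY) is reported against a $25,000/QALY
willingness-to-pay threshold. All costs are 2016 USD.

## Worked example

```python
from ecgcea import load_parameters, run_base_case

params = load_parameters(None)          # built-in base-case parameters
one_year = run_base_case(params, horizon_years=1.0)
lifetime = run_base_case(params)        # 40-year horizon

print(f"1-year cost:  rECG ${one_year['rECG'].cost:,.0f}, "
      f"saving with spECG ${one_year['delta_cost']:,.0f}")
print(f"40-year cost: rECG ${lifetime['rECG'].cost:,.0f}, "
      f"saving ${lifetime['delta_cost']:,.0f}, "
      f"QALY gain {lifetime['delta_qaly']:.4f}")
print(f"rECG length of stay {lifetime['rECG'].mean_los_days:.2f} d "
      f"({lifetime['rECG'].mean_icu_days:.2f} d ICU)")
```

prints

```
1-year cost:  rECG $35,539, saving with spECG $473
40-year cost: rECG $65,351, saving $446, QALY gain 0.0066
rECG length of stay 8.98 d (2.29 d ICU)
```

The first year of rECG care costs $35,539 per patient (the general-ward
per-diem is calibrated to this total); switching to single-patient-use
leads saves $473 in year 1, mostly through averted inpatient SSI days
and DSWI readmissions. Over 40 years the discounted saving is $446 —
slightly less, because the patients spared a fatal infection go on to
accrue routine care costs — together with a small QALY gain, so spECG
dominates. The same commands are available from a shell:

```sh
ecgcea run-base --horizon-years 1
ecgcea run-psa --n 2000 --seed 20160101 --summary psa.json --ce-plane plane.csv
ecgcea run-scenarios
ecgcea generate-claims --seed 7 --out claims.csv
ecgcea analyze-claims claims.csv --window 90 --stratify facility
```

A 2,000-draw PSA (about 10 s) yields a median per-patient saving near
$460 with every draw dominant; at roughly 86,000 Medicare CABG
procedures per year that scales to about $40 million in annual savings.

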