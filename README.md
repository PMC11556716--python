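# cvsofa

Day-1 SOFA scoring from ICU event data, including a **modified
cardiovascular SOFA** built on the norepinephrine-equivalent (NEq) dose and
lactate, with the full validation pipeline around it: Sepsis-3
suspected-infection cohort construction, worst-value extraction, NEq
exposure computation, AUROC/DeLong discrimination analysis, calibration
curves, and a seeded synthetic ICU generator so everything is testable
without access to a credentialed clinical database.

It is aimed at critical-care and biostatistics researchers who want to
compute or re-validate severity scores on MIMIC-style relational event
tables (ICU stays, chart/lab observations, vasoactive infusions,
antibiotic/culture orders).

## The scores

The cardiovascular component of SOFA scores vasopressor therapy by
drug-specific dose bands from the dopamine era:

| score | original CV-SOFA | modified CV-SOFA (M3) |
|---|---|---|
| 0 | MAP ≥ 70 mmHg | MAP ≥ 70 mmHg |
| 1 | MAP < 70 mmHg | MAP < 70 mmHg or NEq ≤ 0.2 |
| 2 | dopamine ≤ 5 or dobutamine (any) | 0.2 < NEq ≤ 0.5 |
| 3 | dopamine > 5 or epi ≤ 0.1 or norepi ≤ 0.1 | NEq > 0.5 |
| 4 | dopamine > 15 or epi > 0.1 or norepi > 0.1 | NEq > 0.5 **and** lactate ≥ 2 |

plus, for the modified score, one point (capped at 4) whenever worst
lactate ≥ 2 mmol/L. Doses in μg/kg/min sustained ≥ 1 h within the first
24 h; NEq is the summed converted rate of all concurrent vasopressors
(norepinephrine 1, epinephrine 1, phenylephrine 1/10, dopamine 1/100,
vasopressin 2.5 per U/min). The M2 variant uses breakpoints 0.1/0.2
μg/kg/min with lactate threshold 4 mmol/L. Totals swap the CV component
into the usual six-component 0–24 sum. See `docs/methods.md` for the full
rules, windows and design choices, `docs/schema.md` for the CSV schema.

## Worked example

`examples/score_single_stay.py` builds one patient-day — lowest MAP
60 mmHg, norepinephrine 0.3 μg/kg/min for 6 h, worst lactate 3.0 mmol/L,
platelets 90 — and prints:

```
lowest MAP            : 60.0 mmHg
max sustained NEq     : 0.3 ug/kg/min
worst lactate         : 3.0 mmol/L
CV-SOFA original      : 4
CV-SOFA modified (M3) : 3
CV-SOFA modified (M2) : 3
coagulation component : 2
total SOFA original   : 6
total SOFA M3         : 5
```

Norepinephrine above 0.1 μg/kg/min maxes out the original CV scale at 4
regardless of dose; M3 places 0.3 μg/kg/min in its middle band (2) and adds
one lactate point, giving 3 — the graded response the modification exists
to restore. The other examples cover cohort inclusion rules
(`cohort_inclusion_rules.py`), the NEq step function
(`neq_exposure_step_function.py`), and a full synthetic validation study
(`simulate_and_validate.py`), which on 2,000 generated patients prints
AUROCs with DeLong 95% CIs per score, e.g.

```
  cv_original    0.619 (0.586-0.651)
  cv_m2          0.659 (0.624-0.694)
  total_original 0.705 (0.668-0.742)
```

together with paired DeLong p-values and the per-level
distribution/mortality table, where the original CV score's level 2 is
nearly empty under the modern-practice generator preset.

## Command line

A thin CLI wraps the library for shell use:

```
cvsofa simulate --n 1000 --seed 7 --out bundle/
cvsofa run --simulate --n 1000 --seed 7 --out results/
cvsofa run --input bundle/ --out results/
```

`run` writes `cohort.csv`, `scores.csv`, `report.json`, figures and a
manifest; `simulate | cohort | score | validate` run the stages separately.

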