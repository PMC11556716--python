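# Bundle CSV schema

A dataset directory holds five CSV files (comma-separated, RFC-4180
quoting, UTF-8, ISO-8601 timestamps to the second, e.g.
`2019-01-01T08:30:00`). Column names are fixed and case-sensitive.
Referential integrity is enforced at read time: every `stay_id` in an event
table must exist in `stays.csv`, and every `subject_id` in `orders.csv`
must belong to some stay.

## stays.csv

One row per ICU stay.

| column | type | notes |
|---|---|---|
| stay_id | string | unique |
| subject_id | string | patient identifier (several stays may share it) |
| intime | timestamp | ICU admission; hour 0 of all scoring windows |
| outtime | timestamp | must be after intime |
| age_years | float | >= 0; inclusion requires >= 18 |
| sex | enum | `male`, `female` |
| icu_type | enum | `MICU`, `MICU/SICU`, `CCU`, `SICU/CV-ICU`, `NeuroICU` |
| hospital_death | bool | in-hospital mortality (the outcome) |
| stay_sequence | int | 1 = first ICU admission for this subject |

## observations.csv

Charted vitals and laboratory values.

| column | type | notes |
|---|---|---|
| stay_id | string | |
| time | timestamp | absolute |
| variable | enum | see vocabulary below |
| value | float | finite |
| units | string | optional; converted to canonical units at read |

Variable vocabulary and canonical units:

| variable | canonical unit | accepted synonyms |
|---|---|---|
| MAP | mmHg | |
| GCS_total | points | total Glasgow Coma Scale, 3–15 |
| lactate | mmol/L | mg/dL (÷ 9.008) |
| platelets | 10^9/L | K/uL, x10^3/uL (× 1) |
| bilirubin | mg/dL | umol/L (÷ 17.104) |
| creatinine | mg/dL | umol/L (÷ 88.42) |
| pao2 | mmHg | |
| fio2 | fraction | percent (÷ 100); values > 1 are auto-rescaled |
| urine_output_24h | mL | |
| heart_rate | bpm | |
| resp_rate | breaths/min | |
| temperature | C | |
| wbc | 10^9/L | K/uL |
| hemoglobin | g/dL | g/L (× 0.1) |

## infusions.csv

Vasoactive drug administration intervals.

| column | type | notes |
|---|---|---|
| stay_id | string | |
| drug | enum | `norepinephrine`, `epinephrine`, `dopamine`, `dobutamine`, `vasopressin`, `phenylephrine` |
| start | timestamp | |
| end | timestamp | must be after start |
| rate | float | >= 0, already weight-normalized |
| rate_units | enum | `units_per_min` for vasopressin, `ug_per_kg_min` for all others |

## orders.csv

Antibiotic and body-fluid culture orders, keyed on the subject (orders may
predate the ICU stay).

| column | type | notes |
|---|---|---|
| subject_id | string | |
| kind | enum | `antibiotic`, `culture` |
| time | timestamp | |
| detail | string | free text (agent or specimen) |

## supports.csv

Day-1 organ-support flags.

| column | type | notes |
|---|---|---|
| stay_id | string | |
| kind | enum | `mechanical_ventilation`, `renal_replacement` |
| active_day1 | bool | |

## Extracting from MIMIC-IV (recipe)

The tables intentionally mirror the MIMIC-IV layout so a credentialed user
can populate them with standard queries: `icu/icustays` → stays.csv (rank
stays per subject by intime for `stay_sequence`); `icu/chartevents` +
`hosp/labevents` → observations.csv (map itemids onto the vocabulary above
and convert units); `icu/inputevents` restricted to the six vasoactive
agents → infusions.csv (rates are stored weight-normalized there);
`hosp/prescriptions`/`emar` (antibiotics) and `hosp/microbiologyevents`
(cultures) → orders.csv; ventilation/RRT flags from the derived concepts →
supports.csv. No direct database connectivity is provided.
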