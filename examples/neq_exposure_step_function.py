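"""Norepinephrine-equivalent exposure from overlapping infusions.

Two agents run concurrently: norepinephrine 0.2 ug/kg/min for 3 h and
vasopressin 0.04 U/min for the middle hour. The summed NEq step function
reaches 0.3 for exactly one hour, which qualifies as the maximum sustained
dose; a 30-minute high-dose burst is shown not to qualify.
"""

import pandas as pd

from cvsofa import neq_exposure, neq_rate

infusions = pd.DataFrame(
    [
        {"drug": "norepinephrine", "start_h": 0.0, "end_h": 3.0,
         "rate": 0.2, "rate_units": "ug_per_kg_min"},
        {"drug": "vasopressin", "start_h": 1.0, "end_h": 2.0,
         "rate": 0.04, "rate_units": "units_per_min"},
    ]
)

exposure = neq_exposure(infusions)
print("vasopressin 0.04 U/min ->", neq_rate("vasopressin", 0.04, "units_per_min"),
      "ug/kg/min NEq")
print("max sustained NEq      ->", round(exposure.max_sustained_neq, 6), "ug/kg/min")
print("qualifying drug rates  ->", exposure.per_drug_max_rate)

burst = pd.DataFrame(
    [
        {"drug": "norepinephrine", "start_h": 0.0, "end_h": 0.5,
         "rate": 0.5, "rate_units": "ug_per_kg_min"},
    ]
)
print("\n30-min burst only      ->", neq_exposure(burst).max_sustained_neq,
      "(fails the >= 1 h rule: no vasopressor exposure counted)")
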