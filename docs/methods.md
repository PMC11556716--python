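# Methods

## Background and scope

The cardiovascular component of the SOFA score (CV-SOFA) dates from an era
of dopamine-first vasopressor practice. Under modern norepinephrine-first
practice its middle band (score 2: low-dose dopamine or any dobutamine) is
nearly empty, and minimal norepinephrine doses jump straight to scores 3–4,
so the component both overestimates mild circulatory failure and loses its
monotone relationship with mortality. This package implements a modified
CV-SOFA that replaces drug-specific dose bands with bands on the summed
norepinephrine-equivalent (NEq) dose plus a lactate criterion, alongside
the original score, and provides the full apparatus needed to validate
either on day-1 ICU data: cohort construction under the Sepsis-3
suspected-infection definition, worst-value extraction, NEq exposure
computation, the six-organ panel, and discrimination/calibration analysis.
Because the clinical database such scores are validated on is
credential-restricted, the package ships a synthetic ICU generator with the
same relational shape, used for all tests.

## Score definitions

Original CV-SOFA (doses in μg/kg/min, sustained ≥ 1 h; the highest-scoring
drug governs):

| score | criterion |
|---|---|
| 0 | MAP ≥ 70 mmHg, no vasoactive drug |
| 1 | MAP < 70 mmHg |
| 2 | dopamine ≤ 5 or dobutamine (any dose) |
| 3 | dopamine > 5, or epinephrine ≤ 0.1, or norepinephrine ≤ 0.1 |
| 4 | dopamine > 15, or epinephrine > 0.1, or norepinephrine > 0.1 |

Modified CV-SOFA, variants M3 and M2: a base score of 1 for hypotension or
NEq ≤ d₁; 2 for d₁ < NEq ≤ d₂; 3 for NEq > d₂; plus one point (capped at 4)
when worst lactate ≥ the variant threshold. M3 uses d₁ = 0.2, d₂ = 0.5
μg/kg/min with lactate ≥ 2 mmol/L; M2 uses d₁ = 0.1, d₂ = 0.2 with lactate
≥ 4 mmol/L. Score 4 is therefore attainable only as NEq > d₂ with the
lactate criterion met. Both the banded-table rendering (rows + add-one
overlay) and the point-list rendering of M3 are asserted equivalent on an
exhaustive grid in the tests.

NEq conversion factors (overridable via a CSV conversion table):
norepinephrine × 1, epinephrine × 1, phenylephrine × 1/10, dopamine × 1/100,
vasopressin × 2.5 per U/min; dobutamine is an inotrope and contributes 0.

Totals swap the CV component only: `total_X = resp + coag + liver + cns +
renal + cv_X`, each component 0–4, totals 0–24. The five non-CV components
use the standard SOFA cutoffs (documented in `cvsofa.scoring`); any missing
input scores 0 for its pathway, i.e. normality is assumed.

## Windows and extraction rules

All scoring works in real-valued hours relative to ICU admission
(intime = 0); windows are half-open `[lo, hi)`:

* vitals (MAP, GCS): `[0, 24)` h;
* laboratory values: `[-6, 24)` h (pre-ICU labs up to 6 h before admission
  count);
* infusions: `[0, 24)` h, clipped, with a minimum sustained duration of
  1.0 h (inclusive; configurable).

Worst values are the in-window extreme per variable (min for MAP,
platelets, GCS; max for lactate, bilirubin, creatinine). The PaO2/FiO2
ratio pairs each in-window PaO2 with the most recent in-window FiO2 at or
before it (fallback: the earliest in-window FiO2, then room air 0.21);
the worst ratio is the minimum.

NEq exposure builds the exact step function of summed concurrent
NEq-converted rates from interval breakpoints (no time discretization).
`max_sustained_neq` is the largest level L such that total time with
NEq ≥ L reaches the minimum duration. Drugs whose total in-window duration
falls short of the minimum are dropped before the step function is built,
which makes "no qualifying vasopressor ⇒ NEq = 0" hold by construction.
`per_drug_max_rate` (feeding the original CV score) keeps the per-interval
reading of the sustained-duration rule: a drug qualifies through any single
clipped interval of at least the minimum duration, matching the
"continuous duration" wording of the original rule. An alternative
aggregation (`neq_aggregation="max_drug"`: the largest single-drug
sustained converted rate) is selectable; the summed step function is the
default because it is the only reading under which the NEq dose of
combination therapy is meaningful.

Boundary choices, all config-exposed: hypotension is strict MAP < 70 mmHg
(the banded table governs over the prose's "70 mmHg or less");
norepinephrine or epinephrine at exactly 0.1 μg/kg/min scores 3 on the
original scale, dopamine at exactly 5 scores 2 and at exactly 15 scores 3;
the minimum infusion duration is inclusive (≥ 1.0 h).

## Cohort definition

Included stays are adult (age ≥ 18 at admission), first ICU admission per
subject (`stay_sequence = 1`), with suspected infection on ICU day 1:
at least one antibiotic order in `[intime, intime + 24 h)` and an
antibiotic–culture pair with the culture within 24 h after the antibiotic
or the antibiotic within 72 h after the culture. The two pairing clauses
are combined as OR (the classic Sepsis-3 reading); a literal AND of both
clauses is selectable (`pairing="and"`) but degenerates to simultaneous
orders and is not the default. Exclusion reasons are assigned in fixed
order (age → first-stay → infection); among multiple qualifying pairs the
earliest antibiotic, then earliest culture, wins.

## Validation statistics

* AUROC is the Mann–Whitney statistic with ties counted ½.
* Variance, 95% CIs and the paired two-score comparison use DeLong's
  structural-components method (midrank formulation); CIs use the exact
  normal 0.975 quantile and are clipped to [0, 1]. With fewer than two
  positives or negatives the variance is undefined and the CI falls back
  to [0, 1], flagged by a NaN variance. A percentile bootstrap CI is
  available as an alternative.
* Calibration is reported two ways, natural for integer scores: observed
  mortality per score level with Wilson 95% intervals, and a univariable
  logistic recalibration of outcome on score (maximum likelihood via a
  binomial GLM), whose intercept and slope are the calibration summary.
  Perfect separation or a constant score flags the fit; the observed
  per-level table is emitted regardless.
* The baseline comparison table reports mean ± SD with Student's t
  (Welch) or Wilcoxon rank-sum p-values for continuous rows and n (%)
  with chi-square (no continuity correction) for categorical rows.
  Two-tailed α = 0.05 throughout; no multiplicity adjustment.

## Synthetic data generator

Each patient i draws from an independent RNG substream keyed on
`(seed, stream, i)`; stream 0 feeds cohort bundles, stream 1 the
Monte-Carlo oracle, so oracle and cohort draws never overlap and patient i
is reproducible regardless of cohort size. A latent severity s ~ N(0, 1)
drives:

* death ~ Bernoulli(expit(−2.2 + 1.0·s)), giving ≈ 13% marginal
  in-hospital mortality;
* MAP charted every 30 min over 24 h at 78 − 6·s + N(0, 6) mmHg (rounded
  to charting precision, floored at 25);
* lactate ~ exp(N(0.7 + 0.35·s, 0.5)) mmol/L, drawn at −2 h and +6 h;
* platelets, bilirubin, creatinine, P/F ratio and a GCS deficit with
  severity-linked means (defaults in `cvsofa.simulate`); labs at −2 h and
  +6 h, each lab missing completely at random with probability 0.05;
* vasopressor exposure ~ Bernoulli(expit(−0.8 + 1.0·s)) (≈ 34% marginal),
  one primary agent from the era's drug mix, NEq-scale dose
  exp(N(−2.12 + 0.5·s, 0.7)) converted back to the agent's native rate,
  infused 2–20 h from within the first 2 h; 15% of exposed patients get an
  additional sub-1-h burst of the same agent to exercise the duration
  filter;
* mechanical ventilation ~ expit(0.7·s) (≈ 50%), renal replacement
  ~ expit(−4 + s);
* antibiotic on day 1 with probability 0.95 and a culture inside a
  qualifying window with probability 0.95; failing cultures are placed
  25–48 h after the antibiotic so that both pairing clauses fail; 1%
  under-18 and 3% non-first stays exercise the other exclusions.

The modern drug mix (norepinephrine 0.47, phenylephrine 0.30, epinephrine
0.10, vasopressin 0.10, dopamine 0.02, dobutamine 0.01) approximates the
agent frequencies of a contemporary US ICU cohort; the legacy preset is
dopamine-dominant (0.40). Under the modern preset the generator+scorer
reproduce the structural finding that motivates the modified score:
original CV-SOFA level 2 is far rarer than level 3 and its observed
mortality tends to sit above level 3's.

`true_auroc` estimates the generator-implied AUROC of any score against
death by scoring fresh oracle draws (default 200,000 patients) through a
summary-level fast path that shares the exact per-patient draws with the
bundle generator; equality of fast-path panels with the full
read → score pipeline is itself enforced by a test, so the oracle cannot
drift from the pipeline.

What the generator does not model: serial (multi-day) organ-failure
dynamics, informative missingness, multi-agent vasopressor regimens,
weight variation (rates are stored weight-normalized), urine output, and
correlated lab panels. Passing tests therefore demonstrate correctness of
the scoring and validation machinery under a faithful but simplified data
distribution — not clinical performance of any score on real ICU data.

## Problem sizes and numerical choices

Test and validation problem sizes were chosen for tight Monte-Carlo
control at interactive runtimes: parameter-recovery checks use a cohort of
5,000 patients against a 200,000-draw oracle; null calibration of the
paired DeLong test uses 1,000 replicates of n = 500; the bootstrap
cross-check uses 2,000 resamples at n = 500. Statistical acceptance bands
are 3 standard errors (binomial or DeLong, as appropriate) around the
generating value. Interval arithmetic in the NEq step function is exact
from breakpoints, with a 1e-12 absolute tolerance on duration and level
comparisons to absorb float summation; CSV round-trips preserve floats
exactly (`float_precision="round_trip"`) and timestamps to the second.

## Known limitations

* The NEq conversion table is the scoping-review standard; institutional
  tables differ mainly on vasopressin and phenylephrine, hence the CSV
  override hook.
* Original CV-SOFA ignores phenylephrine and vasopressin by definition,
  which is faithful to the original rule but means the original/modified
  comparison partly reflects drug coverage, not only banding.
* The respiratory component depends on the PaO2–FiO2 pairing rule
  described above; charting patterns with FiO2 recorded long before PaO2
  will pair stale values.
* In-hospital mortality is the only outcome; no 28-day or ICU mortality.
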