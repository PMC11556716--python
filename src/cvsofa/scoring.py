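"""Day-1 SOFA scoring: original six components plus modified cardiovascular
variants built on norepinephrine-equivalent (NEq) dose and lactate.

The original cardiovascular component scores the single highest-scoring
vasopressor (dopamine / dobutamine / epinephrine / norepinephrine dose
bands). The modified variants replace drug-specific bands with bands on the
summed NEq dose sustained for at least one hour, plus one additional point
(capped at 4) when the worst lactate reaches the variant's threshold:

* M3: 1 point for hypotension or NEq <= 0.2 ug/kg/min; 2 for 0.2 < NEq <= 0.5;
  3 for NEq > 0.5; lactate threshold 2 mmol/L (4 = NEq > 0.5 and lactate >= 2).
* M2: breakpoints 0.1 / 0.2 ug/kg/min; lactate threshold 4 mmol/L.

Worst-value extraction uses half-open windows in hours relative to ICU
admission: vitals [0, 24), labs [-6, 24), infusions [0, 24). Missing
inputs score 0 for their pathway (normality assumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .ehr import DRUGS, EhrBundle, infusion_hours, observation_hours

__all__ = [
    "Windows",
    "ScoreConfig",
    "Variant",
    "M3",
    "M2",
    "VARIANTS",
    "NeqExposure",
    "ScorePanel",
    "DEFAULT_NEQ_FACTORS",
    "load_neq_factors",
    "neq_rate",
    "neq_exposure",
    "worst_value",
    "cv_sofa_original",
    "cv_sofa_modified",
    "organ_component",
    "resp_score",
    "coag_score",
    "liver_score",
    "cns_score",
    "renal_score",
    "score_stay",
    "score_cohort",
    "SCORES_COLUMNS",
]


@dataclass(frozen=True)
class Windows:
    """Observation windows, half-open [lo, hi) in hours from ICU intime."""

    vital_window: tuple[float, float] = (0.0, 24.0)
    lab_window: tuple[float, float] = (-6.0, 24.0)
    infusion_window: tuple[float, float] = (0.0, 24.0)
    min_infusion_hours: float = 1.0

    def __post_init__(self) -> None:
        if self.min_infusion_hours <= 0:
            raise ValueError("min_infusion_hours must be positive")


#: NEq conversion factors into norepinephrine-equivalent ug/kg/min.
#: Vasopressin rates are U/min (factor per unit/min); dobutamine is an
#: inotrope and contributes 0.
DEFAULT_NEQ_FACTORS: dict[str, float] = {
    "norepinephrine": 1.0,
    "epinephrine": 1.0,
    "phenylephrine": 0.1,
    "dopamine": 0.01,
    "vasopressin": 2.5,
    "dobutamine": 0.0,
}


class Variant(NamedTuple):
    """Modified CV score parameterization: NEq breakpoints (ug/kg/min) and
    the lactate add-a-point threshold (mmol/L)."""

    name: str
    neq_low: float
    neq_high: float
    lactate_threshold: float


M3 = Variant("M3", 0.2, 0.5, 2.0)
M2 = Variant("M2", 0.1, 0.2, 4.0)
VARIANTS: dict[str, Variant] = {"M3": M3, "M2": M2}


@dataclass(frozen=True)
class ScoreConfig:
    windows: Windows = Windows()
    neq_factors: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NEQ_FACTORS)
    )
    neq_aggregation: str = "sum"  # "sum" | "max_drug"
    map_threshold: float = 70.0
    strict_hypotension: bool = True  # True: MAP < 70; False: MAP <= 70

    def __post_init__(self) -> None:
        if self.neq_aggregation not in ("sum", "max_drug"):
            raise ValueError("neq_aggregation must be 'sum' or 'max_drug'")


def load_neq_factors(path: str | Path) -> dict[str, float]:
    """Load an NEq conversion override table (CSV: drug, factor, rate_units)."""
    df = pd.read_csv(path)
    factors = dict(DEFAULT_NEQ_FACTORS)
    for row in df.itertuples(index=False):
        if row.drug not in DRUGS:
            raise ValueError(f"unknown drug in conversion table: {row.drug!r}")
        factors[row.drug] = float(row.factor)
    return factors


def neq_rate(
    drug: str,
    rate: float,
    rate_units: str = "ug_per_kg_min",
    factors: dict[str, float] | None = None,
) -> float:
    """Convert one drug rate to norepinephrine-equivalent ug/kg/min."""
    factors = DEFAULT_NEQ_FACTORS if factors is None else factors
    if drug not in factors:
        raise ValueError(f"unknown drug {drug!r}")
    expected = "units_per_min" if drug == "vasopressin" else "ug_per_kg_min"
    if rate_units != expected:
        raise ValueError(f"{drug} rates must be in {expected}, got {rate_units!r}")
    return rate * factors[drug]


@dataclass(frozen=True)
class NeqExposure:
    """Day-1 vasopressor exposure summary.

    ``max_sustained_neq`` is the largest level L of the summed concurrent
    NEq step function such that total in-window time with NEq >= L is at
    least the minimum infusion duration. ``any_vasopressor`` is true iff
    some non-dobutamine agent ran for at least that duration in-window.
    """

    max_sustained_neq: float = 0.0
    any_vasopressor: bool = False
    per_drug_max_rate: dict[str, float] = field(default_factory=dict)


def _sustained_max(segments: list[tuple[float, float]], min_hours: float) -> float:
    """Max level of a step function sustained for >= min_hours.

    ``segments`` are (duration, level) pieces; exact breakpoint arithmetic,
    no discretization.
    """
    levels = sorted({lvl for _, lvl in segments if lvl > 0}, reverse=True)
    for v in levels:
        total = sum(d for d, lvl in segments if lvl >= v - 1e-12)
        if total >= min_hours - 1e-12:
            return v
    return 0.0


def _step_segments(
    intervals: list[tuple[float, float, float]]
) -> list[tuple[float, float]]:
    """Sum overlapping (start, end, rate) intervals into (duration, level)."""
    if not intervals:
        return []
    points = sorted({t for s, e, _ in intervals for t in (s, e)})
    segs = []
    for lo, hi in zip(points[:-1], points[1:]):
        level = sum(r for s, e, r in intervals if s <= lo and e >= hi)
        segs.append((hi - lo, level))
    return segs


def neq_exposure(
    infusions: pd.DataFrame,
    windows: Windows = Windows(),
    factors: dict[str, float] | None = None,
    aggregation: str = "sum",
) -> NeqExposure:
    """Compute NEq exposure for one stay.

    ``infusions`` needs columns drug, start_h, end_h, rate, rate_units
    (hours relative to intime). Intervals are clipped to the infusion
    window; drugs whose total in-window duration falls short of the minimum
    duration do not qualify and are dropped before the step function is
    built (so a non-qualifying exposure yields NEq 0).
    """
    factors = DEFAULT_NEQ_FACTORS if factors is None else factors
    if aggregation not in ("sum", "max_drug"):
        raise ValueError("aggregation must be 'sum' or 'max_drug'")
    w0, w1 = windows.infusion_window
    min_h = windows.min_infusion_hours

    clipped: list[tuple[str, float, float, float, str]] = []
    for row in infusions.itertuples(index=False):
        s, e = max(row.start_h, w0), min(row.end_h, w1)
        if e - s > 0:
            clipped.append((row.drug, s, e, float(row.rate), row.rate_units))

    totals: dict[str, float] = {}
    for drug, s, e, _, _ in clipped:
        totals[drug] = totals.get(drug, 0.0) + (e - s)
    qualifying = {d for d, tot in totals.items() if tot >= min_h - 1e-12}

    per_drug_max_rate = {}
    for drug, s, e, rate, _ in clipped:
        if e - s >= min_h - 1e-12:
            per_drug_max_rate[drug] = max(per_drug_max_rate.get(drug, 0.0), rate)

    any_vp = any(d != "dobutamine" for d in qualifying)

    kept = [
        (drug, s, e, neq_rate(drug, rate, units, factors))
        for drug, s, e, rate, units in clipped
        if drug in qualifying
    ]
    if aggregation == "sum":
        segs = _step_segments([(s, e, r) for _, s, e, r in kept])
        max_neq = _sustained_max(segs, min_h)
    else:
        max_neq = 0.0
        for drug in qualifying:
            segs = _step_segments([(s, e, r) for d, s, e, r in kept if d == drug])
            max_neq = max(max_neq, _sustained_max(segs, min_h))

    if not any_vp:
        max_neq = 0.0
    return NeqExposure(
        max_sustained_neq=max_neq,
        any_vasopressor=any_vp,
        per_drug_max_rate=per_drug_max_rate,
    )


def worst_value(
    observations: pd.DataFrame,
    variable: str,
    window: tuple[float, float],
    direction: str,
) -> float | None:
    """Extreme of one variable within a half-open window [lo, hi) of hours
    relative to intime; ``None`` if no in-window value exists."""
    if direction not in ("min", "max"):
        raise ValueError("direction must be 'min' or 'max'")
    if not len(observations):
        return None
    lo, hi = window
    mask = (
        (observations["variable"] == variable)
        & (observations["t_hours"] >= lo)
        & (observations["t_hours"] < hi)
    )
    vals = observations.loc[mask, "value"]
    if not len(vals):
        return None
    return float(vals.min() if direction == "min" else vals.max())


def _hypotensive(map_min: float | None, config: ScoreConfig) -> bool:
    if map_min is None:
        return False
    if config.strict_hypotension:
        return map_min < config.map_threshold
    return map_min <= config.map_threshold


def cv_sofa_original(
    map_min: float | None,
    neq: NeqExposure,
    config: ScoreConfig = ScoreConfig(),
) -> int:
    """Original cardiovascular SOFA from qualifying (>= 1 h) drug rates.

    Doses in ug/kg/min; the drug implying the highest score governs. An
    absent MAP is treated as normal.
    """
    rates = neq.per_drug_max_rate
    dop = rates.get("dopamine", 0.0)
    epi = rates.get("epinephrine", 0.0)
    nor = rates.get("norepinephrine", 0.0)
    dob = rates.get("dobutamine", 0.0)
    if dop > 15 or epi > 0.1 or nor > 0.1:
        return 4
    if dop > 5 or epi > 0 or nor > 0:
        return 3
    if dop > 0 or dob > 0:
        return 2
    if _hypotensive(map_min, config):
        return 1
    return 0


def cv_sofa_modified(
    map_min: float | None,
    neq: NeqExposure,
    lactate_max: float | None,
    variant: Variant | str = M3,
    config: ScoreConfig = ScoreConfig(),
) -> int:
    """Modified cardiovascular SOFA (M3 or M2).

    Base score from hypotension and the sustained NEq dose band; one point
    added (capped at 4) when worst lactate reaches the variant threshold.
    Absent lactate adds nothing; absent MAP is treated as normal.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    dose = neq.max_sustained_neq if neq.any_vasopressor else 0.0
    if dose > variant.neq_high:
        base = 3
    elif dose > variant.neq_low:
        base = 2
    elif dose > 0 or _hypotensive(map_min, config):
        base = 1
    else:
        base = 0
    add = 1 if lactate_max is not None and lactate_max >= variant.lactate_threshold else 0
    return min(base + add, 4)


def resp_score(pf_ratio: float | None, ventilated: bool) -> int:
    """Respiratory component from PaO2/FiO2 (mmHg); 3-4 require support."""
    if pf_ratio is None:
        return 0
    if pf_ratio < 100 and ventilated:
        return 4
    if pf_ratio < 200 and ventilated:
        return 3
    if pf_ratio < 300:
        return 2
    if pf_ratio < 400:
        return 1
    return 0


def coag_score(platelets: float | None) -> int:
    if platelets is None:
        return 0
    if platelets < 20:
        return 4
    if platelets < 50:
        return 3
    if platelets < 100:
        return 2
    if platelets < 150:
        return 1
    return 0


def liver_score(bilirubin: float | None) -> int:
    if bilirubin is None:
        return 0
    if bilirubin >= 12.0:
        return 4
    if bilirubin >= 6.0:
        return 3
    if bilirubin >= 2.0:
        return 2
    if bilirubin >= 1.2:
        return 1
    return 0


def cns_score(gcs: float | None) -> int:
    if gcs is None:
        return 0
    if gcs < 6:
        return 4
    if gcs <= 9:
        return 3
    if gcs <= 12:
        return 2
    if gcs <= 14:
        return 1
    return 0


def renal_score(creatinine: float | None, urine_24h: float | None = None) -> int:
    score = 0
    if creatinine is not None:
        if creatinine >= 5.0:
            score = 4
        elif creatinine >= 3.5:
            score = 3
        elif creatinine >= 2.0:
            score = 2
        elif creatinine >= 1.2:
            score = 1
    if urine_24h is not None:
        if urine_24h < 200:
            score = max(score, 4)
        elif urine_24h < 500:
            score = max(score, 3)
    return score


def organ_component(
    values: dict[str, float | None],
    component: str,
    ventilated: bool = False,
) -> int:
    """Score one non-cardiovascular component from its worst value(s).

    ``values`` keys per component: resp -> pf_ratio; coag -> platelets;
    liver -> bilirubin; cns -> gcs; renal -> creatinine, urine_24h.
    """
    if component == "resp":
        return resp_score(values.get("pf_ratio"), ventilated)
    if component == "coag":
        return coag_score(values.get("platelets"))
    if component == "liver":
        return liver_score(values.get("bilirubin"))
    if component == "cns":
        return cns_score(values.get("gcs"))
    if component == "renal":
        return renal_score(values.get("creatinine"), values.get("urine_24h"))
    raise ValueError(f"unknown component {component!r}")


def _pf_ratio(obs: pd.DataFrame, windows: Windows) -> float | None:
    """Worst PaO2/FiO2: each in-window PaO2 paired with the most recent
    in-window FiO2 at or before it (fallback: earliest in-window FiO2,
    then room air 0.21); FiO2 given as percent is rescaled."""
    lo, hi = windows.lab_window
    inwin = obs[(obs["t_hours"] >= lo) & (obs["t_hours"] < hi)]
    pao2 = inwin[inwin["variable"] == "pao2"].sort_values("t_hours")
    if not len(pao2):
        return None
    fio2 = inwin[inwin["variable"] == "fio2"].sort_values("t_hours")
    ratios = []
    for row in pao2.itertuples(index=False):
        if len(fio2):
            prior = fio2[fio2["t_hours"] <= row.t_hours]
            f = float(prior["value"].iloc[-1] if len(prior) else fio2["value"].iloc[0])
        else:
            f = 0.21
        if f > 1.0:
            f = f / 100.0
        if f <= 0:
            continue
        ratios.append(row.value / f)
    return min(ratios) if ratios else None


@dataclass(frozen=True)
class ScorePanel:
    """Per-stay day-1 scores: six original components, cardiovascular
    variants, totals, and the physiology behind the CV scores."""

    stay_id: str
    resp: int
    coag: int
    liver: int
    cns: int
    renal: int
    cv_original: int
    cv_m3: int
    cv_m2: int
    map_min: float | None
    lactate_max: float | None
    neq: NeqExposure

    @property
    def total_original(self) -> int:
        return self._base() + self.cv_original

    @property
    def total_m3(self) -> int:
        return self._base() + self.cv_m3

    @property
    def total_m2(self) -> int:
        return self._base() + self.cv_m2

    def _base(self) -> int:
        return self.resp + self.coag + self.liver + self.cns + self.renal

    def as_dict(self) -> dict:
        return {
            "stay_id": self.stay_id,
            "resp": self.resp,
            "coag": self.coag,
            "liver": self.liver,
            "cns": self.cns,
            "renal": self.renal,
            "cv_original": self.cv_original,
            "cv_m2": self.cv_m2,
            "cv_m3": self.cv_m3,
            "total_original": self.total_original,
            "total_m2": self.total_m2,
            "total_m3": self.total_m3,
            "map_min": self.map_min,
            "lactate_max": self.lactate_max,
            "max_sustained_neq": self.neq.max_sustained_neq,
            "any_vasopressor": self.neq.any_vasopressor,
        }


SCORES_COLUMNS = [
    "stay_id",
    "resp",
    "coag",
    "liver",
    "cns",
    "renal",
    "cv_original",
    "cv_m2",
    "cv_m3",
    "total_original",
    "total_m2",
    "total_m3",
    "map_min",
    "lactate_max",
    "max_sustained_neq",
    "any_vasopressor",
]


def panel_from_summaries(
    stay_id: str,
    map_min: float | None,
    lactate_max: float | None,
    neq: NeqExposure,
    pf_ratio: float | None,
    platelets: float | None,
    bilirubin: float | None,
    gcs: float | None,
    creatinine: float | None,
    urine_24h: float | None = None,
    ventilated: bool = False,
    config: ScoreConfig = ScoreConfig(),
) -> ScorePanel:
    """Assemble a panel directly from already-extracted worst values."""
    return ScorePanel(
        stay_id=stay_id,
        resp=resp_score(pf_ratio, ventilated),
        coag=coag_score(platelets),
        liver=liver_score(bilirubin),
        cns=cns_score(gcs),
        renal=renal_score(creatinine, urine_24h),
        cv_original=cv_sofa_original(map_min, neq, config),
        cv_m3=cv_sofa_modified(map_min, neq, lactate_max, M3, config),
        cv_m2=cv_sofa_modified(map_min, neq, lactate_max, M2, config),
        map_min=map_min,
        lactate_max=lactate_max,
        neq=neq,
    )


def _score_one(
    stay_id: str,
    obs: pd.DataFrame,
    infusions: pd.DataFrame,
    ventilated: bool,
    config: ScoreConfig,
) -> ScorePanel:
    w = config.windows
    map_min = worst_value(obs, "MAP", w.vital_window, "min")
    lactate_max = worst_value(obs, "lactate", w.lab_window, "max")
    exposure = neq_exposure(infusions, w, config.neq_factors, config.neq_aggregation)
    return panel_from_summaries(
        stay_id=stay_id,
        map_min=map_min,
        lactate_max=lactate_max,
        neq=exposure,
        pf_ratio=_pf_ratio(obs, w),
        platelets=worst_value(obs, "platelets", w.lab_window, "min"),
        bilirubin=worst_value(obs, "bilirubin", w.lab_window, "max"),
        gcs=worst_value(obs, "GCS_total", w.vital_window, "min"),
        creatinine=worst_value(obs, "creatinine", w.lab_window, "max"),
        urine_24h=worst_value(obs, "urine_output_24h", w.lab_window, "min"),
        ventilated=ventilated,
        config=config,
    )


def _vent_flags(bundle: EhrBundle) -> dict[str, bool]:
    sup = bundle.supports
    if not len(sup):
        return {}
    mv = sup[(sup["kind"] == "mechanical_ventilation") & sup["active_day1"]]
    return {sid: True for sid in mv["stay_id"]}


def score_stay(
    bundle: EhrBundle,
    stay_id: str,
    config: ScoreConfig = ScoreConfig(),
) -> ScorePanel:
    """Score a single stay from the bundle's event tables."""
    if stay_id not in set(bundle.stays["stay_id"]):
        raise KeyError(f"stay_id {stay_id!r} not in bundle")
    obs = observation_hours(bundle)
    inf = infusion_hours(bundle)
    vent = _vent_flags(bundle)
    return _score_one(
        stay_id,
        obs[obs["stay_id"] == stay_id],
        inf[inf["stay_id"] == stay_id],
        vent.get(stay_id, False),
        config,
    )


def score_cohort(
    bundle: EhrBundle,
    cohort: pd.DataFrame | Iterable[str] | None = None,
    config: ScoreConfig = ScoreConfig(),
) -> pd.DataFrame:
    """Score every included stay; returns a scores table (one row per stay,
    stable stay order, columns :data:`SCORES_COLUMNS`)."""
    if cohort is None:
        ids = list(bundle.stays["stay_id"])
    elif isinstance(cohort, pd.DataFrame):
        ids = list(cohort.loc[cohort["included"], "stay_id"])
    else:
        ids = list(cohort)

    obs = observation_hours(bundle)
    inf = infusion_hours(bundle)
    vent = _vent_flags(bundle)
    obs_by = {k: g for k, g in obs.groupby("stay_id")} if len(obs) else {}
    inf_by = {k: g for k, g in inf.groupby("stay_id")} if len(inf) else {}
    empty_obs = obs.iloc[0:0]
    empty_inf = inf.iloc[0:0]

    rows = []
    for sid in ids:
        panel = _score_one(
            sid,
            obs_by.get(sid, empty_obs),
            inf_by.get(sid, empty_inf),
            vent.get(sid, False),
            config,
        )
        rows.append(panel.as_dict())
    return pd.DataFrame(rows, columns=SCORES_COLUMNS)


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, index=False)
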