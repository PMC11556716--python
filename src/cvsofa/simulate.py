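"""Seeded synthetic ICU data with the statistical structure the scoring
and validation pipeline assumes.

A latent standard-normal severity drives everything per patient: in-hospital
death through a logistic link, the MAP series downward, lactate and the
organ labs via (log-)linear links, vasopressor exposure probability and
NEq-scale dose, and organ-support flags. Antibiotic/culture order times are
placed to satisfy or violate the suspected-infection inclusion windows with
stated probabilities. The drug mix is era-switchable: the ``modern`` preset
is norepinephrine-dominant with dopamine/dobutamine rare; ``legacy`` is
dopamine-dominant.

Each patient draws from an independent RNG substream keyed on
``(seed, stream, patient_index)``, so patient i is reproducible regardless
of cohort size, and oracle draws (stream 1) never overlap cohort draws
(stream 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ehr import EhrBundle
from .scoring import (
    NeqExposure,
    ScoreConfig,
    ScorePanel,
    neq_rate,
    panel_from_summaries,
)

__all__ = [
    "SimParams",
    "MODERN_DRUG_MIX",
    "LEGACY_DRUG_MIX",
    "simulate_bundle",
    "simulate_panels",
    "true_auroc",
    "make_toy_fixture",
]

MODERN_DRUG_MIX: dict[str, float] = {
    "norepinephrine": 0.47,
    "phenylephrine": 0.30,
    "epinephrine": 0.10,
    "vasopressin": 0.10,
    "dopamine": 0.02,
    "dobutamine": 0.01,
}

LEGACY_DRUG_MIX: dict[str, float] = {
    "norepinephrine": 0.20,
    "phenylephrine": 0.10,
    "epinephrine": 0.10,
    "vasopressin": 0.05,
    "dopamine": 0.40,
    "dobutamine": 0.15,
}

_DEFAULT_ORGAN_PARAMS: dict[str, dict[str, float]] = {
    # linear-in-severity labs: value = mean + slope*severity + N(0, sd)
    "platelets": {"mean": 220.0, "slope": -40.0, "sd": 60.0, "floor": 5.0},
    "pf_ratio": {"mean": 350.0, "slope": -60.0, "sd": 80.0, "floor": 40.0},
    # lognormal labs: value = exp(log_mean + slope*severity + N(0, sd))
    "bilirubin": {"log_mean": -0.223, "slope": 0.35, "sd": 0.6},
    "creatinine": {"log_mean": 0.0, "slope": 0.30, "sd": 0.4},
    # GCS deficit: gcs = clip(round(15 - max(0, N(mean+slope*sev, sd))), 3, 15)
    "gcs_deficit": {"mean": 0.8, "slope": 1.4, "sd": 1.5},
}

_ICU_TYPES = ["MICU", "MICU/SICU", "CCU", "SICU/CV-ICU", "NeuroICU"]
_ICU_PROBS = [0.22, 0.20, 0.09, 0.48, 0.01]

_BASE_TIME = pd.Timestamp("2019-01-01 00:00:00")


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults emulate a modern-era suspected-infection
    ICU cohort (norepinephrine-dominant vasopressor practice, ~12-13%
    in-hospital mortality, ~1/3 vasopressor exposure)."""

    n_patients: int = 1000
    seed: int = 0
    mortality_intercept: float = -2.2
    mortality_slope: float = 1.0
    map_base: float = 78.0
    map_severity_drop: float = 6.0
    map_noise_sd: float = 6.0
    lactate_log_mean: float = 0.7
    lactate_log_slope: float = 0.35
    lactate_log_sd: float = 0.5
    vasopressor_logit_intercept: float = -0.8
    vasopressor_logit_slope: float = 1.0
    drug_mix: dict[str, float] | None = None
    neq_dose_log_mean: float = -2.12
    neq_dose_log_slope: float = 0.5
    neq_dose_log_sd: float = 0.7
    organ_lab_params: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_ORGAN_PARAMS.items()}
    )
    p_antibiotic_day1: float = 0.95
    p_culture_within_window: float = 0.95
    p_underage: float = 0.01
    p_second_stay: float = 0.03
    p_missing_lab: float = 0.05
    p_short_infusion: float = 0.15
    vent_logit_intercept: float = 0.0
    vent_logit_slope: float = 0.7
    rrt_logit_intercept: float = -4.0
    rrt_logit_slope: float = 1.0
    era: str = "modern"

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.era not in ("modern", "legacy"):
            raise ValueError("era must be 'modern' or 'legacy'")
        for name in (
            "p_antibiotic_day1",
            "p_culture_within_window",
            "p_underage",
            "p_second_stay",
            "p_missing_lab",
            "p_short_infusion",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        mix = self.effective_drug_mix()
        if abs(sum(mix.values()) - 1.0) > 1e-9 or min(mix.values()) < 0:
            raise ValueError("drug_mix must be a probability vector summing to 1")

    def effective_drug_mix(self) -> dict[str, float]:
        if self.drug_mix is not None:
            return self.drug_mix
        return MODERN_DRUG_MIX if self.era == "modern" else LEGACY_DRUG_MIX

    def inclusion_probability(self) -> float:
        """Probability a generated stay passes all three inclusion criteria."""
        return (
            (1.0 - self.p_underage)
            * (1.0 - self.p_second_stay)
            * self.p_antibiotic_day1
            * self.p_culture_within_window
        )


def _draw_patient(i: int, params: SimParams, stream: int) -> dict:
    """All generating values for patient ``i`` (fixed draw order).

    The summaries here are exact images of what worst-value extraction and
    NEq-exposure computation recover from the event tables built from them.
    """
    rng = np.random.default_rng([params.seed, stream, i])
    mix = params.effective_drug_mix()
    drugs = list(mix)
    probs = [mix[d] for d in drugs]

    sev = float(rng.standard_normal())
    death_prob = _expit(params.mortality_intercept + params.mortality_slope * sev)
    died = bool(rng.random() < death_prob)

    underage = rng.random() < params.p_underage
    age = (
        float(rng.uniform(14.0, 17.9))
        if underage
        else float(np.clip(rng.normal(65.0, 17.0), 18.0, 100.0))
    )
    second = rng.random() < params.p_second_stay
    sex = "male" if rng.random() < 0.55 else "female"
    icu_type = str(rng.choice(_ICU_TYPES, p=_ICU_PROBS))

    map_series = (
        params.map_base
        - params.map_severity_drop * sev
        + rng.normal(0.0, params.map_noise_sd, 48)
    )
    map_series = np.round(np.maximum(map_series, 25.0), 1)  # charted precision

    lac = params.organ_lab_params  # alias only for brevity below
    lactate = np.exp(
        rng.normal(
            params.lactate_log_mean + params.lactate_log_slope * sev,
            params.lactate_log_sd,
            2,
        )
    )
    p = lac["platelets"]
    platelets = np.maximum(
        rng.normal(p["mean"] + p["slope"] * sev, p["sd"], 2), p["floor"]
    )
    b = lac["bilirubin"]
    bilirubin = np.exp(rng.normal(b["log_mean"] + b["slope"] * sev, b["sd"], 2))
    c = lac["creatinine"]
    creatinine = np.exp(rng.normal(c["log_mean"] + c["slope"] * sev, c["sd"], 2))
    f = lac["pf_ratio"]
    pf = float(max(rng.normal(f["mean"] + f["slope"] * sev, f["sd"]), f["floor"]))
    g = lac["gcs_deficit"]
    deficit = max(0.0, rng.normal(g["mean"] + g["slope"] * sev, g["sd"]))
    gcs = int(np.clip(round(15 - deficit), 3, 15))

    ventilated = bool(
        rng.random() < _expit(params.vent_logit_intercept + params.vent_logit_slope * sev)
    )
    rrt = bool(
        rng.random() < _expit(params.rrt_logit_intercept + params.rrt_logit_slope * sev)
    )

    on_vasopressor = bool(
        rng.random()
        < _expit(
            params.vasopressor_logit_intercept + params.vasopressor_logit_slope * sev
        )
    )
    drug = None
    rate = 0.0
    inf_start = inf_end = 0.0
    short_infusion = False
    if on_vasopressor:
        drug = drugs[int(rng.choice(len(drugs), p=probs))]
        if drug == "dobutamine":
            rate = float(np.exp(rng.normal(np.log(4.0), 0.4)))
        else:
            neq_dose = float(
                np.exp(
                    rng.normal(
                        params.neq_dose_log_mean + params.neq_dose_log_slope * sev,
                        params.neq_dose_log_sd,
                    )
                )
            )
            from .scoring import DEFAULT_NEQ_FACTORS

            rate = neq_dose / DEFAULT_NEQ_FACTORS[drug]
        inf_start = float(rng.uniform(0.0, 2.0))
        inf_end = inf_start + float(rng.uniform(2.0, 20.0))
        short_infusion = rng.random() < params.p_short_infusion

    missing = {
        name: bool(rng.random() < params.p_missing_lab)
        for name in ("lactate", "platelets", "bilirubin", "creatinine", "pf")
    }

    abx_day1 = rng.random() < params.p_antibiotic_day1
    # 1-second margins on the window edges keep second-resolution timestamp
    # flooring from flipping a window decision.
    t_abx = float(rng.uniform(0.01, 23.99)) if abx_day1 else float(rng.uniform(30.0, 48.0))
    cx_ok = rng.random() < params.p_culture_within_window
    if cx_ok:
        if rng.random() < 0.5:
            t_cx = t_abx + float(rng.uniform(0.0, 23.99))
        else:
            t_cx = t_abx - float(rng.uniform(0.0, 71.99))
    else:
        t_cx = t_abx + float(rng.uniform(25.0, 48.0))

    return {
        "i": i,
        "severity": sev,
        "death_prob": death_prob,
        "died": died,
        "age": age,
        "stay_sequence": 2 if second else 1,
        "sex": sex,
        "icu_type": icu_type,
        "map_series": map_series,
        "lactate": lactate,
        "platelets": platelets,
        "bilirubin": bilirubin,
        "creatinine": creatinine,
        "pf": pf,
        "gcs": gcs,
        "ventilated": ventilated,
        "rrt": rrt,
        "drug": drug,
        "rate": rate,
        "inf_start": inf_start,
        "inf_end": inf_end,
        "short_infusion": short_infusion,
        "missing": missing,
        "t_abx": t_abx,
        "t_cx": t_cx,
        "included_expected": bool(
            not underage and not second and abx_day1 and cx_ok
        ),
    }


def _summary_exposure(d: dict) -> NeqExposure:
    if d["drug"] is None:
        return NeqExposure()
    drug, rate = d["drug"], d["rate"]
    units = "units_per_min" if drug == "vasopressin" else "ug_per_kg_min"
    if drug == "dobutamine":
        return NeqExposure(0.0, False, {drug: rate})
    return NeqExposure(neq_rate(drug, rate, units), True, {drug: rate})


def _summary_panel(d: dict, config: ScoreConfig) -> ScorePanel:
    m = d["missing"]
    return panel_from_summaries(
        stay_id=f"s{d['i']:07d}",
        map_min=float(d["map_series"].min()),
        lactate_max=None if m["lactate"] else float(d["lactate"].max()),
        neq=_summary_exposure(d),
        pf_ratio=None if m["pf"] else d["pf"],
        platelets=None if m["platelets"] else float(d["platelets"].min()),
        bilirubin=None if m["bilirubin"] else float(d["bilirubin"].max()),
        gcs=float(d["gcs"]),
        creatinine=None if m["creatinine"] else float(d["creatinine"].max()),
        ventilated=d["ventilated"],
        config=config,
    )


def simulate_panels(
    params: SimParams,
    config: ScoreConfig = ScoreConfig(),
    stream: int = 0,
) -> pd.DataFrame:
    """Per-patient score panels computed directly from the generating
    summaries (no event tables). Distributionally identical to running the
    full read -> score pipeline on :func:`simulate_bundle` output — panel
    equality between the two paths is enforced by tests."""
    rows = []
    for i in range(params.n_patients):
        d = _draw_patient(i, params, stream)
        row = _summary_panel(d, config).as_dict()
        row["hospital_death"] = d["died"]
        row["included"] = d["included_expected"]
        row["severity"] = d["severity"]
        row["death_prob"] = d["death_prob"]
        rows.append(row)
    return pd.DataFrame(rows)


def _hours(h: float) -> pd.Timedelta:
    return pd.Timedelta(seconds=math.floor(h * 3600.0))


def simulate_bundle(params: SimParams) -> tuple[EhrBundle, pd.DataFrame]:
    """Generate an event-table bundle plus the generating truth table."""
    stays, obs, infs, orders, supports, truth = [], [], [], [], [], []
    for i in range(params.n_patients):
        d = _draw_patient(i, params, stream=0)
        sid = f"s{i:07d}"
        subj = f"p{i:07d}"
        intime = (_BASE_TIME + pd.Timedelta(hours=3 * i)).floor("s")
        outtime = intime + pd.Timedelta(days=5)
        stays.append(
            {
                "stay_id": sid,
                "subject_id": subj,
                "intime": intime,
                "outtime": outtime,
                "age_years": round(d["age"], 2),
                "sex": d["sex"],
                "icu_type": d["icu_type"],
                "hospital_death": d["died"],
                "stay_sequence": d["stay_sequence"],
            }
        )

        def ob(t_h: float, variable: str, value: float) -> None:
            obs.append(
                {
                    "stay_id": sid,
                    "time": intime + _hours(t_h),
                    "variable": variable,
                    "value": float(value),
                    "units": None,
                }
            )

        for j, v in enumerate(d["map_series"]):
            ob(0.25 + 0.5 * j, "MAP", v)
        ob(1.0, "GCS_total", d["gcs"])
        m = d["missing"]
        lab_times = (-2.0, 6.0)
        if not m["lactate"]:
            for t, v in zip(lab_times, d["lactate"]):
                ob(t, "lactate", v)
        if not m["platelets"]:
            for t, v in zip(lab_times, d["platelets"]):
                ob(t, "platelets", v)
        if not m["bilirubin"]:
            for t, v in zip(lab_times, d["bilirubin"]):
                ob(t, "bilirubin", v)
        if not m["creatinine"]:
            for t, v in zip(lab_times, d["creatinine"]):
                ob(t, "creatinine", v)
        if not m["pf"]:
            ob(3.5, "fio2", 0.5)
            ob(4.0, "pao2", d["pf"] * 0.5)

        if d["drug"] is not None:
            units = "units_per_min" if d["drug"] == "vasopressin" else "ug_per_kg_min"
            infs.append(
                {
                    "stay_id": sid,
                    "drug": d["drug"],
                    "start": intime + _hours(d["inf_start"]),
                    "end": intime + _hours(d["inf_end"]),
                    "rate": d["rate"],
                    "rate_units": units,
                }
            )
            if d["short_infusion"]:
                # sub-1h burst of the same agent at a lower rate: exercises
                # the minimum-duration filter without moving the sustained max
                infs.append(
                    {
                        "stay_id": sid,
                        "drug": d["drug"],
                        "start": intime + _hours(d["inf_start"] + 1.0),
                        "end": intime + _hours(d["inf_start"] + 1.5),
                        "rate": d["rate"] * 0.5,
                        "rate_units": units,
                    }
                )

        orders.append(
            {
                "subject_id": subj,
                "kind": "antibiotic",
                "time": intime + _hours(d["t_abx"]),
                "detail": "broad-spectrum",
            }
        )
        orders.append(
            {
                "subject_id": subj,
                "kind": "culture",
                "time": intime + _hours(d["t_cx"]),
                "detail": "blood",
            }
        )
        supports.append(
            {
                "stay_id": sid,
                "kind": "mechanical_ventilation",
                "active_day1": d["ventilated"],
            }
        )
        supports.append(
            {"stay_id": sid, "kind": "renal_replacement", "active_day1": d["rrt"]}
        )
        truth.append(
            {
                "stay_id": sid,
                "subject_id": subj,
                "severity": d["severity"],
                "death_prob": d["death_prob"],
                "died": d["died"],
                "included_expected": d["included_expected"],
                "drug": d["drug"] or "",
                "rate": d["rate"],
                "map_min": float(d["map_series"].min()),
                "lactate_max": float(d["lactate"].max()),
            }
        )

    from .ehr import CANONICAL_UNITS

    obs_df = pd.DataFrame(obs)
    if len(obs_df):
        obs_df["units"] = obs_df["variable"].map(CANONICAL_UNITS)
    bundle = EhrBundle(
        stays=pd.DataFrame(stays),
        observations=obs_df,
        infusions=pd.DataFrame(
            infs,
            columns=["stay_id", "drug", "start", "end", "rate", "rate_units"],
        ),
        orders=pd.DataFrame(orders),
        supports=pd.DataFrame(supports),
    )
    if len(bundle.infusions):
        bundle.infusions["start"] = bundle.infusions["start"].astype("datetime64[s]")
        bundle.infusions["end"] = bundle.infusions["end"].astype("datetime64[s]")
    return bundle, pd.DataFrame(truth)


def true_auroc(
    params: SimParams,
    score: str = "total_m3",
    n_oracle: int = 200_000,
    config: ScoreConfig = ScoreConfig(),
) -> float:
    """Monte-Carlo estimate of the generator-implied AUROC of ``score``
    against in-hospital death among included patients (fresh draws from
    oracle stream 1, never overlapping cohort draws)."""
    from .stats import auroc_point

    panels = simulate_panels(replace(params, n_patients=n_oracle), config, stream=1)
    panels = panels[panels["included"]]
    return auroc_point(
        panels[score].to_numpy(dtype=float),
        panels["hospital_death"].to_numpy(dtype=int),
    )


def make_toy_fixture() -> EhrBundle:
    """Deterministic hand-written 6-patient bundle covering the inclusion
    and scoring edge cases used across the test suite.

    Stays: (1) under-18, (2) second ICU stay, (3) antibiotics too late,
    (4) the worked scoring stay (MAP 60, norepinephrine 0.3 for 6 h,
    lactate 3.0, platelets 90), (5) included stay with no event data,
    (6) combination-vasopressor stay qualifying via culture-before-
    antibiotic pairing.
    """
    t0 = pd.Timestamp("2020-03-01 08:00:00")

    def stay(n, age, seq, died=False, icu="MICU"):
        return {
            "stay_id": f"stay{n}",
            "subject_id": f"subj{n}",
            "intime": t0,
            "outtime": t0 + pd.Timedelta(days=4),
            "age_years": age,
            "sex": "female" if n % 2 else "male",
            "icu_type": icu,
            "hospital_death": died,
            "stay_sequence": seq,
        }

    stays = pd.DataFrame(
        [
            stay(1, 16.0, 1),
            stay(2, 50.0, 2),
            stay(3, 60.0, 1),
            stay(4, 70.0, 1, died=True, icu="SICU/CV-ICU"),
            stay(5, 45.0, 1),
            stay(6, 80.0, 1, died=True, icu="CCU"),
        ]
    )
    for col in ("intime", "outtime"):
        stays[col] = stays[col].astype("datetime64[s]")

    def ob(n, t_h, variable, value):
        return {
            "stay_id": f"stay{n}",
            "time": t0 + pd.Timedelta(hours=t_h),
            "variable": variable,
            "value": value,
            "units": None,
        }

    observations = pd.DataFrame(
        [
            # worked stay 4: MAP 60, lactate 3.0, platelets 90, rest normal
            ob(4, 2.0, "MAP", 60.0),
            ob(4, 10.0, "MAP", 75.0),
            ob(4, 2.0, "lactate", 3.0),
            ob(4, -2.0, "platelets", 90.0),
            ob(4, 1.0, "GCS_total", 15.0),
            ob(4, 3.0, "bilirubin", 0.8),
            ob(4, 3.0, "creatinine", 0.9),
            # stay 6: MAP 65, lactate 2.0
            ob(6, 1.0, "MAP", 65.0),
            ob(6, 4.0, "lactate", 2.0),
            ob(6, 1.0, "GCS_total", 14.0),
            # stay 3 has observations but fails inclusion
            ob(3, 5.0, "MAP", 80.0),
        ]
    )
    observations["time"] = observations["time"].astype("datetime64[s]")
    from .ehr import CANONICAL_UNITS

    observations["units"] = observations["variable"].map(CANONICAL_UNITS)

    def infusion(n, drug, start_h, end_h, rate, units="ug_per_kg_min"):
        return {
            "stay_id": f"stay{n}",
            "drug": drug,
            "start": t0 + pd.Timedelta(hours=start_h),
            "end": t0 + pd.Timedelta(hours=end_h),
            "rate": rate,
            "rate_units": units,
        }

    infusions = pd.DataFrame(
        [
            infusion(4, "norepinephrine", 0.0, 6.0, 0.3),
            infusion(6, "norepinephrine", 0.0, 3.0, 0.2),
            infusion(6, "vasopressin", 1.0, 2.0, 0.04, "units_per_min"),
        ]
    )
    for col in ("start", "end"):
        infusions[col] = infusions[col].astype("datetime64[s]")

    def order(n, kind, t_h, detail):
        return {
            "subject_id": f"subj{n}",
            "kind": kind,
            "time": t0 + pd.Timedelta(hours=t_h),
            "detail": detail,
        }

    orders = pd.DataFrame(
        [
            # stays 1 and 2 would qualify on orders but fail earlier criteria
            order(1, "antibiotic", 2.0, "cefepime"),
            order(1, "culture", 3.0, "blood"),
            order(2, "antibiotic", 1.0, "vancomycin"),
            order(2, "culture", 2.0, "urine"),
            # stay 3: antibiotic after day 1 and culture outside both windows
            order(3, "antibiotic", 30.0, "ceftriaxone"),
            order(3, "culture", 58.0, "blood"),
            # stay 4: antibiotic day 1, culture 18 h later
            order(4, "antibiotic", 2.0, "piperacillin-tazobactam"),
            order(4, "culture", 20.0, "blood"),
            # stay 5: minimal included stay
            order(5, "antibiotic", 6.0, "meropenem"),
            order(5, "culture", 7.0, "sputum"),
            # stay 6: culture 50 h before the day-1 antibiotic (72 h rule)
            order(6, "culture", -50.0, "blood"),
            order(6, "antibiotic", 1.0, "cefazolin"),
        ]
    )
    orders["time"] = orders["time"].astype("datetime64[s]")

    supports = pd.DataFrame(
        [
            {
                "stay_id": f"stay{n}",
                "kind": "mechanical_ventilation",
                "active_day1": False,
            }
            for n in range(1, 7)
        ]
    )
    return EhrBundle(
        stays=stays,
        observations=observations,
        infusions=infusions,
        orders=orders,
        supports=supports,
    )
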