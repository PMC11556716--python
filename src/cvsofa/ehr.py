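"""Domain model and CSV I/O for day-1 ICU event data.

The bundle mirrors the relational shape of an ICU EHR export: one table of
ICU stays plus event tables (charted observations, vasoactive infusions,
antibiotic/culture orders, organ-support flags) keyed on the stay or
subject. Files carry absolute ISO-8601 timestamps; all scoring logic works
in real-valued hours relative to ICU admission (intime = 0.0), so the
score code never touches wall-clock time.

Canonical units are fixed per variable (see :data:`CANONICAL_UNITS`); a
small dialect table converts common synonyms at read time and conversion
is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EhrBundle",
    "BundleError",
    "VARIABLES",
    "DRUGS",
    "CANONICAL_UNITS",
    "canonicalize_units",
    "read_bundle",
    "write_bundle",
    "validate_bundle",
    "observation_hours",
    "infusion_hours",
]


class BundleError(ValueError):
    """Raised for schema, vocabulary, unit or referential-integrity faults."""


#: Controlled observation vocabulary and the canonical unit of each variable.
CANONICAL_UNITS: dict[str, str] = {
    "MAP": "mmHg",
    "GCS_total": "points",
    "lactate": "mmol/L",
    "platelets": "10^9/L",
    "bilirubin": "mg/dL",
    "creatinine": "mg/dL",
    "pao2": "mmHg",
    "fio2": "fraction",
    "urine_output_24h": "mL",
    "heart_rate": "bpm",
    "resp_rate": "breaths/min",
    "temperature": "C",
    "wbc": "10^9/L",
    "hemoglobin": "g/dL",
}

VARIABLES = frozenset(CANONICAL_UNITS)

DRUGS = frozenset(
    {
        "norepinephrine",
        "epinephrine",
        "dopamine",
        "dobutamine",
        "vasopressin",
        "phenylephrine",
    }
)

SEXES = frozenset({"male", "female"})
ICU_TYPES = frozenset({"MICU", "MICU/SICU", "CCU", "SICU/CV-ICU", "NeuroICU"})
ORDER_KINDS = frozenset({"antibiotic", "culture"})
SUPPORT_KINDS = frozenset({"mechanical_ventilation", "renal_replacement"})
RATE_UNITS = frozenset({"ug_per_kg_min", "units_per_min"})

# Multiplicative conversion factors into the canonical unit, keyed on
# (variable, source unit). Canonical units map to 1.0 so canonicalization
# is idempotent. Lactate: molar mass 90.08 g/mol -> mg/dL / 9.008 = mmol/L.
# Bilirubin: umol/L / 17.104 = mg/dL. Creatinine: umol/L / 88.42 = mg/dL.
_UNIT_FACTORS: dict[tuple[str, str], float] = {
    ("lactate", "mg/dL"): 1.0 / 9.008,
    ("platelets", "K/uL"): 1.0,
    ("platelets", "x10^3/uL"): 1.0,
    ("bilirubin", "umol/L"): 1.0 / 17.104,
    ("creatinine", "umol/L"): 1.0 / 88.42,
    ("fio2", "percent"): 1.0 / 100.0,
    ("wbc", "K/uL"): 1.0,
    ("hemoglobin", "g/L"): 0.1,
}
for _var, _unit in CANONICAL_UNITS.items():
    _UNIT_FACTORS[(_var, _unit)] = 1.0


def canonicalize_units(variable: str, value: float, source_units: str) -> float:
    """Convert ``value`` of ``variable`` from ``source_units`` to the
    canonical unit. Unknown variable or unit strings are fatal."""
    if variable not in VARIABLES:
        raise BundleError(f"unknown variable {variable!r}")
    try:
        factor = _UNIT_FACTORS[(variable, source_units)]
    except KeyError:
        raise BundleError(
            f"unknown unit {source_units!r} for variable {variable!r}"
        ) from None
    return value * factor


STAY_COLUMNS = [
    "stay_id",
    "subject_id",
    "intime",
    "outtime",
    "age_years",
    "sex",
    "icu_type",
    "hospital_death",
    "stay_sequence",
]
OBS_COLUMNS = ["stay_id", "time", "variable", "value", "units"]
INFUSION_COLUMNS = ["stay_id", "drug", "start", "end", "rate", "rate_units"]
ORDER_COLUMNS = ["subject_id", "kind", "time", "detail"]
SUPPORT_COLUMNS = ["stay_id", "kind", "active_day1"]

_FILES = {
    "stays": ("stays.csv", STAY_COLUMNS),
    "observations": ("observations.csv", OBS_COLUMNS),
    "infusions": ("infusions.csv", INFUSION_COLUMNS),
    "orders": ("orders.csv", ORDER_COLUMNS),
    "supports": ("supports.csv", SUPPORT_COLUMNS),
}

_TIME_COLS = {
    "stays": ["intime", "outtime"],
    "observations": ["time"],
    "infusions": ["start", "end"],
    "orders": ["time"],
    "supports": [],
}


@dataclass
class EhrBundle:
    """All event tables for one dataset, as pandas DataFrames with the
    documented column layout (see ``docs/schema.md``)."""

    stays: pd.DataFrame
    observations: pd.DataFrame = field(default_factory=lambda: _empty("observations"))
    infusions: pd.DataFrame = field(default_factory=lambda: _empty("infusions"))
    orders: pd.DataFrame = field(default_factory=lambda: _empty("orders"))
    supports: pd.DataFrame = field(default_factory=lambda: _empty("supports"))

    @property
    def n_stays(self) -> int:
        return len(self.stays)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "stays": self.stays,
            "observations": self.observations,
            "infusions": self.infusions,
            "orders": self.orders,
            "supports": self.supports,
        }


def _empty(name: str) -> pd.DataFrame:
    _, cols = _FILES[name]
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    for c in _TIME_COLS[name]:
        df[c] = pd.Series(dtype="datetime64[s]")
    return df


def validate_bundle(bundle: EhrBundle) -> None:
    """Enforce vocabulary, invariants and referential integrity.

    A dangling stay_id (or order subject_id) is rejected, never repaired.
    """
    stays = bundle.stays
    for name, (fname, cols) in _FILES.items():
        df = bundle.tables()[name]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise BundleError(f"{fname}: missing columns {missing}")

    if len(stays):
        if stays["stay_id"].duplicated().any():
            raise BundleError("stays.csv: duplicated stay_id")
        bad = stays[~(stays["outtime"] > stays["intime"])]
        if len(bad):
            raise BundleError(
                f"stays.csv: outtime <= intime for stay_id {bad['stay_id'].tolist()}"
            )
        if (stays["age_years"].astype(float) < 0).any():
            raise BundleError("stays.csv: negative age_years")
        if (stays["stay_sequence"].astype(int) < 1).any():
            raise BundleError("stays.csv: stay_sequence < 1")
        _check_vocab(stays["sex"], SEXES, "stays.csv", "sex")
        _check_vocab(stays["icu_type"], ICU_TYPES, "stays.csv", "icu_type")

    obs = bundle.observations
    if len(obs):
        _check_vocab(obs["variable"], VARIABLES, "observations.csv", "variable")
        if not np.isfinite(obs["value"].astype(float)).all():
            raise BundleError("observations.csv: non-finite value")

    inf = bundle.infusions
    if len(inf):
        _check_vocab(inf["drug"], DRUGS, "infusions.csv", "drug")
        _check_vocab(inf["rate_units"], RATE_UNITS, "infusions.csv", "rate_units")
        if not (inf["end"] > inf["start"]).all():
            raise BundleError("infusions.csv: end <= start")
        if (inf["rate"].astype(float) < 0).any():
            raise BundleError("infusions.csv: negative rate")
        vp = inf["drug"] == "vasopressin"
        if (inf.loc[vp, "rate_units"] != "units_per_min").any():
            raise BundleError("infusions.csv: vasopressin must use units_per_min")
        if (inf.loc[~vp, "rate_units"] != "ug_per_kg_min").any():
            raise BundleError(
                "infusions.csv: non-vasopressin drugs must use ug_per_kg_min"
            )

    if len(bundle.orders):
        _check_vocab(bundle.orders["kind"], ORDER_KINDS, "orders.csv", "kind")
    if len(bundle.supports):
        _check_vocab(bundle.supports["kind"], SUPPORT_KINDS, "supports.csv", "kind")

    stay_ids = set(stays["stay_id"])
    subject_ids = set(stays["subject_id"])
    for name in ("observations", "infusions", "supports"):
        df = bundle.tables()[name]
        if len(df):
            dangling = set(df["stay_id"]) - stay_ids
            if dangling:
                raise BundleError(
                    f"{name}.csv: stay_id not in stays.csv: {sorted(dangling)}"
                )
    if len(bundle.orders):
        dangling = set(bundle.orders["subject_id"]) - subject_ids
        if dangling:
            raise BundleError(
                f"orders.csv: subject_id not in stays.csv: {sorted(dangling)}"
            )


def _check_vocab(series: pd.Series, vocab: frozenset, fname: str, col: str) -> None:
    bad = ~series.isin(vocab)
    if bad.any():
        rows = series.index[bad].tolist()[:10]
        vals = sorted(set(series[bad]))
        raise BundleError(f"{fname}: unknown {col} {vals} at rows {rows}")


def _parse_times(df: pd.DataFrame, cols: list[str], fname: str) -> pd.DataFrame:
    for col in cols:
        raw = df[col]
        parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
        bad = parsed.isna() & raw.notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise BundleError(
                f"{fname}: unparseable timestamp {raw.iloc[idx]!r} at row {idx}"
            )
        df[col] = parsed.astype("datetime64[s]")
    return df


def read_bundle(directory: str | Path) -> EhrBundle:
    """Read and validate the five schema CSV files from ``directory``.

    Observation values are converted to canonical units using the ``units``
    column; timestamps are parsed to second precision.
    """
    directory = Path(directory)
    frames: dict[str, pd.DataFrame] = {}
    for name, (fname, cols) in _FILES.items():
        path = directory / fname
        if not path.exists():
            raise BundleError(f"missing file: {fname}")
        df = pd.read_csv(
            path,
            float_precision="round_trip",
            dtype={
                c: str
                for c in cols
                if c
                in (
                    "stay_id",
                    "subject_id",
                    "variable",
                    "drug",
                    "kind",
                    "detail",
                    "sex",
                    "icu_type",
                    "rate_units",
                    "units",
                )
            },
        )
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise BundleError(f"{fname}: missing columns {missing}")
        df = _parse_times(df[cols].copy(), _TIME_COLS[name], fname)
        frames[name] = df

    obs = frames["observations"]
    if len(obs):
        obs["value"] = obs["value"].astype(float)
        bad_var = ~obs["variable"].isin(VARIABLES)
        if bad_var.any():
            _check_vocab(obs["variable"], VARIABLES, "observations.csv", "variable")
        obs["units"] = obs["units"].fillna(obs["variable"].map(CANONICAL_UNITS))
        obs["value"] = [
            canonicalize_units(v, x, u)
            for v, x, u in zip(obs["variable"], obs["value"], obs["units"])
        ]
        obs["units"] = obs["variable"].map(CANONICAL_UNITS)
    inf = frames["infusions"]
    if len(inf):
        inf["rate"] = inf["rate"].astype(float)
    stays = frames["stays"]
    if len(stays):
        stays["age_years"] = stays["age_years"].astype(float)
        stays["stay_sequence"] = stays["stay_sequence"].astype(int)
        stays["hospital_death"] = stays["hospital_death"].astype(bool)
    sup = frames["supports"]
    if len(sup):
        sup["active_day1"] = sup["active_day1"].astype(bool)

    bundle = EhrBundle(**frames)
    validate_bundle(bundle)
    return bundle


def write_bundle(bundle: EhrBundle, directory: str | Path) -> None:
    """Write the bundle as the five schema CSVs (round-trip exact: ISO-8601
    timestamps to the second, numerics at full repr precision)."""
    validate_bundle(bundle)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, (fname, cols) in _FILES.items():
        df = bundle.tables()[name].copy()
        for col in _TIME_COLS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        df[cols].to_csv(directory / fname, index=False)


def observation_hours(bundle: EhrBundle) -> pd.DataFrame:
    """Observations with a ``t_hours`` column: hours since the stay's intime."""
    obs = bundle.observations
    if not len(obs):
        out = obs.copy()
        out["t_hours"] = pd.Series(dtype=float)
        return out
    intime = bundle.stays.set_index("stay_id")["intime"]
    out = obs.copy()
    out["t_hours"] = (
        out["time"] - out["stay_id"].map(intime)
    ).dt.total_seconds() / 3600.0
    return out


def infusion_hours(bundle: EhrBundle) -> pd.DataFrame:
    """Infusions with ``start_h``/``end_h`` columns relative to intime."""
    inf = bundle.infusions
    if not len(inf):
        out = inf.copy()
        out["start_h"] = pd.Series(dtype=float)
        out["end_h"] = pd.Series(dtype=float)
        return out
    intime = bundle.stays.set_index("stay_id")["intime"]
    out = inf.copy()
    base = out["stay_id"].map(intime)
    out["start_h"] = (out["start"] - base).dt.total_seconds() / 3600.0
    out["end_h"] = (out["end"] - base).dt.total_seconds() / 3600.0
    return out
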