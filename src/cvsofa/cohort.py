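"""Study-cohort construction: adult, first ICU stay, suspected infection.

Suspected infection follows the Sepsis-3 operational definition pairing
antibiotic administration with body-fluid culture sampling: a culture
within 24 h after an antibiotic, or an antibiotic within 72 h after a
culture — plus the requirement that at least one antibiotic order falls on
ICU day 1 ([intime, intime + 24 h)).

The two pairing clauses are combined as an OR by default (``pairing="or"``,
the classic Sepsis-3 reading); ``pairing="and"`` applies both window checks
to the same pair literally.
"""

from __future__ import annotations

import logging

import pandas as pd

from .ehr import EhrBundle

__all__ = ["first_adult_stays", "suspected_infection", "build_cohort"]

log = logging.getLogger(__name__)

ADULT_AGE = 18.0
DAY1_HOURS = 24.0
CULTURE_AFTER_ABX_HOURS = 24.0
ABX_AFTER_CULTURE_HOURS = 72.0

COHORT_COLUMNS = [
    "stay_id",
    "included",
    "exclusion_reason",
    "antibiotic_day1_time",
    "qualifying_culture_time",
]


def first_adult_stays(bundle: EhrBundle) -> pd.DataFrame:
    """Stays with age >= 18 years and stay_sequence == 1, input order kept."""
    stays = bundle.stays
    if not len(stays):
        return stays.copy()
    keep = (stays["age_years"] >= ADULT_AGE) & (stays["stay_sequence"] == 1)
    return stays[keep].copy()


def suspected_infection(
    orders: pd.DataFrame,
    intime: pd.Timestamp,
    pairing: str = "or",
) -> tuple[bool, pd.Timestamp | None, pd.Timestamp | None]:
    """Evaluate the suspected-infection rule for one stay.

    ``orders`` must already be restricted to the stay's subject. Returns
    ``(qualifies, antibiotic_time, culture_time)`` for the earliest
    qualifying antibiotic–culture pair (ties broken by earliest antibiotic,
    then earliest culture); times are ``None`` when the rule fails.
    """
    if pairing not in ("or", "and"):
        raise ValueError(f"pairing must be 'or' or 'and', got {pairing!r}")
    if not len(orders):
        return False, None, None
    abx_times = sorted(orders.loc[orders["kind"] == "antibiotic", "time"])
    cx_times = sorted(orders.loc[orders["kind"] == "culture", "time"])
    if not abx_times or not cx_times:
        return False, None, None

    day1_lo, day1_hi = intime, intime + pd.Timedelta(hours=DAY1_HOURS)
    if not any(day1_lo <= a < day1_hi for a in abx_times):
        return False, None, None

    best: tuple[pd.Timestamp, pd.Timestamp] | None = None
    for a in abx_times:
        for c in cx_times:
            cx_after = a <= c <= a + pd.Timedelta(hours=CULTURE_AFTER_ABX_HOURS)
            abx_after = c <= a <= c + pd.Timedelta(hours=ABX_AFTER_CULTURE_HOURS)
            ok = (cx_after and abx_after) if pairing == "and" else (cx_after or abx_after)
            if ok and (best is None or (a, c) < best):
                best = (a, c)
    if best is None:
        return False, None, None
    return True, best[0], best[1]


def build_cohort(bundle: EhrBundle, pairing: str = "or") -> pd.DataFrame:
    """One row per stay with inclusion flag and first failing criterion.

    Exclusion reasons are assigned in fixed order: age -> first-stay ->
    suspected-infection; the result is independent of input row order.
    """
    stays = bundle.stays
    orders_by_subject = (
        {k: g for k, g in bundle.orders.groupby("subject_id")}
        if len(bundle.orders)
        else {}
    )
    rows = []
    for stay in stays.itertuples(index=False):
        reason = "none"
        t_abx = t_cx = None
        if stay.age_years < ADULT_AGE:
            reason = "age_lt_18"
        elif stay.stay_sequence != 1:
            reason = "not_first_stay"
        else:
            sub_orders = orders_by_subject.get(
                stay.subject_id, bundle.orders.iloc[0:0]
            )
            ok, t_abx, t_cx = suspected_infection(sub_orders, stay.intime, pairing)
            if not ok:
                reason = "no_suspected_infection"
        rows.append(
            {
                "stay_id": stay.stay_id,
                "included": reason == "none",
                "exclusion_reason": reason,
                "antibiotic_day1_time": t_abx,
                "qualifying_culture_time": t_cx,
            }
        )
    cohort = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    if len(cohort):
        counts = cohort["exclusion_reason"].value_counts().to_dict()
        log.info(
            "cohort: %d/%d included; exclusions: %s",
            int(cohort["included"].sum()),
            len(cohort),
            {k: v for k, v in sorted(counts.items()) if k != "none"},
        )
    return cohort


def write_cohort(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    for col in ("antibiotic_day1_time", "qualifying_culture_time"):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
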