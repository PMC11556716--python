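import pandas as pd
import pytest

from cvsofa.simulate import SimParams, make_toy_fixture, simulate_bundle


@pytest.fixture(scope="session")
def toy_bundle():
    return make_toy_fixture()


@pytest.fixture(scope="session")
def small_bundle():
    """Seeded 300-stay synthetic bundle shared across tests."""
    bundle, truth = simulate_bundle(SimParams(n_patients=300, seed=42))
    return bundle, truth


def make_infusions(rows):
    """Build an infusion frame in relative hours for neq_exposure tests.

    rows: (drug, start_h, end_h, rate[, rate_units])
    """
    recs = []
    for row in rows:
        drug, s, e, r = row[:4]
        units = row[4] if len(row) > 4 else (
            "units_per_min" if drug == "vasopressin" else "ug_per_kg_min"
        )
        recs.append(
            {"drug": drug, "start_h": s, "end_h": e, "rate": r, "rate_units": units}
        )
    return pd.DataFrame(
        recs, columns=["drug", "start_h", "end_h", "rate", "rate_units"]
    )


def make_observations(rows):
    """Observation frame in relative hours: rows of (variable, t_hours, value)."""
    return pd.DataFrame(
        [{"variable": v, "t_hours": t, "value": x} for v, t, x in rows],
        columns=["variable", "t_hours", "value"],
    )
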