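"""Shared fixtures: a small synthetic registry run once per session, plus a
micro-bundle builder for hand-constructed edge cases."""

from __future__ import annotations

import pandas as pd
import pytest

from lexirate.cohort import CohortBuilder, relative_prescriptions
from lexirate.exposure import ExposureExpander
from lexirate.registry import RegistryBundle
from lexirate.simulate import null_scenario, generate_bundle, scaled


def make_bundle(persons=None, prescriptions=None, events=None) -> RegistryBundle:
    """Build a validated micro-bundle from row dicts (DK defaults)."""
    p_defaults = {
        "sex": "male",
        "birth_date": "1950-01-01",
        "country": "DK",
        "data_start": "1996-01-01",
        "data_end": "2010-12-31",
    }
    rows = []
    for p in persons or []:
        rows.append({**p_defaults, **p})
    p_df = pd.DataFrame(rows)
    for col in ("birth_date", "data_start", "data_end"):
        p_df[col] = pd.to_datetime(p_df[col])
    rx_df = pd.DataFrame(
        prescriptions or [], columns=["person_id", "dispense_date", "atc_code", "ddd_amount"]
    )
    if len(rx_df):
        rx_df["dispense_date"] = pd.to_datetime(rx_df["dispense_date"])
        rx_df["ddd_amount"] = rx_df["ddd_amount"].astype(float)
    ev_df = pd.DataFrame(
        events or [], columns=["person_id", "event_date", "event_type", "diagnosis_code"]
    )
    if len(ev_df):
        ev_df["event_date"] = pd.to_datetime(ev_df["event_date"])
        ev_df["diagnosis_code"] = ev_df["diagnosis_code"].fillna("")
    return RegistryBundle(persons=p_df, prescriptions=rx_df, events=ev_df)


@pytest.fixture(scope="session")
def small_scenario():
    return scaled(null_scenario(), 1200)


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    bundle, truth = generate_bundle(small_scenario, seed=11)
    return bundle, truth


@pytest.fixture(scope="session")
def small_cohort(small_bundle):
    bundle, _ = small_bundle
    builder = CohortBuilder()
    cohort = builder.fit().transform(bundle)
    return cohort, builder.exclusions_, builder.n_insulin_users_


@pytest.fixture(scope="session")
def small_intervals(small_bundle, small_cohort):
    bundle, _ = small_bundle
    cohort, _, _ = small_cohort
    rx = relative_prescriptions(bundle, cohort)
    return ExposureExpander(scheme="broad").fit().transform(cohort, rx)
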