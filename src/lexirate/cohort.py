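"""New-user cohort assembly: eligibility, index date, censoring, covariates.

A person enters the cohort at the first-ever insulin dispensing (index date)
if that dispensing falls at least one year after the start of observable
registry time (the lead-in that defines a *new* user), the person is an adult
(≥18 years) at index, and there is no cancer history other than non-melanoma
skin cancer.  Follow-up runs from index to the earliest of first non-NMSC
cancer, death, emigration/transfer-out, end of the person's data or end of
the country's study period.  Records with zero-length follow-up are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exposure import DAYS_PER_YEAR
from .registry import RegistryBundle, classify_cancer_site, classify_insulin, day_number

__all__ = ["CohortBuilder", "assemble_cohort", "classify_diabetes", "endpoint_for_site"]

CENSOR_REASONS = ("cancer", "death", "emigration_or_transfer", "admin_end")

EXCLUSION_ORDER = (
    "insufficient_lead_in",
    "age_lt_18",
    "prior_cancer",
    "zero_follow_up",
)


def _classified_prescriptions(bundle: RegistryBundle) -> pd.DataFrame:
    rx = bundle.prescriptions.copy()
    codes = rx["atc_code"].unique()
    cmap = {c: classify_insulin(c, bundle.dictionary) for c in codes}
    rx["insulin_class"] = rx["atc_code"].map(cmap)
    rx["dispense_day"] = day_number(rx["dispense_date"])
    return rx


def _classified_events(bundle: RegistryBundle) -> pd.DataFrame:
    ev = bundle.events.copy()
    ev["event_day"] = day_number(ev["event_date"])
    cancers = ev["event_type"] == "cancer"
    sites = np.full(len(ev), "", dtype=object)
    uniq = ev.loc[cancers, "diagnosis_code"].unique()
    smap = {c: classify_cancer_site(c, bundle.dictionary) for c in uniq}
    sites[cancers.to_numpy()] = ev.loc[cancers, "diagnosis_code"].map(smap).to_numpy()
    ev["site"] = sites
    return ev


class CohortBuilder(BaseEstimator, TransformerMixin):
    """Assemble the new-insulin-user cohort from a registry bundle.

    Parameters
    ----------
    lead_in_days : int
        Prescription-free observable history required before index (365 by
        default, counted from max(data_start, study-period start)).
    min_age : float
        Minimum age at index in years.

    After ``transform`` the builder exposes ``exclusions_`` (counts per
    criterion) applied in the fixed order: insufficient lead-in, age,
    prior cancer, zero follow-up — each person is counted once, under the
    first criterion it fails.
    """

    def __init__(self, lead_in_days: int = 365, min_age: float = 18.0):
        self.lead_in_days = lead_in_days
        self.min_age = min_age

    def fit(self, X: RegistryBundle | None = None, y=None) -> "CohortBuilder":
        return self

    def transform(self, bundle: RegistryBundle) -> pd.DataFrame:
        rx = _classified_prescriptions(bundle)
        ev = _classified_events(bundle)
        persons = bundle.persons.copy()
        persons["birth_day"] = day_number(persons["birth_date"])
        persons["start_day"] = day_number(persons["data_start"])
        persons["end_day"] = day_number(persons["data_end"])
        study = {
            c: (day_number(a), day_number(b)) for c, (a, b) in bundle.study_periods.items()
        }
        persons["study_start"] = persons["country"].map({c: s for c, (s, _) in study.items()})
        persons["study_end"] = persons["country"].map({c: e for c, (_, e) in study.items()})

        insulin_rx = rx[rx["insulin_class"] != "non_insulin"]
        first_ins = insulin_rx.groupby("person_id")["dispense_day"].min().rename("index_day")
        df = persons.merge(first_ins, on="person_id", how="inner")
        n_users = len(df)

        df["obs_start"] = np.maximum(df["start_day"], df["study_start"])
        df["age_at_index"] = (df["index_day"] - df["birth_day"]) / DAYS_PER_YEAR

        # first cancer events relative to index
        cancer = ev[(ev["event_type"] == "cancer") & (ev["site"] != "nmsc")]
        cancer = cancer.merge(df[["person_id", "index_day"]], on="person_id", how="inner")
        prior = cancer[cancer["event_day"] < cancer["index_day"]]
        prior_ids = set(prior["person_id"])
        post = cancer[cancer["event_day"] >= cancer["index_day"]]
        first_cancer = post.groupby("person_id")["event_day"].min().rename("cancer_day")

        death = ev[ev["event_type"] == "death"].groupby("person_id")["event_day"].min()
        emig = ev[ev["event_type"] == "emigration"].groupby("person_id")["event_day"].min()
        df = (
            df.merge(first_cancer, on="person_id", how="left")
            .merge(death.rename("death_day"), on="person_id", how="left")
            .merge(emig.rename("emig_day"), on="person_id", how="left")
        )

        admin = np.minimum(df["end_day"], df["study_end"]).astype(float)
        cand = np.vstack(
            [
                df["cancer_day"].to_numpy(dtype=float),
                df["death_day"].to_numpy(dtype=float),
                df["emig_day"].to_numpy(dtype=float),
                admin.to_numpy(),
            ]
        )
        cand = np.where(np.isnan(cand), np.inf, cand)
        censor_day = cand.min(axis=0)
        # tie precedence: cancer > death > emigration > admin (outcome first)
        reason_idx = np.argmin(cand, axis=0)  # argmin takes the first minimum
        reasons = np.asarray(CENSOR_REASONS)[reason_idx]

        df["censor_day"] = censor_day
        df["censor_reason"] = reasons

        ok_lead = df["index_day"] >= df["obs_start"] + self.lead_in_days
        ok_age = df["age_at_index"] >= self.min_age
        ok_history = ~df["person_id"].isin(prior_ids)
        ok_fu = df["censor_day"] > df["index_day"]

        excl_reason = np.select(
            [~ok_lead, ~ok_age, ~ok_history, ~ok_fu],
            list(EXCLUSION_ORDER),
            default="",
        )
        self.exclusions_ = {
            crit: int((excl_reason == crit).sum()) for crit in EXCLUSION_ORDER
        }
        self.n_insulin_users_ = n_users

        keep = df[excl_reason == ""].copy()
        keep["censor_day"] = keep["censor_day"].astype(int)
        keep["follow_up_days"] = keep["censor_day"] - keep["index_day"]
        keep["follow_up_years"] = keep["follow_up_days"] / DAYS_PER_YEAR
        keep["index_year"] = (
            pd.to_datetime(keep["index_day"], unit="D", origin="unix").dt.year
        )

        # sites diagnosed on the censor date (same-day multiples all count)
        hit = cancer.merge(
            keep[["person_id", "censor_day", "censor_reason"]], on="person_id"
        )
        hit = hit[(hit["censor_reason"] == "cancer") & (hit["event_day"] == hit["censor_day"])]
        site_sets = (
            hit.groupby("person_id")["site"]
            .apply(lambda s: ";".join(sorted(set(s))))
            .rename("first_cancer_sites")
        )
        keep = keep.merge(site_sets, on="person_id", how="left")
        keep["first_cancer_sites"] = keep["first_cancer_sites"].fillna("")

        keep["diabetes_type"] = classify_diabetes(keep, rx)
        flags = _baseline_flags(keep, rx, bundle)
        for flag in ("niad", "statin", "nsaid", "hrt"):
            keep[flag] = flags[flag]
        keep.loc[keep["sex"] == "male", "hrt"] = False

        cols = [
            "person_id", "sex", "country", "birth_day", "index_day", "index_year",
            "censor_day", "censor_reason", "follow_up_days", "follow_up_years",
            "age_at_index", "diabetes_type", "niad", "statin", "nsaid", "hrt",
            "first_cancer_sites",
        ]
        return keep[cols].reset_index(drop=True)


def _comed_class(atc: pd.Series, comed_map: dict[str, str]) -> pd.Series:
    out = pd.Series(np.full(len(atc), "", dtype=object), index=atc.index)
    for prefix, group in sorted(comed_map.items(), key=lambda kv: -len(kv[0])):
        mask = (out == "") & atc.str.upper().str.startswith(prefix)
        out[mask] = group
    return out


def _baseline_flags(
    cohort: pd.DataFrame, rx: pd.DataFrame, bundle: RegistryBundle
) -> pd.DataFrame:
    """Baseline co-medication flags: ≥1 prescription with the group's ATC
    prefix within the year before index ([index − 365, index))."""
    comed = rx[["person_id", "atc_code", "dispense_day"]].copy()
    comed["group"] = _comed_class(comed["atc_code"], bundle.dictionary.comed_map)
    comed = comed[comed["group"] != ""]
    merged = comed.merge(cohort[["person_id", "index_day"]], on="person_id")
    in_window = merged[
        (merged["dispense_day"] >= merged["index_day"] - 365)
        & (merged["dispense_day"] < merged["index_day"])
    ]
    out = pd.DataFrame(index=cohort.index)
    for group in ("niad", "statin", "nsaid", "hrt"):
        flagged = set(in_window.loc[in_window["group"] == group, "person_id"])
        out[group] = cohort["person_id"].isin(flagged)
    return out


def classify_diabetes(cohort: pd.DataFrame, rx: pd.DataFrame) -> pd.Series:
    """Proxy diabetes type from age at index and NIAD history.

    Age ≤30 with no non-insulin glucose-lowering drug on or before index →
    type 1; age ≥40 (NIAD or not) → type 2; everyone else unspecified.
    """
    niad = rx[rx["atc_code"].str.upper().str.startswith("A10B")]
    merged = niad.merge(cohort[["person_id", "index_day"]], on="person_id")
    ever_niad_ids = set(
        merged.loc[merged["dispense_day"] <= merged["index_day"], "person_id"]
    )
    ever_niad = cohort["person_id"].isin(ever_niad_ids)
    age = cohort["age_at_index"]
    return pd.Series(
        np.select(
            [(age <= 30) & ~ever_niad, age >= 40],
            ["type1", "type2"],
            default="unspecified",
        ),
        index=cohort.index,
    )


def endpoint_for_site(record: pd.Series | dict, site: str) -> int:
    """1 iff the record's follow-up ended with a first cancer matching ``site``
    (``any_cancer`` matches every cancer censoring; same-day multiple primaries
    count for each of their site-specific endpoints)."""
    from .registry import CANCER_SITES

    if site != "any_cancer" and site not in CANCER_SITES:
        raise ValueError(f"unknown cancer site {site!r}")
    if record["censor_reason"] != "cancer":
        return 0
    if site == "any_cancer":
        return 1
    sites = str(record["first_cancer_sites"]).split(";")
    return int(site in sites)


def relative_prescriptions(bundle: RegistryBundle, cohort: pd.DataFrame) -> pd.DataFrame:
    """Insulin prescriptions of cohort members with ``day`` offsets from index.

    Input frame for :class:`lexirate.exposure.ExposureExpander`; non-insulin
    records are dropped here, pre-index insulin cannot occur by construction
    (index is the first-ever insulin dispensing).
    """
    rx = _classified_prescriptions(bundle)
    rx = rx[rx["insulin_class"] != "non_insulin"]
    merged = rx.merge(cohort[["person_id", "index_day"]], on="person_id", how="inner")
    merged["day"] = merged["dispense_day"] - merged["index_day"]
    return merged[["person_id", "insulin_class", "day", "ddd_amount"]]


def assemble_cohort(
    bundle: RegistryBundle, lead_in_days: int = 365, min_age: float = 18.0
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Functional wrapper: returns (cohort table, exclusion-count log)."""
    builder = CohortBuilder(lead_in_days=lead_in_days, min_age=min_age)
    cohort = builder.fit_transform(bundle)
    return cohort, builder.exclusions_
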