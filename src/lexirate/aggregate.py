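"""Semi-aggregate person-time tables, crude incidence rates and descriptives.

The semi-aggregate representation — events and person-years cross-classified
by every categorical model covariate — carries the complete sufficient
statistics of the Poisson likelihood, so multi-country data can be pooled and
modelled without sharing individual records and with coefficients identical
to an individual-level fit.

Crude rates come with exact (Garwood) Poisson confidence intervals and the
registries' small-cell confidentiality rule: cells with 1–5 events publish
the count but withhold the rate and interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .exposure import DAYS_PER_YEAR
from .registry import CANCER_SITES

__all__ = [
    "PersonTimeAggregator",
    "aggregate",
    "crude_rates",
    "poisson_exact_ci",
    "descriptives",
    "SEX_SPECIFIC_SITES",
    "COMED_ADJUSTMENT",
]

#: Endpoints restricted to one sex (the other sex contributes no person-time).
SEX_SPECIFIC_SITES = {"breast": "female", "endometrial": "female", "prostate": "male"}

#: Site-specific co-medication adjustment sets; every model additionally
#: adjusts for NIAD use.  Configurable at the aggregator/model level.
COMED_ADJUSTMENT: dict[str, tuple[str, ...]] = {
    "liver": ("statin", "nsaid"),
    "colorectal": ("statin", "nsaid"),
    "breast": ("statin", "nsaid", "hrt"),
    "endometrial": ("statin", "nsaid", "hrt"),
}

BASE_STRATA = ["country", "sex", "age_band", "calendar_band", "duration_band", "niad"]


def covariate_columns(
    endpoint: str,
    sex_stratum: str = "both",
    adjust_menopause: bool = False,
    comed_map: dict[str, tuple[str, ...]] | None = None,
) -> list[str]:
    """Stratification keys for an endpoint: base covariates, the relevant
    co-medication and — for sex strata — no sex column."""
    comed_map = COMED_ADJUSTMENT if comed_map is None else comed_map
    cols = list(BASE_STRATA)
    if sex_stratum != "both" or endpoint in SEX_SPECIFIC_SITES:
        cols.remove("sex")
    cols += list(comed_map.get(endpoint, ()))
    if adjust_menopause:
        cols.append("menopausal_status")
    return cols


def _event_column(intervals: pd.DataFrame, cohort: pd.DataFrame, endpoint: str) -> pd.Series:
    if endpoint == "any_cancer":
        return intervals["event_any"]
    if endpoint not in CANCER_SITES:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    sites = cohort.set_index("person_id")["first_cancer_sites"].astype(str)
    hit = sites.str.split(";").apply(lambda xs: endpoint in xs)
    return (
        intervals["event_any"].astype(bool)
        & intervals["person_id"].map(hit).fillna(False).astype(bool)
    ).astype(int)


class PersonTimeAggregator(BaseEstimator, TransformerMixin):
    """Collapse interval rows into an events/person-years table per endpoint.

    Parameters
    ----------
    endpoint : str
        Cancer site or ``any_cancer``.
    sex_stratum : {"both", "male", "female"}
        Restrict to one sex; sex-specific endpoints are restricted
        automatically and then carry no sex column.
    exposure_classes : tuple of str
        Insulin classes whose category columns become strata.
    adjust_menopause : bool
        Include time-dependent menopausal status (sensitivity analyses for
        breast/endometrial cancer).
    """

    def __init__(
        self,
        endpoint: str = "any_cancer",
        sex_stratum: str = "both",
        exposure_classes: tuple[str, ...] = ("human", "glargine", "detemir"),
        adjust_menopause: bool = False,
        comed_map: dict[str, tuple[str, ...]] | None = None,
    ):
        self.endpoint = endpoint
        self.sex_stratum = sex_stratum
        self.exposure_classes = exposure_classes
        self.adjust_menopause = adjust_menopause
        self.comed_map = comed_map

    def fit(self, X=None, y=None) -> "PersonTimeAggregator":
        self.strata_ = covariate_columns(
            self.endpoint, self.sex_stratum, self.adjust_menopause, self.comed_map
        ) + [f"cat_{c}" for c in self.exposure_classes]
        return self

    def transform(
        self, intervals: pd.DataFrame, cohort: pd.DataFrame | None = None
    ) -> pd.DataFrame:
        if cohort is None:
            raise ValueError("cohort frame is required")
        if not hasattr(self, "strata_"):
            self.fit()
        df = intervals
        restrict = SEX_SPECIFIC_SITES.get(self.endpoint, None)
        if self.sex_stratum != "both":
            if restrict is not None and restrict != self.sex_stratum:
                raise ValueError(
                    f"{self.endpoint} is restricted to {restrict}; "
                    f"cannot analyse stratum {self.sex_stratum!r}"
                )
            restrict = self.sex_stratum
        if restrict is not None:
            df = df[df["sex"] == restrict]
        df = df.copy()
        df["event"] = _event_column(df, cohort, self.endpoint)
        if (df.loc[df["event"] > 0, "person_days"] <= 0).any():
            raise ValueError("event attributed to an interval with zero person-time")
        out = (
            df.groupby(self.strata_, observed=True)
            .agg(events=("event", "sum"), person_days=("person_days", "sum"))
            .reset_index()
        )
        out["person_years"] = out.pop("person_days") / DAYS_PER_YEAR
        out = out[out["person_years"] > 0]
        return out.sort_values(self.strata_, kind="stable").reset_index(drop=True)


def aggregate(
    intervals: pd.DataFrame,
    cohort: pd.DataFrame,
    endpoint: str = "any_cancer",
    sex_stratum: str = "both",
    exposure_classes: tuple[str, ...] = ("human", "glargine", "detemir"),
    adjust_menopause: bool = False,
) -> pd.DataFrame:
    """Functional wrapper over :class:`PersonTimeAggregator`."""
    agg = PersonTimeAggregator(
        endpoint=endpoint,
        sex_stratum=sex_stratum,
        exposure_classes=exposure_classes,
        adjust_menopause=adjust_menopause,
    )
    return agg.fit().transform(intervals, cohort=cohort)


def poisson_exact_ci(events: int, person_years: float) -> tuple[float, float]:
    """Exact (Garwood) 95% CI for a Poisson rate, per unit person-time.

    lo = chi2(0.025, 2k) / (2T),  hi = chi2(0.975, 2(k+1)) / (2T); the lower
    bound is 0 when no events occurred.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    k = int(events)
    lo = 0.0 if k == 0 else stats.chi2.ppf(0.025, 2 * k) / (2 * person_years)
    hi = stats.chi2.ppf(0.975, 2 * (k + 1)) / (2 * person_years)
    return lo, hi


def crude_rates(
    cohort: pd.DataFrame,
    endpoint: str = "any_cancer",
    per: float = 1000.0,
    suppress_below: int = 6,
) -> pd.DataFrame:
    """Country × sex crude incidence rates for an endpoint, per 1000 PY.

    Rates and exact CIs are withheld (NaN, ``suppressed=True``) in cells with
    more than zero but fewer than ``suppress_below`` events, following
    registry confidentiality practice.  Sex-specific endpoints only emit the
    relevant sex.
    """
    df = cohort.copy()
    restrict = SEX_SPECIFIC_SITES.get(endpoint)
    if restrict is not None:
        df = df[df["sex"] == restrict]
    is_cancer = df["censor_reason"] == "cancer"
    if endpoint == "any_cancer":
        df["event"] = is_cancer.astype(int)
    else:
        if endpoint not in CANCER_SITES:
            raise ValueError(f"unknown cancer site {endpoint!r}")
        padded = ";" + df["first_cancer_sites"].fillna("").astype(str) + ";"
        df["event"] = (is_cancer & padded.str.contains(f";{endpoint};", regex=False)).astype(int)
    rows = []
    for (ctry, sex), grp in df.groupby(["country", "sex"], observed=True):
        events = int(grp["event"].sum())
        py = float(grp["follow_up_years"].sum())
        if py <= 0:
            raise ValueError(f"zero person-years in stratum {(ctry, sex)}")
        suppressed = 0 < events < suppress_below
        if suppressed:
            rate = lo = hi = np.nan
        else:
            rate = per * events / py
            lo, hi = poisson_exact_ci(events, py)
            lo, hi = per * lo, per * hi
        rows.append(
            {
                "endpoint": endpoint,
                "country": ctry,
                "sex": sex,
                "events": events,
                "person_years": py,
                "rate": rate,
                "ci_low": lo,
                "ci_high": hi,
                "suppressed": suppressed,
            }
        )
    return pd.DataFrame(rows).sort_values(["country", "sex"]).reset_index(drop=True)


def descriptives(
    cohort: pd.DataFrame, intervals: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-country baseline and follow-up summary (plus a pooled row).

    Mirrors the usual cohort baseline table: N, % male, mean (SD) age,
    age-band counts, follow-up mean / median / IQR, person-years (total and
    male) and baseline co-medication counts.  When interval rows are
    supplied, ever-use counts per insulin class (any exposed category during
    follow-up) are added.
    """
    from .exposure import AGE_BAND_EDGES, AGE_BAND_LABELS  # local: avoid cycle

    ever: pd.DataFrame | None = None
    if intervals is not None:
        cat_cols = [c for c in intervals.columns if c.startswith("cat_")]
        ever = intervals.groupby("person_id", observed=True)[cat_cols].agg(
            lambda s: (s != "non-exposed").any()
        )
        ever = cohort[["person_id", "country"]].join(ever, on="person_id")
    rows = []
    groups = list(cohort.groupby("country", observed=True)) + [("pooled", cohort)]
    for ctry, grp in groups:
        fu = grp["follow_up_years"]
        row = {
            "country": ctry,
            "n": len(grp),
            "pct_male": 100 * (grp["sex"] == "male").mean() if len(grp) else np.nan,
            "age_mean": grp["age_at_index"].mean(),
            "age_sd": grp["age_at_index"].std(),
            "fu_mean": fu.mean(),
            "fu_median": fu.median(),
            "fu_q1": fu.quantile(0.25),
            "fu_q3": fu.quantile(0.75),
            "person_years": fu.sum(),
            "person_years_male": grp.loc[grp["sex"] == "male", "follow_up_years"].sum(),
        }
        band_idx = np.searchsorted(
            np.asarray(AGE_BAND_EDGES, dtype=float),
            grp["age_at_index"].to_numpy(),
            side="right",
        )
        for i, lab in enumerate(AGE_BAND_LABELS):
            row[f"age_{lab}"] = int((band_idx == i).sum())
        for flag in ("niad", "statin", "nsaid", "hrt"):
            if flag in grp.columns:
                row[f"baseline_{flag}"] = int(grp[flag].sum())
        if ever is not None:
            sub = ever if ctry == "pooled" else ever[ever["country"] == ctry]
            for col in [c for c in sub.columns if c.startswith("cat_")]:
                row[f"ever_{col[4:]}"] = int(sub[col].fillna(False).sum())
        rows.append(row)
    return pd.DataFrame(rows)
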