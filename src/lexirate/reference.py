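"""Published descriptive marginals of the five-country new-insulin-user cohorts.

These are the printed per-country baseline/follow-up characteristics and
sex- and site-specific crude incidence summaries of the multi-country
registry study this pipeline re-implements.  They serve as *inputs* for
arithmetic cross-checks: pooled totals, weighted means and exact Poisson
rates recomputed from these marginals must reproduce the printed values.
No individual-level registry data are contained or derivable here.
"""

from __future__ import annotations

__all__ = [
    "COHORT_SIZES",
    "PERSON_YEARS_THOUSANDS",
    "MEAN_FOLLOW_UP_YEARS",
    "EVER_USE",
    "ANY_CANCER_EVENTS",
    "SELECTED_CRUDE_RATES",
    "pooled_size",
    "pooled_person_years",
    "weighted_mean_follow_up",
    "pooled_cancer_cases",
    "pooled_ever_use",
]

#: New insulin users per country cohort.
COHORT_SIZES = {"DK": 66_698, "FI": 105_945, "NO": 21_541, "SE": 85_319, "UK": 47_609}

#: Person-years accumulated, in thousands: (all, male).
PERSON_YEARS_THOUSANDS = {
    "DK": (331.2, 184.4),
    "FI": (589.1, 316.9),
    "NO": (57.8, 32.4),
    "SE": (226.6, 131.3),
    "UK": (265.3, 141.6),
}

#: Mean follow-up time (years) per country cohort.
MEAN_FOLLOW_UP_YEARS = {"DK": 5.3, "FI": 5.6, "NO": 2.7, "SE": 2.7, "UK": 5.7}

#: Ever-use of each insulin class during follow-up, per country.
EVER_USE = {
    "human": {"DK": 54_216, "FI": 68_894, "NO": 17_579, "SE": 48_976, "UK": 23_183},
    "glargine": {"DK": 7_151, "FI": 43_741, "NO": 1_447, "SE": 15_138, "UK": 15_374},
    "detemir": {"DK": 9_520, "FI": 24_593, "NO": 868, "SE": 4_367, "UK": 7_373},
}

#: Incident any-cancer cases by country and sex.
ANY_CANCER_EVENTS = {
    "DK": {"male": 2_733, "female": 1_950},
    "FI": {"male": 5_315, "female": 3_618},
    "NO": {"male": 542, "female": 333},
    "SE": {"male": 2_272, "female": 1_361},
    "UK": {"male": 1_918, "female": 1_348},
}

#: Selected printed site rows: (events, printed IR/1000 PY, CI low, CI high),
#: keyed by (site, country, sex).  Person-years follow from
#: PERSON_YEARS_THOUSANDS (female = all − male).
SELECTED_CRUDE_RATES = {
    ("liver", "DK", "male"): (144, 0.78, 0.66, 0.92),
    ("liver", "DK", "female"): (28, 0.19, 0.13, 0.28),
    ("pancreas", "NO", "male"): (76, 2.35, 1.85, 2.94),
    ("prostate", "FI", "male"): (1_339, 4.23, 4.00, 4.46),
    ("breast", "UK", "female"): (301, 2.43, 2.17, 2.72),
    ("any_cancer", "DK", "male"): (2_733, 14.82, 14.27, 15.39),
    ("any_cancer", "UK", "female"): (1_348, 10.89, 10.32, 11.49),
}


def pooled_size() -> int:
    return sum(COHORT_SIZES.values())


def pooled_person_years() -> float:
    """Total person-years (in thousands) across the five cohorts."""
    return sum(v[0] for v in PERSON_YEARS_THOUSANDS.values())


def weighted_mean_follow_up() -> float:
    """Cohort-size-weighted mean follow-up in years."""
    num = sum(COHORT_SIZES[c] * MEAN_FOLLOW_UP_YEARS[c] for c in COHORT_SIZES)
    return num / pooled_size()


def pooled_cancer_cases() -> int:
    return sum(sum(v.values()) for v in ANY_CANCER_EVENTS.values())


def pooled_ever_use(insulin_class: str) -> int:
    return sum(EVER_USE[insulin_class].values())


def person_years_for(country: str, sex: str) -> float:
    """Person-years (raw, not thousands) for a country × sex stratum."""
    all_py, male_py = PERSON_YEARS_THOUSANDS[country]
    py = male_py if sex == "male" else all_py - male_py
    return py * 1000.0
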