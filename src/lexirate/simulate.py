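"""Synthetic five-country registry generator with known rate-ratio structure.

Emulates national prescription/cancer registries well enough to exercise every
downstream stage: new insulin users with realistic age/sex structure, refill
chains per insulin class with switching and stopping (a semi-Markov
prescribing model), baseline co-medication, death/emigration censoring and
cancer incidence from piecewise-constant hazards.

The cancer hazard of a person in interval ``[t, t+120)`` of follow-up is

    lambda(t) = lambda_site * exp( sum_c beta_c[cat_c(t)] )

where ``cat_c(t)`` is the cumulative-duration category of insulin class ``c``
evaluated at the interval start *with the analysis's own exposure engine and
120-day grid*.  Truth and estimand therefore coincide by construction: the
``true_log_rr`` a scenario declares for, say, glargine in category "1-2" is
exactly the glargine-vs-human model contrast for that category (human insulin
and every non-exposed level carry coefficient zero).  The multiplier applies
to all sites alike, so site choice is independent of exposure.

Everything is a pure function of ``(scenario, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import exposure as _exp
from .exposure import DAYS_PER_YEAR, GRID_DAYS, CategoryScheme
from .registry import COUNTRIES, RegistryBundle, STUDY_PERIODS, day_number

__all__ = [
    "SimulationScenario",
    "TruthRecord",
    "generate_bundle",
    "null_scenario",
    "effect_scenario",
    "scaled",
]

_BROAD = CategoryScheme.broad()

#: Representative ICD-10 code emitted for each simulated cancer site.
SITE_CODES = {
    "liver": "C22",
    "pancreas": "C25",
    "lung": "C34",
    "melanoma": "C43",
    "bladder": "C67",
    "colorectal": "C18",
    "nhl": "C83",
    "breast": "C50",
    "endometrial": "C54",
    "prostate": "C61",
    "nmsc": "C44",
    "other_cancer": "C80",
}

_CLASS_ATC = {
    "human": "A10AB01",
    "glargine": "A10AE04",
    "detemir": "A10AE05",
    "other_insulin": "A10AD05",
}
_CLASS_ORDER = ("human", "glargine", "detemir", "other_insulin")

_WOMEN_ONLY = {"breast", "endometrial"}
_MEN_ONLY = {"prostate"}


class EmptyBundleError(ValueError):
    """Raised when a scenario describes a zero-person population."""


def _default_n() -> dict[str, int]:
    # country mix proportional to the five cohorts' sizes, desk-scale total
    return {"DK": 1020, "FI": 1620, "NO": 330, "SE": 1300, "UK": 730}


def _default_ages() -> dict[str, float]:
    # pooled age-band mixture of new insulin users (decade bands, 80+ open)
    return {
        "18-30": 0.0458,
        "30-40": 0.0749,
        "40-50": 0.1123,
        "50-60": 0.2012,
        "60-70": 0.2410,
        "70-80": 0.1972,
        "80+": 0.1276,
    }


def _default_hazards() -> dict[str, float]:
    # events per 1000 person-years; sex-specific sites apply to one sex only,
    # totals land near 15/1000 PY of any cancer for either sex
    return {
        "liver": 0.5,
        "pancreas": 1.6,
        "lung": 1.5,
        "melanoma": 0.4,
        "bladder": 0.7,
        "colorectal": 1.7,
        "nhl": 0.4,
        "breast": 2.6,
        "endometrial": 1.05,
        "prostate": 3.5,
        "other_cancer": 4.7,
        "nmsc": 1.5,
    }


def _zero_log_rr() -> dict[str, dict[str, float]]:
    return {
        cls: {lab: 0.0 for lab in _BROAD.labels} for cls in ("glargine", "detemir")
    }


@dataclass(frozen=True)
class SimulationScenario:
    """All knobs of the generator; defaults describe the study conditions.

    Hazards are per 1000 person-years, probabilities per refill, gaps in
    days.  ``true_log_rr`` maps insulin class → broad duration category →
    log rate ratio versus human insulin (non-exposed levels are implicitly
    zero; classes not listed behave like human insulin).
    """

    n_per_country: dict[str, int] = field(default_factory=_default_n)
    age_distribution: dict[str, float] = field(default_factory=_default_ages)
    sex_ratio_male: float = 0.56
    init_probs: dict[str, float] = field(
        default_factory=lambda: {
            "human": 0.75, "glargine": 0.15, "detemir": 0.07, "other_insulin": 0.03
        }
    )
    refill_gap_mean: float = 90.0
    refill_gap_sd: float = 21.0
    refill_gap_min: float = 30.0
    ddd_per_refill_mean: float = 90.0
    ddd_per_refill_sigma: float = 0.25
    stop_prob: float = 0.015
    switch_prob: float = 0.02
    baseline_hazards: dict[str, float] = field(default_factory=_default_hazards)
    true_log_rr: dict[str, dict[str, float]] = field(default_factory=_zero_log_rr)
    death_rate: float = 0.055
    emigration_rate: float = 0.004
    frac_insufficient_lead_in: float = 0.05
    frac_under_18: float = 0.015
    frac_prior_cancer: float = 0.03
    frac_nmsc_history: float = 0.01
    frac_late_entry: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.baseline_hazards.values()):
            raise ValueError("hazards must be non-negative")
        for p in (
            self.sex_ratio_male, self.stop_prob, self.switch_prob,
            self.frac_insufficient_lead_in, self.frac_under_18,
            self.frac_prior_cancer, self.frac_nmsc_history, self.frac_late_entry,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        for cls, cats in self.true_log_rr.items():
            missing = set(_BROAD.labels) - set(cats)
            if missing:
                raise ValueError(f"true_log_rr[{cls}] missing categories {sorted(missing)}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationScenario":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class TruthRecord:
    """Realised per-person history plus the scenario's true rate ratios."""

    scenario: SimulationScenario
    seed: int
    persons: pd.DataFrame  # index/censor components and true event data

    @property
    def true_rr(self) -> dict[str, dict[str, float]]:
        return {
            cls: {cat: float(np.exp(v)) for cat, v in cats.items()}
            for cls, cats in self.scenario.true_log_rr.items()
        }


def null_scenario(**overrides) -> SimulationScenario:
    """All true rate ratios equal to 1 (log-RR 0 everywhere)."""
    return SimulationScenario(**overrides)


def effect_scenario(rr: float, insulin_class: str = "glargine", **overrides) -> SimulationScenario:
    """Constant effect: ``insulin_class`` carries log(rr) in every duration
    category (vs human insulin); everything else is at the null."""
    if rr <= 0:
        raise ValueError("rr must be > 0")
    tlr = _zero_log_rr()
    tlr[insulin_class] = {lab: float(np.log(rr)) for lab in _BROAD.labels}
    return SimulationScenario(true_log_rr=tlr, **overrides)


def scaled(scenario: SimulationScenario, n_total: int) -> SimulationScenario:
    """Same scenario with the country mix rescaled to ``n_total`` persons."""
    cur = sum(scenario.n_per_country.values())
    if cur == 0:
        raise EmptyBundleError("cannot rescale an empty scenario")
    raw = {c: n_total * v / cur for c, v in scenario.n_per_country.items()}
    out = {c: int(np.floor(v)) for c, v in raw.items()}
    # largest-remainder rounding to hit n_total exactly
    rem = sorted(raw, key=lambda c: raw[c] - out[c], reverse=True)
    for c in rem[: n_total - sum(out.values())]:
        out[c] += 1
    return replace(scenario, n_per_country=out)


def _truth_multiplier(
    rx: pd.DataFrame, window: np.ndarray, scenario: SimulationScenario
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-(person, interval) log hazard multiplier from exposure categories.

    Returns (person_index, interval_start, log_multiplier) over the 120-day
    grid covering each person's potential follow-up window, computed with the
    analysis's own episode engine so truth and estimand share the grid.
    """
    n = len(window)
    n_int = np.maximum(np.ceil(window / GRID_DAYS), 1).astype(int)
    pidx = np.repeat(np.arange(n), n_int)
    start = np.concatenate([np.arange(m) for m in n_int]) * GRID_DAYS
    logm = np.zeros(len(pidx))
    eps = _exp._episodes_frame(
        rx.rename(columns={"pid": "person_id"}), grace_days=0, stockpile=True
    )
    grid = pd.DataFrame({"person_id": pidx, "_t": start, "_row": np.arange(len(pidx))})
    grid = grid.sort_values("_t", kind="stable")  # merge_asof needs global order
    for cls, cats in scenario.true_log_rr.items():
        if all(v == 0.0 for v in cats.values()):
            continue
        ec = eps[eps["insulin_class"] == cls][
            ["person_id", "ep_start", "ep_end", "cum_before"]
        ].sort_values("ep_start", kind="stable")
        merged = pd.merge_asof(
            grid, ec, left_on="_t", right_on="ep_start", by="person_id",
            direction="backward",
        ).sort_values("_row", kind="stable")
        s = merged["ep_start"].to_numpy(dtype=float)
        ever = ~np.isnan(s)
        inside = np.clip(
            np.minimum(merged["ep_end"].to_numpy(dtype=float), start) - s, 0, None
        )
        cum = np.where(ever, merged["cum_before"].to_numpy(dtype=float) + inside, 0.0)
        idx = np.searchsorted(np.asarray(_BROAD.boundaries), cum / DAYS_PER_YEAR, "left")
        beta = np.asarray([cats[lab] for lab in _BROAD.labels])[idx]
        logm += np.where(ever, beta, 0.0)
    return pidx, start, logm


def generate_bundle(
    scenario: SimulationScenario, seed: int | None = None
) -> tuple[RegistryBundle, TruthRecord]:
    """Draw a full multi-country registry bundle plus its truth record."""
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = sum(int(v) for v in scenario.n_per_country.values())
    if n == 0:
        raise EmptyBundleError("scenario describes zero persons")

    country = np.concatenate(
        [np.full(int(scenario.n_per_country.get(c, 0)), c) for c in COUNTRIES]
    )
    study_start = np.asarray(
        [day_number(pd.Timestamp(STUDY_PERIODS[c][0])) for c in country]
    )
    study_end = np.asarray(
        [day_number(pd.Timestamp(STUDY_PERIODS[c][1])) for c in country]
    )

    sex = np.where(rng.random(n) < scenario.sex_ratio_male, "male", "female")

    bands = list(scenario.age_distribution)
    weights = np.asarray([scenario.age_distribution[b] for b in bands])
    weights = weights / weights.sum()
    band_idx = rng.choice(len(bands), size=n, p=weights)
    lo = np.asarray([18, 30, 40, 50, 60, 70, 80], dtype=float)[band_idx]
    hi = np.asarray([30, 40, 50, 60, 70, 80, 95], dtype=float)[band_idx]
    age = lo + rng.random(n) * (hi - lo)
    minors = rng.random(n) < scenario.frac_under_18
    age = np.where(minors, 16 + 2 * rng.random(n), age)

    span = study_end - study_start
    late = rng.random(n) < scenario.frac_late_entry
    data_start = study_start + np.where(
        late, (rng.random(n) * np.maximum(span - 3 * 365, 1)).astype(int), 0
    )
    data_end = study_end

    short_lead = rng.random(n) < scenario.frac_insufficient_lead_in
    headroom = np.maximum(data_end - data_start - 366, 1)
    index_day = np.where(
        short_lead,
        data_start + rng.integers(0, 365, n),
        data_start + 365 + (rng.random(n) * headroom).astype(int),
    )
    index_day = np.minimum(index_day, data_end - 1)

    birth_day = np.minimum(
        (index_day - age * DAYS_PER_YEAR).astype(int), data_start - 1
    )
    age = (index_day - birth_day) / DAYS_PER_YEAR  # exact post-rounding age

    death_day = index_day + np.maximum(
        1, (rng.exponential(1.0 / scenario.death_rate, n) * DAYS_PER_YEAR).astype(int)
    )
    emig_day = index_day + np.maximum(
        1, (rng.exponential(1.0 / scenario.emigration_rate, n) * DAYS_PER_YEAR).astype(int)
    )
    rx_end = np.minimum.reduce([data_end, death_day, emig_day])

    # ---- insulin refill chains (semi-Markov) ---------------------------
    max_span = int(np.max(rx_end - index_day)) if n else 0
    # sized so the clipped-normal gap sum overshoots the longest window by
    # many standard deviations; vectorised over a fixed refill count
    n_refills_max = max(2, int(np.ceil(max_span / scenario.refill_gap_mean * 1.2)) + 8)
    n_refills_max = min(n_refills_max, 400)
    gaps = np.clip(
        rng.normal(scenario.refill_gap_mean, scenario.refill_gap_sd, (n, n_refills_max)),
        scenario.refill_gap_min,
        None,
    )
    offsets = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(gaps, axis=1)[:, :-1]], axis=1
    ).astype(int)
    dates = index_day[:, None] + offsets

    stop_draw = rng.random((n, n_refills_max)) < scenario.stop_prob
    stop_draw[:, 0] = False
    first_stop = np.where(stop_draw.any(axis=1), stop_draw.argmax(axis=1), n_refills_max)

    init_idx = rng.choice(
        len(_CLASS_ORDER),
        size=n,
        p=[scenario.init_probs.get(c, 0.0) for c in _CLASS_ORDER],
    )
    switch_draw = rng.random((n, n_refills_max)) < scenario.switch_prob
    switch_draw[:, 0] = False
    n_switch = np.cumsum(switch_draw, axis=1)
    max_sw = int(n_switch.max()) if n else 0
    path = np.empty((n, max_sw + 1), dtype=int)
    path[:, 0] = init_idx
    for m in range(1, max_sw + 1):
        path[:, m] = (path[:, m - 1] + 1 + rng.integers(0, 3, n)) % len(_CLASS_ORDER)
    class_idx = np.take_along_axis(path, n_switch, axis=1)

    ddd = np.exp(
        rng.normal(
            np.log(scenario.ddd_per_refill_mean) - scenario.ddd_per_refill_sigma**2 / 2,
            scenario.ddd_per_refill_sigma,
            (n, n_refills_max),
        )
    )

    refill_no = np.arange(n_refills_max)[None, :]
    keep = (refill_no < first_stop[:, None]) & (dates < rx_end[:, None])
    pid_mat = np.broadcast_to(np.arange(n)[:, None], dates.shape)
    rx_long = pd.DataFrame(
        {
            "pid": pid_mat[keep],
            "dispense_day": dates[keep],
            "class_idx": class_idx[keep],
            "ddd_amount": np.round(ddd[keep], 1),
        }
    )
    rx_long["insulin_class"] = np.asarray(_CLASS_ORDER)[rx_long["class_idx"]]

    # ---- cancer process on the analysis grid ---------------------------
    window = rx_end - index_day
    rel = pd.DataFrame(
        {
            "person_id": rx_long["pid"],
            "insulin_class": rx_long["insulin_class"],
            "day": rx_long["dispense_day"] - index_day[rx_long["pid"].to_numpy()],
            "ddd_amount": rx_long["ddd_amount"],
        }
    )
    pidx, istart, logm = _truth_multiplier(rel, window, scenario)

    is_female = sex == "female"
    site_names = [s for s in scenario.baseline_hazards if s != "nmsc"]
    rates = np.asarray([scenario.baseline_hazards[s] for s in site_names])
    male_mask = np.asarray(
        [0.0 if s in _WOMEN_ONLY else 1.0 for s in site_names]
    )
    female_mask = np.asarray([0.0 if s in _MEN_ONLY else 1.0 for s in site_names])
    total_per_day = {
        True: float((rates * female_mask).sum()) / 1000.0 / DAYS_PER_YEAR,
        False: float((rates * male_mask).sum()) / 1000.0 / DAYS_PER_YEAR,
    }
    lam0 = np.where(is_female, total_per_day[True], total_per_day[False])

    ilen = np.minimum(istart + GRID_DAYS, window[pidx]) - istart
    lam_int = lam0[pidx] * np.exp(logm)
    cumhaz_steps = lam_int * np.maximum(ilen, 0)
    # first grid interval where the person's cumulative hazard crosses an
    # Exp(1) budget; pidx is sorted by construction (repeat of arange)
    budget = rng.exponential(1.0, n)
    n_int = np.maximum(np.ceil(window / GRID_DAYS), 1).astype(int)
    grp_start = np.concatenate([[0], np.cumsum(n_int)[:-1]])
    cum = np.cumsum(cumhaz_steps)
    base = np.concatenate([[0.0], cum])[grp_start]
    cum_within = cum - np.repeat(base, n_int)
    crossed = cum_within >= budget[pidx]
    row_or_inf = np.where(crossed, np.arange(len(pidx)), len(pidx))
    first_row = np.minimum.reduceat(row_or_inf, grp_start)
    has = first_row < len(pidx)
    fr = np.where(has, first_row, 0)
    prev = cum_within[fr] - cumhaz_steps[fr]
    t_off = istart[fr] + (budget - prev) / np.maximum(lam_int[fr], 1e-300)
    cancer_off = np.where(has, np.floor(t_off), np.nan)
    valid = has & (np.nan_to_num(cancer_off, nan=np.inf) < window)
    cancer_day = np.where(valid, index_day + np.nan_to_num(cancer_off), np.nan)

    # site choice: the exposure multiplier is common to all sites, so the
    # site distribution depends on sex only
    probs_f = rates * female_mask
    probs_f = probs_f / probs_f.sum()
    probs_m = rates * male_mask
    probs_m = probs_m / probs_m.sum()
    u = rng.random(n)
    pick_f = np.searchsorted(np.cumsum(probs_f), u)
    pick_m = np.searchsorted(np.cumsum(probs_m), u)
    site_idx = np.where(is_female, pick_f, pick_m).clip(0, len(site_names) - 1)
    cancer_site = np.asarray(site_names, dtype=object)[site_idx]

    # NMSC: independent, does not end follow-up
    nmsc_rate = scenario.baseline_hazards.get("nmsc", 0.0)
    if nmsc_rate > 0:
        nmsc_off = rng.exponential(1000.0 * DAYS_PER_YEAR / nmsc_rate, n)
    else:
        nmsc_off = np.full(n, np.inf)
    nmsc_cap = np.where(valid, np.nan_to_num(cancer_off, nan=np.inf), window)
    has_nmsc = nmsc_off < nmsc_cap
    nmsc_day = index_day + np.floor(nmsc_off)

    prior_cancer = rng.random(n) < scenario.frac_prior_cancer
    prior_off = rng.integers(30, 1500, n)
    prior_day = np.maximum(index_day - prior_off, data_start + 1)
    prior_site = np.asarray(site_names, dtype=object)[
        np.where(is_female, pick_f, pick_m).clip(0, len(site_names) - 1)
    ]
    prior_nmsc = rng.random(n) < scenario.frac_nmsc_history
    prior_nmsc_day = np.maximum(index_day - rng.integers(30, 1500, n), data_start + 1)

    # ---- assemble tables ------------------------------------------------
    person_id = np.asarray([f"{c}{i:07d}" for i, c in enumerate(country)], dtype=object)

    def _dates(days: np.ndarray) -> pd.Series:
        return pd.Series(pd.to_datetime(np.asarray(days, dtype="int64"), unit="D"))

    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "sex": sex,
            "birth_date": _dates(birth_day),
            "country": country,
            "data_start": _dates(data_start),
            "data_end": _dates(data_end),
        }
    )

    rx_frames = [
        pd.DataFrame(
            {
                "person_id": person_id[rx_long["pid"].to_numpy()],
                "dispense_date": _dates(rx_long["dispense_day"].to_numpy()),
                "atc_code": rx_long["insulin_class"].map(_CLASS_ATC).to_numpy(),
                "ddd_amount": rx_long["ddd_amount"].to_numpy(),
            }
        )
    ]
    comed_specs = [
        ("A10BA02", 0.75, None),
        ("C10AA01", 0.40, None),
        ("M01AE01", 0.25, None),
        ("G03CA03", 0.16, "female"),
    ]
    for atc, p, sex_only in comed_specs:
        flag = rng.random(n) < p
        if sex_only is not None:
            flag &= sex == sex_only
        back = rng.integers(1, 366, n)
        day = np.maximum(index_day - back, data_start)
        rx_frames.append(
            pd.DataFrame(
                {
                    "person_id": person_id[flag],
                    "dispense_date": _dates(day[flag]),
                    "atc_code": atc,
                    "ddd_amount": 100.0,
                }
            )
        )
    prescriptions = pd.concat(rx_frames, ignore_index=True)
    prescriptions = prescriptions.sort_values(
        ["person_id", "dispense_date", "atc_code"], kind="stable"
    ).reset_index(drop=True)

    ev_frames = []
    has_cancer = ~np.isnan(cancer_day)
    ev_frames.append(
        pd.DataFrame(
            {
                "person_id": person_id[has_cancer],
                "event_date": _dates(cancer_day[has_cancer].astype(int)),
                "event_type": "cancer",
                "diagnosis_code": pd.Series(cancer_site[has_cancer]).map(SITE_CODES).to_numpy(),
            }
        )
    )
    ev_frames.append(
        pd.DataFrame(
            {
                "person_id": person_id[has_nmsc],
                "event_date": _dates(nmsc_day[has_nmsc].astype(int)),
                "event_type": "cancer",
                "diagnosis_code": "C44",
            }
        )
    )
    ev_frames.append(
        pd.DataFrame(
            {
                "person_id": person_id[prior_cancer],
                "event_date": _dates(prior_day[prior_cancer]),
                "event_type": "cancer",
                "diagnosis_code": pd.Series(prior_site[prior_cancer]).map(SITE_CODES).to_numpy(),
            }
        )
    )
    ev_frames.append(
        pd.DataFrame(
            {
                "person_id": person_id[prior_nmsc],
                "event_date": _dates(prior_nmsc_day[prior_nmsc]),
                "event_type": "cancer",
                "diagnosis_code": "C44",
            }
        )
    )
    died = death_day <= data_end
    ev_frames.append(
        pd.DataFrame(
            {
                "person_id": person_id[died],
                "event_date": _dates(death_day[died]),
                "event_type": "death",
                "diagnosis_code": "",
            }
        )
    )
    emigrated = (emig_day <= data_end) & (emig_day < death_day)
    ev_frames.append(
        pd.DataFrame(
            {
                "person_id": person_id[emigrated],
                "event_date": _dates(emig_day[emigrated]),
                "event_type": "emigration",
                "diagnosis_code": "",
            }
        )
    )
    events = pd.concat(ev_frames, ignore_index=True)
    events = events.sort_values(
        ["person_id", "event_date", "event_type"], kind="stable"
    ).reset_index(drop=True)

    bundle = RegistryBundle(persons=persons, prescriptions=prescriptions, events=events)

    truth_persons = pd.DataFrame(
        {
            "person_id": person_id,
            "index_day": index_day,
            "death_day": death_day,
            "emig_day": emig_day,
            "cancer_day": cancer_day,
            "cancer_site": np.where(has_cancer, cancer_site, ""),
            "window_days": window,
            "short_lead_in": short_lead,
            "prior_cancer": prior_cancer,
        }
    )
    truth = TruthRecord(scenario=scenario, seed=seed, persons=truth_persons)
    return bundle, truth
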