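"""Time-varying cumulative insulin exposure on a 120-day grid.

Each dispensing of ``d`` defined daily doses covers ``ceil(d)`` days at an
assumed consumption of 1 DDD/day.  A purchase made while previous coverage
still runs extends coverage from the current coverage end (stockpiling
carry-forward); a purchase after a gap opens a new coverage episode.
Cumulative treatment time counts covered days only: it accrues while covered,
freezes during gaps and resumes on re-exposure.

Follow-up is split into 120-day intervals from the index date; the exposure
category of every insulin class is evaluated at each interval start and held
fixed within the interval, which makes all covariates piecewise constant
(Lexis-style splitting).  Two category schemes are supported:

* ``broad`` — ≤0.5, 0.5–1, then 1-year bins with terminal >6 years,
* ``fine``  — same to 6 years, then 1-year bins with terminal 9–10 years,

each preceded by a ``non-exposed`` level for person-time before the first
dispensing of that class (this is what prevents immortal-time bias: the time
between index and first exposure is modelled, not discarded).

A brute-force day-resolution oracle (:func:`day_level_oracle`) re-derives the
same quantities by simulating the DDD stock one day at a time; it exists for
testing only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .registry import INSULIN_CLASSES

__all__ = [
    "GRID_DAYS",
    "DAYS_PER_YEAR",
    "NON_EXPOSED",
    "CategoryScheme",
    "coverage_episodes",
    "cumulative_days_at",
    "categorize",
    "expand_person",
    "day_level_oracle",
    "ExposureExpander",
]

GRID_DAYS = 120
DAYS_PER_YEAR = 365.25
NON_EXPOSED = "non-exposed"

#: Decade age bands used as the time-dependent age covariate.
AGE_BAND_EDGES = [30, 40, 50, 60, 70, 80]
AGE_BAND_LABELS = ["18-30", "30-40", "40-50", "50-60", "60-70", "70-80", "80+"]


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered duration bins (years) for cumulative treatment time.

    ``boundaries`` are the inner cut points; bins are half-open on the left,
    ``(lo, hi]``, so exactly half a year of exposure still falls in "<=0.5".
    The last label is an open terminal bin.  An exposed person with zero
    accumulated days (category evaluated at the very start of exposure) sits
    in the first bin.
    """

    name: str
    boundaries: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries) + 1:
            raise ValueError("need one more label than inner boundaries")

    @classmethod
    def broad(cls) -> "CategoryScheme":
        return cls(
            name="broad",
            boundaries=(0.5, 1, 2, 3, 4, 5, 6),
            labels=("<=0.5", "0.5-1", "1-2", "2-3", "3-4", "4-5", "5-6", ">6"),
        )

    @classmethod
    def fine(cls) -> "CategoryScheme":
        return cls(
            name="fine",
            boundaries=(0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9),
            labels=(
                "<=0.5", "0.5-1", "1-2", "2-3", "3-4", "4-5",
                "5-6", "6-7", "7-8", "8-9", "9-10",
            ),
        )

    @classmethod
    def by_name(cls, name: str) -> "CategoryScheme":
        if name == "broad":
            return cls.broad()
        if name == "fine":
            return cls.fine()
        raise ValueError(f"unknown category scheme {name!r}")

    @property
    def all_labels(self) -> tuple[str, ...]:
        return (NON_EXPOSED,) + self.labels

    @property
    def max_years(self) -> float:
        return self.boundaries[-1]


def coverage_episodes(
    prescriptions: pd.DataFrame,
    follow_up_end: int,
    grace_days: int = 0,
    stockpile: bool = True,
) -> list[tuple[int, int]]:
    """Coverage episodes ``[(start, end), ...]`` for one person × insulin class.

    ``prescriptions`` needs columns ``day`` (offset from index, sorted
    ascending) and ``ddd_amount``.  Episodes are half-open day intervals,
    disjoint, sorted and truncated at ``follow_up_end``.  With stockpiling a
    purchase arriving under coverage pushes the coverage end out by its DDD
    count; without it overlapping coverage is discarded (union of per-purchase
    windows).  Gaps no longer than ``grace_days`` are bridged into a single
    episode (bridged days count as exposed).
    """
    days = prescriptions["day"].to_numpy()
    if len(days) and (np.diff(days) < 0).any():
        raise ValueError("prescriptions must be sorted by dispense day")
    amounts = np.ceil(prescriptions["ddd_amount"].to_numpy()).astype(int)
    if (amounts <= 0).any():
        raise ValueError("ddd_amount must be positive")

    raw: list[list[int]] = []
    cover_end = -1  # exclusive end of current coverage; -1 = none yet
    for d, a in zip(days.tolist(), amounts.tolist()):
        if not raw or d > cover_end + grace_days:
            raw.append([d, d + a])
            cover_end = d + a
        else:
            # d <= cover_end: stockpiled carry-forward; within grace of the
            # end: coverage resumes at d and the bridged gap counts as exposed
            new_end = (max(cover_end, d) + a) if stockpile else max(cover_end, d + a)
            raw[-1][1] = new_end
            cover_end = new_end
    episodes = [
        (s, min(e, follow_up_end)) for s, e in raw if s < follow_up_end and min(e, follow_up_end) > s
    ]
    return episodes


def cumulative_days_at(t: int, episodes: list[tuple[int, int]]) -> int:
    """Covered days accrued strictly before day ``t`` (from index).

    Zero before the first episode, frozen during gaps, saturating at the
    total covered day count once past the last episode.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    total = 0
    for start, end in episodes:
        lo, hi = max(start, 0), min(end, t)
        if hi > lo:
            total += hi - lo
    return total


def categorize(cum_days: float, scheme: CategoryScheme, ever_exposed: bool) -> str:
    """Duration-category label for a cumulative covered-day count."""
    if cum_days < 0:
        raise ValueError("cum_days must be non-negative")
    if not ever_exposed:
        return NON_EXPOSED
    years = cum_days / DAYS_PER_YEAR
    idx = int(np.searchsorted(np.asarray(scheme.boundaries), years, side="left"))
    return scheme.labels[idx]


def _age_band(age_years: float) -> str:
    idx = int(np.searchsorted(np.asarray(AGE_BAND_EDGES, dtype=float), age_years, side="right"))
    return AGE_BAND_LABELS[idx]


def expand_person(
    record: dict,
    episodes_by_class: dict[str, list[tuple[int, int]]],
    scheme: CategoryScheme,
    grid_days: int = GRID_DAYS,
) -> list[dict]:
    """Split one person's follow-up into ≤``grid_days``-day interval rows.

    ``record`` needs ``follow_up_days`` (censor − index, > 0), ``age_at_index``
    (years), ``sex``, ``index_year`` and ``event`` (endpoint occurred at
    censoring).  Reference implementation — clear rather than fast; the
    vectorised :class:`ExposureExpander` is cross-checked against it.
    """
    fu = int(record["follow_up_days"])
    if fu <= 0:
        raise ValueError("follow-up must be positive (censor after index)")
    rows: list[dict] = []
    first_rx = {
        cls: (eps[0][0] if eps else None) for cls, eps in episodes_by_class.items()
    }
    for start in range(0, fu, grid_days):
        end = min(start + grid_days, fu)
        age = record["age_at_index"] + start / DAYS_PER_YEAR
        row: dict = {
            "person_id": record.get("person_id"),
            "interval_start": start,
            "interval_end": end,
            "person_days": end - start,
            "age_band": _age_band(age),
            "duration_band": int(start / DAYS_PER_YEAR),
            "event": int(bool(record.get("event")) and end == fu),
        }
        if record["sex"] == "female":
            row["menopausal_status"] = "post" if age >= 50 else "pre"
        else:
            row["menopausal_status"] = "n/a"
        for cls, eps in episodes_by_class.items():
            cum = cumulative_days_at(start, eps)
            ever = first_rx[cls] is not None and first_rx[cls] <= start
            row[f"cum_days_{cls}"] = cum
            row[f"cat_{cls}"] = categorize(cum, scheme, ever)
        rows.append(row)
    return rows


def day_level_oracle(
    prescriptions: pd.DataFrame,
    follow_up_end: int,
    classes: tuple[str, ...] = INSULIN_CLASSES,
    grace_days: int = 0,
    stockpile: bool = True,
) -> pd.DataFrame:
    """Brute-force day-by-day DDD stock simulation (testing only).

    For each insulin class, walks every day from 0 to ``follow_up_end``,
    adding ``ceil(ddd_amount)`` to the stock on dispense days and consuming
    one DDD per covered day.  Returns one row per day with per-class
    ``covered_<cls>`` flags and ``cum_<cls>`` running covered-day counters.
    Without stockpiling the stock is capped at each purchase's own window;
    with a grace period the exposure state survives gaps of up to
    ``grace_days`` (and those days count as covered, matching the episode
    engine's bridging rule).
    """
    n = int(follow_up_end)
    out = {"day": np.arange(n, dtype=int)}
    for cls in classes:
        sub = prescriptions[prescriptions["insulin_class"] == cls]
        add_on: dict[int, list[int]] = {}
        for d, a in zip(sub["day"].tolist(), np.ceil(sub["ddd_amount"].to_numpy()).astype(int)):
            add_on.setdefault(d, []).append(int(a))
        covered = np.zeros(n, dtype=bool)
        stock = 0
        cover_end: int | None = None  # day after the last stock-backed day
        for day in range(n):
            if day in add_on:
                if cover_end is not None and stock == 0 and 0 < day - cover_end <= grace_days:
                    covered[cover_end:day] = True  # bridge: treatment resumed in time
                for a in add_on[day]:
                    stock = stock + a if stockpile else max(stock, a)
            if stock > 0:
                covered[day] = True
                stock -= 1
                cover_end = day + 1
        out[f"covered_{cls}"] = covered
        out[f"cum_{cls}"] = np.concatenate([[0], np.cumsum(covered)[:-1]])
    return pd.DataFrame(out)


def _episodes_frame(
    rx: pd.DataFrame,
    grace_days: int = 0,
    stockpile: bool = True,
) -> pd.DataFrame:
    """Vectorised episode construction for many persons at once.

    ``rx`` columns: person_id, insulin_class, day (offset from index),
    ddd_amount.  Uses the identity  end_j = A_j + max_{i<=j}(day_i − A_{i-1})
    with A the running ceil-DDD sum, which reproduces the carry-forward
    recurrence without a Python loop.  Returns episodes with per-episode
    cumulative covered days accrued before the episode starts.
    """
    if rx.empty:
        return pd.DataFrame(
            columns=["person_id", "insulin_class", "ep_start", "ep_end", "cum_before"]
        )
    rx = rx.sort_values(["person_id", "insulin_class", "day"], kind="stable").copy()
    g = rx.groupby(["person_id", "insulin_class"], sort=False)
    amt = np.ceil(rx["ddd_amount"].to_numpy()).astype("int64")
    rx["_a"] = amt
    rx["_A"] = g["_a"].cumsum()
    if stockpile:
        rx["_x"] = rx["day"] - (rx["_A"] - rx["_a"])
        rx["_end"] = rx["_A"] + rx.groupby(["person_id", "insulin_class"], sort=False)["_x"].cummax()
    else:
        # union of per-purchase windows: running max of day + amount
        rx["_end"] = (rx["day"] + rx["_a"]).groupby(
            [rx["person_id"], rx["insulin_class"]]
        ).cummax()
    prev_end = rx.groupby(["person_id", "insulin_class"], sort=False)["_end"].shift()
    new_ep = prev_end.isna() | (rx["day"] > prev_end + grace_days)
    rx["_ep"] = new_ep.groupby([rx["person_id"], rx["insulin_class"]]).cumsum()
    eps = (
        rx.groupby(["person_id", "insulin_class", "_ep"], sort=False)
        .agg(ep_start=("day", "first"), ep_end=("_end", "last"))
        .reset_index()
        .drop(columns="_ep")
    )
    length = eps["ep_end"] - eps["ep_start"]
    eps["cum_before"] = (
        length.groupby([eps["person_id"], eps["insulin_class"]]).cumsum() - length
    )
    return eps


class ExposureExpander(BaseEstimator, TransformerMixin):
    """Transform a cohort + prescriptions into 120-day interval rows.

    Parameters
    ----------
    scheme : {"broad", "fine"}
        Cumulative-duration category scheme.
    grid_days : int
        Interval length of the splitting grid (120 by default).
    grace_days : int
        Coverage gaps up to this length are bridged (0 = strict coverage).
    stockpile : bool
        Carry forward surplus DDDs from overlapping purchases.
    classes : tuple of str
        Insulin classes for which timelines are computed.
    calendar_width : int
        Width (years) of the baseline calendar-time bins (index year).
    duration_cap : int or None
        Cap (years) for the duration-of-insulin-treated-diabetes band; by
        default the scheme's terminal boundary, which avoids sparse and
        aliased duration levels in small cohorts.
    """

    def __init__(
        self,
        scheme: str = "broad",
        grid_days: int = GRID_DAYS,
        grace_days: int = 0,
        stockpile: bool = True,
        classes: tuple[str, ...] = INSULIN_CLASSES,
        calendar_width: int = 3,
        duration_cap: int | None = None,
    ):
        self.scheme = scheme
        self.grid_days = grid_days
        self.grace_days = grace_days
        self.stockpile = stockpile
        self.classes = classes
        self.calendar_width = calendar_width
        self.duration_cap = duration_cap

    def fit(self, X=None, y=None) -> "ExposureExpander":
        self.scheme_ = CategoryScheme.by_name(self.scheme)
        self.duration_cap_ = (
            int(self.scheme_.max_years) if self.duration_cap is None else self.duration_cap
        )
        return self

    def transform(self, cohort: pd.DataFrame, prescriptions: pd.DataFrame | None = None) -> pd.DataFrame:
        """Expand every cohort record into interval rows.

        ``cohort`` comes from :class:`lexirate.cohort.CohortBuilder` (needs
        index_day, censor_day, birth_day, sex, country, index_year, niad,
        statin, nsaid, hrt, censor_reason).  ``prescriptions`` must carry
        person_id, day-offset ``day`` relative to index and ``insulin_class``
        (pre-classified); rows of non-modelled classes are ignored.
        """
        if prescriptions is None:
            raise ValueError("prescriptions frame is required")
        if not hasattr(self, "scheme_"):
            self.fit()
        scheme = self.scheme_
        cohort = cohort.reset_index(drop=True)
        fu = (cohort["censor_day"] - cohort["index_day"]).to_numpy()
        if (fu <= 0).any():
            raise ValueError("all cohort records must have positive follow-up")

        n_int = np.ceil(fu / self.grid_days).astype(int)
        person_idx = np.repeat(np.arange(len(cohort)), n_int)
        k = np.concatenate([np.arange(m) for m in n_int]) if len(n_int) else np.array([], int)
        start = k * self.grid_days
        end = np.minimum(start + self.grid_days, fu[person_idx])

        rows = pd.DataFrame(
            {
                "person_id": cohort["person_id"].to_numpy()[person_idx],
                "interval_start": start,
                "interval_end": end,
                "person_days": end - start,
            }
        )
        age = cohort["age_at_index"].to_numpy()[person_idx] + start / DAYS_PER_YEAR
        rows["age_band"] = np.asarray(AGE_BAND_LABELS)[
            np.searchsorted(np.asarray(AGE_BAND_EDGES, dtype=float), age, side="right")
        ]
        rows["duration_band"] = np.minimum(
            (start / DAYS_PER_YEAR).astype(int), self.duration_cap_
        ).astype(str)
        iy = cohort["index_year"].to_numpy()[person_idx]
        lo = (iy - 1987) // self.calendar_width * self.calendar_width + 1987
        rows["calendar_band"] = pd.Series(lo).astype(str) + "-" + pd.Series(
            lo + self.calendar_width - 1
        ).astype(str)
        sex = cohort["sex"].to_numpy()[person_idx]
        rows["sex"] = sex
        rows["country"] = cohort["country"].to_numpy()[person_idx]
        rows["menopausal_status"] = np.where(
            sex == "female", np.where(age >= 50, "post", "pre"), "n/a"
        )
        for flag in ("niad", "statin", "nsaid", "hrt"):
            rows[flag] = cohort[flag].to_numpy()[person_idx]
        is_last = k == (n_int[person_idx] - 1)
        rows["event_any"] = (
            is_last & (cohort["censor_reason"].to_numpy()[person_idx] == "cancer")
        ).astype(int)

        # --- exposure timelines -----------------------------------------
        rx = prescriptions[prescriptions["insulin_class"].isin(self.classes)]
        rx = rx[rx["day"] >= 0]  # new-user design: nothing precedes index
        eps = _episodes_frame(rx, grace_days=self.grace_days, stockpile=self.stockpile)
        rows = rows.sort_values(["person_id", "interval_start"], kind="stable").reset_index(
            drop=True
        )
        left = rows[["person_id"]].copy()
        left["_t"] = rows["interval_start"].to_numpy()
        left["_row"] = np.arange(len(left))
        left = left.sort_values("_t", kind="stable")  # merge_asof needs global order
        for cls in self.classes:
            ec = eps[eps["insulin_class"] == cls][
                ["person_id", "ep_start", "ep_end", "cum_before"]
            ].sort_values("ep_start", kind="stable")
            merged = pd.merge_asof(
                left,
                ec,
                left_on="_t",
                right_on="ep_start",
                by="person_id",
                direction="backward",
            ).sort_values("_row", kind="stable")
            t = merged["_t"].to_numpy()
            s = merged["ep_start"].to_numpy(dtype=float)
            e = merged["ep_end"].to_numpy(dtype=float)
            cb = merged["cum_before"].to_numpy(dtype=float)
            ever = ~np.isnan(s)
            inside = np.clip(np.minimum(e, t) - s, 0, None)
            cum = np.where(ever, cb + inside, 0.0)
            years = cum / DAYS_PER_YEAR
            idx = np.searchsorted(np.asarray(scheme.boundaries), years, side="left")
            cats = np.asarray(scheme.labels)[idx]
            rows[f"cum_days_{cls}"] = cum.astype(int)
            rows[f"cat_{cls}"] = np.where(ever, cats, NON_EXPOSED)
        return rows
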