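"""Coverage episodes, cumulative exposure, categorisation and grid expansion.

The day-resolution oracle re-derives coverage by brute force; the interval
engine must agree with it exactly, both on hand-picked cases and on
randomised prescription histories.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lexirate.exposure import (
    DAYS_PER_YEAR,
    NON_EXPOSED,
    CategoryScheme,
    ExposureExpander,
    categorize,
    coverage_episodes,
    cumulative_days_at,
    day_level_oracle,
    expand_person,
)


def rx_frame(rows, cls="glargine"):
    return pd.DataFrame(
        [{"insulin_class": cls, "day": d, "ddd_amount": a} for d, a in rows]
    )


class TestCoverageEpisodes:
    def test_single_purchase_covers_its_ddd_count(self):
        eps = coverage_episodes(rx_frame([(0, 100)]), follow_up_end=10_000)
        assert eps == [(0, 100)]

    def test_overlapping_purchase_extends_from_coverage_end(self):
        # 50 DDD at day 0 plus 50 DDD at day 30: stock carries forward
        eps = coverage_episodes(rx_frame([(0, 50), (30, 50)]), follow_up_end=10_000)
        assert eps == [(0, 100)]

    def test_gap_opens_new_episode(self):
        eps = coverage_episodes(rx_frame([(0, 30), (60, 30)]), follow_up_end=10_000)
        assert eps == [(0, 30), (60, 90)]

    def test_truncated_at_follow_up_end(self):
        eps = coverage_episodes(rx_frame([(0, 100)]), follow_up_end=40)
        assert eps == [(0, 40)]

    def test_fractional_ddd_rounds_up(self):
        eps = coverage_episodes(rx_frame([(0, 29.5)]), follow_up_end=1_000)
        assert eps == [(0, 30)]

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            coverage_episodes(rx_frame([(60, 30), (0, 30)]), follow_up_end=1_000)

    def test_grace_period_bridges_short_gaps(self):
        eps = coverage_episodes(
            rx_frame([(0, 30), (40, 30)]), follow_up_end=1_000, grace_days=15
        )
        assert eps == [(0, 70)]  # gap of 10 days bridged, coverage resumes at 40

    def test_no_stockpile_discards_overlap(self):
        eps = coverage_episodes(
            rx_frame([(0, 100), (30, 50)]), follow_up_end=1_000, stockpile=False
        )
        assert eps == [(0, 100)]


class TestCumulativeDays:
    def test_zero_before_any_exposure(self):
        assert cumulative_days_at(0, [(0, 30)]) == 0

    def test_frozen_during_gap_then_resumes(self):
        eps = [(0, 30), (60, 90)]
        assert cumulative_days_at(45, eps) == 30
        assert cumulative_days_at(75, eps) == 45

    def test_saturates_after_last_episode(self):
        assert cumulative_days_at(10_000, [(0, 30), (60, 90)]) == 60

    def test_monotone_in_time(self):
        eps = [(0, 30), (60, 90), (200, 230)]
        vals = [cumulative_days_at(t, eps) for t in range(0, 400, 7)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestCategorize:
    broad = CategoryScheme.broad()
    fine = CategoryScheme.fine()

    @pytest.mark.parametrize(
        "days,scheme,expected",
        [
            (100, "broad", "<=0.5"),
            (0, "broad", "<=0.5"),  # just started: exposed with zero accrued days
            (int(0.5 * DAYS_PER_YEAR), "broad", "<=0.5"),  # boundary is inclusive
            (200, "broad", "0.5-1"),
            (2300, "broad", ">6"),
            (2300, "fine", "6-7"),
            (4000, "fine", "9-10"),
        ],
    )
    def test_duration_bins(self, days, scheme, expected):
        assert categorize(days, CategoryScheme.by_name(scheme), ever_exposed=True) == expected

    def test_never_exposed_is_non_exposed_category(self):
        assert categorize(0, self.broad, ever_exposed=False) == NON_EXPOSED

    def test_negative_days_rejected(self):
        with pytest.raises(ValueError):
            categorize(-1, self.broad, ever_exposed=True)

    def test_partition_every_value_has_exactly_one_label(self):
        for days in range(0, 5000, 13):
            lab = categorize(days, self.broad, True)
            assert lab in self.broad.labels
            lab_f = categorize(days, self.fine, True)
            assert lab_f in self.fine.labels


class TestExpandPerson:
    record = {
        "person_id": "p",
        "follow_up_days": 300,
        "age_at_index": 60.0,
        "sex": "male",
        "index_year": 2003,
        "event": True,
    }

    def test_partition_arithmetic(self):
        rows = expand_person(self.record, {"glargine": []}, CategoryScheme.broad())
        assert [(r["interval_start"], r["interval_end"]) for r in rows] == [
            (0, 120), (120, 240), (240, 300)
        ]
        assert sum(r["person_days"] for r in rows) == 300

    def test_event_sits_in_final_interval_only(self):
        rows = expand_person(self.record, {}, CategoryScheme.broad())
        assert [r["event"] for r in rows] == [0, 0, 1]

    def test_categories_update_at_interval_starts(self):
        rows = expand_person(self.record, {"glargine": [(0, 400)]}, CategoryScheme.broad())
        # cum at starts 0/120/240 days: 0, 120, 240 -> 0.0, 0.33, 0.66 years
        assert [r["cat_glargine"] for r in rows] == ["<=0.5", "<=0.5", "0.5-1"]
        assert [r["cum_days_glargine"] for r in rows] == [0, 120, 240]

    def test_menopausal_status_crosses_50_mid_follow_up(self):
        # 49.5 + 240/365.25 = 50.16: the 50-year cut falls inside the second interval
        record = dict(self.record, sex="female", age_at_index=49.5)
        rows = expand_person(record, {}, CategoryScheme.broad())
        assert [r["menopausal_status"] for r in rows] == ["pre", "pre", "post"]

    def test_zero_follow_up_rejected(self):
        with pytest.raises(ValueError):
            expand_person(dict(self.record, follow_up_days=0), {}, CategoryScheme.broad())


@st.composite
def prescription_histories(draw):
    n = draw(st.integers(1, 12))
    days = sorted(draw(st.lists(st.integers(0, 1200), min_size=n, max_size=n)))
    amounts = draw(
        st.lists(st.floats(0.5, 200, allow_nan=False), min_size=n, max_size=n)
    )
    return rx_frame(list(zip(days, amounts)))


@settings(max_examples=80, derandomize=True, deadline=None)
@given(rx=prescription_histories(), fu=st.integers(100, 1500))
def test_episode_union_equals_oracle_covered_days(rx, fu):
    """Episode union and the day-level stock simulation mark the same days."""
    eps = coverage_episodes(rx, follow_up_end=fu)
    oracle = day_level_oracle(rx, fu, classes=("glargine",))
    covered = np.zeros(fu, dtype=bool)
    for s, e in eps:
        covered[max(s, 0):e] = True
    assert (covered == oracle["covered_glargine"].to_numpy()).all()


@settings(max_examples=80, derandomize=True, deadline=None)
@given(rx=prescription_histories(), fu=st.integers(100, 1500))
def test_cumulative_days_match_oracle_at_grid_points(rx, fu):
    eps = coverage_episodes(rx, follow_up_end=fu)
    oracle = day_level_oracle(rx, fu, classes=("glargine",))
    cum = oracle["cum_glargine"].to_numpy()
    for t in range(0, fu, 120):
        assert cumulative_days_at(t, eps) == cum[t]


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    rx=prescription_histories(),
    extra_day=st.integers(0, 1200),
    extra_amount=st.floats(1, 150, allow_nan=False),
)
def test_adding_a_prescription_never_decreases_cumulative_exposure(
    rx, extra_day, extra_amount
):
    fu = 1500
    base = coverage_episodes(rx, follow_up_end=fu)
    augmented = rx_frame(
        sorted(
            list(zip(rx["day"], rx["ddd_amount"])) + [(extra_day, extra_amount)],
            key=lambda t: t[0],
        )
    )
    more = coverage_episodes(augmented, follow_up_end=fu)
    for t in range(0, fu, 60):
        assert cumulative_days_at(t, more) >= cumulative_days_at(t, base)


def test_expander_matches_reference_implementation(small_bundle, small_cohort, small_intervals):
    """Vectorised grid expansion equals the per-person reference on real data."""
    from lexirate.cohort import relative_prescriptions

    bundle, _ = small_bundle
    cohort, _, _ = small_cohort
    rx = relative_prescriptions(bundle, cohort)
    scheme = CategoryScheme.broad()
    sample = cohort.sample(25, random_state=0)
    by_person = dict(tuple(small_intervals.groupby("person_id")))
    for _, rec in sample.iterrows():
        sub = rx[rx["person_id"] == rec["person_id"]].sort_values("day")
        eps = {
            cls: coverage_episodes(
                sub[sub["insulin_class"] == cls], int(rec["follow_up_days"])
            )
            for cls in ("human", "glargine", "detemir", "other_insulin")
        }
        ref = expand_person(
            {
                "person_id": rec["person_id"],
                "follow_up_days": rec["follow_up_days"],
                "age_at_index": rec["age_at_index"],
                "sex": rec["sex"],
                "index_year": rec["index_year"],
                "event": rec["censor_reason"] == "cancer",
            },
            eps,
            scheme,
        )
        got = by_person[rec["person_id"]].sort_values("interval_start")
        assert len(ref) == len(got)
        for row, (_, vec) in zip(ref, got.iterrows()):
            assert row["interval_start"] == vec["interval_start"]
            assert row["person_days"] == vec["person_days"]
            for cls in ("human", "glargine", "detemir"):
                assert row[f"cat_{cls}"] == vec[f"cat_{cls}"], (
                    rec["person_id"], row["interval_start"], cls
                )
                assert row[f"cum_days_{cls}"] == vec[f"cum_days_{cls}"]
            assert row["age_band"] == vec["age_band"]
            assert row["menopausal_status"] == vec["menopausal_status"]


def test_partition_invariant_per_person(small_cohort, small_intervals):
    """Summed interval person-days reproduce each follow-up exactly."""
    cohort, _, _ = small_cohort
    summed = small_intervals.groupby("person_id")["person_days"].sum()
    fu = cohort.set_index("person_id")["follow_up_days"]
    assert (summed.reindex(fu.index) == fu).all()


def test_no_immortal_time(small_intervals):
    """Every person contributes from day 0; pre-first-prescription time sits
    in the non-exposed category rather than being dropped."""
    first = small_intervals.groupby("person_id")["interval_start"].min()
    assert (first == 0).all()
    # glargine-naive person-time is categorised, not missing
    assert small_intervals["cat_glargine"].notna().all()
    assert (small_intervals["cat_glargine"] == NON_EXPOSED).any()
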