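"""New-user eligibility, censoring, diabetes type and baseline covariates."""

import pandas as pd
import pytest

from lexirate.cohort import CohortBuilder, assemble_cohort, endpoint_for_site

from conftest import make_bundle


def one_person_bundle(
    birth="1950-01-01",
    first_insulin="2000-06-15",
    extra_rx=(),
    events=(),
    sex="male",
    data_start="1996-01-01",
):
    rx = [
        {"person_id": "p1", "dispense_date": first_insulin, "atc_code": "A10AB01",
         "ddd_amount": 90.0}
    ] + [dict(r, person_id="p1") for r in extra_rx]
    ev = [dict(e, person_id="p1") for e in events]
    return make_bundle(
        persons=[{"person_id": "p1", "birth_date": birth, "sex": sex,
                  "data_start": data_start}],
        prescriptions=rx,
        events=ev,
    )


class TestEligibility:
    def test_short_lead_in_excluded(self):
        bundle = one_person_bundle(first_insulin="1996-04-10")  # 100 days after start
        cohort, log = assemble_cohort(bundle)
        assert cohort.empty
        assert log["insufficient_lead_in"] == 1

    def test_lead_in_exactly_one_year_included(self):
        bundle = one_person_bundle(first_insulin="1997-01-01")  # day 366 >= 365
        cohort, log = assemble_cohort(bundle)
        assert len(cohort) == 1

    def test_minor_at_index_excluded(self):
        bundle = one_person_bundle(birth="1983-01-01", first_insulin="2000-06-15")
        cohort, log = assemble_cohort(bundle)  # aged 17.5 at index
        assert cohort.empty
        assert log["age_lt_18"] == 1

    def test_prior_cancer_excludes(self):
        bundle = one_person_bundle(
            events=[{"event_date": "1999-01-01", "event_type": "cancer",
                     "diagnosis_code": "C34"}]
        )
        cohort, log = assemble_cohort(bundle)
        assert cohort.empty
        assert log["prior_cancer"] == 1

    def test_nmsc_history_does_not_exclude(self):
        bundle = one_person_bundle(
            events=[
                {"event_date": "1999-01-01", "event_type": "cancer", "diagnosis_code": "C44"},
                {"event_date": "2004-03-01", "event_type": "cancer", "diagnosis_code": "C18"},
            ]
        )
        cohort, _ = assemble_cohort(bundle)
        assert len(cohort) == 1
        rec = cohort.iloc[0]
        assert rec["censor_reason"] == "cancer"
        assert rec["first_cancer_sites"] == "colorectal"

    def test_cancer_on_index_date_gives_zero_follow_up_exclusion(self):
        bundle = one_person_bundle(
            events=[{"event_date": "2000-06-15", "event_type": "cancer",
                     "diagnosis_code": "C18"}]
        )
        cohort, log = assemble_cohort(bundle)
        assert cohort.empty
        assert log["zero_follow_up"] == 1


class TestCensoring:
    def test_earliest_of_death_and_admin_end(self):
        bundle = one_person_bundle(
            events=[{"event_date": "2005-02-01", "event_type": "death",
                     "diagnosis_code": ""}]
        )
        cohort, _ = assemble_cohort(bundle)
        rec = cohort.iloc[0]
        assert rec["censor_reason"] == "death"
        assert rec["follow_up_days"] == (
            pd.Timestamp("2005-02-01") - pd.Timestamp("2000-06-15")
        ).days

    def test_cancer_takes_precedence_on_same_day(self):
        bundle = one_person_bundle(
            events=[
                {"event_date": "2005-02-01", "event_type": "death", "diagnosis_code": ""},
                {"event_date": "2005-02-01", "event_type": "cancer", "diagnosis_code": "C25"},
            ]
        )
        cohort, _ = assemble_cohort(bundle)
        assert cohort.iloc[0]["censor_reason"] == "cancer"

    def test_admin_end_at_study_period_close(self):
        cohort, _ = assemble_cohort(one_person_bundle())
        rec = cohort.iloc[0]
        assert rec["censor_reason"] == "admin_end"
        assert rec["follow_up_days"] == (
            pd.Timestamp("2010-12-31") - pd.Timestamp("2000-06-15")
        ).days

    def test_emigration_censors(self):
        bundle = one_person_bundle(
            events=[{"event_date": "2003-07-01", "event_type": "emigration",
                     "diagnosis_code": ""}]
        )
        cohort, _ = assemble_cohort(bundle)
        assert cohort.iloc[0]["censor_reason"] == "emigration_or_transfer"


class TestDiabetesType:
    def test_young_without_niad_is_type1(self):
        bundle = one_person_bundle(birth="1975-06-15")  # age 25 at index
        cohort, _ = assemble_cohort(bundle)
        assert cohort.iloc[0]["diabetes_type"] == "type1"

    def test_older_with_niad_is_type2(self):
        bundle = one_person_bundle(
            birth="1938-06-15",  # age 62
            extra_rx=[{"dispense_date": "1999-10-01", "atc_code": "A10BA02",
                       "ddd_amount": 100.0}],
        )
        cohort, _ = assemble_cohort(bundle)
        assert cohort.iloc[0]["diabetes_type"] == "type2"

    def test_middle_age_is_unspecified(self):
        bundle = one_person_bundle(birth="1965-06-15")  # age 35
        cohort, _ = assemble_cohort(bundle)
        assert cohort.iloc[0]["diabetes_type"] == "unspecified"

    def test_young_with_niad_is_unspecified(self):
        bundle = one_person_bundle(
            birth="1975-06-15",
            extra_rx=[{"dispense_date": "1999-10-01", "atc_code": "A10BA02",
                       "ddd_amount": 100.0}],
        )
        cohort, _ = assemble_cohort(bundle)
        assert cohort.iloc[0]["diabetes_type"] == "unspecified"


class TestBaselineFlags:
    def test_statin_inside_window(self):
        bundle = one_person_bundle(
            extra_rx=[{"dispense_date": "1999-11-27", "atc_code": "C10AA01",
                       "ddd_amount": 100.0}]  # 200 days before index
        )
        cohort, _ = assemble_cohort(bundle)
        assert bool(cohort.iloc[0]["statin"]) is True

    def test_statin_outside_window(self):
        bundle = one_person_bundle(
            extra_rx=[{"dispense_date": "1999-05-11", "atc_code": "C10AA01",
                       "ddd_amount": 100.0}]  # 400 days before index
        )
        cohort, _ = assemble_cohort(bundle)
        assert bool(cohort.iloc[0]["statin"]) is False

    def test_hrt_always_false_for_men(self):
        bundle = one_person_bundle(
            sex="male",
            extra_rx=[{"dispense_date": "2000-01-15", "atc_code": "G03CA03",
                       "ddd_amount": 100.0}],
        )
        cohort, _ = assemble_cohort(bundle)
        assert bool(cohort.iloc[0]["hrt"]) is False

    def test_prescription_on_index_day_not_baseline(self):
        bundle = one_person_bundle(
            extra_rx=[{"dispense_date": "2000-06-15", "atc_code": "C10AA01",
                       "ddd_amount": 100.0}]
        )
        cohort, _ = assemble_cohort(bundle)
        assert bool(cohort.iloc[0]["statin"]) is False


class TestEndpoints:
    def test_same_day_primaries_count_for_both_sites(self):
        bundle = one_person_bundle(
            events=[
                {"event_date": "2004-03-01", "event_type": "cancer", "diagnosis_code": "C18"},
                {"event_date": "2004-03-01", "event_type": "cancer", "diagnosis_code": "C67"},
            ]
        )
        cohort, _ = assemble_cohort(bundle)
        rec = cohort.iloc[0]
        assert endpoint_for_site(rec, "colorectal") == 1
        assert endpoint_for_site(rec, "bladder") == 1
        assert endpoint_for_site(rec, "lung") == 0
        assert endpoint_for_site(rec, "any_cancer") == 1

    def test_death_censoring_is_no_event_for_every_site(self):
        bundle = one_person_bundle(
            events=[{"event_date": "2005-02-01", "event_type": "death",
                     "diagnosis_code": ""}]
        )
        rec = assemble_cohort(bundle)[0].iloc[0]
        for site in ("colorectal", "prostate", "any_cancer"):
            assert endpoint_for_site(rec, site) == 0

    def test_unknown_site_rejected(self):
        rec = {"censor_reason": "cancer", "first_cancer_sites": "lung"}
        with pytest.raises(ValueError):
            endpoint_for_site(rec, "appendix")


class TestAccounting:
    def test_exclusions_plus_included_equals_insulin_users(self, small_bundle):
        bundle, _ = small_bundle
        builder = CohortBuilder()
        cohort = builder.fit().transform(bundle)
        assert len(cohort) + sum(builder.exclusions_.values()) == builder.n_insulin_users_

    def test_no_prior_cancer_in_cohort(self, small_bundle, small_cohort):
        bundle, _ = small_bundle
        cohort, _, _ = small_cohort
        ev = bundle.events
        cancers = ev[(ev["event_type"] == "cancer") & (ev["diagnosis_code"] != "C44")]
        merged = cancers.merge(
            cohort[["person_id", "index_day"]], on="person_id", how="inner"
        )
        days = merged["event_date"].values.astype("datetime64[D]").astype(int)
        assert (days >= merged["index_day"].to_numpy()).all()

    def test_positive_follow_up_for_all(self, small_cohort):
        cohort, _, _ = small_cohort
        assert (cohort["follow_up_days"] > 0).all()

    def test_censor_reasons_are_valid(self, small_cohort):
        cohort, _, _ = small_cohort
        assert set(cohort["censor_reason"]) <= {
            "cancer", "death", "emigration_or_transfer", "admin_end"
        }
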