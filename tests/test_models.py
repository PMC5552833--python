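"""Poisson rate models: closed forms, likelihood sufficiency and contrasts."""

import numpy as np
import pandas as pd
import pytest

from lexirate.aggregate import aggregate
from lexirate.exposure import DAYS_PER_YEAR
from lexirate.models import (
    FitResult,
    ModelSpec,
    PoissonRateModel,
    rr_contrast,
    run_main_analysis,
    run_sensitivity,
)


def cells(rows):
    base = {
        "cat_human": "non-exposed", "cat_glargine": "non-exposed",
        "cat_detemir": "non-exposed",
    }
    return pd.DataFrame([{**base, **r} for r in rows])


class TestClosedForms:
    def test_single_cell_intercept_is_log_rate(self):
        table = cells([{"events": 10, "person_years": 1000.0}])
        m = PoissonRateModel(covariates=[], insulin_classes=()).fit(table)
        assert m.coef_["const"] == pytest.approx(np.log(0.01), abs=1e-8)

    def test_saturated_two_cell_model_reproduces_crude_ratio(self):
        table = cells(
            [
                {"events": 10, "person_years": 1000.0, "niad": False},
                {"events": 20, "person_years": 1000.0, "niad": True},
            ]
        )
        m = PoissonRateModel(covariates=["niad"], insulin_classes=()).fit(table)
        term = [c for c in m.coef_.index if c != "const"][0]
        assert np.exp(abs(m.coef_[term])) == pytest.approx(2.0, abs=1e-8)
        assert m.predict(table) == pytest.approx([10.0, 20.0], abs=1e-6)

    def test_exposure_contrast_from_saturated_cells(self):
        table = cells(
            [
                {"events": 10, "person_years": 1000.0},
                {"events": 20, "person_years": 1000.0, "cat_human": "<=0.5"},
                {"events": 25, "person_years": 1000.0, "cat_glargine": "<=0.5"},
            ]
        )
        m = PoissonRateModel(covariates=[]).fit(table)
        rr, lo, hi = m.rr_contrast("glargine", "human", "<=0.5")
        assert rr == pytest.approx(2.5 / 2.0, abs=1e-8)

    def test_contrast_against_non_exposed_reference(self):
        table = cells(
            [
                {"events": 10, "person_years": 1000.0},
                {"events": 30, "person_years": 1000.0, "cat_glargine": "<=0.5"},
            ]
        )
        m = PoissonRateModel(covariates=[], insulin_classes=("glargine",)).fit(table)
        rr, _, _ = m.rr_contrast("glargine", "glargine", "non-exposed")
        assert rr == pytest.approx(1.0)
        rr2, _, _ = m.rr_contrast("glargine", "glargine", "<=0.5")
        assert rr2 == pytest.approx(1.0)  # identity contrast, same category


class TestContrastArithmetic:
    def make_fit(self):
        idx = ["cat_glargine[1-2]", "cat_human[1-2]"]
        params = pd.Series([np.log(2.0), np.log(1.25)], index=idx)
        cov = pd.DataFrame(np.diag([0.04, 0.01]), index=idx, columns=idx)
        return FitResult(params=params, cov=cov, deviance=0.0, converged=True,
                         n_obs=2, n_events=10)

    def test_rr_is_exp_of_coefficient_difference(self):
        rr, lo, hi = rr_contrast(self.make_fit(), "glargine", "human", "1-2")
        assert rr == pytest.approx(1.6)
        se = np.sqrt(0.05)
        assert lo == pytest.approx(1.6 * np.exp(-1.96 * se))
        assert hi == pytest.approx(1.6 * np.exp(1.96 * se))

    def test_identity_contrast_degenerates_at_one(self):
        rr, lo, hi = rr_contrast(self.make_fit(), "glargine", "glargine", "1-2")
        assert (rr, lo, hi) == (1.0, 1.0, 1.0)

    def test_symmetry_reciprocal(self):
        fit = self.make_fit()
        rr_ab, lo_ab, hi_ab = rr_contrast(fit, "glargine", "human", "1-2")
        rr_ba, lo_ba, hi_ba = rr_contrast(fit, "human", "glargine", "1-2")
        assert rr_ab == pytest.approx(1 / rr_ba)
        assert lo_ab == pytest.approx(1 / hi_ba)
        assert hi_ab == pytest.approx(1 / lo_ba)

    def test_missing_category_raises_lookup_error(self):
        with pytest.raises(KeyError):
            rr_contrast(self.make_fit(), "glargine", "human", ">6")


class TestFitContracts:
    def test_zero_event_table_rejected(self):
        table = cells([{"events": 0, "person_years": 10.0}])
        with pytest.raises(ValueError, match="zero events"):
            PoissonRateModel(covariates=[], insulin_classes=()).fit(table)

    def test_covariance_symmetric_psd(self, small_cohort, small_intervals):
        cohort, _, _ = small_cohort
        table = aggregate(small_intervals, cohort)
        m = PoissonRateModel().fit(table)
        cov = m.cov_.to_numpy()
        assert np.allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > -1e-10

    def test_semi_aggregate_fit_equals_interval_level_fit(
        self, small_cohort, small_intervals
    ):
        """Collapsing to (events, PY) per covariate pattern preserves the
        Poisson likelihood: identical coefficients either way."""
        cohort, _, _ = small_cohort
        table = aggregate(small_intervals, cohort)
        m1 = PoissonRateModel().fit(table)
        ivt = small_intervals.copy()
        ivt["events"] = ivt["event_any"]
        ivt["person_years"] = ivt["person_days"] / DAYS_PER_YEAR
        m2 = PoissonRateModel().fit(ivt)
        diff = (m1.coef_ - m2.coef_.reindex(m1.coef_.index)).abs().max()
        assert diff < 1e-8


class TestModelSpec:
    def test_sex_specific_site_forbids_both(self):
        with pytest.raises(ValueError):
            ModelSpec(endpoint="breast", sex_stratum="both")

    def test_sex_stratified_models_omit_sex_covariate(self):
        spec = ModelSpec(endpoint="prostate", sex_stratum="men")
        assert "sex" not in spec.covariates
        both = ModelSpec(endpoint="any_cancer", sex_stratum="both")
        assert "sex" in both.covariates


class TestMainAnalysis:
    def test_structure_of_contrast_table(self, small_cohort, small_intervals):
        cohort, _, _ = small_cohort
        results, log = run_main_analysis(
            cohort, small_intervals, endpoints=("any_cancer",)
        )
        assert set(results["sex"]) <= {"male", "female"}
        assert set(results["contrast"]) <= {
            "glargine_vs_human", "detemir_vs_human", "glargine_vs_detemir"
        }
        assert (results["rr"] > 0).all()
        finite = results[np.isfinite(results["ci_high"])]
        assert (finite["ci_low"] <= finite["rr"]).all()
        assert (finite["rr"] <= finite["ci_high"]).all()

    def test_prostate_runs_men_only(self, small_cohort, small_intervals):
        cohort, _, _ = small_cohort
        results, log = run_main_analysis(
            cohort, small_intervals, endpoints=("prostate",)
        )
        entries = [e for e in log if e["endpoint"] == "prostate"]
        assert [e["sex"] for e in entries] == ["male"]

    def test_secondary_run_combines_sexes(self, small_cohort, small_intervals):
        cohort, _, _ = small_cohort
        results, log = run_main_analysis(
            cohort, small_intervals, scheme="fine", secondary=True,
            endpoints=("any_cancer",),
        )
        entries = [e for e in log if e["endpoint"] == "any_cancer"]
        assert [e["sex"] for e in entries] == ["both"]


class TestSensitivity:
    def test_drop_cohort_removes_country(self, small_cohort, small_intervals):
        cohort, _, _ = small_cohort
        res, log = run_sensitivity(
            cohort, small_intervals, "drop_cohort", drop_country="UK",
            endpoints=("any_cancer",),
        )
        assert all(e["status"] in ("ok", "skipped_no_events") or "failed" in e["status"]
                   for e in log)

    def test_t2d_only_on_cohort_without_t2d_is_empty_not_crash(
        self, small_cohort, small_intervals
    ):
        cohort, _, _ = small_cohort
        no_t2d = cohort[cohort["diabetes_type"] != "type2"].assign(
            diabetes_type="type1"
        ).iloc[0:0]
        res, log = run_sensitivity(no_t2d, small_intervals, "t2d_only")
        assert res.empty
        assert log[0]["status"] == "empty_cohort"

    def test_index_restriction_is_noop_when_all_post_2000(
        self, small_cohort, small_intervals
    ):
        cohort, _, _ = small_cohort
        post = cohort[cohort["index_year"] >= 2000]
        sub = small_intervals[small_intervals["person_id"].isin(set(post["person_id"]))]
        a, _ = run_main_analysis(post, sub, endpoints=("any_cancer",))
        b, _ = run_sensitivity(post, sub, "index_ge_2000", endpoints=("any_cancer",))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_variant_rejected(self, small_cohort, small_intervals):
        cohort, _, _ = small_cohort
        with pytest.raises(ValueError, match="variant"):
            run_sensitivity(cohort, small_intervals, "bootstrap")
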