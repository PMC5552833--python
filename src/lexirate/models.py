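"""Multivariable Poisson rate models and active-comparator rate-ratio contrasts.

Events in each semi-aggregate cell are modelled as Poisson counts with the
natural log of the cell's person-years as offset, so coefficients live on the
log-rate scale.  Each insulin class enters as its own categorical exposure
variable whose within-variable reference is that class's *non-exposed* level;
fitting all classes in one model lets any two be contrasted at equal
cumulative duration:

    RR(a vs b, cat) = exp(beta_a[cat] - beta_b[cat]),

with a Wald 95% CI from Var(beta_a) + Var(beta_b) - 2 Cov(beta_a, beta_b).
Because the Poisson log-likelihood depends on the data only through the
(events, person-years) sums per covariate pattern, fits on the collapsed
table and on raw interval rows coincide exactly — the identity behind the
semi-aggregate pooling of the five country cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .aggregate import (
    SEX_SPECIFIC_SITES,
    PersonTimeAggregator,
    covariate_columns,
)
from .exposure import NON_EXPOSED, CategoryScheme

__all__ = [
    "ModelSpec",
    "PoissonRateModel",
    "fit_poisson",
    "rr_contrast",
    "run_main_analysis",
    "run_sensitivity",
    "MAIN_SITES",
]

#: The ten site-specific cancers of primary interest.
MAIN_SITES = (
    "liver", "pancreas", "lung", "melanoma", "bladder",
    "colorectal", "nhl", "breast", "endometrial", "prostate",
)

DEFAULT_CLASSES = ("human", "glargine", "detemir")


@dataclass(frozen=True)
class ModelSpec:
    """What one Poisson model adjusts for and which exposures it carries."""

    endpoint: str = "any_cancer"
    sex_stratum: str = "both"  # {"men"/"male", "women"/"female", "both"}
    scheme: str = "broad"
    insulin_classes: tuple[str, ...] = DEFAULT_CLASSES
    adjust_menopause: bool = False

    def __post_init__(self) -> None:
        stratum = _canon_sex(self.sex_stratum)
        restrict = SEX_SPECIFIC_SITES.get(self.endpoint)
        if restrict is not None and stratum == "both":
            raise ValueError(
                f"{self.endpoint} is sex-specific; sex_stratum='both' is not allowed"
            )

    @property
    def covariates(self) -> list[str]:
        return covariate_columns(
            self.endpoint, _canon_sex(self.sex_stratum), self.adjust_menopause
        )


def _canon_sex(s: str) -> str:
    return {"men": "male", "women": "female"}.get(s, s)


class RankDeficiencyError(np.linalg.LinAlgError):
    """Design matrix not full rank; message names the aliased columns."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the iteration trace."""


@dataclass
class FitResult:
    """Converged Poisson MLE on the log-rate scale."""

    params: pd.Series
    cov: pd.DataFrame
    deviance: float
    converged: bool
    n_obs: int
    n_events: int
    events_per_level: dict[str, int] = field(default_factory=dict)
    dropped_levels: tuple[str, ...] = ()
    stalled: bool = False  # accepted on a quasi-separation ridge

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov.loc[term, term]))


class PoissonRateModel(BaseEstimator):
    """Poisson regression on a semi-aggregate table (sklearn-style estimator).

    Parameters
    ----------
    covariates : list of str or None
        Categorical adjustment terms; None derives them from ``endpoint`` /
        ``sex_stratum`` (country, age band, calendar band, duration band,
        NIAD, sex when both sexes are modelled, plus site-relevant
        co-medication).
    insulin_classes : tuple of str
        Exposure variables entering the model (each with its own
        non-exposed reference).
    scheme : {"broad", "fine"}
        Duration-category scheme of the ``cat_<class>`` columns.
    tol : float
        Relative convergence tolerance of the IRLS deviance (1e-10).

    Fitted attributes: ``coef_`` (pd.Series), ``cov_`` (pd.DataFrame),
    ``deviance_``, ``converged_``, ``result_`` (:class:`FitResult`).
    """

    def __init__(
        self,
        endpoint: str = "any_cancer",
        sex_stratum: str = "both",
        covariates: list[str] | None = None,
        insulin_classes: tuple[str, ...] = DEFAULT_CLASSES,
        scheme: str = "broad",
        adjust_menopause: bool = False,
        tol: float = 1e-10,
        maxiter: int = 100,
    ):
        self.endpoint = endpoint
        self.sex_stratum = sex_stratum
        self.covariates = covariates
        self.insulin_classes = insulin_classes
        self.scheme = scheme
        self.adjust_menopause = adjust_menopause
        self.tol = tol
        self.maxiter = maxiter

    # -- design ----------------------------------------------------------
    def _covariate_list(self, table: pd.DataFrame) -> list[str]:
        covs = (
            self.covariates
            if self.covariates is not None
            else covariate_columns(
                self.endpoint, _canon_sex(self.sex_stratum), self.adjust_menopause
            )
        )
        return [c for c in covs if c in table.columns]

    def _reduce_separation(
        self, table: pd.DataFrame
    ) -> tuple[pd.DataFrame, tuple[str, ...]]:
        """Remove rows of zero-event non-reference levels (iteratively).

        A categorical level whose cells carry person-time but no events sends
        its coefficient to -inf; the limit of the likelihood equals the
        likelihood with those cells removed and the level's column dropped,
        so the reduced fit *is* the limiting MLE of the remaining terms.
        References: the event-richest level per covariate, non-exposed per
        exposure variable (never removed).
        """
        covs = self._covariate_list(table)
        cat_cols = [f"cat_{c}" for c in self.insulin_classes]
        work = table.reset_index(drop=True)
        removed: list[str] = []
        while True:
            hit = np.zeros(len(work), dtype=bool)
            for col in covs + cat_cols:
                ev = work.groupby(col, observed=True)["events"].sum()
                ref = NON_EXPOSED if col in cat_cols else ev.idxmax()
                for lev, tot in ev.items():
                    if tot == 0 and lev != ref:
                        hit |= (work[col] == lev).to_numpy()
                        removed.append(f"{col}[{lev}]")
            if not hit.any():
                break
            work = work[~hit].reset_index(drop=True)
        return work, tuple(removed)

    def _design(self, table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
        covs = self._covariate_list(table)
        scheme = CategoryScheme.by_name(self.scheme)
        cols = {"const": np.ones(len(table))}
        dropped: list[str] = []
        events = table["events"].to_numpy()
        events_per_level: dict[str, int] = {}
        for cov in covs:
            ev = table.groupby(cov, observed=True)["events"].sum()
            ref = ev.idxmax()  # event-richest level anchors the covariate
            for lev in sorted(map(str, ev.index)):
                if lev == str(ref):
                    continue
                mask = (table[cov].astype(str) == lev).to_numpy()
                cols[f"{cov}[{lev}]"] = mask.astype(float)
        for cls in self.insulin_classes:
            col = f"cat_{cls}"
            vals = table[col].astype(str)
            for lev in scheme.labels:  # reference: non-exposed
                mask = (vals == lev).to_numpy()
                name = f"{col}[{lev}]"
                if not mask.any():
                    dropped.append(name)
                    continue
                cols[name] = mask.astype(float)
                events_per_level[name] = int(events[mask].sum())
        X = pd.DataFrame(cols, index=table.index)
        self._events_per_level = events_per_level
        self._dropped = tuple(dropped)  # reported via FitResult.dropped_levels
        return X, covs

    # -- estimator API ----------------------------------------------------
    def fit(self, table: pd.DataFrame, y=None) -> "PoissonRateModel":
        """Fit the model to a semi-aggregate table (events, person_years)."""
        if (table["events"] < 0).any():
            raise ValueError("negative event counts")
        if int(table["events"].sum()) == 0:
            raise ValueError("table has zero events; model is not identifiable")
        table, removed = self._reduce_separation(table)
        X, _ = self._design(table)
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            aliased = _aliased_columns(X)
            raise RankDeficiencyError(
                f"design matrix rank {rank} < {X.shape[1]}; aliased terms: {aliased}"
            )
        offset = np.log(table["person_years"].to_numpy())
        model = sm.GLM(
            table["events"].to_numpy(), X, family=sm.families.Poisson(), offset=offset
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=self.maxiter, tol=self.tol, scale=1.0)
        # contract: converged when the *relative* log-likelihood (deviance)
        # change drops below tol; statsmodels' own criterion is absolute, so
        # assess the trace ourselves.  With zero-event exposure levels the
        # MLE drifts to -inf (separation) while the deviance settles — that
        # counts as converged; the level's huge variance speaks for itself.
        trace = getattr(res, "fit_history", {}).get("deviance", [])
        self.stalled_ = False
        if not res.converged:
            rel = (
                abs(trace[-1] - trace[-2]) / (abs(trace[-1]) + 1e-8)
                if len(trace) >= 2
                else np.inf
            )
            if rel < self.tol:
                pass  # met the relative criterion even if statsmodels' absolute one failed
            elif rel < 1e-8:
                # quasi-separation: the deviance creeps along a flat ridge
                # (some parameter *combination* is unbounded).  The finite
                # part of the fit is settled; accept it and flag the stall.
                self.stalled_ = True
            else:
                raise ConvergenceError(
                    f"IRLS did not converge in {self.maxiter} iterations "
                    f"(deviance trace tail: {trace[-5:]})"
                )
        self.coef_ = pd.Series(res.params, index=X.columns)
        self.cov_ = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
        self.deviance_ = float(res.deviance)
        self.converged_ = bool(res.converged)
        self.result_ = FitResult(
            params=self.coef_,
            cov=self.cov_,
            deviance=self.deviance_,
            converged=self.converged_,
            n_obs=len(table),
            n_events=int(table["events"].sum()),
            events_per_level=dict(self._events_per_level),
            dropped_levels=self._dropped + removed,
            stalled=self.stalled_,
        )
        return self

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Expected event counts for the rows of a semi-aggregate table."""
        X, _ = self._design(table)
        X = X.reindex(columns=self.coef_.index, fill_value=0.0)
        return np.exp(
            X.to_numpy() @ self.coef_.to_numpy()
            + np.log(table["person_years"].to_numpy())
        )

    # -- contrasts --------------------------------------------------------
    def _term(self, insulin: str, category: str) -> str | None:
        if category == NON_EXPOSED:
            return None  # within-variable reference
        name = f"cat_{insulin}[{category}]"
        if name not in self.coef_.index:
            raise KeyError(
                f"category {category!r} of {insulin!r} not in the fitted model "
                f"(empty level or unknown label)"
            )
        return name

    def rr_contrast(
        self, insulin_a: str, insulin_b: str, category: str, alpha: float = 0.05
    ) -> tuple[float, float, float]:
        """Rate ratio of ``insulin_a`` vs ``insulin_b`` at equal cumulative
        duration, with a Wald (1 − alpha) CI."""
        ta, tb = self._term(insulin_a, category), self._term(insulin_b, category)
        beta_a = self.coef_[ta] if ta else 0.0
        beta_b = self.coef_[tb] if tb else 0.0
        var = 0.0
        if ta:
            var += self.cov_.loc[ta, ta]
        if tb:
            var += self.cov_.loc[tb, tb]
        if ta and tb:
            var -= 2 * self.cov_.loc[ta, tb]
        diff = beta_a - beta_b
        # 1.96 at the conventional level (normal-theory 95% CI); exact
        # quantile for any other alpha
        z = 1.96 if alpha == 0.05 else float(stats_norm_ppf(1 - alpha / 2))
        se = float(np.sqrt(max(var, 0.0)))
        with np.errstate(over="ignore"):  # separation-sized SEs give inf bounds
            return (
                float(np.exp(diff)),
                float(np.exp(diff - z * se)),
                float(np.exp(diff + z * se)),
            )

    def contrast_stats(
        self, insulin_a: str, insulin_b: str, category: str
    ) -> tuple[float, float]:
        """(log-RR difference, its SE) for a Wald test of RR = 1."""
        ta, tb = self._term(insulin_a, category), self._term(insulin_b, category)
        beta_a = self.coef_[ta] if ta else 0.0
        beta_b = self.coef_[tb] if tb else 0.0
        var = 0.0
        if ta:
            var += self.cov_.loc[ta, ta]
        if tb:
            var += self.cov_.loc[tb, tb]
        if ta and tb:
            var -= 2 * self.cov_.loc[ta, tb]
        return float(beta_a - beta_b), float(np.sqrt(max(var, 0.0)))


def stats_norm_ppf(q: float) -> float:
    from scipy.stats import norm

    return norm.ppf(q)


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns involved in exact collinearity, found via QR pivoting."""
    arr = X.to_numpy()
    q, r = np.linalg.qr(arr)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    return [c for c, d in zip(X.columns, diag) if d < tol]


def fit_poisson(
    table: pd.DataFrame, spec: ModelSpec | None = None, **kwargs
) -> FitResult:
    """Functional wrapper: fit a Poisson model and return its FitResult."""
    spec = spec or ModelSpec()
    model = PoissonRateModel(
        endpoint=spec.endpoint,
        sex_stratum=spec.sex_stratum,
        insulin_classes=spec.insulin_classes,
        scheme=spec.scheme,
        adjust_menopause=spec.adjust_menopause,
        **kwargs,
    )
    model.fit(table)
    return model.result_


def rr_contrast(
    fit: FitResult, insulin_a: str, insulin_b: str, category: str
) -> tuple[float, float, float]:
    """RR and Wald 95% CI for a contrast, from a bare :class:`FitResult`."""
    model = PoissonRateModel()
    model.coef_ = fit.params
    model.cov_ = fit.cov
    return model.rr_contrast(insulin_a, insulin_b, category)


_CONTRAST_PAIRS = (
    ("glargine", "human"),
    ("detemir", "human"),
    ("glargine", "detemir"),
)


def _strata_for(endpoint: str, secondary: bool) -> list[str]:
    restrict = SEX_SPECIFIC_SITES.get(endpoint)
    if restrict is not None:
        return [restrict]
    return ["both"] if secondary else ["male", "female"]


def run_main_analysis(
    cohort: pd.DataFrame,
    intervals: pd.DataFrame,
    scheme: str = "broad",
    secondary: bool = False,
    insulin_classes: tuple[str, ...] = DEFAULT_CLASSES,
    endpoints: tuple[str, ...] | None = None,
    adjust_menopause: bool = False,
) -> tuple[pd.DataFrame, list[dict]]:
    """Fit all endpoint × sex-stratum models and emit the RR contrast table.

    Primary run: sex- and site-specific endpoints plus any cancer, broad
    scheme.  Secondary run (``secondary=True``): both sexes combined
    (sex-specific sites keep their single sex) with the fine scheme.
    Endpoints with zero events are skipped and logged.
    """
    sites = tuple(endpoints) if endpoints is not None else MAIN_SITES + ("any_cancer",)
    cat_scheme = CategoryScheme.by_name(scheme)
    rows: list[dict] = []
    log: list[dict] = []
    for endpoint in sites:
        for stratum in _strata_for(endpoint, secondary):
            agg = PersonTimeAggregator(
                endpoint=endpoint,
                sex_stratum=stratum,
                exposure_classes=insulin_classes,
                adjust_menopause=adjust_menopause and endpoint in ("breast", "endometrial"),
            )
            table = agg.fit().transform(intervals, cohort=cohort)
            n_events = int(table["events"].sum())
            if n_events == 0:
                log.append(
                    {"endpoint": endpoint, "sex": stratum, "status": "skipped_no_events"}
                )
                continue
            model = PoissonRateModel(
                endpoint=endpoint,
                sex_stratum=stratum,
                insulin_classes=insulin_classes,
                scheme=scheme,
                adjust_menopause=agg.adjust_menopause,
            )
            try:
                model.fit(table)
            except (RankDeficiencyError, ConvergenceError, ValueError) as err:
                log.append(
                    {"endpoint": endpoint, "sex": stratum, "status": f"failed: {err}"}
                )
                continue
            log.append(
                {
                    "endpoint": endpoint,
                    "sex": stratum,
                    "status": "ok",
                    "n_events": n_events,
                    "deviance": model.deviance_,
                    "stalled": model.result_.stalled,
                    "dropped_levels": list(model.result_.dropped_levels),
                }
            )
            epl = model.result_.events_per_level
            for a, b in _CONTRAST_PAIRS:
                if a not in insulin_classes or b not in insulin_classes:
                    continue
                for cat in cat_scheme.labels:
                    ta, tb = f"cat_{a}[{cat}]", f"cat_{b}[{cat}]"
                    if ta not in model.coef_.index or tb not in model.coef_.index:
                        continue
                    rr, lo, hi = model.rr_contrast(a, b, cat)
                    rows.append(
                        {
                            "endpoint": endpoint,
                            "sex": stratum,
                            "scheme": scheme,
                            "contrast": f"{a}_vs_{b}",
                            "category": cat,
                            "rr": rr,
                            "ci_low": lo,
                            "ci_high": hi,
                            "n_events_a": epl.get(ta, 0),
                            "n_events_b": epl.get(tb, 0),
                        }
                    )
    result = pd.DataFrame(
        rows,
        columns=[
            "endpoint", "sex", "scheme", "contrast", "category",
            "rr", "ci_low", "ci_high", "n_events_a", "n_events_b",
        ],
    )
    if len(result):
        result["n_comparisons"] = len(result)
    return result, log


def run_sensitivity(
    cohort: pd.DataFrame,
    intervals: pd.DataFrame,
    variant: str,
    scheme: str = "broad",
    drop_country: str | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, list[dict]]:
    """Re-run the main analysis under a sensitivity specification.

    Variants: ``t2d_only`` (type 2 diabetes criteria), ``index_ge_2000``
    (index date from 2000 on), ``drop_cohort`` (remove one country, pass
    ``drop_country``), ``adjust_menopause`` (menopausal status into the
    breast/endometrial models).
    """
    if variant == "t2d_only":
        keep = cohort[cohort["diabetes_type"] == "type2"]
    elif variant == "index_ge_2000":
        cutoff = pd.Timestamp("2000-01-01")
        keep = cohort[cohort["index_year"] >= cutoff.year]
    elif variant == "drop_cohort":
        if drop_country is None:
            raise ValueError("drop_cohort needs drop_country")
        keep = cohort[cohort["country"] != drop_country]
    elif variant == "adjust_menopause":
        keep = cohort
        kwargs["adjust_menopause"] = True
    else:
        raise ValueError(f"unknown sensitivity variant {variant!r}")
    if keep.empty:
        return pd.DataFrame(), [{"variant": variant, "status": "empty_cohort"}]
    sub = intervals[intervals["person_id"].isin(set(keep["person_id"]))]
    return run_main_analysis(keep, sub, scheme=scheme, **kwargs)
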