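# Methods

`lexirate` implements a registry-based, new-user, active-comparator cohort
analysis of time-varying cumulative drug exposure, in the form used by
multi-country insulin–cancer safety studies: prescription records are turned
into covered-time episodes, follow-up is split on a 120-day grid, person-time
is pooled as semi-aggregate event/person-year tables, and incidence is
modelled with Poisson regression whose coefficients yield duration-specific
rate-ratio contrasts between insulin classes. This note records the model,
the parameters that matter, what the synthetic registries do and do not
emulate, and the numerical choices where the design was genuinely open.

## Study design encoded in the pipeline

**New-user design.** A person enters at the first-ever insulin dispensing
(the index date) and only if at least 365 days of observable registry time
precede it. Observable time starts at max(person's data start, country study
period start); entering observation mid-study therefore starts the lead-in
clock then, not at the registry's founding. The lead-in length is a
parameter (`CohortBuilder(lead_in_days=...)`).

**Eligibility.** Age ≥ 18 years at index; no cancer history other than
non-melanoma skin cancer (NMSC, ICD-10 C44). Exclusions are counted once per
person, under the first failing criterion in the fixed order lead-in → age →
cancer history → zero follow-up.

**Follow-up and censoring.** Person-time runs over the half-open interval
[index, censor), where the censor date is the earliest of: first non-NMSC
cancer, death, emigration/transfer-out, end of the person's data, end of the
country's study period. On same-day ties the outcome wins (cancer before
death): registries resolve dates to the day, and the outcome is the quantity
of interest. Site-specific analyses are censored at the first cancer of
*any* non-NMSC site — another site's cancer ends follow-up without an event.
Multiple primaries recorded on one date count as events for each of their
site-specific endpoints.

**Active comparator.** Human insulin is the comparison treatment: it shares
the indication with the analogues, so contrasts between exposure categories
of equal cumulative duration largely cancel confounding by indication and
time-on-treatment effects.

## Exposure model

Each dispensing of *d* DDDs covers ⌈*d*⌉ days at an assumed 1 DDD/day. A
purchase made while coverage remains extends coverage from the current
coverage end (stockpiling carry-forward); a purchase after a gap starts a new
episode at its dispense date. Cumulative treatment time counts *covered* days
only: it freezes in gaps and resumes on re-dispensing. Two switches modify
this: `stockpile=False` replaces carry-forward by the union of per-purchase
windows, and `grace_days=g` bridges gaps of at most *g* days (bridged days
count as exposed). Both default to the strict reading (carry-forward, no
grace); the grace option exists because "exposure stopped" is genuinely
ambiguous between a strict covered-days and a lenient calendar-time reading,
and the two settings bracket the possibilities.

Follow-up is split at 0, 120, 240, … days from index. At each interval start
the cumulative covered days of every insulin class are evaluated and binned:

* broad scheme: non-exposed, ≤0.5, 0.5–1, 1–2, …, 5–6, >6 years;
* fine scheme: the same to 6 years, then 1-year bins with terminal 9–10.

Bins are half-open on the left, (lo, hi], so exactly half a year still falls
in "≤0.5"; an exposed person with zero accrued days (evaluated at the moment
exposure starts) sits in the first bin; years = days/365.25. The category is
frozen within each 120-day interval even when a boundary is crossed
mid-interval. Time before a class's first dispensing is that class's
non-exposed category — it is modelled, never dropped, which is what removes
immortal-time bias.

A brute-force day-level oracle (`day_level_oracle`) re-derives coverage by
simulating the DDD stock one day at a time; the interval engine is required
(and tested) to agree with it exactly, on hand-built cases, on randomised
prescription histories, and on >1000 full synthetic persons.

## Covariates

Time-dependent: age in decade bands (18–30 … 80+), duration of
insulin-treated diabetes (years since index, 1-year bands, capped at the
exposure scheme's terminal boundary to avoid aliasing against the exposure
categories in small cohorts), menopausal status for women (post iff age ≥ 50
at the interval start). Time-fixed: sex (when both sexes are modelled),
country, baseline calendar time (index year in 3-year bins, configurable),
baseline use of non-insulin antidiabetic drugs (NIAD, ATC A10B), and
site-relevant co-medication — statins (C10A) and NSAIDs (M01A) for liver and
colorectal cancer, those plus HRT (G03) for breast and endometrial cancer.
Baseline use means ≥1 dispensing in [index − 365 d, index); HRT is evaluated
for women only. Diabetes type is a proxy: type 1 iff age ≤ 30 and no NIAD on
or before index, type 2 iff age ≥ 40, otherwise unspecified; it stratifies a
sensitivity analysis rather than entering the models.

## Statistical model

Events in each semi-aggregate cell (events and person-years cross-classified
by all categorical covariates plus the exposure category of each modelled
insulin class) are Poisson with log person-years offset:

    E[events] = PY · exp(β₀ + Σ covariates + Σ_class β_class[cat_class]).

The semi-aggregate table carries the complete sufficient statistics of this
likelihood, so the collapsed fit equals the individual-level fit exactly;
the suite asserts coefficient agreement to 1e-8 (observed ~1e-14). This is
what lets multiple countries pool results without sharing records.

Each insulin class is its own categorical variable whose reference is that
class's *non-exposed* level. With all classes in one model, two treatments
are contrasted at equal cumulative duration:

    RR = exp(β_a[cat] − β_b[cat]),
    SE² = Var(β_a) + Var(β_b) − 2 Cov(β_a, β_b),

with a 1.96-normal (Wald) 95% CI. The other-insulin class's timeline is
computed but not modelled by default (`insulin_classes` switches this).
No multiple-testing correction is applied; the contrast table carries an
`n_comparisons` column instead.

### Numerical choices

* Fitting is IRLS on the Poisson GLM (via statsmodels) with convergence at
  relative deviance change < 1e-10.
* A categorical level carrying person-time but **zero events** sends its
  coefficient to −∞ (separation). The likelihood's limit equals the
  likelihood with that level's rows removed, so the model removes such
  levels (iteratively) before fitting and reports them as dropped; the
  reduced fit *is* the limiting MLE of the remaining terms. Reference
  levels are exempt: exposure variables keep non-exposed as reference, and
  ordinary covariates use their event-richest level as reference so the
  anchor can never be event-free.
* Quasi-separation along a *combination* of parameters can leave the
  deviance creeping down a flat ridge; fits whose per-iteration relative
  change has fallen below 1e-8 (R's `glm` criterion) are accepted and
  flagged `stalled` in the diagnostics. Affected contrasts are visible
  through very large standard errors.
* Exact rank deficiency raises an error naming the aliased columns; the
  analysis driver logs it and continues with the other endpoints.
* Crude incidence rates use the exact (Garwood) Poisson interval,
  lo = χ²(0.025, 2k)/(2T), hi = χ²(0.975, 2(k+1))/(2T), and the registry
  confidentiality rule: cells with 1–5 events publish the count but not the
  rate.

## Synthetic registries

The generator emulates five country cohorts (DK, FI, NO, SE, UK) with the
size proportions, age mixture (decade bands), sex ratio (56% male) and study
periods of the published five-country insulin cohorts, at a desk-scale
default of 5,000 persons. Prescribing is semi-Markov: an initial class
(human 75%, glargine 15%, detemir 7%, other 3%), refills of ~90 DDDs every
~90 days (σ = 21, minimum 30), and per-refill stopping (1.5%) and switching
(2%) probabilities. Baseline co-medication is drawn as independent flags
(NIAD 75%, statin 40%, NSAID 25%, HRT 16% of women). Death (5.5%/year) and
emigration (0.4%/year) censor; small fractions of short lead-in (5%),
under-18 entry (1.5%) and cancer history (3%) exercise the exclusion rules.

Cancer arises from piecewise-constant per-site hazards (summing to ≈15
events/1000 PY of any cancer, with breast/endometrial restricted to women
and prostate to men) multiplied by exp(Σ true log-RR) of the person's
current exposure categories — evaluated with the *analysis's own* episode
engine and 120-day grid, so the scenario's declared rate ratio is exactly
the model contrast being estimated and recovery tests are clean parameter
recovery, not grid-mismatch studies. The multiplier applies to all sites
alike, making the site distribution independent of exposure. NMSC occurs as
an independent process that does not end follow-up. Output is a pure
function of (scenario, seed).

What the generator does **not** emulate: confounding structure (baseline
flags are independent of both exposure and outcome), country-specific
prescribing calibration, dose variation relevant to dose–response, secular
trends, or differential data quality between registries. Passing recovery
and calibration tests therefore demonstrates that the *estimator machinery*
is unbiased and calibrated under the stated generating model — not that any
particular real-world confounder is handled.

## Monte-Carlo calibration

Two studies run the entire chain per replicate on the any-cancer endpoint:

Both work on a duration-category set fixed in advance — ≤0.5, 0.5–1, 1–2
and 2–3 years, the bins the ~4.5-year mean follow-up keeps well populated.
Anything data-dependent in their construction would distort them:
inverse-variance weights couple the weights to the estimates and bias a
pooled contrast upward, and including or excluding categories by their
observed event counts conditions on the very counts the Wald statistic is
built from (a category drops out exactly when one arm fluctuated low, i.e.
when the test would have rejected), tilting the null rejection rate. Both
studies therefore use the fixed set with equal weights and no count-based
filtering; a category removed from a model entirely (no events anywhere)
is skipped.

* **Recovery** — constant glargine-vs-human RR 1.5, 200 replicates of 8,000
  persons; the per-replicate estimate is the equal-weight average of the
  four per-category contrasts, with the variance from the full coefficient
  covariance. Checks: |mean − log 1.5| ≤ 3 Monte-Carlo SEs; CI coverage
  within binomial bounds of 0.95.
* **Type-I calibration** — null scenario, 200 replicates of 8,000 persons;
  every glargine/detemir-vs-human contrast on the fixed set is Wald-tested,
  and the pooled rejection rate must lie within binomial 95% bounds of 0.05.

Replicate cohort sizes are the package's desk-scale choice: large enough for
the Poisson MLE's asymptotics to hold for the pooled contrast (the estimator
is consistent but, like any log-linear MLE, finitely biased when ~45
parameters chase ~100 events), small enough that a few hundred full-pipeline
replicates run on one CPU in minutes.

## Known limitations

* CPRD-style Read-code dictionaries and DDD derivation from free-text dosage
  are out of scope; the data model takes DDDs as given.
* Crude rates are unstandardised by design; no age-adjusted rates.
* Site-specific models on desk-scale synthetic cohorts are event-poor; the
  separation handling above keeps them honest but their contrasts are wide.
* The day-level oracle is O(days) per person and intended for tests only.
* Calendar-band and age-band widths inside the models are defaults
  (3-year / decade), configurable but not data-driven.
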