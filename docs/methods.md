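# Methods

## Problem and model

`savakit` quantifies small-area variation in elective-surgery admission
rates. The setting is a province partitioned into k health districts; for a
given procedure and observation period, district i contributes an observed
admission count y_i and an expected count e_i obtained by indirect age–sex
standardization (the pooled stratum rates of the whole province, applied to
district i's own population structure). The statistic of interest is the
systematic component of variation,

    SCV = (1/k) · ( Σ_i (y_i − e_i)² / e_i²  −  Σ_i 1/e_i ),

reported on a ×100 scale. Under the working model y_i ~ Poisson(e_i·λ_i)
with district relative risks λ_i i.i.d., E[λ]=1, Var[λ]=σ², we have
E[(y_i−e_i)²/e_i²] = σ² + 1/e_i, so the second term subtracts the variance
contribution of Poisson noise and the statistic is an unbiased estimator of
100·σ² — the *systematic*, not random, between-district variation. The
estimator can be negative in finite samples; it is reported as computed,
never truncated at zero, because truncation would bias the parameter
recovery that the test-suite verifies.

SCV values are read on a five-level scale with left-closed intervals:
below 1 no variation, [1,3) minimal, [3,6) medium, [6,10) high, and 10 or
more very high. The boundary handling ("between 1 and 3" read as [1,3)) is a
design choice, made for consistency with "less than 1" defining the lowest
class; `classify_scv` is monotone in its argument by construction.

Auxiliary spread measures on district rates: range (max − min), extremal
quotient (max/min, reported as undefined rather than infinite when the
minimum rate is 0), sample standard deviation (n−1 denominator; the choice
of denominator is ours, and documented here because the convention varies),
and coefficient of variation (SD/mean).

## Standardization

Rates are stratified by 5-year age band (0–4 … 80–84, 85+) and sex;
the banding is configurable. Person-years for a multi-year period are the
sum of the annual population counts over its years, so all rates are per
person-year and reported at a configurable scale (per 1,000 for overall
admissions, per 100,000 for individual procedures). Whether published
two-year rates of this kind are annualized or cumulative is generally
ambiguous; per person-year is the self-consistent choice and is applied
uniformly.

* Direct method: `direct_standardized_rate` is the standard-population-
  weighted mean of an area's stratum rates. Strata with zero person-years
  are dropped from both the numerator and the weight mass (logged); a
  zero-population stratum carrying events is a hard error, as is a standard
  population with no weight on any defined stratum.
* Indirect method: `expected_events` applies pooled stratum rates to the
  area's person-years. In the pipeline each period is **self-standardized**:
  the standard rates are pooled over exactly the analysed areas and that
  period's own data, which guarantees Σ_i e_i = Σ_i y_i per procedure and
  period (verified to 1e-9 relative in the tests). This conservation is what
  makes SCV values comparable across periods with very different volumes.
* Per-procedure rate denominators are the person-years of the age bands
  that intersect the procedure's age bounds (whole bands; a band partially
  covered by a bound, such as 15–19 under a ≤17 rule, is counted in full).
  The synthetic generator uses the same convention, so generated rates and
  analysed rates are directly comparable.

## Confidence intervals

Published SCV confidence intervals for this kind of analysis rarely state a
method, so the interval here is the package's own choice: a parametric
bootstrap. Replicates draw y_i* ~ Poisson(e_i · y_i/e_i) with e_i held
fixed and recompute the SCV; the interval is the percentile interval
(default level 0.95, B = 1000, mandatory seed, deterministic given the
seed). One analytic consequence, exercised in the tests: every replicate
SCV is bounded below by −(100/k)·Σ1/e_i, so when y = e the point estimate
sits exactly at that support infimum and the percentile interval lies at or
above it while covering the true no-variation value 0.

## Cohort definitions and filters

Discharge abstracts are filtered in two stages.

Record-level eligibility: public-hospital admissions of residents of the
configured areas, with the discharge-date year inside the study period
(period membership is keyed on the discharge date). Non-resident rows are
dropped with a log message by default, or can be made a hard error.

Cohort-level inclusion, per procedure: any listed ICD-9-CM procedure code
(exact match on dotted codes by default; prefix matching is opt-in), integer
age at admission within inclusive bounds ("≤ 17" and "≥ 65" include the
boundary ages), and no diagnosis code — principal **or** secondary, the
stricter reading — in an excluded category. Categories map to configurable
ICD-9-CM chapter ranges: neoplasm 140–239, trauma 800–959, poisoning
960–989, femoral-neck fracture 820.x. V and E codes never match the numeric
ranges. An admission listing two qualifying codes of the same cohort counts
once (deduplication by record id); admissions, not patients, are the unit
of analysis — readmissions count separately. The five default cohorts:

| cohort | codes | age | excluded diagnoses |
|---|---|---|---|
| tonsillectomy | 28.2, 28.3 | ≤ 17 | neoplasm, trauma, poisoning |
| hip replacement | 81.51, 81.52 | ≥ 65 | femoral-neck fracture |
| knee replacement | 81.54 | — | trauma |
| vein stripping | 38.59 | — | — |
| knee arthroscopy | 80.26 | — | — |

Knee arthroscopy and vein stripping carry no diagnosis exclusions by
definition, so excluded-diagnosis decoys are never generated for them.

## Synthetic data generator

The generator emulates a four-district province of 500,000 inhabitants
(district shares 45/26/15/14 %) observed over 2018–2021, with a constant,
plausible age pyramid split evenly by sex. Each procedure has a baseline
rate per 100,000 age-eligible person-years (defaults of pre-pandemic
magnitude: tonsillectomy 315.72, hip replacement 491.35, knee replacement
171.10, vein stripping 35.71, knee arthroscopy 255.02 — scenario defaults,
not ground-truth claims about any real province). District relative risks
λ_i are i.i.d. gamma (shape 1/σ², scale σ²) or lognormal
(μ = −½·log(1+σ²), s² = log(1+σ²)), both with mean 1 and variance σ²
(default 0.05, so the true SCV on the ×100 scale is 5); σ² = 0 forces
λ_i = 1 exactly. Years from 2020 onward are multiplied by a per-procedure
reduction factor (defaults 0.43 / 0.75 / 0.73 / 0.24 / 0.66, producing
count reductions of roughly 57/25/27/76/34 % — the magnitudes seen for
these procedures during the pandemic). Cell counts are Poisson; each event
becomes one record with an age drawn uniformly in its band intersected with
the procedure's bounds and a date drawn uniformly in its year.

Decoy records exercise the filters: private-hospital admissions,
excluded-diagnosis admissions, and out-of-age admissions, each at rate 0.05
relative to the local true-event intensity (a value chosen once as "small
but non-negligible"). The truth report carries every λ_i, the per
(procedure, year, district) true counts, all decoy record ids and the
implied SCV target 100·σ², so tests can verify that the filters remove
every decoy and, with decoys disabled, recover the generated counts
exactly. Everything is reproducible from the scenario seed.

What the generator does **not** emulate: patient identity and readmission
structure, cross-district patient flows to hospitals, waiting-list dynamics,
within-district heterogeneity, secular trends, or seasonality. Passing
tests therefore show that the statistics and filters behave correctly under
the stated Poisson/relative-risk model, not that real discharge data meet
that model.

## Pipeline

`run_analysis` performs the two-phase comparison: phase 1 builds overall
(per 1,000) and per-procedure (per 100,000) rate tables per district and
period with percent changes; phase 2 computes per procedure and period the
self-standardized area counts and the SCV with CI and classification.
Percent changes are 100·(after − before)/before, kept at full precision
internally and rounded to integers in the rendered report (rates to two
decimals, SCV to two decimals); a non-positive baseline yields an
explicit NA, never a division error. A procedure with an empty cohort in a
period is flagged "no events" and gets no SCV. Per-run bootstrap seeds are
derived deterministically from the config seed and the (procedure, period)
position, so a re-run with the same inputs and seed is byte-identical.
Filter-stage record counts (raw → eligible → cohort) are logged in the
report and are non-increasing by construction. Any analysed area with zero
population in a period is a hard error naming the area and period.

Indexed rates against an external multi-region reference (reference mean
= 100) are supported only through `indexed_rate` with a user-supplied
reference mean; no external benchmarking data is bundled or fetched.

## Problem sizes used by the checks

The parameter-recovery check uses k = 50 equally sized areas with expected
counts of 200 and 500 replicates, where the Monte-Carlo standard error of
the mean SCV is ≈ 0.05 — small enough to resolve the target of 5.0. The
four-district default scenario is deliberately noisy (a single draw of four
λ_i is a poor estimate of σ²), which is why recovery is asserted at k = 50
and the k = 4 scenario is used for structural checks (conservation, decoy
filtering, determinism, report consistency).

## Known limitations

* Published per-district SCV values for the real province are **not**
  reproducible from published material alone: the district-level age–sex
  population structure that fixes the e_i is not public, and rate tables
  round to two decimals. The package therefore validates the statistic by
  exact-arithmetic oracle, by parameter recovery on synthetic data, and by
  the conservation identity — not by matching published point values.
* The SCV's sensitivity to within-area population density is known but not
  operationalized here; no density adjustment is implemented.
* Partial age bands at cohort bounds use whole-band person-years (see
  Standardization); with 5-year bands this biases eligible-population
  denominators slightly upward for bounded cohorts, identically in both
  periods, and cancels from the self-standardized SCV.
* The percentile bootstrap undercovers when counts are very small
  (few events per area); no small-count correction is applied.
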