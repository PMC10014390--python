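# savakit

Small-area variation analysis of elective-surgery hospitalizations.

Health systems that serve one territory through several districts often show
admission rates for schedulable ("elective") surgery — tonsillectomy, hip and
knee replacement, vein stripping, knee arthroscopy — that differ between
districts far more than patient need can explain. `savakit` is a toolkit for
quantifying that *unwarranted variation* from hospital-discharge abstracts:

* **Cohort extraction** — parse discharge abstracts (delimited text with
  ICD-9-CM procedure and diagnosis codes), keep public-hospital admissions of
  residents discharged in a study period, and build per-procedure cohorts
  from inclusion criteria (code sets, inclusive age bounds, excluded
  diagnosis categories such as neoplasm, trauma, poisoning or femoral-neck
  fracture).
* **Standardization** — crude, directly standardized (standard-population
  stratum weights) and indirectly standardized rates by 5-year age band and
  sex; the indirect method yields the expected counts e_i.
* **Variation statistics** — the systematic component of variation

      SCV = (1/k) · ( Σᵢ (yᵢ − eᵢ)²/eᵢ²  −  Σᵢ 1/eᵢ ),   reported ×100,

  which subtracts expected Poisson noise from the squared standardized
  deviations and estimates 100·σ², the variance of mean-1 district relative
  risks. With a parametric-bootstrap confidence interval, a five-level
  classification (<1 none, [1,3) minimal, [3,6) medium, [6,10) high, ≥10
  very high), and the classic spread measures (range, extremal quotient,
  SD, CV).
* **Synthetic province generator** — a four-district province (population
  shares 45/26/15/14 %, 500,000 inhabitants, 2018–2021) with known district
  relative risks, per-procedure baseline rates, a post-2020 reduction
  factor, and decoy records that the filters must remove; ground truth is
  emitted alongside the data.
* **Two-period pipeline** — rate tables per district and period, percent
  changes, and per-procedure SCV comparison between a pre- and post-shock
  period (e.g. before/after the COVID-19 pandemic), as CSV, JSON and
  Markdown.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

```python
import savakit as sk

cfg = sk.default_scenario(seed=3)                 # 4 districts, sigma^2 = 0.05
records, population, truth = sk.generate_dataset(cfg)
analysis = sk.AnalysisConfig(
    areas=tuple(a for a, _ in cfg.areas),
    period1=sk.StudyPeriod("2018-2019", 2018, 2019),
    period2=sk.StudyPeriod("2020-2021", 2020, 2021),
    seed=42,
)
report = sk.run_analysis(records, population, analysis)
print(report.to_markdown())
```

prints (abridged):

```
## Procedure counts

- hip_replacement: 1322 -> 948 (-28%)
- knee_arthroscopy: 3014 -> 1947 (-35%)
- knee_replacement: 2015 -> 1503 (-25%)
- tonsillectomy: 695 -> 297 (-57%)
- vein_stripping: 408 -> 95 (-77%)

## Systematic component of variation (x100)

- hip_replacement 2018-2019: SCV 11.23 (8.26 - 14.72), very_high
- hip_replacement 2020-2021: SCV 6.37 (3.67 - 10.45), high
- tonsillectomy 2018-2019: SCV 4.85 (2.11 - 9.61), medium
- vein_stripping 2020-2021: SCV 1.73 (-3.24 - 18.66), minimal
```

The count reductions mirror the generator's pandemic-era factors (0.75 for
hip replacement, 0.43 for tonsillectomy, 0.24 for vein stripping, …). The
SCV lines are the phase-2 comparison: each value estimates 100·σ² for that
procedure and period from just 4 districts, so individual values scatter
widely around the scenario's true 5.0 — this draw's district effects were
λ = (1.51, 1.08, 0.89, 0.60), genuinely variable, and the statistic reads
medium-to-very-high variation accordingly. Averaged over replicates and
scaled to 50 districts, the estimator recovers σ² tightly (see the test
suite). Negative SCVs are legitimate small-sample outcomes of the noise
correction and classify as no variation.

The same steps are available from a shell:

```sh
savakit simulate --seed 3 --out-dir scenario/
savakit run --discharges scenario/discharges.csv \
            --population scenario/population.csv \
            --config analysis.yaml --out-dir results/
```

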