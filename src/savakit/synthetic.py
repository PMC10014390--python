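"""Synthetic discharge data with known ground truth.

Emulates a four-district province of half a million inhabitants observed
over 2018-2021.  Each procedure has a baseline admission rate applied to its
age-eligible strata; each area carries a multiplicative relative risk drawn
from a mean-1 distribution with chosen variance sigma^2 (the estimand of the
systematic component of variation, whose true value on the x100 scale is
100*sigma^2); years from 2020 onward are scaled by a per-procedure pandemic
reduction factor.  Cell-level event counts are Poisson; each event is
materialized as a discharge record.  Optional decoy records — excluded
diagnoses, out-of-age-range ages, private-hospital admissions — must all be
removed by the cohort filters, which the test-suite verifies.

Everything is reproducible from the scenario seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_discharge import (
    DEFAULT_AGE_BANDS,
    DEFAULT_PROCEDURES,
    DischargeRecord,
    PopulationTable,
    ProcedureDefinition,
    parse_age_band,
)

#: Default district population shares (Bolzano 45%, Merano 26%, Brunico 15%,
#: Bressanone 14%).
DEFAULT_AREAS: tuple[tuple[str, float], ...] = (
    ("bolzano", 0.45),
    ("merano", 0.26),
    ("brunico", 0.15),
    ("bressanone", 0.14),
)

#: Plausible age-band population shares for an ageing alpine province
#: (sum to 1; split evenly by sex within band).
DEFAULT_AGE_BAND_SHARES: dict[str, float] = {
    "0-4": 0.040, "5-9": 0.045, "10-14": 0.050, "15-19": 0.050,
    "20-24": 0.050, "25-29": 0.050, "30-34": 0.055, "35-39": 0.060,
    "40-44": 0.070, "45-49": 0.080, "50-54": 0.080, "55-59": 0.075,
    "60-64": 0.065, "65-69": 0.060, "70-74": 0.055, "75-79": 0.045,
    "80-84": 0.035, "85+": 0.035,
}

_OPEN_BAND_WIDTH = 15  # sampling width for the open-ended 85+ band


@dataclass(frozen=True)
class ProcedureScenario:
    """Generating parameters for one procedure.

    ``baseline_rate`` is per 100,000 person-years of the age-eligible
    population (the procedure's cohort age bounds, or all ages when it has
    none).  ``principal_diagnosis`` is the benign diagnosis written on true
    events; ``decoy_diagnosis`` lies in an excluded category and is used only
    on excluded-diagnosis decoys.
    """

    baseline_rate: float
    principal_diagnosis: str
    decoy_diagnosis: str | None = None
    rate_multipliers: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def multiplier(self, band: str, sex: str) -> float:
        return float(self.rate_multipliers.get((band, sex), 1.0))


#: Baseline rates per 100,000 eligible person-years, magnitudes typical of the
#: pre-pandemic period, and pandemic-era multiplicative factors chosen to
#: produce the roughly 25-76% reductions seen for these procedures.
DEFAULT_PROCEDURE_SCENARIOS: dict[str, ProcedureScenario] = {
    "tonsillectomy": ProcedureScenario(315.72, "474.0", "162.9"),
    "hip_replacement": ProcedureScenario(491.35, "715.15", "820.8"),
    "knee_replacement": ProcedureScenario(171.10, "715.16", "823.00"),
    "vein_stripping": ProcedureScenario(35.71, "454.9"),
    "knee_arthroscopy": ProcedureScenario(255.02, "717.7"),
}

DEFAULT_COVID_REDUCTION: dict[str, float] = {
    "tonsillectomy": 0.43,
    "hip_replacement": 0.75,
    "knee_replacement": 0.73,
    "vein_stripping": 0.24,
    "knee_arthroscopy": 0.66,
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of a synthetic province scenario."""

    areas: tuple[tuple[str, float], ...] = DEFAULT_AREAS
    total_population: int = 500_000
    years: tuple[int, ...] = (2018, 2019, 2020, 2021)
    age_band_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_BAND_SHARES)
    )
    procedures: Mapping[str, ProcedureScenario] = field(
        default_factory=lambda: dict(DEFAULT_PROCEDURE_SCENARIOS)
    )
    procedure_definitions: Mapping[str, ProcedureDefinition] = field(
        default_factory=lambda: dict(DEFAULT_PROCEDURES)
    )
    sigma2: float = 0.05
    rr_distribution: str = "gamma"  # or "lognormal"
    covid_reduction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVID_REDUCTION)
    )
    covid_start_year: int = 2020
    private_fraction: float = 0.05
    decoy_excluded_diagnosis: float = 0.05
    decoy_out_of_age: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(s for _, s in self.areas) - 1.0) > 1e-9:
            raise ValueError("area population shares must sum to 1")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.rr_distribution not in ("gamma", "lognormal"):
            raise ValueError("rr_distribution must be 'gamma' or 'lognormal'")
        for name, f in self.covid_reduction.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"covid_reduction[{name!r}] must be in [0, 1]")
        for p in (self.private_fraction, self.decoy_excluded_diagnosis,
                  self.decoy_out_of_age):
            if not (0.0 <= p <= 1.0):
                raise ValueError("decoy probabilities must be in [0, 1]")
        if abs(sum(self.age_band_shares.values()) - 1.0) > 1e-9:
            raise ValueError("age-band shares must sum to 1")

    def replace(self, **changes) -> "ScenarioConfig":
        return dataclasses.replace(self, **changes)


def default_scenario(**overrides) -> ScenarioConfig:
    return ScenarioConfig(**overrides)


def equal_share_areas(k: int, prefix: str = "area") -> tuple[tuple[str, float], ...]:
    """k equally populated areas — handy for scaled-up recovery scenarios."""
    return tuple((f"{prefix}{i:02d}", 1.0 / k) for i in range(k))


def draw_area_effects(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> dict[str, float]:
    """Draw i.i.d. area relative risks with mean 1 and variance sigma^2.

    Gamma: shape 1/sigma^2, scale sigma^2.  Lognormal: mu = -log(1+sigma^2)/2,
    s^2 = log(1+sigma^2).  With sigma^2 = 0 every effect is exactly 1.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    names = [a for a, _ in config.areas]
    s2 = config.sigma2
    if s2 == 0:
        lam = np.ones(len(names))
    elif config.rr_distribution == "gamma":
        lam = rng.gamma(shape=1.0 / s2, scale=s2, size=len(names))
    else:
        sln2 = np.log1p(s2)
        lam = rng.lognormal(mean=-0.5 * sln2, sigma=np.sqrt(sln2), size=len(names))
    return dict(zip(names, lam.tolist()))


def generate_population(config: ScenarioConfig) -> PopulationTable:
    """Deterministic population table: shares applied to the total, per year."""
    rows = []
    for area, share in config.areas:
        for band, bshare in config.age_band_shares.items():
            n_band = config.total_population * share * bshare
            for sex in ("F", "M"):
                for year in config.years:
                    rows.append(
                        {"area": area, "age_band": band, "sex": sex,
                         "year": year, "count": round(n_band / 2.0, 3)}
                    )
    return PopulationTable(pd.DataFrame(rows))


def _eligible_bands(
    proc_def: ProcedureDefinition, bands: Sequence[str]
) -> list[tuple[str, int, int]]:
    """Bands intersecting the procedure's age bounds, with sampling ranges."""
    out = []
    for band in bands:
        lo, hi = parse_age_band(band)
        hi_eff = hi if hi is not None else lo + _OPEN_BAND_WIDTH - 1
        a = lo if proc_def.min_age is None else max(lo, proc_def.min_age)
        b = hi_eff if proc_def.max_age is None else min(hi_eff, proc_def.max_age)
        if a <= b:
            out.append((band, a, b))
    return out


def _random_date(rng: np.random.Generator, year: int) -> date:
    start = date(year, 1, 1)
    n_days = (date(year + 1, 1, 1) - start).days
    return start + timedelta(days=int(rng.integers(0, n_days)))


def generate_dataset(
    config: ScenarioConfig,
) -> tuple[list[DischargeRecord], PopulationTable, dict]:
    """Generate discharge records, the population table and the ground truth.

    The truth report carries the drawn area effects, the per
    (procedure, year, area) true event counts, the decoy record ids, and the
    implied SCV target 100*sigma^2.
    """
    rng = np.random.default_rng(config.seed)
    population = generate_population(config)
    lam = draw_area_effects(config, rng)

    bands = [b for b in DEFAULT_AGE_BANDS if b in config.age_band_shares]
    records: list[DischargeRecord] = []
    decoy_ids: list[str] = []
    true_counts: dict[str, dict[int, dict[str, int]]] = {}
    expected_means: dict[str, dict[str, float]] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"R{counter:07d}"

    def make_record(area: str, age: int, sex: str, year: int, proc_code: str,
                    diagnosis: str, hospital_type: str) -> DischargeRecord:
        return DischargeRecord(
            record_id=next_id(),
            area=area,
            age=age,
            sex=sex,
            discharge_date=_random_date(rng, year),
            procedure_codes=(proc_code,),
            diagnosis_codes=(diagnosis,),
            hospital_id=f"H-{area}-{'PRIV' if hospital_type == 'private' else '1'}",
            hospital_type=hospital_type,
        )

    for proc_name in sorted(config.procedures):
        scen = config.procedures[proc_name]
        proc_def = config.procedure_definitions[proc_name]
        codes = sorted(proc_def.include_procedure_codes)
        eligible = _eligible_bands(proc_def, bands)
        true_counts[proc_name] = {y: {a: 0 for a, _ in config.areas} for y in config.years}
        expected_means[proc_name] = {a: 0.0 for a, _ in config.areas}

        for area, share in config.areas:
            for band, age_lo, age_hi in eligible:
                band_pop = config.total_population * share * config.age_band_shares[band]
                for sex in ("F", "M"):
                    pop = band_pop / 2.0
                    for year in config.years:
                        covid = (
                            config.covid_reduction.get(proc_name, 1.0)
                            if year >= config.covid_start_year
                            else 1.0
                        )
                        mean = (
                            pop * scen.baseline_rate / 1e5
                            * scen.multiplier(band, sex)
                            * lam[area] * covid
                        )
                        expected_means[proc_name][area] += mean
                        n = int(rng.poisson(mean))
                        true_counts[proc_name][year][area] += n
                        for _ in range(n):
                            age = int(rng.integers(age_lo, age_hi + 1))
                            code = codes[int(rng.integers(0, len(codes)))]
                            rec = make_record(area, age, sex, year, code,
                                              scen.principal_diagnosis, "public")
                            records.append(rec)

                        # Decoy admissions that the filters must remove.
                        if config.private_fraction > 0:
                            for _ in range(int(rng.poisson(mean * config.private_fraction))):
                                age = int(rng.integers(age_lo, age_hi + 1))
                                rec = make_record(area, age, sex, year, codes[0],
                                                  scen.principal_diagnosis, "private")
                                records.append(rec)
                                decoy_ids.append(rec.record_id)
                        if (config.decoy_excluded_diagnosis > 0
                                and scen.decoy_diagnosis is not None):
                            for _ in range(
                                int(rng.poisson(mean * config.decoy_excluded_diagnosis))
                            ):
                                age = int(rng.integers(age_lo, age_hi + 1))
                                rec = make_record(area, age, sex, year, codes[0],
                                                  scen.decoy_diagnosis, "public")
                                records.append(rec)
                                decoy_ids.append(rec.record_id)

            # Out-of-age decoys exist only for procedures with age bounds.
            if config.decoy_out_of_age > 0 and (
                proc_def.min_age is not None or proc_def.max_age is not None
            ):
                area_mean = expected_means[proc_name][area]
                if proc_def.min_age is not None:
                    bad_lo, bad_hi = max(0, proc_def.min_age - 25), proc_def.min_age - 1
                else:
                    bad_lo, bad_hi = proc_def.max_age + 1, proc_def.max_age + 25
                for year in config.years:
                    n_bad = int(rng.poisson(
                        area_mean / len(config.years) * config.decoy_out_of_age
                    ))
                    for _ in range(n_bad):
                        age = int(rng.integers(bad_lo, bad_hi + 1))
                        sex = "F" if rng.random() < 0.5 else "M"
                        rec = make_record(area, age, sex, year, codes[0],
                                          scen.principal_diagnosis, "public")
                        records.append(rec)
                        decoy_ids.append(rec.record_id)

    truth = {
        "seed": config.seed,
        "sigma2": config.sigma2,
        "true_scv": 100.0 * config.sigma2,
        "area_effects": lam,
        "true_counts": {
            p: {str(y): dict(by_area) for y, by_area in per_year.items()}
            for p, per_year in true_counts.items()
        },
        "expected_event_means": expected_means,
        "decoy_record_ids": decoy_ids,
        "n_records": len(records),
    }
    return records, population, truth
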