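"""Crude, directly standardized and indirectly standardized admission rates.

Rates are stratified by age band and sex.  The direct method averages an
area's stratum-specific rates with a common standard population's stratum
weights; the indirect method applies pooled (all-area) stratum rates to an
area's own population structure to get the expected event count ``e_i`` that
the systematic-component-of-variation statistic compares with the observed
count ``y_i``.  When the standard rates are pooled over exactly the analysed
areas, the expected counts conserve the observed total (sum e_i = sum y_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

Stratum = Hashable  # typically an (age_band, sex) pair


@dataclass(frozen=True)
class AreaCounts:
    """Observed and expected events for one area, one procedure, one period."""

    area: str
    observed: int
    expected: float
    population: float = 0.0

    def __post_init__(self) -> None:
        if self.observed < 0:
            raise ValueError(f"area {self.area}: observed events < 0")
        if self.expected <= 0:
            raise ValueError(f"area {self.area}: expected events must be > 0")

    @property
    def ratio(self) -> float:
        """Standardized admission ratio y_i / e_i."""
        return self.observed / self.expected


@dataclass
class StratumRates:
    """Stratum-specific rates per person-year, with their source counts.

    Strata with zero person-years have no defined rate; they are listed in
    ``undefined`` rather than silently treated as zero.
    """

    rates: dict[Stratum, float]
    source_events: dict[Stratum, float] = field(default_factory=dict)
    source_person_years: dict[Stratum, float] = field(default_factory=dict)
    undefined: set[Stratum] = field(default_factory=set)

    def rate(self, stratum: Stratum) -> float:
        if stratum in self.undefined:
            raise KeyError(f"rate undefined for stratum {stratum!r} (zero person-years)")
        return self.rates[stratum]


def pooled_stratum_rates(
    events: Mapping[Stratum, float],
    person_years: Mapping[Stratum, float],
) -> StratumRates:
    """Stratum rates from pooled events and person-years (the indirect standard)."""
    rates: dict[Stratum, float] = {}
    undefined: set[Stratum] = set()
    for s, py in person_years.items():
        ev = float(events.get(s, 0.0))
        if py > 0:
            rates[s] = ev / py
        else:
            if ev > 0:
                raise ValueError(f"stratum {s!r}: events without person-years")
            undefined.add(s)
            logger.warning("stratum %r has zero person-years; rate undefined", s)
    return StratumRates(
        rates=rates,
        source_events={s: float(v) for s, v in events.items()},
        source_person_years={s: float(v) for s, v in person_years.items()},
        undefined=undefined,
    )


def direct_standardized_rate(
    area_events: Mapping[Stratum, float],
    area_population: Mapping[Stratum, float],
    standard_population: Mapping[Stratum, float],
    scale: float = 1e5,
) -> float:
    """Directly standardized rate: standard-weighted mean of stratum rates.

    Strata with zero person-years are excluded from both the numerator and
    the weight mass (a zero-population stratum with positive events is a
    hard error); the remaining standard weights are renormalized.
    """
    num = 0.0
    wsum = 0.0
    for s, w in standard_population.items():
        if w < 0:
            raise ValueError(f"negative standard weight in stratum {s!r}")
        py = float(area_population.get(s, 0.0))
        ev = float(area_events.get(s, 0.0))
        if py <= 0:
            if ev > 0:
                raise ValueError(f"stratum {s!r}: events without person-years")
            if w > 0:
                logger.warning(
                    "stratum %r has zero person-years; dropped from direct standardization", s
                )
            continue
        num += w * (ev / py)
        wsum += w
    if wsum <= 0:
        raise ValueError("standard population has zero total weight over defined strata")
    return num / wsum * scale


def expected_events(
    area_population: Mapping[Stratum, float],
    standard_rates: StratumRates,
) -> float:
    """Indirectly standardized expected count: e = sum_s pop_s * R_s.

    ``standard_rates`` should come from the pooled events and person-years of
    the same period (the total population as the standard).
    """
    total_py = sum(float(v) for v in area_population.values())
    if total_py <= 0:
        raise ValueError("area has zero total person-years")
    e = 0.0
    for s, py in area_population.items():
        if py == 0 or s in standard_rates.undefined:
            continue
        e += float(py) * standard_rates.rates.get(s, 0.0)
    return e


def indexed_rate(rate: float, reference_mean: float) -> float:
    """Rate as an index against a reference mean set to 100."""
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * rate / reference_mean


def crude_rate(events: float, person_years: float, scale: float = 1e5) -> float:
    if person_years <= 0:
        raise ValueError("person-years must be positive")
    return events / person_years * scale


def area_counts_from_frames(
    events: pd.DataFrame,
    person_years: pd.DataFrame,
    areas: Sequence[str],
) -> list[AreaCounts]:
    """Build self-standardized per-area observed/expected counts.

    ``events`` has columns ``area, age_band, sex, events``; ``person_years``
    has ``area, age_band, sex, person_years``.  The standard rates are pooled
    over the listed areas, so the expected counts conserve the observed total.
    """
    ev = events.set_index(["area", "age_band", "sex"])["events"]
    py = person_years.set_index(["area", "age_band", "sex"])["person_years"]

    pooled_ev = ev.groupby(level=["age_band", "sex"]).sum().to_dict()
    pooled_py = py.groupby(level=["age_band", "sex"]).sum().to_dict()
    standard = pooled_stratum_rates(pooled_ev, pooled_py)

    out: list[AreaCounts] = []
    for a in areas:
        pop = py.loc[a].to_dict() if a in py.index.get_level_values("area") else {}
        obs = int(ev.loc[a].sum()) if a in ev.index.get_level_values("area") else 0
        e = expected_events(pop, standard)
        out.append(AreaCounts(area=a, observed=obs, expected=e,
                              population=float(sum(pop.values()))))
    return out
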