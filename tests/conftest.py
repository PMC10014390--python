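from __future__ import annotations

from datetime import date

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings, strategies as st

from savakit import DischargeRecord, PopulationTable, StudyPeriod

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

AREAS = ("bolzano", "merano", "brunico", "bressanone")


def make_record(
    record_id: str = "R1",
    area: str = "bolzano",
    age: int = 50,
    sex: str = "F",
    discharge_date: date = date(2019, 6, 1),
    procedure_codes: tuple[str, ...] = ("81.51",),
    diagnosis_codes: tuple[str, ...] = ("715.15",),
    hospital_id: str = "H1",
    hospital_type: str = "public",
) -> DischargeRecord:
    return DischargeRecord(
        record_id=record_id,
        area=area,
        age=age,
        sex=sex,
        discharge_date=discharge_date,
        procedure_codes=procedure_codes,
        diagnosis_codes=diagnosis_codes,
        hospital_id=hospital_id,
        hospital_type=hospital_type,
    )


_ids = st.integers(min_value=1, max_value=10**6).map(lambda i: f"R{i}")


def record_strategy(areas: tuple[str, ...] = AREAS) -> st.SearchStrategy:
    """Random admissions covering both periods, both hospital types and a
    spread of procedure and diagnosis codes."""
    return st.builds(
        make_record,
        record_id=_ids,
        area=st.sampled_from(areas + ("elsewhere",)),
        age=st.integers(min_value=0, max_value=99),
        sex=st.sampled_from(["F", "M"]),
        discharge_date=st.dates(min_value=date(2018, 1, 1), max_value=date(2021, 12, 31)),
        procedure_codes=st.lists(
            st.sampled_from(["28.2", "28.3", "81.51", "81.52", "81.54", "38.59",
                             "80.26", "45.13"]),
            min_size=1, max_size=3, unique=True,
        ).map(tuple),
        diagnosis_codes=st.lists(
            st.sampled_from(["474.0", "715.15", "820.8", "162.9", "959.9",
                             "965.0", "401.9", "V27.0"]),
            min_size=0, max_size=3, unique=True,
        ).map(tuple),
        hospital_type=st.sampled_from(["public", "private"]),
    )


@pytest.fixture
def period_pre() -> StudyPeriod:
    return StudyPeriod("2018-2019", 2018, 2019)


@pytest.fixture
def period_post() -> StudyPeriod:
    return StudyPeriod("2020-2021", 2020, 2021)


@pytest.fixture
def tiny_population() -> PopulationTable:
    """Two areas, two bands, both sexes, four years of flat counts."""
    rows = []
    for area, base in (("bolzano", 1000.0), ("merano", 500.0)):
        for band in ("0-4", "5+"):
            for sex in ("F", "M"):
                for year in (2018, 2019, 2020, 2021):
                    rows.append({"area": area, "age_band": band, "sex": sex,
                                 "year": year, "count": base})
    return PopulationTable(pd.DataFrame(rows))
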