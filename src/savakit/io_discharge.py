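"""Reading, validating and filtering hospital-discharge abstracts.

Discharge abstracts arrive as delimited text, one row per admission, carrying
the patient's residence area, age and sex at admission, the discharge date,
ICD-9-CM procedure and diagnosis codes, and the admitting hospital.  This
module parses those rows into :class:`DischargeRecord` objects, applies the
record-level eligibility filters (public hospital, resident area, discharge
year inside the study period) and extracts per-procedure cohorts from
inclusion criteria expressed as :class:`ProcedureDefinition` objects
(procedure-code sets, age bounds, excluded diagnosis categories).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SEXES = frozenset({"F", "M"})
HOSPITAL_TYPES = frozenset({"public", "private"})

#: Default ICD-9-CM diagnosis-category code ranges (inclusive 3-digit stems).
#: Chapter ranges: neoplasms 140-239, injury 800-959, poisoning 960-989;
#: femoral-neck fracture is the single rubric 820.  Overridable per call.
DEFAULT_DIAGNOSIS_CATEGORIES: dict[str, tuple[tuple[int, int], ...]] = {
    "neoplasm": ((140, 239),),
    "trauma": ((800, 959),),
    "poisoning": ((960, 989),),
    "femur_neck_fracture": ((820, 820),),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyPeriod:
    """An inclusive span of calendar years, e.g. 2018-2019 (pre-pandemic)."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError(
                f"start_year {self.start_year} > end_year {self.end_year}"
            )

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def contains(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year

    def union_adjacent(self, other: "StudyPeriod") -> "StudyPeriod":
        """Merge with an adjacent, disjoint period into one span."""
        lo, hi = sorted([self, other], key=lambda p: p.start_year)
        if lo.end_year + 1 != hi.start_year:
            raise ValueError("periods are not adjacent and disjoint")
        return StudyPeriod(f"{lo.start_year}-{hi.end_year}", lo.start_year, hi.end_year)


@dataclass(frozen=True)
class DischargeRecord:
    """One hospital admission as abstracted in the discharge database."""

    record_id: str
    area: str
    age: int
    sex: str
    discharge_date: date
    procedure_codes: tuple[str, ...]
    diagnosis_codes: tuple[str, ...]
    hospital_id: str
    hospital_type: str

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"record {self.record_id}: negative age {self.age}")
        if self.sex not in SEXES:
            raise ValueError(f"record {self.record_id}: sex must be F or M")
        if not self.procedure_codes:
            raise ValueError(f"record {self.record_id}: no procedure codes")
        if self.hospital_type not in HOSPITAL_TYPES:
            raise ValueError(
                f"record {self.record_id}: hospital_type must be public or private"
            )


@dataclass(frozen=True)
class ProcedureDefinition:
    """Inclusion criteria for one elective procedure cohort.

    A record belongs to the cohort iff any of its procedure codes is in
    ``include_procedure_codes``, its age lies inside the (inclusive) bounds,
    and none of its diagnosis codes falls in an excluded category's ranges.
    """

    name: str
    include_procedure_codes: frozenset[str]
    min_age: int | None = None
    max_age: int | None = None
    exclude_diagnosis_categories: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.include_procedure_codes:
            raise ValueError(f"procedure {self.name}: empty code set")
        if (
            self.min_age is not None
            and self.max_age is not None
            and self.min_age > self.max_age
        ):
            raise ValueError(f"procedure {self.name}: min_age > max_age")

    def age_eligible(self, age: int) -> bool:
        if self.min_age is not None and age < self.min_age:
            return False
        if self.max_age is not None and age > self.max_age:
            return False
        return True


#: The five elective procedures under study, with their ICD-9-CM codes,
#: age bounds and diagnosis exclusions.  Tonsillectomy is restricted to
#: patients aged 17 or younger, hip replacement to 65 or older; knee
#: replacement excludes trauma admissions; vein stripping and knee
#: arthroscopy carry no exclusions.
DEFAULT_PROCEDURES: dict[str, ProcedureDefinition] = {
    "tonsillectomy": ProcedureDefinition(
        name="tonsillectomy",
        include_procedure_codes=frozenset({"28.2", "28.3"}),
        max_age=17,
        exclude_diagnosis_categories=frozenset({"neoplasm", "trauma", "poisoning"}),
    ),
    "hip_replacement": ProcedureDefinition(
        name="hip_replacement",
        include_procedure_codes=frozenset({"81.51", "81.52"}),
        min_age=65,
        exclude_diagnosis_categories=frozenset({"femur_neck_fracture"}),
    ),
    "knee_replacement": ProcedureDefinition(
        name="knee_replacement",
        include_procedure_codes=frozenset({"81.54"}),
        exclude_diagnosis_categories=frozenset({"trauma"}),
    ),
    "vein_stripping": ProcedureDefinition(
        name="vein_stripping",
        include_procedure_codes=frozenset({"38.59"}),
    ),
    "knee_arthroscopy": ProcedureDefinition(
        name="knee_arthroscopy",
        include_procedure_codes=frozenset({"80.26"}),
    ),
}


# ---------------------------------------------------------------------------
# ICD-9-CM code normalization
# ---------------------------------------------------------------------------

_DIGITS = re.compile(r"^\d+$")


def normalize_procedure_code(code: str) -> str:
    """Normalize an ICD-9-CM procedure code to dotted form.

    Procedure codes have a two-digit category and up to two decimal digits:
    ``"8151"`` -> ``"81.51"``, ``"28.2"`` stays ``"28.2"``.
    """
    raw = code.strip()
    digits = raw.replace(".", "")
    if not _DIGITS.match(digits) or not (2 <= len(digits) <= 4):
        raise ValueError(f"not an ICD-9-CM procedure code: {code!r}")
    if len(digits) == 2:
        return digits
    return f"{digits[:2]}.{digits[2:]}"


def normalize_diagnosis_code(code: str) -> str:
    """Normalize an ICD-9-CM diagnosis code to dotted form.

    Numeric rubrics have a three-digit stem (``"71515"`` -> ``"715.15"``);
    V codes a two-digit stem after the letter, E codes a three-digit stem.
    """
    raw = code.strip().upper()
    prefix = ""
    digits = raw
    if raw[:1] in ("V", "E"):
        prefix, digits = raw[0], raw[1:]
    digits = digits.replace(".", "")
    if not _DIGITS.match(digits):
        raise ValueError(f"not an ICD-9-CM diagnosis code: {code!r}")
    stem_len = 2 if prefix == "V" else 3
    if len(digits) < stem_len or len(digits) > stem_len + 2:
        raise ValueError(f"not an ICD-9-CM diagnosis code: {code!r}")
    if len(digits) == stem_len:
        return prefix + digits
    return f"{prefix}{digits[:stem_len]}.{digits[stem_len:]}"


def diagnosis_stem(code: str) -> int | None:
    """Integer 3-digit stem of a numeric diagnosis code, None for V/E codes."""
    raw = code.strip().upper()
    if raw[:1] in ("V", "E"):
        return None
    return int(raw.split(".", 1)[0])


def diagnosis_in_categories(
    code: str,
    categories: Iterable[str],
    category_ranges: Mapping[str, Sequence[tuple[int, int]]] = DEFAULT_DIAGNOSIS_CATEGORIES,
) -> bool:
    """True iff the diagnosis code's stem falls in any listed category range."""
    stem = diagnosis_stem(code)
    if stem is None:
        return False
    for cat in categories:
        for lo, hi in category_ranges[cat]:
            if lo <= stem <= hi:
                return True
    return False


# ---------------------------------------------------------------------------
# Reading discharge abstracts
# ---------------------------------------------------------------------------

DEFAULT_COLUMNS: dict[str, str] = {
    "record_id": "record_id",
    "area": "area",
    "age": "age",
    "sex": "sex",
    "discharge_date": "discharge_date",
    "procedure_codes": "procedure_codes",
    "diagnosis_codes": "diagnosis_codes",
    "hospital_id": "hospital_id",
    "hospital_type": "hospital_type",
}


@dataclass(frozen=True)
class RowRejection:
    row: int          # 1-based data-row number (header not counted)
    reason: str


@dataclass
class ReadResult:
    """Parsed records plus the per-row rejection log."""

    records: list[DischargeRecord]
    rejections: list[RowRejection] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _parse_row(row: Mapping[str, str], columns: Mapping[str, str], list_sep: str,
               date_format: str | None) -> DischargeRecord:
    def get(fld: str) -> str:
        return (row.get(columns[fld]) or "").strip()

    age = int(get("age"))
    raw_date = get("discharge_date")
    if date_format:
        d = datetime.strptime(raw_date, date_format).date()
    else:
        d = date.fromisoformat(raw_date)
    procs = tuple(
        normalize_procedure_code(c)
        for c in get("procedure_codes").split(list_sep)
        if c.strip()
    )
    diags = tuple(
        normalize_diagnosis_code(c)
        for c in get("diagnosis_codes").split(list_sep)
        if c.strip()
    )
    return DischargeRecord(
        record_id=get("record_id"),
        area=get("area"),
        age=age,
        sex=get("sex").upper(),
        discharge_date=d,
        procedure_codes=procs,
        diagnosis_codes=diags,
        hospital_id=get("hospital_id"),
        hospital_type=get("hospital_type").lower(),
    )


def read_discharges(
    path: str | Path,
    dialect: Mapping[str, object] | None = None,
) -> ReadResult:
    """Read a delimited discharge-abstract file.

    ``dialect`` may carry ``columns`` (canonical field -> file column name),
    ``list_sep`` (separator inside code-list cells, default ``";"``),
    ``delimiter`` (default ``","``) and ``date_format`` (strptime format;
    default ISO-8601).  Malformed rows are rejected individually and logged;
    a missing mandatory column is a hard error naming the column.
    """
    dialect = dict(dialect or {})
    columns = {**DEFAULT_COLUMNS, **dict(dialect.get("columns", {}))}
    list_sep = str(dialect.get("list_sep", ";"))
    delimiter = str(dialect.get("delimiter", ","))
    date_format = dialect.get("date_format")

    records: list[DischargeRecord] = []
    rejections: list[RowRejection] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for fld, col in columns.items():
            if col not in header:
                raise ValueError(f"missing mandatory column: {col!r} (field {fld})")
        for i, row in enumerate(reader, start=1):
            try:
                records.append(_parse_row(row, columns, list_sep, date_format))
            except (ValueError, KeyError) as exc:
                logger.warning("row %d rejected: %s", i, exc)
                rejections.append(RowRejection(row=i, reason=str(exc)))
    return ReadResult(records=records, rejections=rejections)


def records_to_frame(records: Iterable[DischargeRecord],
                     cohort: str | None = None) -> pd.DataFrame:
    """Tabulate records with the file schema; optional cohort label column."""
    rows = [
        {
            "record_id": r.record_id,
            "area": r.area,
            "age": r.age,
            "sex": r.sex,
            "discharge_date": r.discharge_date.isoformat(),
            "procedure_codes": ";".join(r.procedure_codes),
            "diagnosis_codes": ";".join(r.diagnosis_codes),
            "hospital_id": r.hospital_id,
            "hospital_type": r.hospital_type,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS))
    if cohort is not None:
        df["cohort"] = cohort
    return df


def write_discharges(records: Iterable[DischargeRecord], path: str | Path,
                     cohort: str | None = None) -> None:
    records_to_frame(records, cohort=cohort).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_eligible(
    records: Iterable[DischargeRecord],
    period: StudyPeriod,
    resident_areas: Iterable[str],
    on_unknown_area: str = "reject",
) -> list[DischargeRecord]:
    """Keep public-hospital admissions of residents discharged in the period.

    Records from areas outside ``resident_areas`` are dropped with a log
    message by default; ``on_unknown_area="error"`` raises instead.
    """
    if on_unknown_area not in ("reject", "error"):
        raise ValueError("on_unknown_area must be 'reject' or 'error'")
    areas = set(resident_areas)
    kept: list[DischargeRecord] = []
    for r in records:
        if r.area not in areas:
            if on_unknown_area == "error":
                raise ValueError(f"record {r.record_id}: unknown area {r.area!r}")
            logger.debug("record %s: non-resident area %s dropped", r.record_id, r.area)
            continue
        if r.hospital_type != "public":
            continue
        if not period.contains(r.discharge_date.year):
            continue
        kept.append(r)
    return kept


def extract_cohort(
    records: Iterable[DischargeRecord],
    proc: ProcedureDefinition,
    category_ranges: Mapping[str, Sequence[tuple[int, int]]] = DEFAULT_DIAGNOSIS_CATEGORIES,
    prefix_match: bool = False,
) -> list[DischargeRecord]:
    """Extract the cohort for one procedure definition.

    Retains a record iff any procedure code is included (exact dotted-code
    match unless ``prefix_match``), the age is inside the inclusive bounds,
    and no diagnosis code (principal or secondary) falls in an excluded
    category.  Admissions are deduplicated by ``record_id``: a record listing
    two qualifying codes counts once.
    """
    seen: set[str] = set()
    cohort: list[DischargeRecord] = []
    for r in records:
        if r.record_id in seen:
            continue
        if prefix_match:
            code_hit = any(
                c == inc or c.startswith(inc)
                for c in r.procedure_codes
                for inc in proc.include_procedure_codes
            )
        else:
            code_hit = any(c in proc.include_procedure_codes for c in r.procedure_codes)
        if not code_hit or not proc.age_eligible(r.age):
            continue
        if proc.exclude_diagnosis_categories and any(
            diagnosis_in_categories(d, proc.exclude_diagnosis_categories, category_ranges)
            for d in r.diagnosis_codes
        ):
            continue
        seen.add(r.record_id)
        cohort.append(r)
    return cohort


# ---------------------------------------------------------------------------
# Age bands and population tables
# ---------------------------------------------------------------------------

#: 5-year age bands 0-4 ... 80-84, then open-ended 85+.
DEFAULT_AGE_BANDS: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" for lo in range(0, 85, 5)
) + ("85+",)

_BAND = re.compile(r"^(\d+)-(\d+)$")
_OPEN_BAND = re.compile(r"^(\d+)\+$")


def parse_age_band(label: str) -> tuple[int, int | None]:
    """Bounds of a band label: ``"0-4"`` -> (0, 4), ``"85+"`` -> (85, None)."""
    m = _BAND.match(label)
    if m:
        lo, hi = int(m.group(1)), int(m.group(2))
        if lo > hi:
            raise ValueError(f"bad age band {label!r}")
        return lo, hi
    m = _OPEN_BAND.match(label)
    if m:
        return int(m.group(1)), None
    raise ValueError(f"bad age band {label!r}")


def age_to_band(age: int, bands: Sequence[str] = DEFAULT_AGE_BANDS) -> str:
    for label in bands:
        lo, hi = parse_age_band(label)
        if age >= lo and (hi is None or age <= hi):
            return label
    raise ValueError(f"age {age} not covered by the age bands")


def validate_age_bands(bands: Sequence[str]) -> None:
    """Bands must partition [0, inf) without gaps or overlap, last open."""
    parsed = sorted((parse_age_band(b) for b in bands), key=lambda t: t[0])
    if parsed[0][0] != 0:
        raise ValueError("age bands must start at 0")
    for (lo, hi), (nxt, _) in zip(parsed, parsed[1:]):
        if hi is None or hi + 1 != nxt:
            raise ValueError("age bands must be contiguous and non-overlapping")
    if parsed[-1][1] is not None:
        raise ValueError("last age band must be open-ended")


class PopulationTable:
    """Resident person counts by area, age band, sex and calendar year.

    Wraps a long-format table with columns ``area, age_band, sex, year,
    count``; summing the annual counts over a study period yields the
    person-year denominators for rates.
    """

    COLUMNS = ("area", "age_band", "sex", "year", "count")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"population table missing columns: {sorted(missing)}")
        df = frame.loc[:, list(self.COLUMNS)].copy()
        df["year"] = df["year"].astype(int)
        df["count"] = df["count"].astype(float)
        if (df["count"] < 0).any():
            raise ValueError("population counts must be non-negative")
        bad_sex = set(df["sex"]) - SEXES
        if bad_sex:
            raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
        validate_age_bands(sorted(set(df["age_band"]), key=lambda b: parse_age_band(b)[0]))
        self.frame = df

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def areas(self) -> list[str]:
        return sorted(self.frame["area"].unique())

    @property
    def age_bands(self) -> list[str]:
        return sorted(self.frame["age_band"].unique(), key=lambda b: parse_age_band(b)[0])

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique())

    def require_coverage(self, areas: Iterable[str], period: StudyPeriod) -> None:
        """Every area must be present for every year of the period."""
        present = set(zip(self.frame["area"], self.frame["year"]))
        for a in areas:
            for y in period.years:
                if (a, y) not in present:
                    raise ValueError(f"population table lacks area {a!r} in year {y}")

    def person_years(self, period: StudyPeriod,
                     areas: Iterable[str] | None = None) -> pd.DataFrame:
        """Person-years by (area, age_band, sex) over the period's years."""
        df = self.frame[self.frame["year"].isin(period.years)]
        if areas is not None:
            df = df[df["area"].isin(set(areas))]
        out = (
            df.groupby(["area", "age_band", "sex"], as_index=False)["count"]
            .sum()
            .rename(columns={"count": "person_years"})
        )
        return out
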