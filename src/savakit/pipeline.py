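"""Two-phase small-area variation analysis over two study periods.

Phase 1 builds period rate tables — overall admissions per 1,000 person-years
and per-procedure rates per 100,000 age-eligible person-years — with percent
changes between the periods.  Phase 2 computes, per procedure and period, the
observed and indirectly-standardized expected counts across areas and the
systematic component of variation with its bootstrap confidence interval and
five-level classification.

Each period is self-standardized: the indirect standard rates are the pooled
age-sex rates of that period's own data, so within a procedure and period the
expected counts sum to the observed count.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .io_discharge import (
    DEFAULT_AGE_BANDS,
    DEFAULT_DIAGNOSIS_CATEGORIES,
    DEFAULT_PROCEDURES,
    DischargeRecord,
    PopulationTable,
    ProcedureDefinition,
    StudyPeriod,
    age_to_band,
    extract_cohort,
    filter_eligible,
    read_discharges,
)
from .standardization import area_counts_from_frames, crude_rate
from .variation import ScvResult, compute_scv

logger = logging.getLogger(__name__)


def percent_change(before: float, after: float) -> float:
    """Percent change 100*(after-before)/before; NaN when before <= 0.

    Report writers round to the nearest integer; the value itself keeps
    full precision.
    """
    if before <= 0:
        return math.nan
    return 100.0 * (after - before) / before


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for a two-period analysis run."""

    areas: tuple[str, ...]
    period1: StudyPeriod
    period2: StudyPeriod
    procedures: Mapping[str, ProcedureDefinition] = field(
        default_factory=lambda: dict(DEFAULT_PROCEDURES)
    )
    diagnosis_categories: Mapping[str, Sequence[tuple[int, int]]] = field(
        default_factory=lambda: dict(DEFAULT_DIAGNOSIS_CATEGORIES)
    )
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS
    scale_overall: float = 1e3
    scale_procedure: float = 1e5
    ci_level: float = 0.95
    n_boot: int = 1000
    seed: int = 0
    prefix_match: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        p1, p2 = raw["periods"]
        procs_raw = raw.get("procedures", "default")
        if procs_raw == "default" or procs_raw is None:
            procs = dict(DEFAULT_PROCEDURES)
        else:
            procs = {
                name: ProcedureDefinition(
                    name=name,
                    include_procedure_codes=frozenset(spec["codes"]),
                    min_age=spec.get("min_age"),
                    max_age=spec.get("max_age"),
                    exclude_diagnosis_categories=frozenset(spec.get("exclude", [])),
                )
                for name, spec in procs_raw.items()
            }
        cats = {
            name: tuple(tuple(r) for r in ranges)
            for name, ranges in raw.get(
                "diagnosis_categories", DEFAULT_DIAGNOSIS_CATEGORIES
            ).items()
        }
        return cls(
            areas=tuple(raw["areas"]),
            period1=StudyPeriod(p1.get("label", f"{p1['start_year']}-{p1['end_year']}"),
                                int(p1["start_year"]), int(p1["end_year"])),
            period2=StudyPeriod(p2.get("label", f"{p2['start_year']}-{p2['end_year']}"),
                                int(p2["start_year"]), int(p2["end_year"])),
            procedures=procs,
            diagnosis_categories=cats,
            age_bands=tuple(raw.get("age_bands", DEFAULT_AGE_BANDS)),
            scale_overall=float(raw.get("scale_overall", 1e3)),
            scale_procedure=float(raw.get("scale_procedure", 1e5)),
            ci_level=float(raw.get("ci_level", 0.95)),
            n_boot=int(raw.get("n_boot", 1000)),
            seed=int(raw.get("seed", 0)),
            prefix_match=bool(raw.get("prefix_match", False)),
        )

    @property
    def periods(self) -> tuple[StudyPeriod, StudyPeriod]:
        return (self.period1, self.period2)


@dataclass
class ComparisonReport:
    """All tables of a two-period run, plus the filter-stage log."""

    overall: pd.DataFrame          # area(+overall) x period: admissions, rate per 1,000
    rates: pd.DataFrame            # procedure x area(+overall) x period rate table
    rate_comparison: pd.DataFrame  # procedure x area(+overall): p1, p2, pct_change
    scv: pd.DataFrame              # procedure x period: scv, CI, classification, counts
    area_counts: pd.DataFrame      # procedure x period x area: observed, expected
    count_comparison: pd.DataFrame # procedure: counts p1/p2 and pct change
    filter_log: pd.DataFrame       # stage record counts
    scv_results: dict[tuple[str, str], ScvResult] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("overall", "rates", "rate_comparison", "scv",
                     "area_counts", "count_comparison", "filter_log"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        (out / "report.json").write_text(self.to_json(), encoding="utf-8")
        (out / "report.md").write_text(self.to_markdown(), encoding="utf-8")

    def to_json(self) -> str:
        payload = {
            name: getattr(self, name).to_dict(orient="records")
            for name in ("overall", "rate_comparison", "scv",
                         "area_counts", "count_comparison", "filter_log")
        }
        return json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)

    def to_markdown(self) -> str:
        def fmt_pct(v: float) -> str:
            return "NA" if pd.isna(v) else f"{v:+.0f}%"

        lines = ["# Small-area variation report", "", "## Overall admissions (per 1,000)", ""]
        for _, r in self.overall.iterrows():
            lines.append(f"- {r['area']} {r['period']}: {r['admissions']:.0f} admissions, "
                         f"rate {r['rate']:.2f}")
        lines += ["", "## Procedure counts", ""]
        for _, r in self.count_comparison.iterrows():
            lines.append(f"- {r['procedure']}: {r['count_period1']:.0f} -> "
                         f"{r['count_period2']:.0f} ({fmt_pct(r['count_pct_change'])})")
        lines += ["", "## Systematic component of variation (x100)", ""]
        for _, r in self.scv.iterrows():
            if r["no_events"]:
                lines.append(f"- {r['procedure']} {r['period']}: no events")
            else:
                lines.append(
                    f"- {r['procedure']} {r['period']}: SCV {r['scv']:.2f} "
                    f"({r['ci_low']:.2f} - {r['ci_high']:.2f}), {r['classification']}"
                )
        return "\n".join(lines) + "\n"


def _eligible_band_set(proc: ProcedureDefinition, bands: Sequence[str]) -> set[str]:
    from .io_discharge import parse_age_band

    out = set()
    for band in bands:
        lo, hi = parse_age_band(band)
        a = lo if proc.min_age is None else max(lo, proc.min_age)
        b = hi if proc.max_age is None else (proc.max_age if hi is None else min(hi, proc.max_age))
        if b is None or a <= b:
            out.add(band)
    return out


def _events_frame(records: Iterable[DischargeRecord],
                  bands: Sequence[str]) -> pd.DataFrame:
    rows = [
        {"area": r.area, "age_band": age_to_band(r.age, bands), "sex": r.sex}
        for r in records
    ]
    if not rows:
        return pd.DataFrame(columns=["area", "age_band", "sex", "events"])
    df = pd.DataFrame(rows)
    return df.groupby(["area", "age_band", "sex"], as_index=False).size().rename(
        columns={"size": "events"}
    )


def run_analysis(
    discharges: str | Path | Sequence[DischargeRecord],
    population: str | Path | PopulationTable,
    config: AnalysisConfig,
    out_dir: str | Path | None = None,
) -> ComparisonReport:
    """Run the full two-period analysis; deterministic given the config seed."""
    if isinstance(discharges, (str, Path)):
        result = read_discharges(discharges)
        if result.n_rejected:
            logger.warning("%d malformed rows rejected on read", result.n_rejected)
        records: Sequence[DischargeRecord] = result.records
    else:
        records = list(discharges)
    pop = (
        PopulationTable.from_csv(population)
        if isinstance(population, (str, Path))
        else population
    )
    areas = list(config.areas)
    for period in config.periods:
        pop.require_coverage(areas, period)

    filter_rows = [{"stage": "raw", "period": "-", "procedure": "-",
                    "records": len(records)}]
    eligible: dict[str, list[DischargeRecord]] = {}
    py_all: dict[str, pd.DataFrame] = {}
    for period in config.periods:
        elig = filter_eligible(records, period, areas)
        eligible[period.label] = elig
        filter_rows.append({"stage": "eligible", "period": period.label,
                            "procedure": "-", "records": len(elig)})
        py = pop.person_years(period, areas)
        for a in areas:
            total = py.loc[py["area"] == a, "person_years"].sum()
            if total <= 0:
                raise ValueError(
                    f"area {a!r} has zero eligible population in period {period.label}"
                )
        py_all[period.label] = py

    # ---- Phase 1: overall admissions per 1,000 person-years -----------------
    overall_rows = []
    for period in config.periods:
        py = py_all[period.label]
        by_area = {a: 0 for a in areas}
        for r in eligible[period.label]:
            by_area[r.area] += 1
        for a in areas:
            denom = float(py.loc[py["area"] == a, "person_years"].sum())
            overall_rows.append({
                "area": a, "period": period.label, "admissions": by_area[a],
                "person_years": denom,
                "rate": crude_rate(by_area[a], denom, config.scale_overall),
            })
        total_py = float(py["person_years"].sum())
        overall_rows.append({
            "area": "overall", "period": period.label,
            "admissions": sum(by_area.values()), "person_years": total_py,
            "rate": crude_rate(sum(by_area.values()), total_py, config.scale_overall),
        })
    overall = pd.DataFrame(overall_rows)

    # ---- Phase 1 + 2 per procedure ------------------------------------------
    rate_rows, scv_rows, count_rows, ac_rows = [], [], [], []
    scv_results: dict[tuple[str, str], ScvResult] = {}
    proc_names = sorted(config.procedures)
    for pi, proc_name in enumerate(proc_names):
        proc = config.procedures[proc_name]
        band_set = _eligible_band_set(proc, config.age_bands)
        counts_by_period: dict[str, int] = {}
        for qi, period in enumerate(config.periods):
            cohort = extract_cohort(
                eligible[period.label], proc,
                category_ranges=config.diagnosis_categories,
                prefix_match=config.prefix_match,
            )
            filter_rows.append({"stage": "cohort", "period": period.label,
                                "procedure": proc_name, "records": len(cohort)})
            counts_by_period[period.label] = len(cohort)

            py = py_all[period.label]
            py_elig = py[py["age_band"].isin(band_set)]
            events = _events_frame(cohort, config.age_bands)

            by_area = {a: 0 for a in areas}
            for r in cohort:
                by_area[r.area] += 1
            for a in areas:
                denom = float(py_elig.loc[py_elig["area"] == a, "person_years"].sum())
                rate_rows.append({
                    "procedure": proc_name, "area": a, "period": period.label,
                    "events": by_area[a], "person_years": denom,
                    "rate": crude_rate(by_area[a], denom, config.scale_procedure),
                    "scale": config.scale_procedure,
                })
            denom_all = float(py_elig["person_years"].sum())
            rate_rows.append({
                "procedure": proc_name, "area": "overall", "period": period.label,
                "events": len(cohort), "person_years": denom_all,
                "rate": crude_rate(len(cohort), denom_all, config.scale_procedure),
                "scale": config.scale_procedure,
            })

            if len(cohort) == 0:
                scv_rows.append({
                    "procedure": proc_name, "period": period.label, "no_events": True,
                    "k": len(areas), "scv": math.nan, "ci_low": math.nan,
                    "ci_high": math.nan, "classification": "no_events",
                    "total_observed": 0, "total_expected": math.nan,
                })
                continue

            area_counts = area_counts_from_frames(events, py_elig, areas)
            run_seed = (config.seed + 1009 * (2 * pi + qi)) % (2**31 - 1)
            res = compute_scv(area_counts, level=config.ci_level,
                              n_boot=config.n_boot, seed=run_seed)
            scv_results[(proc_name, period.label)] = res
            scv_rows.append({
                "procedure": proc_name, "period": period.label, "no_events": False,
                "k": res.k, "scv": res.scv, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "classification": res.classification.name,
                "total_observed": res.total_observed,
                "total_expected": res.total_expected,
            })
            for c in area_counts:
                ac_rows.append({
                    "procedure": proc_name, "period": period.label, "area": c.area,
                    "observed": c.observed, "expected": c.expected,
                    "ratio": c.ratio, "person_years": c.population,
                })
        c1 = counts_by_period[config.period1.label]
        c2 = counts_by_period[config.period2.label]
        count_rows.append({
            "procedure": proc_name, "count_period1": c1, "count_period2": c2,
            "count_pct_change": percent_change(c1, c2),
        })

    rates = pd.DataFrame(rate_rows)
    p1l, p2l = config.period1.label, config.period2.label
    wide = rates.pivot_table(index=["procedure", "area"], columns="period",
                             values="rate", aggfunc="first").reset_index()
    wide = wide.rename(columns={p1l: "rate_period1", p2l: "rate_period2"})
    wide["pct_change"] = [
        percent_change(b, a) for b, a in zip(wide["rate_period1"], wide["rate_period2"])
    ]
    wide.columns.name = None

    report = ComparisonReport(
        overall=overall,
        rates=rates,
        rate_comparison=wide,
        scv=pd.DataFrame(scv_rows),
        area_counts=pd.DataFrame(ac_rows),
        count_comparison=pd.DataFrame(count_rows),
        filter_log=pd.DataFrame(filter_rows),
        scv_results=scv_results,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
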