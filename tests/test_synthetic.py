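"""The synthetic-province generator: moments, determinism, round-trips."""

from __future__ import annotations

import numpy as np
import pytest

from savakit import (
    DEFAULT_PROCEDURES,
    StudyPeriod,
    default_scenario,
    draw_area_effects,
    equal_share_areas,
    extract_cohort,
    filter_eligible,
    generate_dataset,
    generate_population,
    scv,
)
from savakit.io_discharge import records_to_frame
from savakit.pipeline import _events_frame
from savakit.standardization import area_counts_from_frames
from savakit.synthetic import ProcedureScenario

FULL_SPAN = StudyPeriod("2018-2021", 2018, 2021)


def no_decoy_scenario(**overrides):
    return default_scenario(
        private_fraction=0.0, decoy_excluded_diagnosis=0.0, decoy_out_of_age=0.0,
        **overrides,
    )


class TestAreaEffects:
    def test_zero_variance_gives_unit_effects(self):
        cfg = default_scenario(sigma2=0.0, seed=1)
        lam = draw_area_effects(cfg)
        assert all(v == 1.0 for v in lam.values())

    @pytest.mark.parametrize("dist", ["gamma", "lognormal"])
    def test_moments_match_target(self, dist):
        cfg = default_scenario(
            areas=equal_share_areas(100_000), sigma2=0.05,
            rr_distribution=dist, seed=12,
        )
        lam = np.array(list(draw_area_effects(cfg).values()))
        assert lam.mean() == pytest.approx(1.0, abs=0.01)
        assert lam.var() == pytest.approx(0.05, abs=0.005)


class TestGenerateDataset:
    def test_same_seed_is_byte_identical(self):
        a = generate_dataset(default_scenario(seed=9))
        b = generate_dataset(default_scenario(seed=9))
        assert records_to_frame(a[0]).equals(records_to_frame(b[0]))
        assert a[2] == b[2]
        assert a[1].frame.equals(b[1].frame)

    def test_round_trip_without_decoys(self):
        """With decoys off the cohort filters recover the generated counts
        exactly, per procedure, period and area."""
        cfg = no_decoy_scenario(seed=5, total_population=100_000)
        records, _, truth = generate_dataset(cfg)
        areas = [a for a, _ in cfg.areas]
        for period in (StudyPeriod("pre", 2018, 2019), StudyPeriod("post", 2020, 2021)):
            eligible = filter_eligible(records, period, areas)
            for name, proc in DEFAULT_PROCEDURES.items():
                cohort = extract_cohort(eligible, proc)
                got = {a: 0 for a in areas}
                for r in cohort:
                    got[r.area] += 1
                want = {
                    a: sum(truth["true_counts"][name][str(y)][a] for y in period.years)
                    for a in areas
                }
                assert got == want

    def test_all_decoys_removed_by_filters(self):
        cfg = default_scenario(seed=6, total_population=100_000)
        records, _, truth = generate_dataset(cfg)
        decoys = set(truth["decoy_record_ids"])
        assert decoys  # scenario defaults do generate decoys
        eligible = filter_eligible(records, FULL_SPAN, [a for a, _ in cfg.areas])
        for proc in DEFAULT_PROCEDURES.values():
            cohort_ids = {r.record_id for r in extract_cohort(eligible, proc)}
            assert cohort_ids.isdisjoint(decoys)

    def test_pandemic_reduction_factor(self):
        """A 0.25 factor from 2020 cuts the post-period count to ~25% of the
        pre-period count, within Poisson noise."""
        cfg = no_decoy_scenario(
            seed=13, sigma2=0.0,
            procedures={"vein_stripping": ProcedureScenario(400.0, "454.9")},
            covid_reduction={"vein_stripping": 0.25},
        )
        _, _, truth = generate_dataset(cfg)
        counts = truth["true_counts"]["vein_stripping"]
        pre = sum(sum(counts[str(y)].values()) for y in (2018, 2019))
        post = sum(sum(counts[str(y)].values()) for y in (2020, 2021))
        sd = np.sqrt(post + 0.0625 * pre)  # var of post - 0.25*pre
        assert abs(post - 0.25 * pre) <= 3 * sd

    def test_population_table_follows_shares(self):
        cfg = default_scenario(seed=0)
        pop = generate_population(cfg)
        year_total = pop.frame[pop.frame["year"] == 2018]["count"].sum()
        assert year_total == pytest.approx(cfg.total_population, rel=1e-6)
        bz = pop.frame[(pop.frame["year"] == 2018) & (pop.frame["area"] == "bolzano")][
            "count"
        ].sum()
        assert bz / year_total == pytest.approx(0.45, rel=1e-6)


class TestPipelineRecovery:
    def test_scv_recovers_sigma2_through_full_chain(self):
        """Generate -> filter -> cohort -> self-standardized expected counts
        -> SCV, at 50 equal areas: the replicate-mean SCV sits within
        Monte-Carlo error of 100*sigma2 = 5."""
        period = StudyPeriod("pre", 2018, 2019)
        vals = []
        for rep in range(10):
            cfg = no_decoy_scenario(
                seed=100 + rep, sigma2=0.05,
                areas=equal_share_areas(50),
                years=(2018, 2019),
                procedures={"vein_stripping": ProcedureScenario(1000.0, "454.9")},
                covid_reduction={},
            )
            records, pop, _ = generate_dataset(cfg)
            areas = [a for a, _ in cfg.areas]
            cohort = extract_cohort(
                filter_eligible(records, period, areas),
                DEFAULT_PROCEDURES["vein_stripping"],
            )
            events = _events_frame(cohort, pop.age_bands)
            ac = area_counts_from_frames(events, pop.person_years(period), areas)
            vals.append(scv(ac))
        mean = np.mean(vals)
        sem = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(mean - 5.0) <= 3 * sem
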