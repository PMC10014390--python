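"""The SCV statistic, its classification, bootstrap CI and spread measures."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from savakit import (
    AreaCounts,
    VariationLevel,
    classify_scv,
    compute_scv,
    scv,
    scv_confidence_interval,
    variation_summary,
)


def scv_oracle(y, e) -> Fraction:
    """Exact-rational hand expansion of the statistic, kept independent of
    the array implementation."""
    k = len(y)
    total = Fraction(0)
    for yi, ei in zip(y, e):
        yi, ei = Fraction(yi), Fraction(ei)
        total += (yi - ei) ** 2 / ei**2 - 1 / ei
    return Fraction(100, k) * total


SMALL_CASES = [
    ((100, 100), (100, 100)),
    ((150, 50), (100, 100)),
    ((12, 8, 10), (10, 10, 10)),
    ((0, 5), (2, 3)),
    ((7, 1, 3, 9), (4, 5, 6, 2)),
    ((1, 1, 1, 1), (1, 1, 1, 1)),
    ((30, 0, 12), (14, 14, 14)),
]


class TestScv:
    @pytest.mark.parametrize("y,e", SMALL_CASES)
    def test_matches_exact_arithmetic_oracle(self, y, e):
        assert scv(y, e) == pytest.approx(float(scv_oracle(y, e)), rel=1e-12)

    def test_frozen_hand_values(self):
        assert scv([100, 100], [100, 100]) == pytest.approx(-1.0)
        assert scv([150, 50], [100, 100]) == pytest.approx(24.0)
        assert scv([12, 8, 10], [10, 10, 10]) == pytest.approx(-22 / 3)

    def test_observed_equal_expected_gives_noise_correction_only(self):
        e = [50, 80, 120]
        assert scv(e, e) == pytest.approx(-(100 / 3) * sum(1 / x for x in e), rel=1e-12)

    def test_accepts_area_counts_objects(self):
        ac = [AreaCounts("a", 150, 100.0), AreaCounts("b", 50, 100.0)]
        assert scv(ac) == pytest.approx(24.0)

    @given(
        ye=st.lists(
            st.tuples(st.integers(0, 200), st.integers(1, 200)),
            min_size=2, max_size=8,
        ),
        seed=st.integers(0, 1000),
    )
    def test_permutation_invariance(self, ye, seed):
        y = [p[0] for p in ye]
        e = [float(p[1]) for p in ye]
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(y))
        assert scv(y, e) == pytest.approx(
            scv([y[i] for i in perm], [e[i] for i in perm]), rel=1e-12
        )

    def test_input_validation(self):
        with pytest.raises(ValueError):
            scv([1], [1])          # k < 2
        with pytest.raises(ValueError):
            scv([1, 2], [1, 0])    # e_i <= 0
        with pytest.raises(ValueError):
            scv([1, -2], [1, 1])   # negative count


class TestClassification:
    @pytest.mark.parametrize(
        "value,level",
        [
            (-2.0, VariationLevel.no_variation),
            (0.43, VariationLevel.no_variation),
            (1.0, VariationLevel.minimal),
            (2.41, VariationLevel.minimal),
            (3.0, VariationLevel.medium),
            (5.99, VariationLevel.medium),
            (6.0, VariationLevel.high),
            (8.42, VariationLevel.high),
            (10.0, VariationLevel.very_high),
            (280.75, VariationLevel.very_high),
        ],
    )
    def test_thresholds_left_closed(self, value, level):
        assert classify_scv(value) is level

    @given(a=st.floats(-50, 400), b=st.floats(-50, 400))
    def test_monotone_in_argument(self, a, b):
        lo, hi = sorted([a, b])
        assert classify_scv(lo) <= classify_scv(hi)


class TestConfidenceInterval:
    def test_deterministic_given_seed(self):
        ac = [AreaCounts("a", 130, 100.0), AreaCounts("b", 70, 100.0),
              AreaCounts("c", 95, 100.0)]
        one = scv_confidence_interval(ac, seed=42)
        two = scv_confidence_interval(ac, seed=42)
        assert one == two
        assert one != scv_confidence_interval(ac, seed=43)

    def test_interval_behaviour_when_y_equals_e(self):
        """With y = e the point estimate sits at the replicate-support infimum
        -(100/k)*sum(1/e_i); the percentile interval lies at or above it and
        straddles the true no-variation value 0."""
        e = [200.0, 200.0, 200.0, 200.0]
        lo, hi = scv_confidence_interval(e, e, seed=7)
        null = -(100 / 4) * sum(1 / x for x in e)
        assert scv(e, e) == pytest.approx(null)
        assert null <= lo <= 0.0 <= hi

    def test_width_shrinks_with_expected_counts(self):
        """At fixed area ratios and k, more events means a tighter interval."""
        ratios = np.array([1.5, 0.7, 1.2, 0.6])
        widths = []
        for base in (1e2, 1e3, 1e4):
            e = np.full(4, base)
            y = e * ratios
            lo, hi = scv_confidence_interval(y, e, seed=5)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_full_result_object(self):
        ac = [AreaCounts("a", 150, 100.0), AreaCounts("b", 50, 100.0)]
        res = compute_scv(ac, seed=1)
        assert res.scv == pytest.approx(24.0)
        assert res.k == 2
        assert res.classification is VariationLevel.very_high
        assert res.per_area_ratio == {"a": 1.5, "b": 0.5}
        assert res.total_observed == 200

    def test_rejects_bad_settings(self):
        ac = [AreaCounts("a", 1, 1.0), AreaCounts("b", 1, 1.0)]
        with pytest.raises(ValueError):
            scv_confidence_interval(ac, level=1.2)
        with pytest.raises(ValueError):
            scv_confidence_interval(ac, n_boot=10)


class TestVariationSummary:
    def test_constant_rates(self):
        s = variation_summary([10, 10, 10])
        assert (s.range, s.extremal_quotient, s.sd, s.cv) == (0.0, 1.0, 0.0, 0.0)

    def test_spread_of_area_rates(self):
        s = variation_summary([137.22, 43.24, 13.79, 12.47])
        assert s.range == pytest.approx(124.75)
        assert s.extremal_quotient == pytest.approx(137.22 / 12.47)

    def test_sample_standard_deviation_uses_n_minus_1(self):
        s = variation_summary([1.0, 3.0])
        assert s.sd == pytest.approx(np.sqrt(2.0))

    @given(c=st.floats(0.1, 100))
    def test_scale_equivariance(self, c):
        base = [4.0, 9.0, 25.0]
        s1 = variation_summary(base)
        s2 = variation_summary([c * r for r in base])
        assert s2.range == pytest.approx(c * s1.range, rel=1e-9)
        assert s2.extremal_quotient == pytest.approx(s1.extremal_quotient, rel=1e-9)
        assert s2.cv == pytest.approx(s1.cv, rel=1e-9)

    def test_zero_minimum_flags_extremal_quotient_undefined(self):
        s = variation_summary([0.0, 5.0])
        assert s.extremal_quotient is None
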