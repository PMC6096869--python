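"""The four threshold transformations and their inversion identities."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icucea import (
    CETPolicy,
    IcuCourse,
    SurvivalOutcome,
    annual_cost_threshold,
    cost_threshold,
    duration_threshold,
    probability_threshold,
    quality_threshold,
    simple_ce_ratio,
)

policies = st.builds(
    CETPolicy,
    threshold_per_qaly=st.floats(min_value=1_000.0, max_value=500_000.0),
    premium_multiplier=st.floats(min_value=1.0, max_value=3.0),
)


class TestProbabilityThreshold:
    @pytest.mark.parametrize(
        "cost, cet, life_years, raw, percent",
        [
            (26_000.0, 30_000.0, 10.0, 26_000.0 / 300_000.0, 9),
            (60_000.0, 100_000.0, 10.0, 0.06, 6),
            (26_000.0, 30_000.0, 70.0, 26_000.0 / 2_100_000.0, 1),
        ],
    )
    def test_reference_scenarios(self, cost, cet, life_years, raw, percent):
        res = probability_threshold(cost, CETPolicy(cet), life_years, 1.0)
        assert res.raw_value == pytest.approx(raw, rel=1e-12)
        assert res.display_value == percent
        assert res.unit == "fraction"
        assert res.feasible

    def test_zero_cost_gives_zero_feasible_threshold(self, uk_policy):
        res = probability_threshold(0.0, uk_policy, 10.0, 1.0)
        assert res.raw_value == 0.0
        assert res.feasible

    def test_threshold_above_one_is_infeasible(self, uk_policy):
        # £1M course, 10 QALYs on offer: no survival chance can justify it
        res = probability_threshold(1_000_000.0, uk_policy, 10.0, 1.0)
        assert res.raw_value > 1.0
        assert not res.feasible

    @pytest.mark.parametrize("life_years, utility", [(0.0, 1.0), (10.0, 0.0), (-1.0, 1.0)])
    def test_denominator_collapse_is_an_error(self, uk_policy, life_years, utility):
        with pytest.raises(ValueError):
            probability_threshold(26_000.0, uk_policy, life_years, utility)

    @given(
        cost=st.floats(min_value=1.0, max_value=1e6),
        life_years=st.floats(min_value=0.5, max_value=80.0),
        policy=policies,
    )
    @settings(max_examples=200)
    def test_inversely_proportional_to_duration_of_survival(self, cost, life_years, policy):
        base = probability_threshold(cost, policy, life_years, 1.0).raw_value
        doubled = probability_threshold(cost, policy, 2.0 * life_years, 1.0).raw_value
        assert doubled == pytest.approx(base / 2.0, rel=1e-9)


class TestCostThreshold:
    @pytest.mark.parametrize(
        "cet, expected",
        [(30_000.0, 300_000.0), (100_000.0, 1_000_000.0)],
    )
    def test_ten_full_quality_years(self, cet, expected):
        res = cost_threshold(CETPolicy(cet), 10.0, 1.0, 0.0, 0.0)
        assert res.raw_value == pytest.approx(expected)
        assert res.feasible

    def test_identical_qaly_outcomes_allow_no_extra_cost(self, uk_policy):
        res = cost_threshold(uk_policy, 10.0, 1.0, 10.0, 1.0)
        assert res.raw_value == 0.0
        assert res.feasible

    def test_dominant_reference_arm_flags_infeasible(self, uk_policy):
        res = cost_threshold(uk_policy, 5.0, 0.5, 10.0, 1.0)
        assert res.raw_value < 0.0
        assert not res.feasible


class TestDurationThreshold:
    @pytest.mark.parametrize(
        "p, life_years, expected_display",
        [
            (1.0, 10.0, 231),  # 230.77 days, adult ICU
            (1.0, 70.0, 1615),  # newborn ICU
            (0.5, 10.0, 115),
        ],
    )
    def test_reference_scenarios(self, uk_policy, p, life_years, expected_display):
        res = duration_threshold(uk_policy, p, life_years, 1.0, 1300.0)
        assert res.display_value == expected_display
        assert res.unit == "days"

    def test_raw_value_kept_at_full_precision(self, uk_policy):
        res = duration_threshold(uk_policy, 1.0, 10.0, 1.0, 1300.0)
        assert res.raw_value == pytest.approx(300_000.0 / 1300.0, rel=1e-12)

    def test_zero_survival_probability_gives_zero_days(self, uk_policy):
        assert duration_threshold(uk_policy, 0.0, 10.0, 1.0, 1300.0).raw_value == 0.0

    def test_zero_daily_cost_is_an_error(self, uk_policy):
        with pytest.raises(ValueError):
            duration_threshold(uk_policy, 1.0, 10.0, 1.0, 0.0)

    @given(
        p=st.floats(min_value=0.0, max_value=1.0),
        k=st.floats(min_value=0.1, max_value=1.0),
        policy=policies,
    )
    @settings(max_examples=200)
    def test_linear_in_survival_probability(self, p, k, policy):
        full = duration_threshold(policy, 1.0, 10.0, 1.0, 1300.0).raw_value
        part = duration_threshold(policy, p * k, 10.0, 1.0, 1300.0).raw_value
        assert part == pytest.approx(full * p * k, rel=1e-9, abs=1e-12)


class TestOngoingTreatment:
    @pytest.mark.parametrize(
        "cet, utility, expected",
        [(30_000.0, 0.1, 3_000.0), (30_000.0, 1.0, 30_000.0), (100_000.0, 0.4, 40_000.0)],
    )
    def test_annual_cost_threshold(self, cet, utility, expected):
        res = annual_cost_threshold(CETPolicy(cet), utility)
        assert res.raw_value == pytest.approx(expected)
        assert res.unit == "money/year"

    @pytest.mark.parametrize(
        "annual_cost, expected, feasible",
        [(12_000.0, 0.4, True), (42_853.0, 42_853.0 / 30_000.0, False), (0.0, 0.0, True)],
    )
    def test_quality_threshold(self, uk_policy, annual_cost, expected, feasible):
        res = quality_threshold(annual_cost, uk_policy)
        assert res.raw_value == pytest.approx(expected, rel=1e-12)
        assert res.feasible is feasible

    @given(q=st.floats(min_value=0.0, max_value=1.0), policy=policies)
    @settings(max_examples=200)
    def test_annual_cost_and_quality_thresholds_are_mutual_inverses(self, q, policy):
        annual = annual_cost_threshold(policy, q).raw_value
        assert quality_threshold(annual, policy).raw_value == pytest.approx(
            q, rel=1e-12, abs=1e-15
        )


class TestInversionOracles:
    """Plugging any threshold back into the CE ratio must reproduce the CET."""

    scenario = dict(daily_cost=1300.0, los_days=20.0, life_years=10.0, utility=1.0)

    @given(
        policy=policies,
        daily_cost=st.floats(min_value=10.0, max_value=10_000.0),
        los=st.floats(min_value=0.5, max_value=365.0),
        life_years=st.floats(min_value=0.5, max_value=80.0),
        utility=st.floats(min_value=0.05, max_value=1.0),
    )
    @settings(max_examples=200)
    def test_ratio_at_probability_threshold_equals_cet(
        self, policy, daily_cost, los, life_years, utility
    ):
        course = IcuCourse(daily_cost, los)
        p_t = probability_threshold(course.total_cost, policy, life_years, utility)
        if not 0.0 < p_t.raw_value <= 1.0:
            return  # infeasible point: no admissible probability attains the CET
        ratio = simple_ce_ratio(
            course, SurvivalOutcome(p_t.raw_value, life_years, utility)
        )
        assert ratio == pytest.approx(policy.effective_threshold, rel=1e-9)

    @given(
        policy=policies,
        daily_cost=st.floats(min_value=10.0, max_value=10_000.0),
        p=st.floats(min_value=0.05, max_value=1.0),
        life_years=st.floats(min_value=0.5, max_value=80.0),
        utility=st.floats(min_value=0.05, max_value=1.0),
    )
    @settings(max_examples=200)
    def test_ratio_at_duration_threshold_equals_cet(
        self, policy, daily_cost, p, life_years, utility
    ):
        d_t = duration_threshold(policy, p, life_years, utility, daily_cost)
        ratio = simple_ce_ratio(
            IcuCourse(daily_cost, d_t.raw_value),
            SurvivalOutcome(p, life_years, utility),
        )
        assert ratio == pytest.approx(policy.effective_threshold, rel=1e-9)

    @given(premium=st.floats(min_value=1.0, max_value=3.0))
    @settings(max_examples=100)
    def test_every_threshold_scales_linearly_with_the_premium(self, premium):
        base = CETPolicy(30_000.0)
        raised = base.with_premium(premium)
        assert probability_threshold(26_000.0, raised, 10.0).raw_value == pytest.approx(
            probability_threshold(26_000.0, base, 10.0).raw_value / premium, rel=1e-12
        )
        assert duration_threshold(raised, 1.0, 10.0, 1.0, 1300.0).raw_value == pytest.approx(
            duration_threshold(base, 1.0, 10.0, 1.0, 1300.0).raw_value * premium, rel=1e-12
        )
        assert cost_threshold(raised, 10.0, 1.0).raw_value == pytest.approx(
            cost_threshold(base, 10.0, 1.0).raw_value * premium, rel=1e-12
        )
        assert annual_cost_threshold(raised, 0.5).raw_value == pytest.approx(
            annual_cost_threshold(base, 0.5).raw_value * premium, rel=1e-12
        )
        assert quality_threshold(12_000.0, raised).raw_value == pytest.approx(
            quality_threshold(12_000.0, base).raw_value / premium, rel=1e-12
        )
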