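import pytest

from icucea import CETPolicy, IcuCourse, SurvivalOutcome


@pytest.fixture
def uk_policy() -> CETPolicy:
    """UK willingness-to-pay: £30,000 per QALY."""
    return CETPolicy(threshold_per_qaly=30_000.0, currency="GBP", label="uk")


@pytest.fixture
def us_policy() -> CETPolicy:
    """US willingness-to-pay benchmark: $100,000 per QALY."""
    return CETPolicy(threshold_per_qaly=100_000.0, currency="USD", label="us")


@pytest.fixture
def uk_course() -> IcuCourse:
    """20-day adult ICU stay at £1,300/day (total £26,000)."""
    return IcuCourse(daily_cost=1300.0, length_of_stay_days=20.0, currency="GBP")


@pytest.fixture
def full_recovery() -> SurvivalOutcome:
    """Certain survival, 10 years at full utility."""
    return SurvivalOutcome(
        probability_of_survival=1.0, life_years_if_survive=10.0, utility_weight=1.0
    )
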