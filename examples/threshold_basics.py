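"""The four decision thresholds for a reference intensive-care stay.

A 20-day adult ICU course at £1,300/day costs £26,000 up front. Judged
against a £30,000/QALY willingness-to-pay threshold with 10 expected
life-years at full utility, each threshold answers one clinical question:
how low a survival chance, how high a cost, how long a stay, and how low a
quality of life still leaves the treatment cost-effective.
"""

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

uk = CETPolicy(threshold_per_qaly=30_000.0, currency="GBP", label="uk")
course = IcuCourse(daily_cost=1300.0, length_of_stay_days=20.0)

ratio = simple_ce_ratio(course, SurvivalOutcome(1.0, 10.0, 1.0))
print(f"cost per QALY of the stay (certain survival): £{ratio:,.0f}")
# £2,600/QALY: far below the threshold when survival is certain.

p_t = probability_threshold(course.total_cost, uk, life_years=10.0, utility=1.0)
print(f"probability threshold: {p_t.display_value:.0f}% (raw {p_t.raw_value:.4f})")
# Treatment stays cost-effective down to a 9% chance of survival.

c_t = cost_threshold(uk, duration2=10.0, quality2=1.0)
print(f"cost threshold for 10 full-quality years: £{c_t.display_value:,.0f}")
# No more than £300,000 may be spent to buy 10 QALYs at £30,000 each.

d_t = duration_threshold(uk, p_survival=1.0, life_years=10.0, utility=1.0,
                         daily_cost=1300.0)
print(f"duration threshold at £1,300/day: {d_t.display_value:.0f} days")
# Guaranteed 10-year survival justifies at most 231 days in intensive care.

q_t = quality_threshold(annual_cost=12_000.0, policy=uk)
print(f"quality threshold for £12,000/year ongoing care: q >= {q_t.raw_value:.1f}")
# Lifelong treatment at £12,000/year is cost-effective only above utility 0.4.

a_t = annual_cost_threshold(uk, utility=0.1)
print(f"annual cost ceiling at utility 0.1: £{a_t.display_value:,.0f}/year")
# At very low quality of life even £3,000/year exhausts the threshold.
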