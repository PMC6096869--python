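"""Regenerate the two reference scenario tables.

The duration table crosses survival probabilities with care settings
(neonatal / paediatric / adult, 70 / 60 / 10 expected life-years, £1,300/day)
to give the maximum cost-effective stay in days. The cost-per-QALY table
prices a 93-day stay at graded utility for UK and US cost assumptions; a
``*`` marks cells whose ratio exceeds the jurisdiction's threshold
(£30,000 or $100,000 per QALY).
"""

from icucea import CETPolicy, cost_per_qaly_table, duration_table
from icucea.tables import (
    REFERENCE_PROBABILITIES,
    REFERENCE_SETTINGS,
    REFERENCE_STAY_DAYS,
    REFERENCE_UTILITIES,
)

uk = CETPolicy(30_000.0, "GBP", "uk")
us = CETPolicy(100_000.0, "USD", "us")

durations = duration_table(REFERENCE_PROBABILITIES, REFERENCE_SETTINGS, uk)
print("Maximum cost-effective stay (days) by survival probability:\n")
print(durations.to_markdown())

costs = cost_per_qaly_table(
    REFERENCE_UTILITIES, REFERENCE_STAY_DAYS, 10.0, [(1300.0, uk), (3000.0, us)]
)
print("\nCost per QALY of a 93-day stay by utility (* exceeds the CET):\n")
print(costs.to_markdown())
# The UK column first exceeds £30,000/QALY at utility 0.4 (30,225), the US
# column first exceeds $100,000/QALY at 0.2 (139,500).
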