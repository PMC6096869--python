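"""Quality/probability frontier when long-term residential care may follow.

A survivor of a short ICU stay needs residential care (£42,853/year over a
10-year horizon) with probability p, living at utility q; otherwise they
live independently at full utility. For each p the frontier reports the
care-branch utility q* at which the episode's expected cost per expected
QALY equals £30,000 — below q* the treatment is not cost-effective.
q* > 1 means no utility level rescues it; q* <= 0 means the threshold never
binds at that care risk.
"""

from icucea import CETPolicy, quality_frontier

uk = CETPolicy(30_000.0, "GBP", "uk")
p_grid = [0.2, 0.3, 0.41, 0.5, 0.6, 0.68, 0.8, 1.0]

print("p_care   q* (1-week, £7,000)   q* (2-week, £14,000)")
one_week = quality_frontier(7_000.0, uk, 42_853.0, 10.0, p_grid)
two_week = quality_frontier(14_000.0, uk, 42_853.0, 10.0, p_grid)
for a, b in zip(one_week, two_week):
    note = "" if a.feasible else "  (non-binding or unattainable)"
    print(f"{a.p_care:6.2f}   {a.q_star:19.3f}   {b.q_star:20.3f}{note}")
# The frontier rises with the care risk: around p = 0.41 a binding utility
# threshold appears for the 1-week stay, and beyond p = 0.68 even full
# utility leaves the stay above the threshold (q* > 1). The dearer 2-week
# stay sits above the 1-week frontier at every p.
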