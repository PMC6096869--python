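# icucea — cost-effectiveness thresholds for intensive-care decisions

When is it justifiable *not* to provide requested intensive care? One
resource-based answer applies the same cost-effectiveness threshold (CET)
that public health systems already use to fund treatments — about
£20,000–30,000 per quality-adjusted life year (QALY) in the UK, roughly
US$100,000–150,000 in the US — to the decision to continue or withhold
intensive care. `icucea` implements that framework for health economists,
intensivists and ethicists who want to compute, probe and debate the
resulting thresholds.

## The model

Against a withdrawal comparator with no cost and no health effect, the
cost-effectiveness of a course of intensive care is

```
CE = C̄ / (p̄ · d̄ₛ · q̄)
```

where `C̄` is the up-front cost of the course (daily cost × length of stay),
`p̄` the probability of survival, `d̄ₛ` the life expectancy if the patient
survives, and `q̄` the health-utility weight of the survivor's health state.
Fixing a CET and solving `CE ≤ CET` for one parameter at a time gives four
closed-form decision thresholds:

| threshold | formula | question it answers |
|---|---|---|
| probability `P_T` | `C̄ / (CET · d̄ₛ · q̄)` | how low a survival chance is too low? |
| cost `C_T` | `CET · (d₂q₂ − d₁q₁)` | how costly is too costly? |
| duration `D_T` | `CET · p̄ · d̄ₛ · q̄ / C̄_d` | how long a stay is too long? |
| quality `Q_T` | `C̄ / CET` (annual cost of ongoing treatment) | how low a quality of life is too low? |

On top of these the package regenerates the reference duration and
cost-per-QALY tables, models the quality/probability frontier when survivors
may need long-term residential care, and quantifies parameter uncertainty
with one-way sweeps and seeded probabilistic sensitivity analysis
(cost-effectiveness acceptability curves).

## Worked example

A 20-day adult ICU stay at £1,300/day (£26,000), judged against
£30,000/QALY with 10 expected life-years at full utility
(`examples/threshold_basics.py`):

```text
cost per QALY of the stay (certain survival): £2,600
probability threshold: 9% (raw 0.0867)
cost threshold for 10 full-quality years: £300,000
duration threshold at £1,300/day: 231 days
quality threshold for £12,000/year ongoing care: q >= 0.4
annual cost ceiling at utility 0.1: £3,000/year
```

Reading: with certain survival the stay costs £2,600 per QALY — far within
the threshold. It remains cost-effective down to a 9% survival chance; at
most £300,000 may be spent to buy those 10 QALYs; at £1,300/day that funds
at most 231 days; and lifelong care costing £12,000/year is cost-effective
only if the resulting quality of life is valued at 0.4 or more.

The other example scripts cover the reference tables
(`reference_tables.py`), the residential-care frontier
(`residential_care_frontier.py`) and the acceptability curve
(`acceptability_curve.py`).

## Command line

The same operations are exposed as a thin CLI:

```bash
icucea threshold probability --los-days 20 --life-years 10
icucea --preset us threshold duration --life-years 10
icucea table cost-per-qaly --arms both
icucea frontier --icu-cost 7000 --care-cost 42853
icucea psa --seed 7 --n 10000 --dist 'p_survival:beta:alpha=2,beta=8'
icucea fixtures --out fixtures/ --seed 1
```

Results go to stdout (JSON by default, `--format csv|text`); logs go to
stderr. Jurisdiction presets `uk` and `us` are built in; more can be added
via `--config presets.yaml`, and `--premium` applies a CET multiplier such
as an end-of-life premium.

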