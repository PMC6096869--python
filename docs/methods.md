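# Methods

## Decision model

The package evaluates a single decision ratio, not a multi-state cohort
model. Continuing intensive care is compared with a withdrawal comparator
assumed to carry no cost and no health effect, so the incremental
cost-effectiveness ratio ΔC/ΔE collapses to C̄ / (p̄ · d̄ₛ · q̄): total
up-front course cost over expected QALYs. All costs are treated as incurred
up front; future costs and QALYs are **not discounted**. A `discount_rate`
config default (0 by default) is accepted for forward compatibility but is
applied nowhere — replication paths are undiscounted by design. Health
utilities are *inputs*: the package does no utility elicitation (time
trade-off, standard gamble), and no empirical survival prediction.

Each threshold is the exact algebraic inversion of the ratio at the CET.
This yields the package's central correctness oracle: plugging any computed
threshold back into the ratio must reproduce the CET to 1e-9 relative, which
the property suite enforces across randomly drawn scenarios (hypothesis,
derandomised). The annual-cost and quality thresholds for ongoing treatment
(CET·q̄ and C̄/CET) are mutual inverses and are tested as such.

## Parameters, units, defaults

| parameter | unit | reference default | note |
|---|---|---|---|
| CET | money/QALY | £30,000 (uk), $100,000 (us) | lower band edges £20,000 / — kept in the preset record |
| daily ICU cost | money/day | £1,300 (uk adult), $3,000 (us medical) | |
| length of stay | days | 20 (worked example), 93 ("3-month" table stay) | |
| survival horizon | years | 10 adult, 60 paediatric, 70 neonatal | predicted survival if discharged alive |
| utility q̄ | [0, 1] | 1 unless varied | 1 = full health |
| premium multiplier | ≥ 1 | 1 | models policies (e.g. an end-of-life premium) that raise the CET; every threshold scales linearly with it |

The 93-day "3-month" stay is fixed by the table itself: 12,090 × 10 / 1,300
= 93 exactly (and 27,900 × 10 / 3,000 = 93), so 93 days is adopted rather
than 90 or 91.

## Numerical conventions

- **Full precision internally, rounding only at display.** Display rounding
  is half-up: days and money to whole units (161.54 → 162, 1038.46 → 1038,
  15,112.5 → 15,113), probabilities to the nearest whole percent (0.0867 →
  9%), utilities to two decimals. Half-up is adopted because it reproduces
  every printed reference cell, including all three whole-percent
  probability thresholds; ceiling rounding would also give 9% but fails
  elsewhere.
- **CET boundary inclusive:** a ratio exactly equal to the threshold counts
  as cost-effective. Table exceedance flags are therefore *strict* (> CET),
  which reproduces the reference flagging pattern exactly (30,225 flagged
  against £30,000; 93,000 not flagged against $100,000).
- **Undefined ratios are signalled, never smuggled.** A zero-QALY
  denominator raises `UndefinedRatioError` in the deterministic path, yields
  `ratio=None` with dominance `undefined` in the incremental path, and
  counts as *not cost-effective* in PSA (denominators stay `n_samples`).
- **Degenerate thresholds:** a probability threshold with zero life-years or
  zero utility is an error (the framework presupposes positive expected
  benefit), not infinity. A negative cost threshold (reference arm dominant)
  is reported as-is with `feasible=False`, not clamped.
- Currencies are opaque labels; any cross-currency comparison raises.

## Long-term-care frontier

A survivor needs residential care (annual cost c, default £42,853/year) with
probability p over the horizon h (default 10 years), living at utility q;
otherwise they live independently at utility 1. Expected cost is
C_icu + p·c·h and expected QALYs h·(p·q + (1−p)). The frontier solves
expected-cost / expected-QALYs = CET for the *care-branch* utility:

    q*(p) = [ (C_icu + p·c·h) / (CET·h) − (1 − p) ] / p

The utility weight is attached to the residential-care branch only because
the quality judgement at issue concerns the patient predicted to need care;
the convention is configurable through `LongTermCareScenario`. Only
q* ∈ (0, 1] is a binding, attainable threshold: q* > 1 means no utility
level makes treatment cost-effective at that care risk, q* ≤ 0 means the
threshold never binds. A brute-force scan of the ICER over q in 1e-4 steps
serves as the independent oracle for the closed form.

Known limitation: the published qualitative readings of this frontier (full
utility exceeded beyond a 50% care risk; q = 0.5 requiring care risk below
20%) are not reproduced by any obvious parameterisation of the stated inputs
— the closed form gives ≈68% at q = 1 for the £7,000 one-week stay. The
model is exposed with explicit conventions and these figures are *not*
treated as reference values.

## Sensitivity analysis

One-way sweeps re-evaluate the simplified ratio over an even grid of a
single parameter. PSA samples parameters independently — beta for
probabilities and utilities, gamma for costs and durations, point masses via
`fixed` — so out-of-range draws are impossible by construction and no
clipping is needed. Sampling uses `numpy.random.default_rng(seed)` with the
seed required, never implicit; identical seeds reproduce results
bit-for-bit. The acceptability curve is the fraction of draws whose ICER is
defined and ≤ each CET grid point, hence monotone in the CET by
construction (asserted, not assumed). Parameters are sampled independently;
correlation between parameters and value-of-information analysis are out of
scope.

Default problem sizes are deliberately small — the thresholds are closed
form and the PSA examples use 10,000 draws — so the entire suite runs in a
few seconds on one CPU.

## Synthetic scenarios and what tests show

The fixture generator emits the four reference scenarios verbatim plus
seeded random scenarios spanning the admissible ranges (daily cost
£100–5,000, stay 1–365 days, survival 1–100%, 0.5–80 life-years, utility
0.05–1, CET 10,000–150,000). These exercise the algebraic identities over
realistic magnitudes; they do not emulate correlations between prognosis,
cost and quality of life seen in real cohorts, nor censoring, discounting or
time-varying daily costs. Passing tests therefore certify the arithmetic and
its invariants, not the clinical realism of any particular parameter choice
— the thresholds are inputs to a normative debate, not bedside rules.

## Design choices made where the design was open

- Preset registry ships two jurisdictions (`uk`, `us`) with the reference
  CETs and daily costs; user config may add presets but not shadow the
  built-ins.
- The duration table holds utility at 1 (the table predates the quality
  dimension conceptually); the underlying operation still accepts q for
  combined use.
- The CLI is a thin serialisation layer — a property test compares its JSON
  output against direct library calls to keep arithmetic out of it.
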