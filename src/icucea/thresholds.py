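"""Closed-form decision thresholds derived from a fixed CET.

With a fixed cost-effectiveness threshold (CET) per QALY, the simplified
ratio C / (p * d_s * q) <= CET can be solved for any one parameter while the
others are held fixed, yielding four thresholds:

* probability threshold  P_T = C / (CET * d_s * q)   — minimum survival
  probability for a course of given cost;
* cost threshold         C_T = CET * (d2*q2 - d1*q1) — maximum incremental
  cost for a given QALY gain;
* duration threshold     D_T = CET * p * d_s * q / C_d — maximum length of
  stay (days) at a given daily cost;
* for ongoing (permanent) treatment, the annual cost threshold CET * q and
  its inverse, the quality threshold Q_T = annual_cost / CET — the minimum
  utility at which treatment with a given yearly cost stays cost-effective.

Every operation returns a :class:`ThresholdResult` carrying both the raw
(full-precision) value and its display form under the package's rounding
policy, plus a feasibility flag: a probability or utility threshold above 1
means no parameter value can make the treatment cost-effective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Dict

from icucea._rounding import (
    display_days,
    display_money,
    display_percent,
    display_utility,
)
from icucea.economics import CETPolicy


@dataclass(frozen=True)
class ThresholdResult:
    """A computed threshold: raw value, display form, unit and feasibility.

    ``raw_value`` is the unrounded number in the threshold's natural unit
    (fraction, money, days, utility or money/year). ``display_value`` is the
    rounded form — for probability thresholds it is a whole *percent*.
    ``feasible`` is False exactly when the raw value falls outside the
    parameter's admissible range (e.g. a required survival probability or
    utility above 1, or a negative cost threshold when the reference arm
    dominates). ``inputs_echo`` records every input for provenance.
    """

    kind: str
    raw_value: float
    display_value: float
    unit: str
    feasible: bool
    inputs_echo: Dict[str, Any]

    def __float__(self) -> float:
        return self.raw_value


def _echo(policy: CETPolicy, **kwargs: Any) -> Dict[str, Any]:
    rec: Dict[str, Any] = dict(kwargs)
    rec.update(
        cet=policy.threshold_per_qaly,
        premium=policy.premium_multiplier,
        effective_cet=policy.effective_threshold,
        currency=policy.currency,
    )
    return rec


def probability_threshold(
    cost: float,
    policy: CETPolicy,
    life_years: float,
    utility: float = 1.0,
) -> ThresholdResult:
    """Minimum survival probability for a course of given total cost.

    P_T = C / (CET * d_s * q). Displayed as a whole percent. The framework
    presupposes a positive expected benefit: ``life_years`` and ``utility``
    must be strictly positive (the denominator collapses otherwise).
    """
    if not math.isfinite(cost) or cost < 0:
        raise ValueError(f"cost must be non-negative, got {cost!r}")
    if life_years <= 0:
        raise ValueError(
            f"life_years must be > 0 for a probability threshold, got {life_years!r}"
        )
    if not 0 < utility <= 1:
        raise ValueError(f"utility must be in (0, 1], got {utility!r}")
    raw = cost / (policy.effective_threshold * life_years * utility)
    return ThresholdResult(
        kind="probability",
        raw_value=raw,
        display_value=display_percent(raw),
        unit="fraction",
        feasible=raw <= 1.0,
        inputs_echo=_echo(policy, cost=cost, life_years=life_years, utility=utility),
    )


def cost_threshold(
    policy: CETPolicy,
    duration2: float,
    quality2: float,
    duration1: float = 0.0,
    quality1: float = 0.0,
) -> ThresholdResult:
    """Maximum incremental cost for a given incremental QALY gain.

    C_T = CET * ((d2 * q2) - (d1 * q1)). The default reference arm (0, 0) is
    withdrawal of treatment. A negative value (reference arm yields more
    QALYs) is reported as-is with ``feasible=False`` rather than clamped, so
    callers can detect dominance.
    """
    for name, dur in (("duration2", duration2), ("duration1", duration1)):
        if not math.isfinite(dur) or dur < 0:
            raise ValueError(f"{name} must be >= 0, got {dur!r}")
    for name, q in (("quality2", quality2), ("quality1", quality1)):
        if not 0 <= q <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {q!r}")
    raw = policy.effective_threshold * (duration2 * quality2 - duration1 * quality1)
    return ThresholdResult(
        kind="cost",
        raw_value=raw,
        display_value=display_money(raw),
        unit="money",
        feasible=raw >= 0.0,
        inputs_echo=_echo(
            policy,
            duration2=duration2,
            quality2=quality2,
            duration1=duration1,
            quality1=quality1,
        ),
    )


def duration_threshold(
    policy: CETPolicy,
    p_survival: float,
    life_years: float,
    utility: float,
    daily_cost: float,
) -> ThresholdResult:
    """Maximum cost-effective length of stay, in days.

    D_T = CET * p * d_s * q / C_d. With guaranteed survival (p = 1) this is
    the plain duration threshold; scaling by the survival probability gives
    the generalisation used for the duration table across care settings.
    """
    if not 0 <= p_survival <= 1:
        raise ValueError(f"p_survival must be in [0, 1], got {p_survival!r}")
    if not math.isfinite(life_years) or life_years < 0:
        raise ValueError(f"life_years must be >= 0, got {life_years!r}")
    if not 0 <= utility <= 1:
        raise ValueError(f"utility must be in [0, 1], got {utility!r}")
    if not math.isfinite(daily_cost) or daily_cost <= 0:
        raise ValueError(f"daily_cost must be > 0, got {daily_cost!r}")
    raw = (policy.effective_threshold * p_survival * life_years * utility) / daily_cost
    return ThresholdResult(
        kind="duration",
        raw_value=raw,
        display_value=display_days(raw),
        unit="days",
        feasible=True,
        inputs_echo=_echo(
            policy,
            p_survival=p_survival,
            life_years=life_years,
            utility=utility,
            daily_cost=daily_cost,
        ),
    )


def annual_cost_threshold(policy: CETPolicy, utility: float) -> ThresholdResult:
    """Maximum yearly cost of ongoing treatment at a given utility.

    C_T = CET * q: one year of ongoing treatment buys q QALYs, so the yearly
    spend must not exceed that fraction of the threshold.
    """
    if not 0 <= utility <= 1:
        raise ValueError(f"utility must be in [0, 1], got {utility!r}")
    raw = policy.effective_threshold * utility
    return ThresholdResult(
        kind="annual_cost",
        raw_value=raw,
        display_value=display_money(raw),
        unit="money/year",
        feasible=True,
        inputs_echo=_echo(policy, utility=utility),
    )


def quality_threshold(annual_cost: float, policy: CETPolicy) -> ThresholdResult:
    """Minimum utility at which ongoing treatment stays cost-effective.

    Q_T = annual_cost / CET, the inverse of :func:`annual_cost_threshold`.
    A value above 1 means no utility level makes the ongoing treatment
    cost-effective (``feasible=False``) — e.g. permanent residential care
    whose yearly cost exceeds the CET outright.
    """
    if not math.isfinite(annual_cost) or annual_cost < 0:
        raise ValueError(f"annual_cost must be >= 0, got {annual_cost!r}")
    raw = annual_cost / policy.effective_threshold
    return ThresholdResult(
        kind="quality",
        raw_value=raw,
        display_value=display_utility(raw),
        unit="utility",
        feasible=raw <= 1.0,
        inputs_echo=_echo(policy, annual_cost=annual_cost),
    )
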