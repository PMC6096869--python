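"""Core cost-effectiveness types and ratios.

The decision problem is whether to provide a course of intensive care to a
patient who will otherwise die. The general instrument is the incremental
cost-effectiveness ratio (ICER),

    ICER = (C2 - C1) / (E2 - E1) = dC / dE,

cost difference over effect difference between a comparison and a reference
intervention, with effects measured in quality-adjusted life years (QALYs).
When the reference is withdrawal/withholding of intensive care — assumed to
carry no cost and no health benefit — the ratio simplifies to

    CE = C / (p * d_s * q),

where C is the up-front cost of the course, p the probability of survival,
d_s the life expectancy if the patient survives, and q the health-utility
weight of the survivor's health state. A treatment is funded when its ratio
does not exceed a jurisdiction's cost-effectiveness threshold (CET) per QALY.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Optional


class UndefinedRatioError(ZeroDivisionError):
    """Raised when a cost-effectiveness ratio has a zero effect denominator."""


class CurrencyMismatchError(ValueError):
    """Raised when two money quantities carry different currency labels.

    Currencies are opaque labels and are never converted; mixing them is
    always a caller error.
    """


def _check_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and non-negative, got {value!r}")


def _check_unit_interval(name: str, value: float) -> None:
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class CETPolicy:
    """A willingness-to-pay threshold per QALY.

    Parameters
    ----------
    threshold_per_qaly:
        Money per QALY, strictly positive. Typical published ranges are
        £20,000–30,000 (UK NHS/NICE practice) and US$100,000–150,000.
    currency:
        ISO-like currency label, e.g. ``"GBP"`` or ``"USD"``.
    label:
        Free-text jurisdiction or policy name.
    premium_multiplier:
        Dimensionless factor >= 1 applied to the threshold, modelling
        policies such as an end-of-life premium that deliberately raise the
        cost-effectiveness bar for certain life-extending treatments.
    """

    threshold_per_qaly: float
    currency: str = "GBP"
    label: str = ""
    premium_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold_per_qaly) or self.threshold_per_qaly <= 0:
            raise ValueError(
                f"threshold_per_qaly must be > 0, got {self.threshold_per_qaly!r}"
            )
        if not math.isfinite(self.premium_multiplier) or self.premium_multiplier < 1:
            raise ValueError(
                f"premium_multiplier must be >= 1, got {self.premium_multiplier!r}"
            )

    @property
    def effective_threshold(self) -> float:
        """Threshold actually applied: base threshold times the premium."""
        return self.threshold_per_qaly * self.premium_multiplier

    def with_premium(self, premium_multiplier: float) -> "CETPolicy":
        return CETPolicy(
            threshold_per_qaly=self.threshold_per_qaly,
            currency=self.currency,
            label=self.label,
            premium_multiplier=premium_multiplier,
        )


@dataclass(frozen=True)
class IcuCourse:
    """A treatment episode: a daily cost incurred over a length of stay.

    All costs are treated as up-front; there is no discounting in the
    reference analysis (an optional annual rate is accepted by downstream
    report helpers as an off-by-default extension, but it is applied nowhere
    in the replication paths).
    """

    daily_cost: float
    length_of_stay_days: float
    currency: str = "GBP"

    def __post_init__(self) -> None:
        _check_finite_nonneg("daily_cost", self.daily_cost)
        _check_finite_nonneg("length_of_stay_days", self.length_of_stay_days)

    @property
    def total_cost(self) -> float:
        return self.daily_cost * self.length_of_stay_days


@dataclass(frozen=True)
class SurvivalOutcome:
    """The outcome triple (p, d_s, q) of a course of intensive care.

    probability_of_survival (p) in [0, 1]; life_years_if_survive (d_s) >= 0;
    utility_weight (q) in [0, 1], the preference-based weight of the
    survivor's health state (1 = full health).
    """

    probability_of_survival: float
    life_years_if_survive: float
    utility_weight: float = 1.0

    def __post_init__(self) -> None:
        _check_unit_interval("probability_of_survival", self.probability_of_survival)
        _check_finite_nonneg("life_years_if_survive", self.life_years_if_survive)
        _check_unit_interval("utility_weight", self.utility_weight)

    @property
    def expected_qalys(self) -> float:
        return (
            self.probability_of_survival
            * self.life_years_if_survive
            * self.utility_weight
        )


@dataclass(frozen=True)
class InterventionArm:
    """One arm of an incremental comparison: mean cost and mean QALYs."""

    mean_cost: float
    mean_effect: float

    def __post_init__(self) -> None:
        _check_finite_nonneg("mean_cost", self.mean_cost)
        _check_finite_nonneg("mean_effect", self.mean_effect)


#: Reference arm for ICU decisions: withdrawal carries no cost and no effect.
ZERO_ARM = InterventionArm(mean_cost=0.0, mean_effect=0.0)


class Dominance(str, Enum):
    """Sign classification of an incremental comparison."""

    COMPARISON_DOMINANT = "comparison_dominant"  # cheaper (or equal) and more effective
    REFERENCE_DOMINANT = "reference_dominant"  # dearer (or equal) and less effective
    TRADE_OFF = "trade_off"  # more costly and more effective (or the reverse)
    UNDEFINED = "undefined"  # zero effect difference: no ratio exists


@dataclass(frozen=True)
class CEResult:
    """Outcome of an incremental comparison.

    ``ratio`` is defined iff the effect difference is non-zero; an undefined
    ratio is signalled through ``dominance`` == UNDEFINED and ``ratio`` is
    ``None``, never a silently propagated division artefact.
    """

    ratio: Optional[float]
    dominance: Dominance
    cost_effective_at: Optional[bool] = None
    delta_cost: float = 0.0
    delta_effect: float = 0.0
    policy: Optional[CETPolicy] = field(default=None, repr=False)


class CostEffectiveness(NamedTuple):
    """Verdict of a threshold comparison: the flag and the headroom left."""

    cost_effective: bool
    margin: float


def expected_qalys(outcome: SurvivalOutcome) -> float:
    """Expected QALYs of a course: p * d_s * q."""
    return outcome.expected_qalys


def total_course_cost(course: IcuCourse) -> float:
    """Total up-front cost of a course: daily cost times length of stay."""
    return course.total_cost


def icer(
    comparison: InterventionArm,
    reference: InterventionArm = ZERO_ARM,
    policy: Optional[CETPolicy] = None,
) -> CEResult:
    """Incremental cost-effectiveness ratio of ``comparison`` vs ``reference``.

    Returns a :class:`CEResult` whose ``ratio`` is dC/dE when the effect
    difference is non-zero. A zero effect difference yields dominance
    ``UNDEFINED`` and ``ratio is None``. Dominance labels are assigned from
    the signs of the differences: a comparison that is no more costly and
    strictly more effective dominates, and symmetrically for the reference.
    When ``policy`` is given and the comparison yields positive incremental
    effect, ``cost_effective_at`` records whether the ratio falls within the
    policy's effective threshold (inclusive).
    """
    delta_cost = comparison.mean_cost - reference.mean_cost
    delta_effect = comparison.mean_effect - reference.mean_effect

    if delta_effect == 0.0:
        return CEResult(
            ratio=None,
            dominance=Dominance.UNDEFINED,
            delta_cost=delta_cost,
            delta_effect=delta_effect,
            policy=policy,
        )

    ratio = delta_cost / delta_effect
    if delta_effect > 0 and delta_cost <= 0:
        dominance = Dominance.COMPARISON_DOMINANT
    elif delta_effect < 0 and delta_cost >= 0:
        dominance = Dominance.REFERENCE_DOMINANT
    else:
        dominance = Dominance.TRADE_OFF

    cost_effective_at: Optional[bool] = None
    if policy is not None and delta_effect > 0:
        cost_effective_at = ratio <= policy.effective_threshold

    return CEResult(
        ratio=ratio,
        dominance=dominance,
        cost_effective_at=cost_effective_at,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        policy=policy,
    )


def simple_ce_ratio(course: IcuCourse, outcome: SurvivalOutcome) -> float:
    """Cost per QALY of a course against a zero-cost, zero-effect reference.

    Equals ``icer`` against the withdrawal arm exactly. Raises
    :class:`UndefinedRatioError` when the expected QALYs are zero.
    """
    qalys = outcome.expected_qalys
    if qalys == 0.0:
        raise UndefinedRatioError(
            "cost-effectiveness ratio undefined: expected QALYs are zero "
            f"(p={outcome.probability_of_survival}, "
            f"d_s={outcome.life_years_if_survive}, q={outcome.utility_weight})"
        )
    return course.total_cost / qalys


def is_cost_effective(
    ratio: float,
    policy: CETPolicy,
    currency: Optional[str] = None,
) -> CostEffectiveness:
    """Compare a cost-per-QALY ratio with a policy threshold.

    The boundary is inclusive: a ratio exactly equal to the effective
    threshold counts as cost-effective. ``margin`` is the effective threshold
    minus the ratio (positive = headroom, negative = exceedance). If
    ``currency`` is supplied it must match the policy's currency.
    """
    if currency is not None and currency != policy.currency:
        raise CurrencyMismatchError(
            f"ratio currency {currency!r} does not match policy currency "
            f"{policy.currency!r}"
        )
    if not math.isfinite(ratio):
        raise ValueError(f"ratio must be finite, got {ratio!r}")
    margin = policy.effective_threshold - ratio
    return CostEffectiveness(cost_effective=ratio <= policy.effective_threshold, margin=margin)
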