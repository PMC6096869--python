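"""Two-branch outcome model with possible long-term residential care.

A survivor of intensive care either needs long-term residential care (with
probability ``p_care``), accruing an annual care cost over the survival
horizon and living at utility ``utility_care``, or lives independently at
utility ``utility_no_care``. Expected cost and expected QALYs of the episode
are

    E[C] = C_icu + p_care * c_care * horizon
    E[Q] = horizon * (p_care * q_care + (1 - p_care) * q_no_care)

(survival through the ICU course is taken as certain in this model; fold a
survival probability into the horizon if needed).

The *quality frontier* asks: for each probability of needing care, what
utility ``q*`` assigned to the cared-for state makes the cost-effectiveness
ratio exactly equal the CET? Setting E[C]/E[Q] = CET with q_no_care = 1 and
solving for the care-branch utility gives the closed form

    q*(p) = [ (C_icu + p * c_care * h) / (CET * h) - (1 - p) ] / p .

q* > 1 means no utility level keeps treatment cost-effective at that care
probability; q* <= 0 means treatment is cost-effective at *any* utility (the
constraint does not bind). Both are flagged infeasible as frontier points —
only q* in (0, 1] is an attainable utility threshold.

Note the published textual readings of this frontier (a 50% care probability
exceeding the UK threshold at full utility; q = 0.5 requiring care risk
below 20%) are not reproduced by any obvious parameterisation of the stated
inputs — the closed form above gives ~68% at q = 1 for a £7,000 stay. The
model is therefore exposed with configurable conventions and the
discrepancy documented rather than silently adjusted; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List

from icucea.economics import CETPolicy, _check_finite_nonneg, _check_unit_interval


@dataclass(frozen=True)
class LongTermCareScenario:
    """An ICU episode whose survivor may need long-term residential care."""

    icu_cost: float
    p_care: float
    annual_care_cost: float
    horizon_years: float = 10.0
    utility_care: float = 1.0
    utility_no_care: float = 1.0

    def __post_init__(self) -> None:
        _check_finite_nonneg("icu_cost", self.icu_cost)
        _check_unit_interval("p_care", self.p_care)
        _check_finite_nonneg("annual_care_cost", self.annual_care_cost)
        _check_unit_interval("utility_care", self.utility_care)
        _check_unit_interval("utility_no_care", self.utility_no_care)
        if not math.isfinite(self.horizon_years) or self.horizon_years <= 0:
            raise ValueError(
                f"horizon_years must be > 0, got {self.horizon_years!r}"
            )


@dataclass(frozen=True)
class FrontierPoint:
    """One point of the quality/probability frontier.

    ``q_star`` is the care-branch utility at which the ratio equals the CET.
    ``feasible`` is True only for q_star in (0, 1]; q_star > 1 means no
    utility rescues cost-effectiveness, q_star <= 0 means the threshold
    never binds.
    """

    p_care: float
    q_star: float
    feasible: bool


def expected_cost(s: LongTermCareScenario) -> float:
    """Expected total cost: up-front ICU cost plus expected care costs.

    Care costs accrue undiscounted over the full horizon.
    """
    return s.icu_cost + s.p_care * s.annual_care_cost * s.horizon_years


def expected_qalys_lt(s: LongTermCareScenario) -> float:
    """Expected QALYs: horizon weighted by the branch-mixture utility."""
    mean_utility = s.p_care * s.utility_care + (1.0 - s.p_care) * s.utility_no_care
    return s.horizon_years * mean_utility


def frontier_utility(
    icu_cost: float,
    policy: CETPolicy,
    annual_care_cost: float,
    horizon_years: float,
    p_care: float,
) -> float:
    """Care-branch utility at which the CE ratio equals the CET (closed form)."""
    if not 0 < p_care <= 1:
        raise ValueError(
            f"p_care must be in (0, 1] on the frontier (no q dependence at 0), "
            f"got {p_care!r}"
        )
    cet = policy.effective_threshold
    total_cost = icu_cost + p_care * annual_care_cost * horizon_years
    return (total_cost / (cet * horizon_years) - (1.0 - p_care)) / p_care


def quality_frontier(
    icu_cost: float,
    policy: CETPolicy,
    annual_care_cost: float,
    horizon_years: float,
    p_grid: Iterable[float],
) -> List[FrontierPoint]:
    """Quality/probability frontier over a grid of care probabilities.

    Non-care survivors are held at full utility on the frontier. Each point
    is the utility of the residential-care state at which the episode's
    expected cost per expected QALY equals the CET exactly.
    """
    _check_finite_nonneg("icu_cost", icu_cost)
    _check_finite_nonneg("annual_care_cost", annual_care_cost)
    if horizon_years <= 0:
        raise ValueError(f"horizon_years must be > 0, got {horizon_years!r}")
    points = []
    for p in p_grid:
        q_star = frontier_utility(icu_cost, policy, annual_care_cost, horizon_years, p)
        points.append(
            FrontierPoint(p_care=p, q_star=q_star, feasible=0.0 < q_star <= 1.0)
        )
    return points
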