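"""Uncertainty analysis: one-way sweeps and probabilistic sensitivity analysis.

The closed-form thresholds rest on point assumptions (daily cost, length of
stay, survival probability, life expectancy, utility) that may each be
challenged. Two standard health-economics instruments quantify how the
cost-effectiveness verdict responds:

* a *one-way sweep* varies a single scenario parameter over a grid while the
  others stay fixed, re-evaluating the cost-per-QALY ratio at each point;
* *probabilistic sensitivity analysis* (PSA) assigns distributions to
  parameters — beta for probabilities and utilities, gamma for costs and
  durations, as is conventional — draws Monte-Carlo samples, and reports the
  fraction of samples that are cost-effective at each point of a CET grid:
  the cost-effectiveness acceptability curve (CEAC).

Sampled parameter sets with zero expected QALYs have no defined ICER; they
are counted as *not* cost-effective (rather than dropped) so acceptability
denominators always equal the number of samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from icucea.economics import UndefinedRatioError
from icucea.scenario import Scenario

#: Parameters a sweep or PSA may vary, with their admissible ranges.
_PARAM_RANGES: Dict[str, tuple] = {
    "daily_cost": (0.0, math.inf),
    "los_days": (0.0, math.inf),
    "p_survival": (0.0, 1.0),
    "life_years": (0.0, math.inf),
    "utility": (0.0, 1.0),
}

_UNIT_INTERVAL_PARAMS = frozenset({"p_survival", "utility"})
_NONNEGATIVE_PARAMS = frozenset({"daily_cost", "los_days", "life_years"})


@dataclass(frozen=True)
class ParameterDistribution:
    """Sampling distribution for one scenario parameter.

    family ``"beta"`` (parameters ``alpha``, ``beta``) is admissible only for
    [0,1]-valued parameters (survival probability, utility); family
    ``"gamma"`` (parameters ``shape``, ``scale``) only for non-negative ones
    (costs, stay, life expectancy); family ``"fixed"`` (parameter ``value``)
    pins the parameter. Out-of-range draws are impossible by construction,
    so no clipping is applied.
    """

    parameter: str
    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.parameter not in _PARAM_RANGES:
            raise ValueError(
                f"unknown parameter {self.parameter!r}; "
                f"expected one of {sorted(_PARAM_RANGES)}"
            )
        if self.family == "beta":
            if self.parameter not in _UNIT_INTERVAL_PARAMS:
                raise ValueError(
                    f"beta distributions are restricted to [0,1]-valued "
                    f"parameters, not {self.parameter!r}"
                )
            a, b = self.params.get("alpha"), self.params.get("beta")
            if a is None or b is None or a <= 0 or b <= 0:
                raise ValueError(f"beta requires alpha > 0 and beta > 0, got {self.params!r}")
        elif self.family == "gamma":
            if self.parameter not in _NONNEGATIVE_PARAMS:
                raise ValueError(
                    f"gamma distributions are restricted to non-negative "
                    f"parameters, not {self.parameter!r}"
                )
            shape, scale = self.params.get("shape"), self.params.get("scale")
            if shape is None or scale is None or shape <= 0 or scale <= 0:
                raise ValueError(
                    f"gamma requires shape > 0 and scale > 0, got {self.params!r}"
                )
        elif self.family == "fixed":
            value = self.params.get("value")
            lo, hi = _PARAM_RANGES[self.parameter]
            if value is None or not lo <= value <= hi:
                raise ValueError(
                    f"fixed value for {self.parameter!r} must lie in "
                    f"[{lo}, {hi}], got {self.params!r}"
                )
        else:
            raise ValueError(
                f"unknown family {self.family!r}; expected beta, gamma or fixed"
            )

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"], size=n)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size=n)
        return np.full(n, float(self.params["value"]))


@dataclass(frozen=True)
class PsaResult:
    """Monte-Carlo PSA output: sampled ICERs and the acceptability curve."""

    seed: int
    n_samples: int
    icers: np.ndarray  # NaN where the ratio is undefined (zero QALYs)
    cet_grid: np.ndarray
    acceptability: np.ndarray  # P(cost-effective) at each CET grid point
    quantiles: Dict[str, float]

    def acceptability_at(self, cet: float) -> float:
        idx = int(np.argmin(np.abs(self.cet_grid - cet)))
        if not math.isclose(self.cet_grid[idx], cet, rel_tol=1e-12):
            raise ValueError(f"CET {cet!r} is not on the grid")
        return float(self.acceptability[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cet": self.cet_grid, "probability_cost_effective": self.acceptability}
        )


def one_way_sweep(
    base: Scenario,
    parameter: str,
    lower: float,
    upper: float,
    n_points: int = 21,
) -> pd.DataFrame:
    """Vary one parameter over an even grid, re-evaluating the CE ratio.

    Returns a DataFrame with columns ``value`` (the parameter value),
    ``ce_ratio`` (cost per QALY; NaN where undefined) and ``cost_effective``
    (inclusive comparison against the scenario's effective CET; undefined
    ratios count as not cost-effective).
    """
    if parameter not in _PARAM_RANGES:
        raise ValueError(
            f"unknown parameter {parameter!r}; expected one of {sorted(_PARAM_RANGES)}"
        )
    lo, hi = _PARAM_RANGES[parameter]
    if not lo <= lower <= hi or not lo <= upper <= hi:
        raise ValueError(
            f"bounds [{lower}, {upper}] outside admissible range "
            f"[{lo}, {hi}] for {parameter!r}"
        )
    if not lower < upper:
        raise ValueError(f"lower must be < upper, got [{lower}, {upper}]")
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")

    values = np.linspace(lower, upper, n_points)
    ratios, flags = [], []
    for v in values:
        scen = base.replace(**{parameter: float(v)})
        try:
            ratio = scen.ce_ratio()
        except UndefinedRatioError:
            ratios.append(math.nan)
            flags.append(False)
            continue
        ratios.append(ratio)
        flags.append(scen.verdict().cost_effective)
    return pd.DataFrame({"value": values, "ce_ratio": ratios, "cost_effective": flags})


def run_psa(
    base: Scenario,
    distributions: Sequence[ParameterDistribution],
    n_samples: int,
    seed: int,
    cet_grid: Optional[Sequence[float]] = None,
) -> PsaResult:
    """Seeded Monte-Carlo PSA over a scenario.

    Parameters without a distribution stay fixed at their scenario values.
    Deterministic given ``seed``: the same seed and inputs reproduce the
    result bit-for-bit. The acceptability at a CET grid point is the
    fraction of samples whose ICER is defined and does not exceed it.
    """
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if seed is None:
        raise ValueError("seed is required; PSA has no implicit randomness")
    names = [d.parameter for d in distributions]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate distributions for parameters: {names}")
    if cet_grid is None:
        cet_grid = np.linspace(0.0, 2.0 * base.policy.effective_threshold, 41)
    cet_grid = np.asarray(cet_grid, dtype=float)

    rng = np.random.default_rng(seed)
    draws: Dict[str, np.ndarray] = {
        name: np.full(n_samples, float(getattr(base, name)))
        for name in _PARAM_RANGES
    }
    # draw in declaration order so results are reproducible for a given spec
    for dist in distributions:
        draws[dist.parameter] = dist.sample(rng, n_samples)

    cost = draws["daily_cost"] * draws["los_days"]
    qalys = draws["p_survival"] * draws["life_years"] * draws["utility"]
    with np.errstate(divide="ignore", invalid="ignore"):
        icers = np.where(qalys > 0.0, cost / qalys, np.nan)

    defined = np.isfinite(icers)
    # undefined ICERs compare as +inf: never cost-effective at any CET
    comparable = np.where(defined, icers, np.inf)
    acceptability = np.array([np.mean(comparable <= cet) for cet in cet_grid])
    if defined.any():
        qs = np.quantile(icers[defined], [0.025, 0.25, 0.5, 0.75, 0.975])
    else:
        qs = [math.nan] * 5
    quantiles = dict(zip(["q2.5", "q25", "q50", "q75", "q97.5"], map(float, qs)))

    return PsaResult(
        seed=seed,
        n_samples=n_samples,
        icers=icers,
        cet_grid=cet_grid,
        acceptability=acceptability,
        quantiles=quantiles,
    )
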