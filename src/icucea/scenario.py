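"""Flat scenario records: one ICU episode plus the policy judging it.

A scenario bundles the parameters of the simplified ratio — daily cost,
length of stay, survival probability, life expectancy, utility — with the
CET policy. Scenarios serialise as flat key-value records in JSON or YAML
with the keys ``daily_cost, los_days, p_survival, life_years, utility, cet,
currency, premium``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Any, Dict, Union

import yaml

from icucea.economics import (
    CETPolicy,
    CostEffectiveness,
    IcuCourse,
    SurvivalOutcome,
    is_cost_effective,
    simple_ce_ratio,
)

_FIELDS = (
    "daily_cost",
    "los_days",
    "p_survival",
    "life_years",
    "utility",
    "cet",
    "currency",
    "premium",
)


@dataclass(frozen=True)
class Scenario:
    """One intensive-care decision scenario."""

    daily_cost: float
    los_days: float
    p_survival: float
    life_years: float
    utility: float = 1.0
    cet: float = 30_000.0
    currency: str = "GBP"
    premium: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        # constructing the components validates every field
        self.course
        self.outcome
        self.policy

    @property
    def course(self) -> IcuCourse:
        return IcuCourse(
            daily_cost=self.daily_cost,
            length_of_stay_days=self.los_days,
            currency=self.currency,
        )

    @property
    def outcome(self) -> SurvivalOutcome:
        return SurvivalOutcome(
            probability_of_survival=self.p_survival,
            life_years_if_survive=self.life_years,
            utility_weight=self.utility,
        )

    @property
    def policy(self) -> CETPolicy:
        return CETPolicy(
            threshold_per_qaly=self.cet,
            currency=self.currency,
            label=self.label,
            premium_multiplier=self.premium,
        )

    def ce_ratio(self) -> float:
        """Cost per QALY of this scenario against the withdrawal comparator."""
        return simple_ce_ratio(self.course, self.outcome)

    def verdict(self) -> CostEffectiveness:
        return is_cost_effective(self.ce_ratio(), self.policy, currency=self.currency)

    def replace(self, **changes: Any) -> "Scenario":
        return replace(self, **changes)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> Dict[str, Any]:
        rec = asdict(self)
        if not rec["label"]:
            rec.pop("label")
        return rec

    @classmethod
    def from_dict(cls, rec: Dict[str, Any]) -> "Scenario":
        unknown = set(rec) - set(_FIELDS) - {"label"}
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        missing = {"daily_cost", "los_days", "p_survival", "life_years"} - set(rec)
        if missing:
            raise ValueError(f"missing scenario keys: {sorted(missing)}")
        return cls(**rec)

    def save(self, path: Union[str, Path]) -> Path:
        """Write the scenario as YAML (.yaml/.yml) or JSON (.json)."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: Union[str, Path]) -> "Scenario":
        path = Path(path)
        text = path.read_text()
        rec = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(rec, dict):
            raise ValueError(f"scenario file {path} does not contain a mapping")
        return cls.from_dict(rec)
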