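"""Scenario tables: duration thresholds and cost/QALY across utility levels.

Two reference tables are regenerated here.

The *duration table* crosses survival probabilities with care-setting
presets (neonatal, paediatric and adult intensive care, with predicted
survival of 70, 60 and 10 years respectively at £1,300/day) and reports the
maximum cost-effective length of stay in whole days.

The *cost-per-QALY table* prices a prolonged stay (the reference case is a
3-month stay, implemented as 93 days) at graded utility levels for UK
(£1,300/day vs £30,000/QALY) and US ($3,000/day vs $100,000/QALY) cost
assumptions, flagging every cell whose ratio strictly exceeds the CET —
the analogue of the italicised cells in printed versions of this analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Dict, List, Sequence, Tuple

import pandas as pd

from icucea._rounding import display_money
from icucea.economics import CETPolicy
from icucea.thresholds import duration_threshold


@dataclass(frozen=True)
class CareSettingPreset:
    """A care setting: predicted survival if discharged alive, and daily cost."""

    label: str
    life_years: float
    daily_cost: float
    currency: str = "GBP"

    def __post_init__(self) -> None:
        if not math.isfinite(self.life_years) or self.life_years <= 0:
            raise ValueError(f"life_years must be > 0, got {self.life_years!r}")
        if not math.isfinite(self.daily_cost) or self.daily_cost <= 0:
            raise ValueError(f"daily_cost must be > 0, got {self.daily_cost!r}")


#: Reference care settings: predicted survival 70 / 60 / 10 years at £1300/day.
NICU = CareSettingPreset("NICU", life_years=70.0, daily_cost=1300.0)
PICU = CareSettingPreset("PICU", life_years=60.0, daily_cost=1300.0)
AICU = CareSettingPreset("AICU", life_years=10.0, daily_cost=1300.0)
REFERENCE_SETTINGS: Tuple[CareSettingPreset, ...] = (NICU, PICU, AICU)

#: Survival-probability rows of the reference duration table.
REFERENCE_PROBABILITIES: Tuple[float, ...] = (0.1, 0.25, 0.5, 0.75)

#: Utility rows of the reference cost/QALY table.
REFERENCE_UTILITIES: Tuple[float, ...] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1)

#: Reference prolonged stay: 3 months, implemented as 93 days (this is the
#: stay length that makes the UK column read 12,090 at full utility:
#: 12,090 * 10 / 1300 = 93).
REFERENCE_STAY_DAYS = 93.0


@dataclass(frozen=True)
class TableCell:
    """One table cell: full-precision value, display form, exceedance flag."""

    raw: float
    display: float
    exceeds_cet: bool = False


@dataclass(frozen=True)
class ThresholdTable:
    """A labelled grid of threshold cells with full input provenance."""

    row_labels: Tuple[Any, ...]
    column_labels: Tuple[str, ...]
    cells: Tuple[Tuple[TableCell, ...], ...]
    provenance: Dict[str, Any] = field(default_factory=dict)

    def cell(self, row: Any, column: str) -> TableCell:
        return self.cells[self.row_labels.index(row)][self.column_labels.index(column)]

    def to_dataframe(self, display: bool = True) -> pd.DataFrame:
        """Table as a DataFrame of display (default) or raw values."""
        data = [
            [c.display if display else c.raw for c in row_cells]
            for row_cells in self.cells
        ]
        return pd.DataFrame(data, index=list(self.row_labels), columns=list(self.column_labels))

    def flags_dataframe(self) -> pd.DataFrame:
        data = [[c.exceeds_cet for c in row_cells] for row_cells in self.cells]
        return pd.DataFrame(data, index=list(self.row_labels), columns=list(self.column_labels))

    def to_csv(self, path: Any) -> None:
        """Write display values with exceedance flags as parallel columns."""
        df = self.to_dataframe()
        flags = self.flags_dataframe()
        out = pd.concat(
            [df, flags.add_suffix(" exceeds_cet")], axis=1
        )
        out.index.name = self.provenance.get("row_name", "row")
        out.to_csv(path)

    def to_markdown(self) -> str:
        """Human-readable rendering; exceeding cells are marked with ``*``."""
        df = self.to_dataframe().astype(object)
        flags = self.flags_dataframe()
        for r in df.index:
            for c in df.columns:
                val = df.loc[r, c]
                txt = f"{val:,}" if isinstance(val, (int, float)) else str(val)
                df.loc[r, c] = txt + ("*" if flags.loc[r, c] else "")
        return df.to_markdown()


def duration_table(
    probabilities: Sequence[float],
    settings: Sequence[CareSettingPreset],
    policy: CETPolicy,
) -> ThresholdTable:
    """Maximum cost-effective stay (days) per survival probability and setting.

    cell(p, setting) = CET * p * life_years / daily_cost, at full utility,
    displayed in whole days. With the reference presets this reproduces the
    12-cell duration table (e.g. 162 days for a 10% survival chance in
    neonatal care; 173 days for 75% in adult care).
    """
    if not probabilities or not settings:
        raise ValueError("probabilities and settings must be non-empty")
    rows = []
    for p in probabilities:
        row = []
        for s in settings:
            res = duration_threshold(
                policy,
                p_survival=p,
                life_years=s.life_years,
                utility=1.0,
                daily_cost=s.daily_cost,
            )
            row.append(TableCell(raw=res.raw_value, display=res.display_value))
        rows.append(tuple(row))
    return ThresholdTable(
        row_labels=tuple(probabilities),
        column_labels=tuple(s.label for s in settings),
        cells=tuple(rows),
        provenance={
            "kind": "duration",
            "row_name": "p_survival",
            "cet": policy.threshold_per_qaly,
            "premium": policy.premium_multiplier,
            "settings": {
                s.label: {"life_years": s.life_years, "daily_cost": s.daily_cost}
                for s in settings
            },
        },
    )


def cost_per_qaly_table(
    utilities: Sequence[float],
    stay_days: float,
    life_years: float,
    arms: Sequence[Tuple[float, CETPolicy]],
) -> ThresholdTable:
    """Cost per QALY of a prolonged stay at graded utility, per cost arm.

    cell(q, arm) = (daily_cost * stay_days) / (life_years * q), displayed as
    whole currency units. ``exceeds_cet`` is strict (ratio > CET), matching
    the convention that a cell exactly at the threshold is still funded.
    Survival through the stay is taken as certain, as in the reference case.
    """
    if not utilities:
        raise ValueError("utilities must be non-empty")
    if any(not 0 < q <= 1 for q in utilities):
        raise ValueError("utilities must lie in (0, 1]")
    if stay_days <= 0:
        raise ValueError(f"stay_days must be > 0, got {stay_days!r}")
    if life_years <= 0:
        raise ValueError(f"life_years must be > 0, got {life_years!r}")
    if not arms:
        raise ValueError("arms must be non-empty")

    labels = []
    for daily_cost, policy in arms:
        label = policy.label or policy.currency
        labels.append(f"{label}" if label not in labels else f"{label} ({daily_cost}/day)")

    rows = []
    for q in utilities:
        row = []
        for daily_cost, policy in arms:
            ratio = (daily_cost * stay_days) / (life_years * q)
            row.append(
                TableCell(
                    raw=ratio,
                    display=display_money(ratio),
                    exceeds_cet=ratio > policy.effective_threshold,
                )
            )
        rows.append(tuple(row))
    return ThresholdTable(
        row_labels=tuple(utilities),
        column_labels=tuple(labels),
        cells=tuple(rows),
        provenance={
            "kind": "cost_per_qaly",
            "row_name": "utility",
            "stay_days": stay_days,
            "life_years": life_years,
            "arms": [
                {
                    "daily_cost": dc,
                    "cet": pol.threshold_per_qaly,
                    "premium": pol.premium_multiplier,
                    "currency": pol.currency,
                }
                for dc, pol in arms
            ],
        },
    )
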