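"""Jurisdiction presets, config loading and fixture generation.

Two jurisdiction presets are built in and always available:

* ``uk`` — CET £20,000–30,000/QALY (default 30,000), adult general ICU at
  £1,300/day;
* ``us`` — CET US$100,000–150,000/QALY (default 100,000), medical ICU at
  $3,000/day.

A config file (YAML, JSON accepted) can add further presets as flat records
under a ``presets`` list; unknown keys and invariant violations are rejected
with named errors. Reference scenarios (a 20-day adult stay under each
jurisdiction, plus neonatal and paediatric variants) are exposed through
:func:`builtin_scenarios` and written to disk by :func:`generate_fixtures`
together with seeded random scenarios for property testing.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import yaml

from icucea.economics import CETPolicy
from icucea.scenario import Scenario


class ConfigError(ValueError):
    """A config file failed to parse or violated a preset invariant."""


@dataclass(frozen=True)
class JurisdictionPreset:
    """A jurisdiction's CET band and typical daily ICU cost."""

    label: str
    cet_low: float
    cet_high: float
    default_cet: float
    daily_icu_cost: float
    currency: str

    def __post_init__(self) -> None:
        if not 0 < self.cet_low <= self.default_cet <= self.cet_high:
            raise ConfigError(
                f"preset {self.label!r}: require 0 < cet_low <= default_cet "
                f"<= cet_high, got cet_low={self.cet_low}, "
                f"default_cet={self.default_cet}, cet_high={self.cet_high}"
            )
        if not math.isfinite(self.daily_icu_cost) or self.daily_icu_cost <= 0:
            raise ConfigError(
                f"preset {self.label!r}: daily_icu_cost must be > 0, "
                f"got {self.daily_icu_cost!r}"
            )

    def policy(self, premium: float = 1.0) -> CETPolicy:
        return CETPolicy(
            threshold_per_qaly=self.default_cet,
            currency=self.currency,
            label=self.label,
            premium_multiplier=premium,
        )


_UK = JurisdictionPreset(
    label="uk",
    cet_low=20_000.0,
    cet_high=30_000.0,
    default_cet=30_000.0,
    daily_icu_cost=1_300.0,
    currency="GBP",
)
_US = JurisdictionPreset(
    label="us",
    cet_low=100_000.0,
    cet_high=150_000.0,
    default_cet=100_000.0,
    daily_icu_cost=3_000.0,
    currency="USD",
)


def builtin_presets() -> Dict[str, JurisdictionPreset]:
    """The built-in jurisdiction presets, keyed by label."""
    return {"uk": _UK, "us": _US}


def builtin_scenarios() -> Dict[str, Scenario]:
    """Reference decision scenarios.

    ``uk-20day``: 20-day adult stay at £1,300/day, certain survival for 10
    years at full utility, judged against £30,000/QALY — the worked example
    whose cost is £26,000 and whose ratio is £2,600/QALY. ``us-20day`` is the
    parallel US case; ``nicu``/``picu`` swap in 70- and 60-year horizons.
    """
    return {
        "uk-20day": Scenario(
            daily_cost=1300.0, los_days=20.0, p_survival=1.0, life_years=10.0,
            utility=1.0, cet=30_000.0, currency="GBP", label="uk-20day",
        ),
        "us-20day": Scenario(
            daily_cost=3000.0, los_days=20.0, p_survival=1.0, life_years=10.0,
            utility=1.0, cet=100_000.0, currency="USD", label="us-20day",
        ),
        "nicu": Scenario(
            daily_cost=1300.0, los_days=20.0, p_survival=1.0, life_years=70.0,
            utility=1.0, cet=30_000.0, currency="GBP", label="nicu",
        ),
        "picu": Scenario(
            daily_cost=1300.0, los_days=20.0, p_survival=1.0, life_years=60.0,
            utility=1.0, cet=30_000.0, currency="GBP", label="picu",
        ),
    }


@dataclass(frozen=True)
class Config:
    """Validated configuration: jurisdiction presets and global defaults."""

    presets: Dict[str, JurisdictionPreset]
    defaults: Dict[str, float]

    def preset(self, label: str) -> JurisdictionPreset:
        try:
            return self.presets[label]
        except KeyError:
            raise ConfigError(
                f"unknown preset {label!r}; available: {sorted(self.presets)}"
            ) from None


_PRESET_KEYS = {"label", "cet_low", "cet_high", "default_cet", "daily_icu_cost", "currency"}
_TOP_KEYS = {"presets", "defaults"}
_DEFAULT_KEYS = {"premium", "discount_rate"}


def load_config(path: Optional[Union[str, Path]] = None) -> Config:
    """Load and validate a config file; built-in presets are always present.

    ``path=None`` or an empty file yields the built-ins only. Unknown keys —
    at the top level, inside a preset record, or among the defaults — are
    rejected by name. A user preset may not shadow a built-in label.
    """
    presets = builtin_presets()
    defaults: Dict[str, float] = {"premium": 1.0, "discount_rate": 0.0}
    if path is None:
        return Config(presets=presets, defaults=defaults)

    path = Path(path)
    text = path.read_text()
    try:
        raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if raw is None:
        return Config(presets=presets, defaults=defaults)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")

    for rec in raw.get("presets", []) or []:
        if not isinstance(rec, dict):
            raise ConfigError(f"{path}: each preset must be a mapping, got {rec!r}")
        extra = set(rec) - _PRESET_KEYS
        if extra:
            raise ConfigError(
                f"{path}: preset {rec.get('label', '?')!r} has unknown keys "
                f"{sorted(extra)}"
            )
        missing = _PRESET_KEYS - set(rec)
        if missing:
            raise ConfigError(
                f"{path}: preset {rec.get('label', '?')!r} missing keys "
                f"{sorted(missing)}"
            )
        preset = JurisdictionPreset(**rec)
        if preset.label in builtin_presets():
            raise ConfigError(
                f"{path}: preset label {preset.label!r} shadows a built-in preset"
            )
        presets[preset.label] = preset

    user_defaults = raw.get("defaults", {}) or {}
    extra = set(user_defaults) - _DEFAULT_KEYS
    if extra:
        raise ConfigError(f"{path}: unknown default keys {sorted(extra)}")
    defaults.update({k: float(v) for k, v in user_defaults.items()})
    if defaults["premium"] < 1.0:
        raise ConfigError(
            f"{path}: defaults.premium must be >= 1, got {defaults['premium']}"
        )
    return Config(presets=presets, defaults=defaults)


def save_config(config: Config, path: Union[str, Path]) -> Path:
    """Write a config so that ``load_config(save_config(c)) == c``."""
    path = Path(path)
    user_presets = [
        asdict(p) for label, p in sorted(config.presets.items())
        if label not in builtin_presets()
    ]
    doc = {"presets": user_presets, "defaults": dict(config.defaults)}
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def generate_fixtures(output_dir: Union[str, Path], seed: int, n_random: int = 8) -> List[Path]:
    """Write reference and seeded random scenario files.

    Emits the four reference scenarios verbatim plus ``n_random`` random
    scenarios spanning the admissible parameter ranges (for property tests).
    Deterministic: the same seed writes identical files.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, scen in builtin_scenarios().items():
        paths.append(scen.save(output_dir / f"{name}.yaml"))

    rng = np.random.default_rng(seed)
    for i in range(n_random):
        scen = Scenario(
            daily_cost=float(np.round(rng.uniform(100.0, 5000.0), 2)),
            los_days=float(np.round(rng.uniform(1.0, 365.0), 1)),
            p_survival=float(np.round(rng.uniform(0.01, 1.0), 4)),
            life_years=float(np.round(rng.uniform(0.5, 80.0), 2)),
            utility=float(np.round(rng.uniform(0.05, 1.0), 4)),
            cet=float(np.round(rng.uniform(10_000.0, 150_000.0), 0)),
            currency=str(rng.choice(["GBP", "USD"])),
            premium=float(rng.choice([1.0, 1.5, 2.0])),
            label=f"random-{i:02d}",
        )
        paths.append(scen.save(output_dir / f"random-{i:02d}.yaml"))
    return paths
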