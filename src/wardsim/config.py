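"""YAML configuration loading.

Recognized top-level keys:

``demand:``   multipliers (5 values), noise_cv, specialing_group
``engine:``   absence {rn, hca}, tolerance, higher_availability,
              empirical_availability (group -> period -> {bank, agency})
``costing:``  base, on_cost, agency_cap, temp_band_mix,
              unsocial {uplift, night_period, weekend_days}

Any omitted key falls back to the shipped defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .costing import RateTable, UnsocialRule
from .demand import CareMultipliers
from .engine import (
    EMPIRICAL_AVAILABILITY,
    AbsenceRates,
    FlexPolicy,
    SimulationParams,
    ToleranceRule,
)


@dataclass(frozen=True)
class AppConfig:
    params: SimulationParams = field(default_factory=SimulationParams)
    rates: RateTable = field(default_factory=RateTable)
    empirical_availability: dict = field(
        default_factory=lambda: {
            g: {p: dict(c) for p, c in t.items()}
            for g, t in EMPIRICAL_AVAILABILITY.items()
        }
    )
    higher_availability: float = 0.75

    def policy(self, name: str) -> FlexPolicy:
        if name == "empirical":
            return FlexPolicy.empirical(self.empirical_availability)
        if name == "higher":
            return FlexPolicy.higher(self.higher_availability)
        return FlexPolicy.from_name(name)


def load_config(path: str | Path | None) -> AppConfig:
    """Build an :class:`AppConfig`, merging a YAML file over defaults."""
    if path is None:
        return AppConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    demand = raw.get("demand", {})
    engine = raw.get("engine", {})
    costing = raw.get("costing", {})

    multipliers = CareMultipliers(
        tuple(demand["multipliers"])
    ) if "multipliers" in demand else CareMultipliers()
    absence_raw = engine.get("absence", {})
    params = SimulationParams(
        multipliers=multipliers,
        noise_cv=float(demand.get("noise_cv", 0.1)),
        specialing_group=demand.get("specialing_group", "hca"),
        absence=AbsenceRates(
            rn=float(absence_raw.get("rn", 0.03)),
            hca=float(absence_raw.get("hca", 0.04)),
        ),
        tolerance=ToleranceRule(tau=float(engine.get("tolerance", 0.15))),
    )

    default_rates = RateTable()
    unsocial_raw = costing.get("unsocial", {})
    rates = RateTable(
        base=costing.get("base", default_rates.base),
        on_cost=float(costing.get("on_cost", default_rates.on_cost)),
        agency_cap=costing.get("agency_cap", default_rates.agency_cap),
        temp_band_mix=costing.get("temp_band_mix", default_rates.temp_band_mix),
        unsocial=UnsocialRule(
            uplift=float(unsocial_raw.get("uplift", 0.30)),
            night_period=int(unsocial_raw.get("night_period", 3)),
            weekend_days=tuple(unsocial_raw.get("weekend_days", (5, 6))),
        ),
    )

    empirical = engine.get("empirical_availability")
    kwargs = {}
    if empirical is not None:
        kwargs["empirical_availability"] = {
            g: {int(p): dict(c) for p, c in t.items()} for g, t in empirical.items()
        }
    return AppConfig(
        params=params,
        rates=rates,
        higher_availability=float(engine.get("higher_availability", 0.75)),
        **kwargs,
    )
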