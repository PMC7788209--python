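"""Annual staffing cost accounting.

Permanent staff are salaried: the full planned establishment is costed for
the year whether or not individuals were absent, and redeployed hours are
cost-neutral.  Bank hours are priced at base x (1 + 0.5 x on-cost) — half of
bank staff attract superannuation — and agency hours at capped rates.  An
unsocial-hours uplift applies to the night period and to all weekend
periods.  The headline outcome is cost per patient-day, where one
patient-day is four patient shifts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .demand import GROUPS
from .planner import EstablishmentPlan
from .synthetic import N_PERIODS, WEEKEND_DAYS

CHANNELS = ("permanent", "bank", "agency")

DEFAULT_BASE_RATES: dict[str, dict[str, float]] = {
    "rn": {"5": 17.0, "6": 21.0, "7": 25.0},
    "hca": {"2": 10.5, "3": 11.5},
}
#: Capped agency rates: about 1.35 x base, i.e. a modest premium over the
#: loaded bank rate, so that filling more shortfall always costs more in
#: total than filling less with a costlier channel mix.
DEFAULT_AGENCY_CAPS: dict[str, dict[str, float]] = {
    "rn": {"5": 23.0, "6": 28.0, "7": 34.0},
    "hca": {"2": 14.0, "3": 15.5},
}
DEFAULT_TEMP_BAND_MIX: dict[str, dict[str, float]] = {
    "rn": {"5": 0.80, "6": 0.20},
    "hca": {"2": 1.00},
}


@dataclass(frozen=True)
class UnsocialRule:
    """Which periods attract the unsocial-hours uplift."""

    uplift: float = 0.30
    night_period: int = 3
    weekend_days: tuple[int, ...] = WEEKEND_DAYS

    def __post_init__(self) -> None:
        if self.uplift < 0:
            raise ValueError("uplift must be >= 0")


@dataclass(frozen=True)
class RateTable:
    """Hourly rates by staff group, pay band and hiring channel."""

    base: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_BASE_RATES.items()}
    )
    on_cost: float = 0.20
    agency_cap: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_AGENCY_CAPS.items()}
    )
    temp_band_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {g: dict(m) for g, m in DEFAULT_TEMP_BAND_MIX.items()}
    )
    unsocial: UnsocialRule = field(default_factory=UnsocialRule)

    def __post_init__(self) -> None:
        if self.on_cost < 0:
            raise ValueError("on_cost must be >= 0")
        for group, bands in self.base.items():
            if any(r < 0 for r in bands.values()):
                raise ValueError(f"negative base rate for group {group}")

    def scaled(self, factor: float) -> "RateTable":
        """All monetary rates multiplied by ``factor`` (homogeneity checks)."""
        return RateTable(
            base={g: {b: r * factor for b, r in m.items()} for g, m in self.base.items()},
            on_cost=self.on_cost,
            agency_cap={
                g: {b: r * factor for b, r in m.items()}
                for g, m in self.agency_cap.items()
            },
            temp_band_mix={g: dict(m) for g, m in self.temp_band_mix.items()},
            unsocial=self.unsocial,
        )


@dataclass(frozen=True)
class CostBreakdown:
    permanent_cost: float
    bank_cost: float
    agency_cost: float
    unsocial_supplement: float
    patient_days: float

    @property
    def total_cost(self) -> float:
        return (
            self.permanent_cost
            + self.bank_cost
            + self.agency_cost
            + self.unsocial_supplement
        )

    @property
    def cost_per_patient_day(self) -> float:
        if self.patient_days <= 0:
            return float("nan")
        return self.total_cost / self.patient_days


def hourly_rate(group: str, band: str, channel: str, rates: RateTable) -> float:
    """Hourly cost of one worked/planned hour for a given channel.

    permanent: base x (1 + on-cost); bank: base x (1 + 0.5 x on-cost);
    agency: the capped rate, independent of on-costs.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; use one of {CHANNELS}")
    table = rates.agency_cap if channel == "agency" else rates.base
    bands = table.get(group, {})
    if band not in bands:
        raise KeyError(
            f"unknown band {band!r} for group {group!r}; known bands: "
            f"{sorted(bands)}"
        )
    if channel == "agency":
        return float(bands[band])
    base = float(bands[band])
    if channel == "permanent":
        return base * (1.0 + rates.on_cost)
    return base * (1.0 + 0.5 * rates.on_cost)


def blended_rate(
    band_mix: Mapping[str, float], group: str, channel: str, rates: RateTable
) -> float:
    """Band-mix-weighted hourly rate."""
    return sum(
        frac * hourly_rate(group, band, channel, rates)
        for band, frac in band_mix.items()
    )


def _blended_base(band_mix: Mapping[str, float], group: str, rates: RateTable) -> float:
    table = rates.base[group]
    return sum(frac * float(table[band]) for band, frac in band_mix.items())


def cost_year(
    records: pd.DataFrame,
    plan: EstablishmentPlan,
    band_mixes: Mapping[str, Mapping[str, Mapping[str, float]]],
    rates: RateTable,
    n_days: int = 365,
) -> CostBreakdown:
    """Price a simulated year.

    ``band_mixes`` maps ward_id -> group -> band -> fraction (permanent
    staff); temporary staff are priced at the hospital-level
    ``rates.temp_band_mix``.  The unsocial supplement is uplift x blended
    base rate applied to hours in the night period on weekdays and all
    periods on weekend days.
    """
    if records.empty:
        raise ValueError("record stream is empty")
    unsocial = rates.unsocial
    dows = np.arange(n_days) % 7
    n_weekend = int(np.isin(dows, unsocial.weekend_days).sum())
    n_weekday = n_days - n_weekend

    permanent = 0.0
    supplement = 0.0
    for ward_id, wp in plan.wards.items():
        mix = band_mixes[ward_id]
        for g, group in enumerate(GROUPS):
            daily = wp.group_daily_hours(g)
            rate = blended_rate(mix[group], group, "permanent", rates)
            permanent += daily * n_days * rate
            night_hours = float(wp.hours[unsocial.night_period, g])
            unsocial_hours = night_hours * n_weekday + daily * n_weekend
            supplement += (
                unsocial.uplift * _blended_base(mix[group], group, rates) * unsocial_hours
            )

    rec_dow = records["day"].to_numpy() % 7
    is_unsocial = np.isin(rec_dow, unsocial.weekend_days) | (
        records["period"].to_numpy() == unsocial.night_period
    )
    bank_cost = agency_cost = 0.0
    for group in GROUPS:
        mix = rates.temp_band_mix[group]
        bank_hours = records[f"bank_{group}"].to_numpy()
        agency_hours = records[f"agency_{group}"].to_numpy()
        bank_cost += float(bank_hours.sum()) * blended_rate(mix, group, "bank", rates)
        agency_cost += float(agency_hours.sum()) * blended_rate(
            mix, group, "agency", rates
        )
        temp_unsocial = float((bank_hours + agency_hours)[is_unsocial].sum())
        supplement += unsocial.uplift * _blended_base(mix, group, rates) * temp_unsocial

    patient_days = float(records["patients"].sum()) / N_PERIODS
    return CostBreakdown(
        permanent_cost=permanent,
        bank_cost=bank_cost,
        agency_cost=agency_cost,
        unsocial_supplement=supplement,
        patient_days=patient_days,
    )
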