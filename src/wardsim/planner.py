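"""Baseline establishment planning.

The permanent staffing plan for each ward is derived from a simulated
observation window (20 days by default, noise off): the daily demand series
is reduced to a single daily baseline (mean, 80% of mean, or the 90th
percentile depending on scenario), spread over the four 6-hour periods by
the ward's diurnal profile, split by skill mix, and finally rounded to the
nearest hours total achievable with 4 h and 6 h staff blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .demand import GROUPS, CareMultipliers, estimate_demand
from .synthetic import (
    N_PERIODS,
    HospitalProfile,
    WardProfile,
    sample_shift_census,
)

SCENARIOS = ("low", "standard", "high")

#: Deployable block lengths in hours.
BLOCK_SIZES = (6, 4)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named baseline scenario and its summary statistic.

    low -> 0.8 x mean, standard -> mean, high -> 90th percentile of the
    observation window's daily demand.
    """

    name: str
    observation_days: int = 20

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; use one of {SCENARIOS}")
        if self.observation_days < 1:
            raise ValueError("observation_days must be >= 1")


@dataclass(frozen=True)
class WardPlan:
    """Planned permanent hours for one ward: (period, group) grid plus the
     4/6 h block decomposition recorded for absence sampling."""

    ward_id: str
    hours: np.ndarray  # shape (4 periods, 2 groups), achievable block sums
    blocks: tuple[tuple[tuple[int, ...], ...], ...]  # [period][group] -> sizes

    @property
    def daily_total_hours(self) -> float:
        return float(self.hours.sum())

    def group_daily_hours(self, group_index: int) -> float:
        return float(self.hours[:, group_index].sum())


@dataclass(frozen=True)
class EstablishmentPlan:
    scenario: str
    wards: Mapping[str, WardPlan]
    hours_per_patient_day: Mapping[str, float]  # diagnostic, at mean census

    @property
    def daily_total_hours(self) -> float:
        return float(sum(w.daily_total_hours for w in self.wards.values()))


# ---------------------------------------------------------------------------
# block arithmetic
# ---------------------------------------------------------------------------


def is_achievable(hours: float) -> bool:
    """True iff ``hours`` is a non-negative integer combination of 4 and 6."""
    h = round(hours)
    if abs(hours - h) > 1e-9:
        return False
    return h == 0 or (h >= 4 and h % 2 == 0)


def round_to_achievable(value: float) -> int:
    """Round to the nearest achievable block sum {0, 4, 6, 8, 10, ...}.

    Ties round up (e.g. 2 -> 4, 5 -> 6).
    """
    if value < 0:
        raise ValueError("value must be >= 0")
    # lower neighbour
    if value < 4:
        lower = 0
    else:
        lower = int(value // 2) * 2
    # upper neighbour
    if value <= 0:
        upper = 0
    elif value <= 4:
        upper = 4
    else:
        upper = int(-(-value // 2)) * 2  # ceil to even via half-steps
        if upper % 2:
            upper += 1
    if upper < value - 1e-9:  # guard: value exactly even integer
        upper = lower
    d_lo = value - lower
    d_hi = upper - value
    return upper if d_hi <= d_lo + 1e-9 else lower


def decompose_blocks(hours: int) -> tuple[int, ...]:
    """Decompose an achievable hours total into the fewest 6/4 h blocks,
    preferring 6 h blocks."""
    if not is_achievable(hours):
        raise ValueError(f"{hours} is not an achievable block sum")
    h = int(round(hours))
    r = h % 6
    if r == 0:
        return (6,) * (h // 6)
    if r == 2:  # need two 4 h blocks
        return (6,) * ((h - 8) // 6) + (4, 4)
    return (6,) * ((h - 4) // 6) + (4,)  # r == 4


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def observe_demand_window(
    ward: WardProfile,
    multipliers: CareMultipliers,
    observation_days: int,
    rng: np.random.Generator,
    specialing_group: str = "hca",
) -> list[float]:
    """Simulate the observation window and return daily total demand hours.

    All four periods of each day are sampled; requirement noise is off — the
    plan is based on classified demand, not realized noise.  Day 0 of the
    window is a Monday.
    """
    if observation_days < 1:
        raise ValueError("observation_days must be >= 1")
    daily = []
    for day in range(observation_days):
        total = 0.0
        for period in range(N_PERIODS):
            census = sample_shift_census(ward, day, period, rng)
            est = estimate_demand(
                census, multipliers, ward.diurnal_profile, ward.skill_mix,
                specialing_group,
            )
            total += est.total_hours
        daily.append(total)
    return daily


def baseline_from_window(daily_hours: Sequence[float], scenario: ScenarioSpec) -> float:
    """Reduce a daily demand series to the scenario's daily baseline.

    standard: arithmetic mean; low: 0.8 x mean; high: empirical 90th
    percentile with linear interpolation between order statistics at
    (n-1)-based plotting positions (numpy's default convention).
    """
    if len(daily_hours) == 0:
        raise ValueError("daily_hours must be non-empty")
    arr = np.asarray(daily_hours, dtype=np.float64)
    if scenario.name == "standard":
        return float(arr.mean())
    if scenario.name == "low":
        return float(0.8 * arr.mean())
    return float(np.percentile(arr, 90))


def distribute_and_round(
    daily_hours: float,
    diurnal_profile: Sequence[float],
    skill_mix: float,
    ward_id: str = "",
) -> WardPlan:
    """Spread a daily baseline over periods and groups, rounding each
    (period, group) cell to the nearest achievable 4/6 h block sum."""
    if daily_hours < 0:
        raise ValueError("daily_hours must be >= 0")
    hours = np.zeros((N_PERIODS, len(GROUPS)))
    blocks = []
    for p in range(N_PERIODS):
        period_hours = daily_hours * float(diurnal_profile[p])
        row = []
        for g, group in enumerate(GROUPS):
            share = skill_mix if group == "rn" else 1.0 - skill_mix
            rounded = round_to_achievable(period_hours * share)
            hours[p, g] = rounded
            row.append(decompose_blocks(rounded))
        blocks.append(tuple(row))
    return WardPlan(ward_id=ward_id, hours=hours, blocks=tuple(blocks))


def plan_hospital(
    hospital: HospitalProfile,
    scenario: ScenarioSpec,
    multipliers: CareMultipliers,
    rng: np.random.Generator,
    specialing_group: str = "hca",
) -> EstablishmentPlan:
    """Plan every ward of a hospital from a fresh observation window.

    The caller supplies the window RNG; the runner uses a dedicated stream
    (seeded ``base_seed - 1``) so plans never share randomness with the
    simulated year.
    """
    wards: dict[str, WardPlan] = {}
    hppd: dict[str, float] = {}
    for ward in hospital.wards:
        window = observe_demand_window(
            ward, multipliers, scenario.observation_days, rng, specialing_group
        )
        baseline = baseline_from_window(window, scenario)
        plan = distribute_and_round(
            baseline, ward.diurnal_profile, ward.skill_mix, ward.ward_id
        )
        wards[ward.ward_id] = plan
        mean_census = ward.mean_census()
        hppd[ward.ward_id] = (
            plan.daily_total_hours / mean_census if mean_census > 0 else float("nan")
        )
    return EstablishmentPlan(scenario=scenario.name, wards=wards, hours_per_patient_day=hppd)


def plan_to_frame(plan: EstablishmentPlan):
    """Long-format table of the plan (ward_id, period, staff_group, hours)."""
    import pandas as pd

    rows = []
    for ward_id in sorted(plan.wards):
        wp = plan.wards[ward_id]
        for p in range(N_PERIODS):
            for g, group in enumerate(GROUPS):
                rows.append(
                    {
                        "ward_id": ward_id,
                        "period": p,
                        "staff_group": group,
                        "hours": float(wp.hours[p, g]),
                    }
                )
    return pd.DataFrame(rows)
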