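"""Per-shift nursing demand: acuity-weighted care hours and noisy requirements.

Each acuity level carries an hours-per-patient-day multiplier (config, not a
constant: the published instrument's values are proprietary).  A shift's
estimated demand is the census-weighted daily hours scaled by the period's
diurnal weight, plus one whole person-shift (6 h) per specialed patient.
The "actual" requirement applies mean-1 multiplicative lognormal noise per
level, reflecting patients needing more or less than is typical for their
category; specialing hours are never noised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthetic import N_LEVELS, SHIFT_HOURS, ShiftCensus

GROUPS = ("rn", "hca")

#: Shipped default hours-per-patient-day multipliers for levels 0,1a,1b,2,3.
DEFAULT_MULTIPLIERS = (2.0, 2.8, 3.4, 3.9, 12.0)


@dataclass(frozen=True)
class CareMultipliers:
    """Hours of care per patient-day for each of the five acuity levels."""

    hours_per_patient_day: tuple[float, ...] = DEFAULT_MULTIPLIERS

    def __post_init__(self) -> None:
        h = self.hours_per_patient_day
        if len(h) != N_LEVELS:
            raise ValueError("need 5 multipliers")
        if any(x <= 0 for x in h):
            raise ValueError("multipliers must be strictly positive")
        if max(h) != h[-1]:
            raise ValueError("level-3 multiplier must be the maximum")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.hours_per_patient_day, dtype=np.float64)


@dataclass(frozen=True)
class DemandEstimate:
    """Acuity-tool-style demand estimate for one ward-shift.

    ``level_hours`` keeps the per-level general-care shift hours so the noisy
    realization can be recomputed without re-deriving the census arithmetic.
    """

    ward_id: str
    day_index: int
    period_index: int
    rn_hours: float
    hca_hours: float
    level_hours: tuple[float, ...]
    specialing_hours: float
    skill_mix: float
    specialing_group: str

    @property
    def total_hours(self) -> float:
        return self.rn_hours + self.hca_hours


@dataclass(frozen=True)
class ActualRequirement:
    """Noise-adjusted requirement: what the patients truly needed."""

    ward_id: str
    day_index: int
    period_index: int
    rn_hours: float
    hca_hours: float

    @property
    def total_hours(self) -> float:
        return self.rn_hours + self.hca_hours


def split_by_skill_mix(
    general_hours: float,
    specialing_hours: float,
    skill_mix: float,
    specialing_group: str,
) -> tuple[float, float]:
    """Split general care hours by skill mix; assign specialing to one group."""
    rn = general_hours * skill_mix
    hca = general_hours * (1.0 - skill_mix)
    if specialing_group == "rn":
        rn += specialing_hours
    else:
        hca += specialing_hours
    return rn, hca


def estimate_demand(
    census: ShiftCensus,
    multipliers: CareMultipliers,
    diurnal_profile,
    skill_mix: float,
    specialing_group: str = "hca",
) -> DemandEstimate:
    """Estimated staffing requirement for the patients present at shift start.

    daily hours = sum(level counts x multiplier); the shift receives the
    period's diurnal share; each specialed patient adds one 6 h person-shift.
    """
    weight = float(diurnal_profile[census.period_index])
    if not 0.0 <= weight <= 1.0:
        raise ValueError("diurnal weight must lie in [0, 1]")
    counts = np.asarray(census.counts_by_level, dtype=np.float64)
    level_hours = counts * multipliers.as_array() * weight
    specialing_hours = SHIFT_HOURS * census.specialing_count
    rn, hca = split_by_skill_mix(
        float(level_hours.sum()), specialing_hours, skill_mix, specialing_group
    )
    return DemandEstimate(
        ward_id=census.ward_id,
        day_index=census.day_index,
        period_index=census.period_index,
        rn_hours=rn,
        hca_hours=hca,
        level_hours=tuple(float(x) for x in level_hours),
        specialing_hours=specialing_hours,
        skill_mix=skill_mix,
        specialing_group=specialing_group,
    )


def lognormal_mean_one(cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with mean 1 and coefficient of variation cv."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    sigma2 = math.log1p(cv * cv)
    return -0.5 * sigma2, math.sqrt(sigma2)


def realize_actual_requirement(
    estimate: DemandEstimate,
    census: ShiftCensus,
    noise_cv: float,
    rng: np.random.Generator,
) -> ActualRequirement:
    """Apply per-level mean-1 lognormal noise to the estimate's level hours.

    With ``noise_cv == 0`` the actual requirement equals the estimate exactly
    (and no RNG draw is consumed).  Specialing hours are not noised.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if noise_cv == 0:
        return ActualRequirement(
            ward_id=estimate.ward_id,
            day_index=estimate.day_index,
            period_index=estimate.period_index,
            rn_hours=estimate.rn_hours,
            hca_hours=estimate.hca_hours,
        )
    mu, sigma = lognormal_mean_one(noise_cv)
    factors = rng.lognormal(mean=mu, sigma=sigma, size=N_LEVELS)
    noisy_general = float(np.dot(estimate.level_hours, factors))
    rn, hca = split_by_skill_mix(
        noisy_general,
        estimate.specialing_hours,
        estimate.skill_mix,
        estimate.specialing_group,
    )
    return ActualRequirement(
        ward_id=estimate.ward_id,
        day_index=estimate.day_index,
        period_index=estimate.period_index,
        rn_hours=rn,
        hca_hours=hca,
    )
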