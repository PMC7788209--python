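"""Synthetic hospital generation and per-shift census sampling.

A hospital is a collection of wards grouped into divisions (the redeployment
pools).  Each ward carries day-of-week-specific census distributions, an
acuity-mix distribution over the five dependency levels, a specialing rate,
a skill mix and a diurnal staffing profile.  Everything here is synthetic:
census distributions are discretized truncated normals and acuity mixes are
Dirichlet draws, parameterized so that downstream stages see the same
statistical structure an empirical extract would provide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

#: The five acuity/dependency levels, lowest to highest need.
LEVELS = ("0", "1a", "1b", "2", "3")
N_LEVELS = len(LEVELS)

#: Four 6-hour periods per day: morning, afternoon, evening, night.
N_PERIODS = 4
SHIFT_HOURS = 6.0

#: Day 0 of every simulated stream is a Monday (fixed for reproducibility).
WEEKEND_DAYS = (5, 6)

_TOL = 1e-9


class ConfigurationError(ValueError):
    """Raised when generator or profile configuration is invalid."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WardProfile:
    """Static description of one ward.

    ``census_dist`` holds seven discrete distributions (Monday..Sunday) over
    patient counts ``0..beds``.  ``acuity_mean``/``acuity_concentration``
    parameterize a Dirichlet over 5-component proportion vectors; a ``None``
    concentration makes the mix deterministic (always the mean).
    """

    ward_id: str
    division_id: str
    beds: int
    census_dist: tuple[Mapping[int, float], ...]
    acuity_mean: tuple[float, ...]
    acuity_concentration: float | None
    specialing_rate: float
    skill_mix: float
    diurnal_profile: tuple[float, ...]
    band_mix: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        if self.beds <= 0:
            raise ConfigurationError(f"beds: must be positive, got {self.beds}")
        if len(self.census_dist) != 7:
            raise ConfigurationError("census_dist: need 7 day-of-week entries")
        for dow, dist in enumerate(self.census_dist):
            if not dist:
                raise ConfigurationError(f"census_dist[{dow}]: empty")
            if any(k < 0 or k > self.beds for k in dist):
                raise ConfigurationError(
                    f"census_dist[{dow}]: support outside [0, beds]"
                )
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"census_dist[{dow}]: probabilities do not sum to 1"
                )
        if len(self.acuity_mean) != N_LEVELS:
            raise ConfigurationError("acuity_mean: need 5 components")
        if abs(sum(self.acuity_mean) - 1.0) > _TOL:
            raise ConfigurationError("acuity_mean: must sum to 1")
        if self.specialing_rate < 0:
            raise ConfigurationError("specialing_rate: must be >= 0")
        if not 0.0 <= self.skill_mix <= 1.0:
            raise ConfigurationError("skill_mix: must lie in [0, 1]")
        if len(self.diurnal_profile) != N_PERIODS:
            raise ConfigurationError("diurnal_profile: need 4 weights")
        if any(w < 0 for w in self.diurnal_profile):
            raise ConfigurationError("diurnal_profile: weights must be >= 0")
        if abs(sum(self.diurnal_profile) - 1.0) > _TOL:
            raise ConfigurationError("diurnal_profile: weights must sum to 1")

    def census_support(self, day_of_week: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, probabilities) for one day-of-week distribution."""
        dist = self.census_dist[day_of_week]
        vals = np.fromiter(dist.keys(), dtype=np.int64)
        probs = np.fromiter(dist.values(), dtype=np.float64)
        order = np.argsort(vals)
        return vals[order], probs[order]

    def mean_census(self) -> float:
        """Average of the seven daily census means (diagnostic)."""
        means = []
        for dow in range(7):
            vals, probs = self.census_support(dow)
            means.append(float(np.dot(vals, probs)))
        return float(np.mean(means))


@dataclass(frozen=True)
class HospitalProfile:
    """A hospital: wards partitioned into divisions."""

    hospital_id: str
    wards: tuple[WardProfile, ...]
    divisions: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for div_id, ward_ids in self.divisions.items():
            if not ward_ids:
                raise ConfigurationError(f"division {div_id}: empty")
            for wid in ward_ids:
                if wid in seen:
                    raise ConfigurationError(
                        f"ward {wid}: assigned to both {seen[wid]} and {div_id}"
                    )
                seen[wid] = div_id
        ward_ids = {w.ward_id for w in self.wards}
        if ward_ids != set(seen):
            raise ConfigurationError("divisions do not partition the ward set")
        for w in self.wards:
            if seen[w.ward_id] != w.division_id:
                raise ConfigurationError(
                    f"ward {w.ward_id}: division_id inconsistent with partition"
                )

    @property
    def n_wards(self) -> int:
        return len(self.wards)

    def ward(self, ward_id: str) -> WardProfile:
        for w in self.wards:
            if w.ward_id == ward_id:
                return w
        raise KeyError(ward_id)


@dataclass(frozen=True)
class ShiftCensus:
    """Realized patients on a ward at one shift start."""

    ward_id: str
    day_index: int
    period_index: int
    counts_by_level: tuple[int, ...]
    specialing_count: int

    def __post_init__(self) -> None:
        if len(self.counts_by_level) != N_LEVELS:
            raise ValueError("counts_by_level: need 5 entries")
        if any(c < 0 for c in self.counts_by_level):
            raise ValueError("counts_by_level: must be non-negative")
        if self.specialing_count < 0:
            raise ValueError("specialing_count: must be non-negative")
        if self.specialing_count > self.total_patients:
            raise ValueError("specialing_count exceeds total patients")

    @property
    def total_patients(self) -> int:
        return int(sum(self.counts_by_level))


# ---------------------------------------------------------------------------
# generator configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for :func:`generate_hospital`.

    Ranges are inclusive ``(lo, hi)`` pairs sampled uniformly per ward.
    ``weekend_occupancy_factor`` < 1 produces the weekday/weekend contrast in
    census means; set it to 1.0 to disable the contrast.
    """

    n_wards: int = 20
    wards_per_division: int = 5
    beds_range: tuple[int, int] = (16, 32)
    occupancy_range: tuple[float, float] = (0.85, 0.95)
    occupancy_cv: float = 0.12
    weekend_occupancy_factor: float = 0.92
    acuity_base: tuple[float, ...] = (0.35, 0.30, 0.20, 0.10, 0.05)
    acuity_concentration: float = 30.0
    specialing_range: tuple[float, float] = (0.0, 0.5)
    skill_mix_range: tuple[float, float] = (0.45, 0.75)
    diurnal_profile: tuple[float, ...] = (0.32, 0.27, 0.22, 0.19)
    hospital_id: str = "H1"

    def __post_init__(self) -> None:
        if self.n_wards < 1:
            raise ConfigurationError(f"n_wards: must be >= 1, got {self.n_wards}")
        if self.wards_per_division < 1:
            raise ConfigurationError(
                f"wards_per_division: must be >= 1, got {self.wards_per_division}"
            )
        lo, hi = self.beds_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(f"beds_range: invalid range {self.beds_range}")
        olo, ohi = self.occupancy_range
        if not (0 < olo <= ohi <= 1.2):
            raise ConfigurationError(
                f"occupancy_range: invalid range {self.occupancy_range}"
            )
        if self.occupancy_cv < 0:
            raise ConfigurationError("occupancy_cv: must be >= 0")
        if not 0 < self.weekend_occupancy_factor <= 1.5:
            raise ConfigurationError("weekend_occupancy_factor: must be positive")
        if abs(sum(self.acuity_base) - 1.0) > 1e-6:
            raise ConfigurationError("acuity_base: must sum to 1")
        slo, shi = self.specialing_range
        if slo < 0 or shi < slo:
            raise ConfigurationError(
                f"specialing_range: invalid range {self.specialing_range}"
            )


#: Default permanent pay-band mixes per staff group.
DEFAULT_BAND_MIX: dict[str, dict[str, float]] = {
    "rn": {"5": 0.55, "6": 0.35, "7": 0.10},
    "hca": {"2": 0.65, "3": 0.35},
}


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------


def largest_remainder_integerize(
    total: int, proportions: Sequence[float]
) -> np.ndarray:
    """Split ``total`` into integers proportional to ``proportions``.

    Floors each share, then hands the leftover units to the components with
    the largest fractional remainders; ties are broken by the first (lowest)
    index.  Outputs sum to ``total`` and each is within 1 of its exact share.
    """
    if total < 0:
        raise ValueError(f"total must be non-negative, got {total}")
    p = np.asarray(proportions, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must sum to 1")
    exact = total * p
    counts = np.floor(exact).astype(np.int64)
    leftover = total - int(counts.sum())
    if leftover > 0:
        # stable argsort on negated remainders -> first index wins ties
        order = np.argsort(-(exact - counts), kind="stable")
        counts[order[:leftover]] += 1
    return counts


def integerize_many(totals: np.ndarray, proportions: np.ndarray) -> np.ndarray:
    """Vectorized largest-remainder rounding: (n,) totals x (n, 5) proportions."""
    exact = totals[:, None] * proportions
    counts = np.floor(exact).astype(np.int64)
    leftover = (totals - counts.sum(axis=1)).astype(np.int64)
    rem = exact - counts
    order = np.argsort(-rem, axis=1, kind="stable")
    ranks = np.argsort(order, axis=1, kind="stable")
    counts += ranks < leftover[:, None]
    return counts


def discretized_truncated_normal(beds: int, mean: float, cv: float) -> dict[int, float]:
    """Discrete distribution on ``0..beds``: normal(mean, cv*mean) pmf by cdf
    differences, renormalized over the truncated support."""
    ks = np.arange(beds + 1)
    if cv <= 0 or mean <= 0:
        k = int(round(min(max(mean, 0.0), beds)))
        return {k: 1.0}
    sd = cv * mean
    upper = stats.norm.cdf(ks + 0.5, loc=mean, scale=sd)
    lower = stats.norm.cdf(ks - 0.5, loc=mean, scale=sd)
    pmf = upper - lower
    pmf = np.clip(pmf, 0.0, None)
    pmf /= pmf.sum()
    return {int(k): float(v) for k, v in zip(ks, pmf) if v > 1e-12}


def sample_dirichlet(
    mean: Sequence[float], concentration: float | None, rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Dirichlet draws tolerating zero-mass components (gamma(0) == 0).

    ``concentration=None`` returns the mean vector exactly (degenerate mix).
    """
    m = np.asarray(mean, dtype=np.float64)
    n = 1 if size is None else size
    if concentration is None:
        out = np.tile(m, (n, 1))
    else:
        alpha = m * concentration
        g = rng.gamma(np.broadcast_to(alpha, (n, alpha.size)))
        s = g.sum(axis=1, keepdims=True)
        out = np.where(s > 0, g / np.where(s > 0, s, 1.0), m)
    return out[0] if size is None else out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def generate_hospital(config: GeneratorConfig, seed: int) -> HospitalProfile:
    """Generate a synthetic hospital deterministically from ``(config, seed)``.

    Wards are assigned to divisions in contiguous blocks of
    ``wards_per_division``; the last block may be smaller.
    """
    rng = np.random.default_rng(seed)
    width = max(2, len(str(config.n_wards)))
    wards = []
    divisions: dict[str, list[str]] = {}
    for i in range(config.n_wards):
        ward_id = f"W{i + 1:0{width}d}"
        div_index = i // config.wards_per_division
        division_id = f"D{div_index + 1:02d}"
        beds = int(rng.integers(config.beds_range[0], config.beds_range[1] + 1))
        occ = float(rng.uniform(*config.occupancy_range))
        census = []
        for dow in range(7):
            factor = (
                config.weekend_occupancy_factor if dow in WEEKEND_DAYS else 1.0
            )
            census.append(
                discretized_truncated_normal(beds, occ * beds * factor, config.occupancy_cv)
            )
        # mild per-ward jitter of the acuity mean
        acuity_mean = sample_dirichlet(
            config.acuity_base, 200.0, rng
        )
        acuity_mean = tuple(float(x) for x in acuity_mean / acuity_mean.sum())
        specialing = float(rng.uniform(*config.specialing_range))
        skill = float(rng.uniform(*config.skill_mix_range))
        wards.append(
            WardProfile(
                ward_id=ward_id,
                division_id=division_id,
                beds=beds,
                census_dist=tuple(census),
                acuity_mean=acuity_mean,
                acuity_concentration=config.acuity_concentration,
                specialing_rate=specialing,
                skill_mix=skill,
                diurnal_profile=tuple(config.diurnal_profile),
                band_mix={g: dict(m) for g, m in DEFAULT_BAND_MIX.items()},
            )
        )
        divisions.setdefault(division_id, []).append(ward_id)
    return HospitalProfile(
        hospital_id=config.hospital_id,
        wards=tuple(wards),
        divisions={d: tuple(ws) for d, ws in divisions.items()},
    )


def sample_shift_census(
    ward: WardProfile, day_index: int, period_index: int, rng: np.random.Generator
) -> ShiftCensus:
    """Sample one ward-shift census.

    Draw order (documented, relied on for reproducibility): total patients
    from the day-of-week census distribution, then an acuity proportion
    vector, then the Poisson specialing count (truncated at total patients).
    """
    if day_index < 0:
        raise ValueError("day_index must be >= 0")
    if not 0 <= period_index < N_PERIODS:
        raise ValueError("period_index must be in 0..3")
    vals, probs = ward.census_support(day_index % 7)
    total = int(rng.choice(vals, p=probs))
    props = sample_dirichlet(ward.acuity_mean, ward.acuity_concentration, rng)
    counts = largest_remainder_integerize(total, props)
    if ward.specialing_rate > 0:
        specialing = min(int(rng.poisson(ward.specialing_rate)), total)
    else:
        specialing = 0
    return ShiftCensus(
        ward_id=ward.ward_id,
        day_index=day_index,
        period_index=period_index,
        counts_by_level=tuple(int(c) for c in counts),
        specialing_count=specialing,
    )


def census_stream_frame(census_list: Sequence[ShiftCensus]):
    """Tabulate sampled censuses for CSV export (RFC 4180, header row)."""
    import pandas as pd

    rows = [
        {
            "ward_id": c.ward_id,
            "day": c.day_index,
            "period": c.period_index,
            **{f"level_{lvl}": c.counts_by_level[i] for i, lvl in enumerate(LEVELS)},
            "specialing": c.specialing_count,
        }
        for c in census_list
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# YAML round trip
# ---------------------------------------------------------------------------


def hospital_to_dict(hospital: HospitalProfile) -> dict:
    return {
        "hospital_id": hospital.hospital_id,
        "divisions": {d: list(ws) for d, ws in hospital.divisions.items()},
        "wards": [
            {
                "ward_id": w.ward_id,
                "division_id": w.division_id,
                "beds": w.beds,
                "census_dist": [
                    {int(k): float(v) for k, v in dist.items()}
                    for dist in w.census_dist
                ],
                "acuity_mean": [float(x) for x in w.acuity_mean],
                "acuity_concentration": w.acuity_concentration,
                "specialing_rate": w.specialing_rate,
                "skill_mix": w.skill_mix,
                "diurnal_profile": [float(x) for x in w.diurnal_profile],
                "band_mix": {g: dict(m) for g, m in w.band_mix.items()},
            }
            for w in hospital.wards
        ],
    }


def hospital_from_dict(data: Mapping) -> HospitalProfile:
    wards = tuple(
        WardProfile(
            ward_id=w["ward_id"],
            division_id=w["division_id"],
            beds=int(w["beds"]),
            census_dist=tuple(
                {int(k): float(v) for k, v in dist.items()}
                for dist in w["census_dist"]
            ),
            acuity_mean=tuple(float(x) for x in w["acuity_mean"]),
            acuity_concentration=(
                None
                if w.get("acuity_concentration") is None
                else float(w["acuity_concentration"])
            ),
            specialing_rate=float(w["specialing_rate"]),
            skill_mix=float(w["skill_mix"]),
            diurnal_profile=tuple(float(x) for x in w["diurnal_profile"]),
            band_mix={g: dict(m) for g, m in w["band_mix"].items()},
        )
        for w in data["wards"]
    )
    return HospitalProfile(
        hospital_id=data["hospital_id"],
        wards=wards,
        divisions={d: tuple(ws) for d, ws in data["divisions"].items()},
    )


def save_hospital(hospital: HospitalProfile, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(hospital_to_dict(hospital), fh, sort_keys=False)


def load_hospital(path) -> HospitalProfile:
    with open(path) as fh:
        return hospital_from_dict(yaml.safe_load(fh))
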