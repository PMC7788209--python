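"""Per-shift staffing simulation core.

Each ward-shift runs through a fixed pipeline: census sampling -> demand
estimate -> short-notice absence -> face-value balance assessment ->
within-division redeployment of whole people -> bank/agency escalation under
availability probabilities -> noisy actual requirement -> state
classification.  Requests for cover are made at face value (one person for
one person); achieved staffing is productivity-weighted (redeployed and bank
staff 90% as efficient, agency 75%).

Randomness is organized as six named substreams spawned from the replication
seed in a fixed order (census, acuity, specialing, absence, noise,
availability), so runs with the same seed share census/absence/noise draws
exactly even when flexible-staffing policies differ.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .demand import (
    GROUPS,
    CareMultipliers,
    estimate_demand,
    lognormal_mean_one,
    realize_actual_requirement,
)
from .planner import EstablishmentPlan, WardPlan
from .synthetic import (
    N_LEVELS,
    N_PERIODS,
    SHIFT_HOURS,
    HospitalProfile,
    ShiftCensus,
    integerize_many,
    sample_dirichlet,
    sample_shift_census,
)

logger = logging.getLogger(__name__)

HALF_BLOCK = 3.0  # redeployment granularity: half a 6 h shift

POLICY_MODES = ("none", "empirical", "higher", "unlimited")
STATES = ("understaffed", "adequate", "overstaffed")

YEAR_DAYS = 365


# ---------------------------------------------------------------------------
# policy and parameter types
# ---------------------------------------------------------------------------


def _availability_array(table: Mapping) -> np.ndarray:
    """(group, period, channel) probabilities from a nested mapping
    {group: {period: {bank: p, agency: p}}}."""
    arr = np.zeros((len(GROUPS), N_PERIODS, 2))
    for g, group in enumerate(GROUPS):
        for p in range(N_PERIODS):
            cell = table[group][p]
            arr[g, p, 0] = cell["bank"]
            arr[g, p, 1] = cell["agency"]
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("availability probabilities must lie in [0, 1]")
    return arr


def _flat_table(bank: Mapping[int, float], agency: Mapping[int, float]) -> dict:
    return {p: {"bank": bank[p], "agency": agency[p]} for p in range(N_PERIODS)}


#: Default "empirical" availability: day/evening/night probabilities spanning
#: the stated 5%-45% range; agency = bank - 0.10 floored at 0.05.
_EMPIRICAL_BANK = {
    "rn": {0: 0.35, 1: 0.35, 2: 0.25, 3: 0.15},
    "hca": {0: 0.45, 1: 0.45, 2: 0.35, 3: 0.25},
}
EMPIRICAL_AVAILABILITY = {
    group: _flat_table(
        _EMPIRICAL_BANK[group],
        {p: max(0.05, v - 0.10) for p, v in _EMPIRICAL_BANK[group].items()},
    )
    for group in GROUPS
}


def _uniform_availability(p: float) -> dict:
    return {
        group: _flat_table({i: p for i in range(N_PERIODS)}, {i: p for i in range(N_PERIODS)})
        for group in GROUPS
    }


@dataclass(frozen=True)
class FlexPolicy:
    """Flexible-staffing policy: redeployment switch, temporary-staff
    availability probabilities and productivity discounts."""

    mode: str
    availability: np.ndarray = field(default_factory=lambda: np.zeros((2, N_PERIODS, 2)))
    e_redeploy: float = 0.9
    e_bank: float = 0.9
    e_agency: float = 0.75
    redeployment_enabled: bool = True

    def __post_init__(self) -> None:
        if self.mode not in POLICY_MODES:
            raise ValueError(f"unknown policy mode {self.mode!r}")
        a = np.asarray(self.availability)
        if a.shape != (len(GROUPS), N_PERIODS, 2):
            raise ValueError("availability must have shape (2, 4, 2)")
        if a.min() < 0 or a.max() > 1:
            raise ValueError("availability probabilities must lie in [0, 1]")
        if self.mode == "unlimited" and not np.all(a == 1.0):
            raise ValueError("unlimited policy requires all probabilities = 1")
        if self.mode == "none" and self.redeployment_enabled:
            raise ValueError("mode 'none' forbids redeployment")

    @classmethod
    def none(cls) -> "FlexPolicy":
        return cls(mode="none", redeployment_enabled=False)

    @classmethod
    def empirical(cls, table: Mapping | None = None) -> "FlexPolicy":
        return cls(
            mode="empirical",
            availability=_availability_array(table or EMPIRICAL_AVAILABILITY),
        )

    @classmethod
    def higher(cls, p: float = 0.75) -> "FlexPolicy":
        return cls(mode="higher", availability=_availability_array(_uniform_availability(p)))

    @classmethod
    def unlimited(cls) -> "FlexPolicy":
        return cls(mode="unlimited", availability=_availability_array(_uniform_availability(1.0)))

    @classmethod
    def from_name(cls, name: str) -> "FlexPolicy":
        return {
            "none": cls.none,
            "empirical": cls.empirical,
            "higher": cls.higher,
            "unlimited": cls.unlimited,
        }[name]()


@dataclass(frozen=True)
class AbsenceRates:
    """Short-notice sickness probabilities per planned person-block."""

    rn: float = 0.03
    hca: float = 0.04

    def __post_init__(self) -> None:
        if not (0 <= self.rn <= 1 and 0 <= self.hca <= 1):
            raise ValueError("absence rates must lie in [0, 1]")

    def rate(self, group: str) -> float:
        return self.rn if group == "rn" else self.hca


@dataclass(frozen=True)
class ToleranceRule:
    """Symmetric tolerance band around the actual requirement."""

    tau: float = 0.15

    def __post_init__(self) -> None:
        if not 0 <= self.tau < 1:
            raise ValueError("tau must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationParams:
    multipliers: CareMultipliers = field(default_factory=CareMultipliers)
    noise_cv: float = 0.1
    absence: AbsenceRates = field(default_factory=AbsenceRates)
    tolerance: ToleranceRule = field(default_factory=ToleranceRule)
    specialing_group: str = "hca"


@dataclass(frozen=True)
class GroupHours:
    rn: float = 0.0
    hca: float = 0.0

    def get(self, group: str) -> float:
        return self.rn if group == "rn" else self.hca

    @property
    def total(self) -> float:
        return self.rn + self.hca


@dataclass(frozen=True)
class ShiftStaffingRecord:
    """One ward-shift: requirement, achieved hours by source, and state."""

    ward_id: str
    day_index: int
    period_index: int
    patients_at_start: int
    estimate_hours: GroupHours
    actual_requirement_hours: GroupHours
    permanent_worked_hours: GroupHours
    redeployed_in_hours: GroupHours
    redeployed_out_hours: GroupHours
    bank_hours: GroupHours
    agency_hours: GroupHours
    achieved_effective_hours: GroupHours
    state: str

    @property
    def achieved_effective_total(self) -> float:
        return self.achieved_effective_hours.total


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def apply_absence(
    blocks: Mapping[str, Sequence[int]],
    rates: AbsenceRates,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Remove each planned person-block independently with the group's
    absence probability; returns available permanent hours per group."""
    available: dict[str, float] = {}
    for group in GROUPS:
        rate = rates.rate(group)
        hours = 0.0
        for block in blocks[group]:
            if rate <= 0 or rng.random() >= rate:
                hours += block
        available[group] = hours
    return available


@dataclass(frozen=True)
class Balance:
    """Face-value shortfall/surplus for one ward and group."""

    shortfall_hours: float
    surplus_hours: float

    @property
    def shortfall_half_blocks(self) -> int:
        """Requestable redeployment blocks in 3 h halves: ceil(shortfall/3)."""
        return int(math.ceil(self.shortfall_hours / HALF_BLOCK - 1e-9))

    @property
    def spare_half_blocks(self) -> int:
        """Donatable halves that keep the donor at or above its estimate."""
        return int(self.surplus_hours // HALF_BLOCK + 1e-9)

    @property
    def shortfall_whole_people(self) -> int:
        """Shortfall expressed in whole 6 h people (ceiling)."""
        return int(math.ceil(self.shortfall_hours / SHIFT_HOURS - 1e-9))

    def request_blocks(self) -> tuple[float, ...]:
        """6 h blocks, with a trailing 3 h half-block when shortfall mod 6 is
        in (0, 3] — the redeployment request decomposition."""
        halves = self.shortfall_half_blocks
        return (6.0,) * (halves // 2) + ((3.0,) if halves % 2 else ())


def assess_balance(
    available_hours: Mapping[str, float], estimate_hours: Mapping[str, float]
) -> dict[str, Balance]:
    """Face-value comparison of available permanent hours to the estimate."""
    out = {}
    for group in GROUPS:
        avail = available_hours[group]
        est = estimate_hours[group]
        if avail < 0 or est < 0:
            raise ValueError("hours must be non-negative")
        out[group] = Balance(
            shortfall_hours=max(0.0, est - avail),
            surplus_hours=max(0.0, avail - est),
        )
    return out


def redeploy_division(
    balances: Mapping[str, Mapping[str, Balance]],
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str, str, float]]:
    """Greedy within-division redeployment of whole people.

    Staff move in 3 h half-shift quanta, one at a time, from the
    largest-surplus donor to the largest-shortfall recipient of the same
    staff group (ties broken by ward_id); donations never push a donor below
    its own estimate.  Consecutive same-pair quanta are coalesced into 6 h
    whole-shift moves.  Returns (donor, recipient, group, hours) moves.
    """
    moves: list[tuple[str, str, str, float]] = []
    for group in GROUPS:
        remaining = {
            w: balances[w][group].shortfall_hours
            for w in balances
            if balances[w][group].shortfall_hours > 1e-9
        }
        request_halves = {
            w: balances[w][group].shortfall_half_blocks for w in remaining
        }
        spare = {
            w: balances[w][group].spare_half_blocks
            for w in balances
            if balances[w][group].spare_half_blocks > 0
        }
        raw: list[tuple[str, str]] = []
        while request_halves and spare:
            max_short = max(remaining.values())
            recipient = min(w for w in remaining if remaining[w] >= max_short - 1e-12)
            max_spare = max(spare.values())
            donor = min(w for w in spare if spare[w] == max_spare)
            raw.append((donor, recipient))
            spare[donor] -= 1
            if spare[donor] == 0:
                del spare[donor]
            request_halves[recipient] -= 1
            remaining[recipient] = max(0.0, remaining[recipient] - HALF_BLOCK)
            if request_halves[recipient] == 0:
                del request_halves[recipient]
                del remaining[recipient]
        # coalesce consecutive identical donor->recipient quanta into 6 h moves
        i = 0
        while i < len(raw):
            j = i
            while j < len(raw) and raw[j] == raw[i]:
                j += 1
            run = j - i
            donor, recipient = raw[i]
            moves.extend(
                (donor, recipient, group, 6.0) for _ in range(run // 2)
            )
            if run % 2:
                moves.append((donor, recipient, group, 3.0))
            i = j
    return moves


def request_temporary(
    shortfall_hours: Mapping[str, float],
    policy: FlexPolicy,
    period_index: int,
    rng: np.random.Generator,
) -> dict[str, tuple[float, float]]:
    """Escalate residual shortfall to bank then agency, block by block.

    Each full 6 h of shortfall is requested as a 6 h block; any remainder is
    requested as one final partial block of exactly the remaining hours, so
    raw hired hours never exceed the face-value shortfall.  A block is first
    a bank request (success probability p_bank); on failure it escalates to
    agency (p_agency); on a second failure it stays unfilled.
    """
    if policy.mode == "none":
        raise ValueError("request_temporary requires a policy with mode != 'none'")
    out: dict[str, tuple[float, float]] = {}
    for g, group in enumerate(GROUPS):
        shortfall = shortfall_hours[group]
        p_bank = policy.availability[g, period_index, 0]
        p_agency = policy.availability[g, period_index, 1]
        bank = agency = 0.0
        n_full = int(shortfall // SHIFT_HOURS + 1e-9)
        partial = shortfall - n_full * SHIFT_HOURS
        blocks = [SHIFT_HOURS] * n_full + ([partial] if partial > 1e-9 else [])
        for hours in blocks:
            if rng.random() < p_bank:
                bank += hours
            elif rng.random() < p_agency:
                agency += hours
        out[group] = (bank, agency)
    return out


def classify_shift(
    achieved_effective_hours: float,
    actual_requirement_hours: float,
    rule: ToleranceRule,
) -> str:
    """Understaffed below (1-tau) x requirement, overstaffed above
    (1+tau) x requirement, else adequate (boundaries count as adequate)."""
    if achieved_effective_hours < 0 or actual_requirement_hours < 0:
        raise ValueError("hours must be non-negative")
    req = actual_requirement_hours
    if req == 0:
        return "adequate" if achieved_effective_hours == 0 else "overstaffed"
    eps = 1e-9 * max(req, 1.0)  # exact band edges count as adequate
    if achieved_effective_hours < (1.0 - rule.tau) * req - eps:
        return "understaffed"
    if achieved_effective_hours > (1.0 + rule.tau) * req + eps:
        return "overstaffed"
    return "adequate"


# ---------------------------------------------------------------------------
# shift simulation (single-shift reference implementation)
# ---------------------------------------------------------------------------


def simulate_shift(
    hospital: HospitalProfile,
    plan: EstablishmentPlan,
    policy: FlexPolicy,
    params: SimulationParams,
    rng: np.random.Generator,
    day_index: int = 0,
    period_index: int = 0,
) -> list[ShiftStaffingRecord]:
    """Simulate one shift across all wards of a hospital.

    Reference implementation mirroring :func:`simulate_year`'s pipeline with
    a single generator; draw order is census/acuity/specialing per ward, then
    absence per ward, then noise per ward, then availability.
    """
    censuses = {}
    estimates = {}
    for ward in hospital.wards:
        census = sample_shift_census(ward, day_index, period_index, rng)
        censuses[ward.ward_id] = census
        estimates[ward.ward_id] = estimate_demand(
            census, params.multipliers, ward.diurnal_profile, ward.skill_mix,
            params.specialing_group,
        )
    available = {}
    for ward in hospital.wards:
        blocks = {
            group: plan.wards[ward.ward_id].blocks[period_index][g]
            for g, group in enumerate(GROUPS)
        }
        available[ward.ward_id] = apply_absence(blocks, params.absence, rng)

    balances = {
        wid: assess_balance(
            available[wid],
            {"rn": estimates[wid].rn_hours, "hca": estimates[wid].hca_hours},
        )
        for wid in available
    }

    red_in = {wid: {g: 0.0 for g in GROUPS} for wid in available}
    red_out = {wid: {g: 0.0 for g in GROUPS} for wid in available}
    if policy.redeployment_enabled:
        for div_wards in hospital.divisions.values():
            moves = redeploy_division({w: balances[w] for w in div_wards})
            for donor, recipient, group, hours in moves:
                red_out[donor][group] += hours
                red_in[recipient][group] += hours

    bank = {wid: {g: 0.0 for g in GROUPS} for wid in available}
    agency = {wid: {g: 0.0 for g in GROUPS} for wid in available}
    if policy.mode != "none":
        for ward in hospital.wards:
            wid = ward.ward_id
            # ward-level cap: hires only raise the ward toward adequate; a
            # surplus in one group nets against the other group's shortfall
            net = {
                g: available[wid][g] - red_out[wid][g] + red_in[wid][g]
                for g in GROUPS
            }
            total_residual = max(
                0.0, estimates[wid].total_hours - sum(net.values())
            )
            residual = {}
            for g in GROUPS:  # rn-first allocation, documented tie-break
                r = min(
                    max(
                        0.0,
                        getattr(estimates[wid], f"{g}_hours") - net[g],
                    ),
                    total_residual,
                )
                residual[g] = r
                total_residual -= r
            filled = request_temporary(residual, policy, period_index, rng)
            for g in GROUPS:
                bank[wid][g], agency[wid][g] = filled[g]

    records = []
    for ward in hospital.wards:
        wid = ward.ward_id
        actual = realize_actual_requirement(
            estimates[wid], censuses[wid], params.noise_cv, rng
        )
        perm = {g: available[wid][g] - red_out[wid][g] for g in GROUPS}
        eff = {
            g: perm[g]
            + policy.e_redeploy * red_in[wid][g]
            + policy.e_bank * bank[wid][g]
            + policy.e_agency * agency[wid][g]
            for g in GROUPS
        }
        state = classify_shift(
            sum(eff.values()), actual.total_hours, params.tolerance
        )
        records.append(
            ShiftStaffingRecord(
                ward_id=wid,
                day_index=day_index,
                period_index=period_index,
                patients_at_start=censuses[wid].total_patients,
                estimate_hours=GroupHours(estimates[wid].rn_hours, estimates[wid].hca_hours),
                actual_requirement_hours=GroupHours(actual.rn_hours, actual.hca_hours),
                permanent_worked_hours=GroupHours(perm["rn"], perm["hca"]),
                redeployed_in_hours=GroupHours(red_in[wid]["rn"], red_in[wid]["hca"]),
                redeployed_out_hours=GroupHours(red_out[wid]["rn"], red_out[wid]["hca"]),
                bank_hours=GroupHours(bank[wid]["rn"], bank[wid]["hca"]),
                agency_hours=GroupHours(agency[wid]["rn"], agency[wid]["hca"]),
                achieved_effective_hours=GroupHours(eff["rn"], eff["hca"]),
                state=state,
            )
        )
    return records


# ---------------------------------------------------------------------------
# full-year simulation (vectorized presampling + per-shift loop)
# ---------------------------------------------------------------------------


@dataclass
class YearResult:
    """One replication: per-ward-shift records plus bookkeeping totals."""

    records: pd.DataFrame
    replication_seed: int
    patient_shifts: int


def _presample_ward(
    ward, plan: WardPlan, params: SimulationParams, rngs: dict, n_shifts: int
) -> dict:
    """Draw all per-ward stochastic inputs for a year in one pass."""
    days = np.arange(n_shifts) // N_PERIODS
    periods = np.arange(n_shifts) % N_PERIODS
    dows = days % 7

    totals = np.empty(n_shifts, dtype=np.int64)
    for dow in range(7):
        mask = dows == dow
        vals, probs = ward.census_support(dow)
        totals[mask] = rngs["census"].choice(vals, size=int(mask.sum()), p=probs)

    props = sample_dirichlet(
        ward.acuity_mean, ward.acuity_concentration, rngs["acuity"], size=n_shifts
    )
    counts = integerize_many(totals, props)

    if ward.specialing_rate > 0:
        specialing = np.minimum(
            rngs["specialing"].poisson(ward.specialing_rate, n_shifts), totals
        )
    else:
        specialing = np.zeros(n_shifts, dtype=np.int64)

    m = params.multipliers.as_array()
    weights = np.asarray(ward.diurnal_profile)[periods]
    level_hours = counts * m[None, :] * weights[:, None]
    general = level_hours.sum(axis=1)
    spec_hours = SHIFT_HOURS * specialing
    est = np.empty((n_shifts, 2))
    est[:, 0] = general * ward.skill_mix
    est[:, 1] = general * (1.0 - ward.skill_mix)
    gi_spec = 0 if params.specialing_group == "rn" else 1
    est[:, gi_spec] += spec_hours

    # absence: whole planned person-blocks removed independently; draw order
    # period 0..3, group rn/hca, 6 h blocks then 4 h blocks
    n_days = n_shifts // N_PERIODS
    lost = np.zeros((n_shifts, 2))
    rates = [params.absence.rn, params.absence.hca]
    for p in range(N_PERIODS):
        idx = periods == p
        for g in range(2):
            blocks = plan.blocks[p][g]
            n6 = sum(1 for b in blocks if b == 6)
            n4 = len(blocks) - n6
            rate = rates[g]
            day_lost = np.zeros(n_days)
            if rate > 0:
                if n6:
                    day_lost += 6.0 * rngs["absence"].binomial(n6, rate, n_days)
                if n4:
                    day_lost += 4.0 * rngs["absence"].binomial(n4, rate, n_days)
            lost[idx, g] = day_lost
    planned = plan.hours[periods, :]
    avail = planned - lost

    # requirement noise: per-level mean-1 lognormal factors
    if params.noise_cv > 0:
        mu, sigma = lognormal_mean_one(params.noise_cv)
        factors = rngs["noise"].lognormal(mu, sigma, size=(n_shifts, N_LEVELS))
        noisy_general = (level_hours * factors).sum(axis=1)
    else:
        noisy_general = general
    req = np.empty((n_shifts, 2))
    req[:, 0] = noisy_general * ward.skill_mix
    req[:, 1] = noisy_general * (1.0 - ward.skill_mix)
    req[:, gi_spec] += spec_hours

    return {
        "patients": totals,
        "specialing": specialing,
        "est": est,
        "avail": avail,
        "req": req,
    }


def simulate_year(
    hospital: HospitalProfile,
    plan: EstablishmentPlan,
    policy: FlexPolicy,
    params: SimulationParams,
    replication_seed: int,
    n_days: int = YEAR_DAYS,
) -> YearResult:
    """Simulate ``n_days`` (default one year) for every ward.

    Day 0 is a Monday.  Produces one record per ward-shift
    (``n_days x 4 x n_wards`` rows).
    """
    t0 = time.perf_counter()
    ss = np.random.SeedSequence(replication_seed)
    children = ss.spawn(6)
    names = ("census", "acuity", "specialing", "absence", "noise", "availability")
    rngs = {n: np.random.default_rng(c) for n, c in zip(names, children)}

    n_shifts = n_days * N_PERIODS
    ward_ids = [w.ward_id for w in hospital.wards]
    n_wards = len(ward_ids)
    pre = [
        _presample_ward(w, plan.wards[w.ward_id], params, rngs, n_shifts)
        for w in hospital.wards
    ]
    est = np.stack([p["est"] for p in pre])        # (ward, shift, group)
    avail = np.stack([p["avail"] for p in pre])
    req = np.stack([p["req"] for p in pre])
    patients = np.stack([p["patients"] for p in pre])
    specialing = np.stack([p["specialing"] for p in pre])

    divisions = [
        [ward_ids.index(wid) for wid in wids]
        for wids in hospital.divisions.values()
    ]
    id_by_index = ward_ids

    red_in = np.zeros((n_wards, n_shifts, 2))
    red_out = np.zeros((n_wards, n_shifts, 2))
    bank = np.zeros((n_wards, n_shifts, 2))
    agency = np.zeros((n_wards, n_shifts, 2))

    avail_rng = rngs["availability"]
    p_avail = policy.availability  # (group, period, channel)
    hire = policy.mode != "none"
    redeploy = policy.redeployment_enabled

    short = np.maximum(0.0, est - avail)  # face-value, pre-redeployment
    surp = np.maximum(0.0, avail - est)

    for t in range(n_shifts):
        period = t % N_PERIODS
        if redeploy:
            for div in divisions:
                if len(div) < 2:
                    continue
                s_short = short[div, t, :]
                s_surp = surp[div, t, :]
                if not (
                    (s_short.max() > 1e-9) and (s_surp.max() >= HALF_BLOCK)
                ):
                    continue
                balances = {
                    id_by_index[w]: {
                        g: Balance(short[w, t, gi], surp[w, t, gi])
                        for gi, g in enumerate(GROUPS)
                    }
                    for w in div
                }
                moves = redeploy_division(balances)
                for donor, recipient, group, hours in moves:
                    gi = GROUPS.index(group)
                    red_out[ward_ids.index(donor), t, gi] += hours
                    red_in[ward_ids.index(recipient), t, gi] += hours
        if hire:
            for w in range(n_wards):
                # cap total hires at the ward-level face-value shortfall so
                # temporary staff only raise the ward toward adequate and a
                # group surplus is netted against the other group's gap;
                # remaining request capacity is allocated rn-first
                net0 = avail[w, t, 0] - red_out[w, t, 0] + red_in[w, t, 0]
                net1 = avail[w, t, 1] - red_out[w, t, 1] + red_in[w, t, 1]
                total_residual = (est[w, t, 0] + est[w, t, 1]) - (net0 + net1)
                if total_residual <= 1e-9:
                    continue
                for gi in range(2):
                    residual = min(
                        est[w, t, gi] - (net0 if gi == 0 else net1),
                        total_residual,
                    )
                    if residual <= 1e-9:
                        continue
                    p_bank = p_avail[gi, period, 0]
                    p_agency = p_avail[gi, period, 1]
                    n_full = int(residual // SHIFT_HOURS + 1e-9)
                    partial = residual - n_full * SHIFT_HOURS
                    for hours in [SHIFT_HOURS] * n_full + (
                        [partial] if partial > 1e-9 else []
                    ):
                        if avail_rng.random() < p_bank:
                            bank[w, t, gi] += hours
                        elif avail_rng.random() < p_agency:
                            agency[w, t, gi] += hours
                    total_residual -= residual

    perm = avail - red_out
    eff = (
        perm
        + policy.e_redeploy * red_in
        + policy.e_bank * bank
        + policy.e_agency * agency
    )
    eff_total = eff.sum(axis=2)
    req_total = req.sum(axis=2)
    tau = params.tolerance.tau
    eps = 1e-9 * np.maximum(req_total, 1.0)
    under = eff_total < (1.0 - tau) * req_total - eps
    over = eff_total > (1.0 + tau) * req_total + eps
    # requirement exactly zero: adequate iff achieved zero
    zero_req = req_total == 0
    under[zero_req] = False
    over[zero_req] = eff_total[zero_req] > 0
    state = np.where(under, "understaffed", np.where(over, "overstaffed", "adequate"))

    shifts = np.arange(n_shifts)
    frame = pd.DataFrame(
        {
            "ward_id": np.repeat(ward_ids, n_shifts),
            "day": np.tile(shifts // N_PERIODS, n_wards),
            "period": np.tile(shifts % N_PERIODS, n_wards),
            "patients": patients.reshape(-1),
            "specialing": specialing.reshape(-1),
            "est_rn": est[:, :, 0].reshape(-1),
            "est_hca": est[:, :, 1].reshape(-1),
            "req_rn": req[:, :, 0].reshape(-1),
            "req_hca": req[:, :, 1].reshape(-1),
            "perm_rn": perm[:, :, 0].reshape(-1),
            "perm_hca": perm[:, :, 1].reshape(-1),
            "redeployed_in_rn": red_in[:, :, 0].reshape(-1),
            "redeployed_in_hca": red_in[:, :, 1].reshape(-1),
            "redeployed_out_rn": red_out[:, :, 0].reshape(-1),
            "redeployed_out_hca": red_out[:, :, 1].reshape(-1),
            "bank_rn": bank[:, :, 0].reshape(-1),
            "bank_hca": bank[:, :, 1].reshape(-1),
            "agency_rn": agency[:, :, 0].reshape(-1),
            "agency_hca": agency[:, :, 1].reshape(-1),
            "achieved_eff_rn": eff[:, :, 0].reshape(-1),
            "achieved_eff_hca": eff[:, :, 1].reshape(-1),
            "achieved_eff_total": eff_total.reshape(-1),
            "state": state.reshape(-1),
        }
    )
    result = YearResult(
        records=frame,
        replication_seed=replication_seed,
        patient_shifts=int(patients.sum()),
    )
    logger.info(
        "replication seed=%d policy=%s scenario=%s wards=%d runtime=%.2fs",
        replication_seed,
        policy.mode,
        plan.scenario,
        n_wards,
        time.perf_counter() - t0,
    )
    return result
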