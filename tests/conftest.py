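"""Shared fixtures: reference hospitals and degenerate (zero-variance) setups."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from wardsim.engine import SimulationParams
from wardsim.synthetic import (
    DEFAULT_BAND_MIX,
    GeneratorConfig,
    HospitalProfile,
    WardProfile,
    generate_hospital,
    load_hospital,
)

REPO_ROOT = Path(__file__).resolve().parent.parent
FIXTURE_DIR = REPO_ROOT / "fixtures"

FIXTURE_SEED = 2020


@pytest.fixture(scope="session")
def hospital4() -> HospitalProfile:
    return generate_hospital(
        GeneratorConfig(n_wards=4, wards_per_division=4, hospital_id="H4"),
        FIXTURE_SEED,
    )


@pytest.fixture(scope="session")
def hospital20() -> HospitalProfile:
    return generate_hospital(
        GeneratorConfig(n_wards=20, wards_per_division=5, hospital_id="H20"),
        FIXTURE_SEED,
    )


@pytest.fixture(scope="session")
def hospital4_file() -> Path:
    path = FIXTURE_DIR / "hospital_4ward.yaml"
    if not path.exists():
        pytest.skip("committed fixture file missing")
    return path


def make_constant_ward(
    ward_id: str = "W01",
    division_id: str = "D01",
    beds: int = 24,
    census: int = 24,
    acuity=(1.0, 0.0, 0.0, 0.0, 0.0),
    specialing_rate: float = 0.0,
    skill_mix: float = 0.5,
    diurnal=(0.25, 0.25, 0.25, 0.25),
) -> WardProfile:
    """A zero-variance ward: constant census, deterministic acuity mix."""
    return WardProfile(
        ward_id=ward_id,
        division_id=division_id,
        beds=beds,
        census_dist=tuple({census: 1.0} for _ in range(7)),
        acuity_mean=tuple(acuity),
        acuity_concentration=None,
        specialing_rate=specialing_rate,
        skill_mix=skill_mix,
        diurnal_profile=tuple(diurnal),
        band_mix={g: dict(m) for g, m in DEFAULT_BAND_MIX.items()},
    )


@pytest.fixture
def constant_ward() -> WardProfile:
    return make_constant_ward()


@pytest.fixture
def constant_hospital() -> HospitalProfile:
    """Two zero-variance wards in one division.

    With the default level-0 multiplier of 2.0 h/patient-day, 24 patients
    give 48 h/day = 12 h/period = 6 h per period and group: exactly
    achievable, so the standard plan is an exact fit.
    """
    w1 = make_constant_ward("W01")
    w2 = make_constant_ward("W02")
    return HospitalProfile(
        hospital_id="HC",
        wards=(w1, w2),
        divisions={"D01": ("W01", "W02")},
    )


@pytest.fixture
def quiet_params() -> SimulationParams:
    """No absence, no requirement noise."""
    from wardsim.engine import AbsenceRates

    return SimulationParams(noise_cv=0.0, absence=AbsenceRates(rn=0.0, hca=0.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def year(hospital4):
    """One simulated year on the 4-ward fixture (standard, empirical)."""
    from wardsim.engine import FlexPolicy, simulate_year
    from wardsim.planner import ScenarioSpec, plan_hospital

    params = SimulationParams()
    plan = plan_hospital(
        hospital4, ScenarioSpec("standard"), params.multipliers,
        np.random.default_rng(0),
    )
    return simulate_year(hospital4, plan, FlexPolicy.empirical(), params, 77)
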