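"""Shared fixtures: scenarios, simulated cohorts, and hand-built records."""

from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pytest

from carespan.cohort import Cohort
from carespan.records import IndividualRecord, add_months
from carespan.simulate import (HazardParams, ScenarioConfig, default_scenario,
                               simulate_cohort)

DATA_DIR = Path(__file__).parent / "data"

BASELINE = date(2017, 4, 1)


def make_hazards(death=(0.0, 0.0, 0.0), death_slope=(0.0, 0.0, 0.0),
                 entry=(0.0, 0.0, 0.0), entry_slope=(0.0, 0.0, 0.0),
                 recovery=(0.0, 0.0, 0.0)) -> HazardParams:
    return HazardParams(death_base=death, death_slope=death_slope,
                        entry_base=entry, entry_slope=entry_slope,
                        recovery=recovery)


def single_stratum_scenario(params: HazardParams, n: int = 100, seed: int = 0,
                            initial=(1.0, 0.0, 0.0),
                            emigration: float = 0.0,
                            follow_up_years: float = 3.0) -> ScenarioConfig:
    """One population x sex, uniform-ish ages, everyone starting in one mix."""
    from carespan.simulate import AGE_GROUP_LABELS
    key = ("X", "female")
    return ScenarioConfig(
        populations=("X", "Y"),
        hazards={key: params},
        cohort_size={key: n},
        age_weights={key: (0.5, 0.3, 0.12, 0.05, 0.02, 0.01)},
        initial_state={key: {g: tuple(initial) for g in AGE_GROUP_LABELS}},
        emigration_rate=emigration,
        follow_up_years=follow_up_years,
        seed=seed,
    )


def monthly_record(person_id: str, baseline_age: float, states: list[int],
                   end_reason: str = "admin", end_offset_days: int | None = None,
                   population: str = "A", sex: str = "female") -> IndividualRecord:
    """Build a record with monthly states starting one month before baseline."""
    obs_start = add_months(BASELINE, -1)
    birth = BASELINE - timedelta(days=round(baseline_age * 365.25))
    if end_offset_days is None:
        obs_end = add_months(obs_start, len(states))
    else:
        obs_end = obs_start + timedelta(days=end_offset_days)
    return IndividualRecord(
        person_id=person_id, population=population, sex=sex,
        birth_date=birth, obs_start=obs_start, obs_end=obs_end,
        end_reason=end_reason,
        state_history=[(add_months(obs_start, m), s) for m, s in enumerate(states)],
    )


@pytest.fixture(scope="session")
def recovery_scenario() -> ScenarioConfig:
    """Default two-population scenario at recovery-test scale."""
    return default_scenario(seed=11, cohort_size=10_000)


@pytest.fixture(scope="session")
def recovery_cohort(recovery_scenario) -> Cohort:
    return simulate_cohort(recovery_scenario)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Small default-scenario cohort for cheap structural tests."""
    return simulate_cohort(default_scenario(seed=5, cohort_size=600))


def make_value_cohort(values: np.ndarray, population: str = "P",
                      sex: str = "f") -> Cohort:
    """Minimal cohort whose ages-at-start carry arbitrary numeric values.

    Used to exercise the bootstrap machinery with simple statistics such as
    the mean of ``age_in``.
    """
    n = len(values)
    base = np.datetime64("2017-04-01", "D")
    birth = base - np.round(np.asarray(values) * 365.25).astype("timedelta64[D]")
    return Cohort(
        person_id=np.array([f"p{i}" for i in range(n)], dtype=object),
        population=np.full(n, population, dtype=object),
        sex=np.full(n, sex, dtype=object),
        birth_date=birth,
        obs_start=np.full(n, base),
        obs_end=np.full(n, base + np.timedelta64(1096, "D")),
        end_reason=np.full(n, "admin", dtype=object),
        states=np.zeros((n, 1), dtype=np.int8),
        n_months=np.ones(n, dtype=np.int32),
    )
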