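"""Synthetic two-population cohorts with known care-transition hazards.

The generator emulates register-based cohorts of people aged 75+ followed
monthly from a fixed baseline date: three transient care states plus death,
all inter-state transitions allowed (including recovery to lower care
levels), death probabilities rising log-linearly with age and with care
level, emigration censoring, and an administrative end of follow-up.

Hazard parameters are specified per 3-month interval; trajectories are
simulated on a monthly clock using the competing-risk-proportional monthly
probability ``1 - (1 - p)^(1/3)``, so the generator's time step is genuinely
finer than (and independent of) the 3-month estimation grid.  Exact
per-interval transition matrices and the life expectancies they imply are
available as analytic oracles for parameter-recovery tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import yaml

from .cohort import Cohort
from .estimation import DEFAULT_OMEGA, TransitionSurface, default_grid
from .lifetable import LifeExpectancyResult, state_expectancies
from .records import DAYS_PER_YEAR, add_months
from .states import EndReason, State

REFERENCE_AGE = 75.0  # baseline probabilities are anchored at this age

AGE_GROUP_STARTS = (75.0, 80.0, 85.0, 90.0, 95.0, 100.0)
AGE_GROUP_LABELS = ("75-79", "80-84", "85-89", "90-94", "95-99", "100+")


class ConfigurationError(ValueError):
    """Raised when scenario parameters are internally inconsistent."""


@dataclass
class HazardParams:
    """Per-interval (3-month) transition parameters for one population x sex.

    ``death_base`` are death probabilities per interval at age 75 in each
    transient state (no care, home care, care home); ``death_slope`` are
    log-linear slopes per year of age.  ``entry_base``/``entry_slope``
    parameterise care entry (no care -> home care, no care -> care home,
    home care -> care home) the same way.  ``recovery`` holds age-constant
    per-interval probabilities of moving back down (home care -> no care,
    care home -> home care, care home -> no care).
    """

    death_base: tuple[float, float, float]
    death_slope: tuple[float, float, float]
    entry_base: tuple[float, float, float]
    entry_slope: tuple[float, float, float]
    recovery: tuple[float, float, float]

    def exit_probabilities(self, ages) -> np.ndarray:
        """Per-interval exit probabilities at given ages: array (n, 4, 4).

        Entry ``[a, i, j]`` is the probability that a person in transient
        state ``i`` at the interval start is in ``j`` at its end, for
        ``j != i``; diagonal entries are left at zero (the caller derives
        the stay probability residually).
        """
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        da = ages - REFERENCE_AGE
        out = np.zeros((len(ages), 4, 4))
        death = [self.death_base[s] * np.exp(self.death_slope[s] * da) for s in range(3)]
        e_nh = self.entry_base[0] * np.exp(self.entry_slope[0] * da)
        e_nc = self.entry_base[1] * np.exp(self.entry_slope[1] * da)
        e_hc = self.entry_base[2] * np.exp(self.entry_slope[2] * da)
        out[:, 0, 1] = e_nh
        out[:, 0, 2] = e_nc
        out[:, 0, 3] = death[0]
        out[:, 1, 0] = self.recovery[0]
        out[:, 1, 2] = e_hc
        out[:, 1, 3] = death[1]
        out[:, 2, 0] = self.recovery[2]
        out[:, 2, 1] = self.recovery[1]
        out[:, 2, 3] = death[2]
        return out


@dataclass
class ScenarioConfig:
    """Full specification of a two-population synthetic study.

    ``age_weights`` is the baseline age distribution as a mixture over the
    5-year groups 75-79 ... 100+ (uniform within a group); ``initial_state``
    maps each age-group label to the distribution over transient states at
    baseline.  Both are keyed by (population, sex), as are hazards and
    cohort sizes.
    """

    populations: tuple[str, str]
    hazards: dict[tuple[str, str], HazardParams]
    cohort_size: dict[tuple[str, str], int]
    age_weights: dict[tuple[str, str], tuple[float, ...]]
    initial_state: dict[tuple[str, str], dict[str, tuple[float, float, float]]]
    baseline_date: date = date(2017, 4, 1)
    follow_up_years: float = 3.0
    emigration_rate: float = 0.01          # annual censoring probability
    omega: float = DEFAULT_OMEGA
    sexes: tuple[str, str] = ("female", "male")
    seed: int = 0

    def strata(self):
        for pop in self.populations:
            for sex in self.sexes:
                yield pop, sex

    def params(self, population: str, sex: str) -> HazardParams:
        key = (population, sex)
        if key not in self.hazards:
            raise LookupError(f"no hazard parameters for population={population!r}, sex={sex!r}")
        return self.hazards[key]

    def validate(self) -> None:
        if self.follow_up_years <= 0:
            raise ConfigurationError("follow-up length must be positive")
        ages = np.arange(70.0, self.omega + 1e-9, 0.25)
        for (pop, sex), params in self.hazards.items():
            exits = params.exit_probabilities(ages)
            if (exits < 0).any():
                raise ConfigurationError(f"negative probability in hazards[{pop}, {sex}]")
            total = exits.sum(axis=2)[:, :3]
            for s in range(3):
                bad = np.flatnonzero(total[:, s] > 1.0 + 1e-12)
                if len(bad):
                    raise ConfigurationError(
                        f"exit probabilities from state {s} for ({pop}, {sex}) "
                        f"sum to {total[bad[0], s]:.3f} > 1 at age {ages[bad[0]]:.2f}"
                    )
        for key, n in self.cohort_size.items():
            if n < 0:
                raise ConfigurationError(f"negative cohort size for {key}")
        for key, w in self.age_weights.items():
            w = np.asarray(w, dtype=float)
            if len(w) != len(AGE_GROUP_STARTS) or (w < 0).any() or abs(w.sum() - 1) > 1e-9:
                raise ConfigurationError(f"age weights for {key} are not a distribution")
        for key, table in self.initial_state.items():
            for grp, dist in table.items():
                d = np.asarray(dist, dtype=float)
                if len(d) != 3 or (d < 0).any() or abs(d.sum() - 1) > 1e-9:
                    raise ConfigurationError(
                        f"initial-state distribution for {key}, age group {grp} "
                        "is not a distribution over the three transient states"
                    )


def _stratum_rng(seed: int, population: str, sex: str) -> np.random.Generator:
    """Stream keyed by a stable hash of the labels (permutation-invariant)."""
    digest = hashlib.sha256(f"{population}|{sex}".encode()).digest()
    h = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng([seed, h])


def _monthly_matrices(params: HazardParams, ages: np.ndarray) -> np.ndarray:
    """Monthly transition matrices at given ages.

    Per-interval exit mass E becomes ``Em = 1 - (1 - E)^(1/3)`` per month,
    split across destinations proportionally to the per-interval exits.
    """
    exits = params.exit_probabilities(ages)
    total = exits.sum(axis=2)                       # (n, 4); dead row zero
    em = 1.0 - (1.0 - np.clip(total, 0.0, 1.0)) ** (1.0 / 3.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(total > 0, em / total, 0.0)
    m = exits * scale[:, :, None]
    for s in range(3):
        m[:, s, s] = 1.0 - m[:, s, :].sum(axis=1)
    m[:, 3, 3] = 1.0
    return m


def simulate_cohort(config: ScenarioConfig) -> Cohort:
    """Simulate monthly trajectories for every configured stratum.

    Observation starts one calendar month before the baseline date (so the
    baseline care state, defined in the month prior to baseline, is always
    observed) and ends at death, emigration, or baseline + follow-up.  Panel
    rows record the state at each month's start; deaths and censoring events
    within a month are dated mid-month.  Reproducible given ``config.seed``.
    """
    config.validate()
    n_intervals = int(round(12 * config.follow_up_years))
    if abs(12 * config.follow_up_years - n_intervals) > 1e-9:
        raise ConfigurationError("follow-up length must be a whole number of months")
    obs_start = add_months(config.baseline_date, -1)
    month_dates = [add_months(obs_start, m) for m in range(n_intervals + 2)]
    month_d64 = np.array(month_dates, dtype="datetime64[D]")
    admin_end = month_dates[-1]  # == baseline + follow_up
    p_cens = 1.0 - (1.0 - config.emigration_rate) ** (1.0 / 12.0)

    parts: list[Cohort] = []
    for pop, sex in config.strata():
        n = config.cohort_size.get((pop, sex), 0)
        if n == 0:
            continue
        params = config.params(pop, sex)
        rng = _stratum_rng(config.seed, pop, sex)

        groups = rng.choice(len(AGE_GROUP_STARTS), size=n,
                            p=np.asarray(config.age_weights[(pop, sex)], dtype=float))
        width = np.where(groups == len(AGE_GROUP_STARTS) - 1, 4.0, 5.0)
        baseline_age = np.asarray(AGE_GROUP_STARTS)[groups] + width * rng.random(n)
        birth_offset_days = np.round(baseline_age * DAYS_PER_YEAR).astype(np.int64)
        birth = np.datetime64(config.baseline_date, "D") - birth_offset_days

        init_table = config.initial_state[(pop, sex)]
        init_p = np.array([init_table[AGE_GROUP_LABELS[g]] for g in range(len(AGE_GROUP_STARTS))])
        u = rng.random(n)
        cum = init_p.cumsum(axis=1)[groups]
        state0 = (u[:, None] > cum).sum(axis=1).astype(np.int8)

        n_rows = n_intervals + 1                  # months 0 .. n_intervals
        states = np.full((n, n_rows), -1, dtype=np.int8)
        states[:, 0] = state0
        alive = np.ones(n, dtype=bool)
        event_month = np.full(n, -1, dtype=np.int64)
        event_kind = np.zeros(n, dtype=np.int8)   # 0 none, 1 death, 2 censored
        ages_at_month = (month_d64[None, :] - birth[:, None]).astype(float) / DAYS_PER_YEAR

        for m in range(n_intervals):
            idx = np.flatnonzero(alive)
            if len(idx) == 0:
                break
            u_c = rng.random(len(idx))
            u_t = rng.random(len(idx))
            censored = u_c < p_cens
            mm = _monthly_matrices(params, ages_at_month[idx, m])
            cum_m = mm.cumsum(axis=2)
            s = states[idx, m].astype(np.int64)
            nxt = (u_t[:, None] > cum_m[np.arange(len(idx)), s]).sum(axis=1)
            dead = (nxt == int(State.DEAD)) & ~censored
            stop = censored | dead
            event_month[idx[stop]] = m
            event_kind[idx[censored]] = 2
            event_kind[idx[dead]] = 1
            alive[idx[stop]] = False
            cont = idx[~stop]
            states[cont, m + 1] = nxt[~stop].astype(np.int8)

        n_months = np.where(event_month >= 0, event_month + 1, n_rows).astype(np.int32)
        obs_end = np.empty(n, dtype="datetime64[D]")
        end_reason = np.empty(n, dtype=object)
        ev = event_month >= 0
        obs_end[~ev] = np.datetime64(admin_end, "D")
        end_reason[~ev] = EndReason.ADMIN
        if ev.any():
            obs_end[ev] = month_d64[event_month[ev]] + np.timedelta64(14, "D")
            end_reason[ev] = np.where(event_kind[ev] == 1, EndReason.DEATH,
                                      EndReason.CENSORED)
        parts.append(Cohort(
            person_id=np.array([f"{pop}-{sex}-{i:06d}" for i in range(n)], dtype=object),
            population=np.full(n, pop, dtype=object),
            sex=np.full(n, sex, dtype=object),
            birth_date=birth,
            obs_start=np.full(n, np.datetime64(obs_start, "D")),
            obs_end=obs_end,
            end_reason=end_reason,
            states=states,
            n_months=n_months,
        ))
    if not parts:
        raise ConfigurationError("scenario defines no persons")
    return _concat(parts)


def _concat(parts: list[Cohort]) -> Cohort:
    max_m = max(p.states.shape[1] for p in parts)
    padded = []
    for p in parts:
        if p.states.shape[1] < max_m:
            pad = np.full((len(p), max_m - p.states.shape[1]), -1, dtype=np.int8)
            padded.append(np.hstack([p.states, pad]))
        else:
            padded.append(p.states)
    return Cohort(
        person_id=np.concatenate([p.person_id for p in parts]),
        population=np.concatenate([p.population for p in parts]),
        sex=np.concatenate([p.sex for p in parts]),
        birth_date=np.concatenate([p.birth_date for p in parts]),
        obs_start=np.concatenate([p.obs_start for p in parts]),
        obs_end=np.concatenate([p.obs_end for p in parts]),
        end_reason=np.concatenate([p.end_reason for p in parts]),
        states=np.vstack(padded),
        n_months=np.concatenate([p.n_months for p in parts]),
    )


def true_transition_surface(config: ScenarioConfig, population: str,
                            sex: str) -> TransitionSurface:
    """Exact per-interval matrices implied by the hazard parameters.

    Each 3-month matrix is the product of the three monthly matrices at the
    monthly ages within the interval — exactly the chain the simulator runs.
    """
    params = config.params(population, sex)
    grid = default_grid(config.omega)
    month = 1.0 / 12.0
    m0 = _monthly_matrices(params, grid)
    m1 = _monthly_matrices(params, grid + month)
    m2 = _monthly_matrices(params, grid + 2 * month)
    mats = m0 @ m1 @ m2
    return TransitionSurface(ages=grid, delta=float(grid[1] - grid[0]),
                             matrices=mats, kind="true")


def age_group_of(age: float) -> str:
    """5-year baseline age-group label for an age >= 75."""
    if age < AGE_GROUP_STARTS[0]:
        raise ValueError(f"age {age} below the youngest configured group")
    for start, label in zip(reversed(AGE_GROUP_STARTS), reversed(AGE_GROUP_LABELS)):
        if age >= start:
            return label
    raise AssertionError


def true_life_expectancy(config: ScenarioConfig, population: str, sex: str,
                         index_age: float,
                         initial_distribution=None) -> LifeExpectancyResult:
    """Life-table algebra applied to the exact transition surface.

    The default initial distribution is the configured baseline state
    distribution of the age group containing the index age.
    """
    if not (70.0 <= index_age < config.omega):
        raise ValueError(f"index age {index_age} outside [70, omega)")
    surface = true_transition_surface(config, population, sex)
    surface.index_of(index_age)  # raises if off-grid
    if initial_distribution is None:
        initial_distribution = config.initial_state[(population, sex)][age_group_of(index_age)]
    return state_expectancies(surface, index_age, initial_distribution)


# ---------------------------------------------------------------------------
# default scenario and YAML round-trip
# ---------------------------------------------------------------------------

# Baseline care-state composition by 5-year age group, loosely matched to the
# published register-based composition of the Japanese and Swedish 75+
# populations (population A resembles Japan: more home care, fewer care
# homes; population B resembles Sweden).
_INITIAL_STATE_A_MEN = {
    "75-79": (0.932, 0.055, 0.013), "80-84": (0.862, 0.108, 0.030),
    "85-89": (0.740, 0.195, 0.065), "90-94": (0.590, 0.269, 0.141),
    "95-99": (0.473, 0.304, 0.223), "100+": (0.378, 0.370, 0.252),
}
_INITIAL_STATE_B_MEN = {
    "75-79": (0.941, 0.039, 0.020), "80-84": (0.854, 0.096, 0.050),
    "85-89": (0.713, 0.187, 0.100), "90-94": (0.521, 0.295, 0.184),
    "95-99": (0.333, 0.366, 0.301), "100+": (0.214, 0.383, 0.403),
}
_INITIAL_STATE_A_WOMEN = {
    "75-79": (0.905, 0.075, 0.020), "80-84": (0.768, 0.176, 0.056),
    "85-89": (0.571, 0.290, 0.139), "90-94": (0.410, 0.330, 0.260),
    "95-99": (0.317, 0.307, 0.376), "100+": (0.280, 0.248, 0.472),
}
_INITIAL_STATE_B_WOMEN = {
    "75-79": (0.922, 0.055, 0.023), "80-84": (0.789, 0.143, 0.068),
    "85-89": (0.589, 0.261, 0.150), "90-94": (0.371, 0.351, 0.278),
    "95-99": (0.211, 0.355, 0.434), "100+": (0.144, 0.279, 0.577),
}

_AGE_WEIGHTS_MEN = (0.50, 0.30, 0.145, 0.045, 0.009, 0.001)
_AGE_WEIGHTS_WOMEN = (0.44, 0.30, 0.17, 0.07, 0.017, 0.003)


def default_scenario(seed: int = 0, cohort_size: int = 10_000,
                     follow_up_years: float = 3.0) -> ScenarioConfig:
    """Two qualitatively contrasted populations.

    Population A has lower mortality inside the care states and lower
    care-home use; population B has higher in-care mortality and more
    care-home use.  Mortality rises log-linearly with age in every state and
    sharply with care level; women have lower mortality and higher care use
    than men.  Not calibrated to any published transition rates.
    """
    hazards = {
        ("A", "male"): HazardParams(
            death_base=(0.0040, 0.018, 0.055), death_slope=(0.105, 0.085, 0.060),
            entry_base=(0.0060, 0.0006, 0.012), entry_slope=(0.120, 0.150, 0.070),
            recovery=(0.030, 0.004, 0.002),
        ),
        ("A", "female"): HazardParams(
            death_base=(0.0025, 0.013, 0.045), death_slope=(0.115, 0.090, 0.065),
            entry_base=(0.0072, 0.0007, 0.014), entry_slope=(0.120, 0.150, 0.070),
            recovery=(0.030, 0.004, 0.002),
        ),
        ("B", "male"): HazardParams(
            death_base=(0.0040, 0.028, 0.075), death_slope=(0.100, 0.085, 0.060),
            entry_base=(0.0050, 0.0012, 0.020), entry_slope=(0.120, 0.150, 0.070),
            recovery=(0.025, 0.003, 0.0015),
        ),
        ("B", "female"): HazardParams(
            death_base=(0.0027, 0.022, 0.065), death_slope=(0.110, 0.090, 0.065),
            entry_base=(0.0060, 0.0014, 0.024), entry_slope=(0.120, 0.150, 0.070),
            recovery=(0.025, 0.003, 0.0015),
        ),
    }
    return ScenarioConfig(
        populations=("A", "B"),
        hazards=hazards,
        cohort_size={k: cohort_size for k in hazards},
        age_weights={
            ("A", "male"): _AGE_WEIGHTS_MEN, ("B", "male"): _AGE_WEIGHTS_MEN,
            ("A", "female"): _AGE_WEIGHTS_WOMEN, ("B", "female"): _AGE_WEIGHTS_WOMEN,
        },
        initial_state={
            ("A", "male"): _INITIAL_STATE_A_MEN,
            ("B", "male"): _INITIAL_STATE_B_MEN,
            ("A", "female"): _INITIAL_STATE_A_WOMEN,
            ("B", "female"): _INITIAL_STATE_B_WOMEN,
        },
        follow_up_years=follow_up_years,
        seed=seed,
    )


def scenario_to_dict(config: ScenarioConfig) -> dict:
    def key(k):
        return f"{k[0]}|{k[1]}"

    return {
        "populations": list(config.populations),
        "sexes": list(config.sexes),
        "baseline_date": config.baseline_date.isoformat(),
        "follow_up_years": config.follow_up_years,
        "emigration_rate": config.emigration_rate,
        "omega": config.omega,
        "seed": config.seed,
        "cohort_size": {key(k): int(v) for k, v in config.cohort_size.items()},
        "age_weights": {key(k): list(map(float, v)) for k, v in config.age_weights.items()},
        "initial_state": {
            key(k): {g: list(map(float, d)) for g, d in tbl.items()}
            for k, tbl in config.initial_state.items()
        },
        "hazards": {
            key(k): {
                "death_base": list(map(float, p.death_base)),
                "death_slope": list(map(float, p.death_slope)),
                "entry_base": list(map(float, p.entry_base)),
                "entry_slope": list(map(float, p.entry_slope)),
                "recovery": list(map(float, p.recovery)),
            }
            for k, p in config.hazards.items()
        },
    }


def scenario_from_dict(data: dict) -> ScenarioConfig:
    def unkey(s):
        pop, sex = s.split("|")
        return pop, sex

    hazards = {
        unkey(k): HazardParams(
            death_base=tuple(v["death_base"]), death_slope=tuple(v["death_slope"]),
            entry_base=tuple(v["entry_base"]), entry_slope=tuple(v["entry_slope"]),
            recovery=tuple(v["recovery"]),
        )
        for k, v in data["hazards"].items()
    }
    return ScenarioConfig(
        populations=tuple(data["populations"]),
        sexes=tuple(data.get("sexes", ("female", "male"))),
        hazards=hazards,
        cohort_size={unkey(k): int(v) for k, v in data["cohort_size"].items()},
        age_weights={unkey(k): tuple(v) for k, v in data["age_weights"].items()},
        initial_state={
            unkey(k): {g: tuple(d) for g, d in tbl.items()}
            for k, tbl in data["initial_state"].items()
        },
        baseline_date=date.fromisoformat(data.get("baseline_date", "2017-04-01")),
        follow_up_years=float(data.get("follow_up_years", 3.0)),
        emigration_rate=float(data.get("emigration_rate", 0.01)),
        omega=float(data.get("omega", DEFAULT_OMEGA)),
        seed=int(data.get("seed", 0)),
    )


def scenario_to_yaml(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(config), fh, sort_keys=True)


def scenario_from_yaml(path) -> ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))
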