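"""Estimation of 3-month transition probabilities among the care states.

Transitions are counted on a discrete age grid (default 3-month steps from
age 70 to 105): a person contributes one origin/destination pair to every
grid interval they begin under observation, with origin the state in the
month containing the interval-start age, destination the state at the
interval end (death if it occurred within the interval), and exclusion from
both numerator and denominator when censored mid-interval.

Raw probabilities are occurrence/exposure ratios; smoothed probabilities
come from per-transition binomial P-spline fits on the logit scale with the
stay probability defined residually so every row is stochastic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import as_cohort
from .pspline import fit_binomial_pspline
from .states import N_STATES, STATE_LABELS, State, TRANSIENT_STATES

GRID_STEP = 0.25
GRID_START = 70.0
DEFAULT_OMEGA = 105.0

_LABEL_TO_CODE = {v: k for k, v in STATE_LABELS.items()}


def default_grid(omega: float = DEFAULT_OMEGA, start: float = GRID_START,
                 step: float = GRID_STEP) -> np.ndarray:
    """Interval-start ages ``start, start+step, ..., omega-step``."""
    n = int(round((omega - start) / step))
    if n < 1:
        raise ValueError("grid must contain at least one interval")
    return start + step * np.arange(n)


@dataclass
class TransitionCounts:
    """At-risk and destination counts per grid interval and origin state."""

    ages: np.ndarray            # (K,) interval-start ages
    delta: float                # interval width in years
    counts: np.ndarray          # (K, 4, 4) origin -> destination counts
    at_risk: np.ndarray         # (K, 4)

    def __post_init__(self) -> None:
        if not np.array_equal(self.counts.sum(axis=2), self.at_risk):
            raise ValueError("destination counts must sum to the at-risk count")
        if (self.counts < 0).any():
            raise ValueError("negative transition counts")

    @property
    def omega(self) -> float:
        return float(self.ages[-1] + self.delta)

    def observed_initial_distribution(self, index_age: float,
                                      window: float | None = None) -> np.ndarray:
        """Distribution over transient states among those at risk at an age.

        With ``window`` (years), at-risk counts are pooled over grid ages in
        ``[index_age, index_age + window)``, which stabilizes the
        distribution when few people are under observation exactly at the
        index age.
        """
        k = _grid_index(self.ages, index_age)
        k_hi = k + 1 if window is None else k + max(1, int(round(window / self.delta)))
        n = self.at_risk[k:k_hi, :3].sum(axis=0).astype(float)
        if n.sum() == 0:
            raise ValueError(f"no one at risk at age {index_age}")
        return n / n.sum()


@dataclass
class TransitionSurface:
    """Per-interval 4x4 stochastic matrices over the care states."""

    ages: np.ndarray            # (K,) interval-start ages
    delta: float
    matrices: np.ndarray        # (K, 4, 4)
    kind: str = "raw"           # raw | smoothed | true
    missing: np.ndarray = field(default=None)  # (K, 3) transient rows without data

    def __post_init__(self) -> None:
        if self.missing is None:
            self.missing = np.zeros((len(self.ages), 3), dtype=bool)
        self.validate()

    def validate(self) -> None:
        p = self.matrices
        if (p < -1e-12).any() or (p > 1 + 1e-12).any():
            raise ValueError("transition probabilities outside [0, 1]")
        dead = p[:, int(State.DEAD), :]
        if not np.allclose(dead, [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("DEAD row must be exactly (0, 0, 0, 1)")
        rows = p[:, :3, :].sum(axis=2)
        ok = np.abs(rows - 1) <= 1e-9
        if not (ok | self.missing).all():
            raise ValueError("transient rows must sum to 1 within 1e-9")

    @property
    def omega(self) -> float:
        return float(self.ages[-1] + self.delta)

    def index_of(self, age: float) -> int:
        return _grid_index(self.ages, age)

    def matrix_at(self, age: float) -> np.ndarray:
        return self.matrices[self.index_of(age)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy (age, origin, destination, probability, flag) representation."""
        rows = []
        for k, a in enumerate(self.ages):
            for i in range(N_STATES):
                miss = i < 3 and bool(self.missing[k, i])
                for j in range(N_STATES):
                    rows.append(
                        (round(float(a), 6), STATE_LABELS[i], STATE_LABELS[j],
                         float(self.matrices[k, i, j]),
                         "missing" if miss else self.kind)
                    )
        return pd.DataFrame(rows, columns=["age", "origin", "destination",
                                           "probability", "flag"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, delta: float = GRID_STEP) -> "TransitionSurface":
        ages = np.sort(df["age"].unique().astype(float))
        k = len(ages)
        mats = np.zeros((k, N_STATES, N_STATES))
        missing = np.zeros((k, 3), dtype=bool)
        kind = "raw"
        idx = {round(float(a), 6): i for i, a in enumerate(ages)}
        for _, r in df.iterrows():
            ka = idx[round(float(r["age"]), 6)]
            i = _LABEL_TO_CODE[r["origin"]]
            j = _LABEL_TO_CODE[r["destination"]]
            mats[ka, i, j] = r["probability"]
            if r["flag"] == "missing" and i < 3:
                missing[ka, i] = True
            elif r["flag"] != "missing":
                kind = r["flag"]
        return cls(ages=ages, delta=delta, matrices=mats, kind=kind, missing=missing)

    @classmethod
    def from_csv(cls, path, delta: float = GRID_STEP) -> "TransitionSurface":
        return cls.from_frame(pd.read_csv(path), delta=delta)


def _grid_index(ages: np.ndarray, age: float) -> int:
    hits = np.flatnonzero(np.abs(ages - age) < 1e-9)
    if len(hits) != 1:
        raise ValueError(f"age {age} is not on the estimation grid")
    return int(hits[0])


def count_transitions(data, grid: np.ndarray | None = None,
                      omega: float = DEFAULT_OMEGA,
                      window_end=None) -> TransitionCounts:
    """Tabulate per-interval transitions for a cohort.

    ``data`` may be a :class:`~carespan.cohort.Cohort` or a list of
    :class:`~carespan.records.IndividualRecord`.

    ``window_end`` is the administrative end of follow-up (a calendar
    date), when one exists.  Passing it removes a subtle asymmetry: a
    person whose follow-up window closes mid-interval is dropped from that
    interval when they survive (censored mid-interval) but their death
    would still be observed, which inflates death probabilities by roughly
    q/24 under a shared 3-year window.  With ``window_end`` given, persons
    are excluded from any interval their window cannot cover, whether or
    not they died in it.
    """
    cohort = as_cohort(data)
    if grid is None:
        grid = default_grid(omega)
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("empty age grid")
    delta = float(np.diff(grid)[0]) if len(grid) > 1 else GRID_STEP

    age_in = cohort.age_in
    age_out = cohort.age_out
    died = cohort.died
    n_months = cohort.n_months
    states = cohort.states
    if window_end is not None:
        age_win = (np.datetime64(window_end, "D")
                   - cohort.birth_date).astype(float) / 365.25
    else:
        age_win = np.full(len(cohort), np.inf)
    k_grid = len(grid)
    counts = np.zeros((k_grid, N_STATES, N_STATES), dtype=np.int64)

    for k in range(k_grid):
        a = grid[k]
        b = a + delta
        m_a = np.floor((a - age_in) * 12.0 + 1e-6).astype(np.int64)
        at_obs = ((m_a >= 0) & (m_a < n_months) & (age_out > a + 1e-9)
                  & (age_win >= b - 1e-9))
        if not at_obs.any():
            continue
        dead_dest = died & (age_out <= b + 1e-9)
        m_b = np.floor((b - age_in) * 12.0 + 1e-6).astype(np.int64)
        through_b = (age_out >= b - 1e-9) & (m_b < n_months)
        include = at_obs & (dead_dest | through_b)
        rows = np.flatnonzero(include)
        if len(rows) == 0:
            continue
        origin = states[rows, m_a[rows]].astype(np.int64)
        dest = np.where(
            dead_dest[rows], int(State.DEAD),
            states[rows, np.minimum(m_b[rows], n_months[rows] - 1)].astype(np.int64),
        )
        code = origin * N_STATES + dest
        counts[k] += np.bincount(code, minlength=N_STATES * N_STATES).reshape(
            N_STATES, N_STATES
        )
    return TransitionCounts(ages=grid, delta=delta, counts=counts,
                            at_risk=counts.sum(axis=2))


def raw_probabilities(counts: TransitionCounts) -> TransitionSurface:
    """Occurrence/exposure transition probabilities; empty rows flagged missing."""
    k = len(counts.ages)
    mats = np.zeros((k, N_STATES, N_STATES))
    missing = np.zeros((k, 3), dtype=bool)
    for i in range(3):
        n = counts.at_risk[:, i].astype(float)
        has = n > 0
        missing[:, i] = ~has
        mats[has, i, :] = counts.counts[has, i, :] / n[has, None]
    mats[:, int(State.DEAD), int(State.DEAD)] = 1.0
    return TransitionSurface(ages=counts.ages, delta=counts.delta,
                             matrices=mats, kind="raw", missing=missing)


@dataclass
class SplineConfig:
    """P-spline settings for transition-probability smoothing."""

    n_basis: int = 15
    degree: int = 3
    penalty_order: int = 2
    lambdas: np.ndarray = field(default_factory=lambda: np.logspace(-2, 6, 9))


def smooth_probabilities(counts: TransitionCounts,
                         spline_config: SplineConfig | None = None) -> TransitionSurface:
    """Smooth each off-diagonal transition with a binomial P-spline.

    For every origin state the three exit probabilities (including death) are
    fitted on the logit scale against age, weighted by at-risk counts, and
    predicted on the full grid (ages without data are filled from the fit).
    The stay probability is one minus the fitted exits; if the fitted exits
    ever exceed one they are rescaled proportionally with a warning.
    """
    cfg = spline_config or SplineConfig()
    ages = counts.ages
    domain = (float(ages[0]), float(ages[-1]))
    k = len(ages)
    mats = np.zeros((k, N_STATES, N_STATES))
    for i in (int(s) for s in TRANSIENT_STATES):
        n = counts.at_risk[:, i].astype(float)
        n_distinct = int((n > 0).sum())
        if n_distinct < cfg.n_basis:
            raise ValueError(
                f"origin state {STATE_LABELS[i]!r} has data at {n_distinct} grid "
                f"ages, fewer than the {cfg.n_basis} basis functions; reduce "
                "n_basis in SplineConfig"
            )
        exits = [j for j in range(N_STATES) if j != i]
        fitted = np.zeros((k, len(exits)))
        for col, j in enumerate(exits):
            fit = fit_binomial_pspline(
                ages, counts.counts[:, i, j].astype(float), n, domain,
                n_basis=cfg.n_basis, degree=cfg.degree,
                penalty_order=cfg.penalty_order, lambdas=cfg.lambdas,
            )
            fitted[:, col] = fit.predict(ages)
        total = fitted.sum(axis=1)
        over = total > 1.0
        if over.any():
            warnings.warn(
                f"fitted exit probabilities from {STATE_LABELS[i]!r} exceed 1 at "
                f"{int(over.sum())} grid ages; rescaled proportionally",
                stacklevel=2,
            )
            fitted[over] /= total[over, None]
            total = np.minimum(total, 1.0)
        for col, j in enumerate(exits):
            mats[:, i, j] = fitted[:, col]
        mats[:, i, i] = 1.0 - total
    mats[:, int(State.DEAD), int(State.DEAD)] = 1.0
    return TransitionSurface(ages=ages, delta=counts.delta, matrices=mats,
                             kind="smoothed")
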