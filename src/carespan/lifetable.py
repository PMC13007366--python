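"""Occupancy probabilities and state-specific life expectancy.

Given a per-interval transition surface, occupancy is obtained by iterating
``pi(t + delta) = pi(t) P(t)`` from the index age to the terminal age Omega,
where all remaining mass is moved to death (closure).  Expected time in a
transient state credits the full interval width to anyone present at the
interval start (the declared default convention); a trapezoid variant with
half-interval end corrections is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import TransitionSurface
from .states import N_STATES, STATE_LABELS, State


@dataclass
class LifeExpectancyResult:
    """Total remaining life expectancy and expected years per care state."""

    index_age: float
    initial_distribution: np.ndarray      # (3,) over transient states
    total: float
    by_state: np.ndarray                  # (3,) expected years per transient state
    ci: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if abs(self.by_state.sum() - self.total) > 1e-9:
            raise ValueError("state expectancies must sum to total LE")

    def to_frame(self, **labels) -> pd.DataFrame:
        rows = []
        quantities = [("total", self.total)] + [
            (STATE_LABELS[i], float(self.by_state[i])) for i in range(3)
        ]
        for name, est in quantities:
            lo, hi = (self.ci or {}).get(name, (np.nan, np.nan))
            rows.append({**labels, "quantity": name, "estimate": est,
                         "lower": lo, "upper": hi})
        return pd.DataFrame(rows)


def _initial_vector(initial_distribution) -> np.ndarray:
    d = np.asarray(initial_distribution, dtype=float)
    if d.shape == (N_STATES,):
        if abs(d[int(State.DEAD)]) > 1e-12:
            raise ValueError("initial distribution must put no mass on DEAD")
        d = d[:3]
    if d.shape != (3,):
        raise ValueError("initial distribution must have 3 (or 4) entries")
    if abs(d.sum() - 1) > 1e-9 or (d < 0).any():
        raise ValueError("initial distribution must be a probability vector")
    return np.concatenate([d, [0.0]])


def occupancy(surface: TransitionSurface, index_age: float,
              initial_distribution) -> tuple[np.ndarray, np.ndarray]:
    """State-occupancy probabilities at every grid point from the index age.

    Returns ``(ages, occ)`` where ``ages`` runs from the index age to Omega
    inclusive and ``occ[t]`` is the distribution over the four states.  The
    final row applies closure: all transient mass is moved to death at Omega.
    """
    k0 = surface.index_of(index_age)
    k_end = len(surface.ages)
    if surface.missing[k0:, :].any():
        raise ValueError(
            "surface has unfitted (missing) rows between the index age and "
            "Omega; apply smooth_probabilities first"
        )
    pi = _initial_vector(initial_distribution)
    out = np.empty((k_end - k0 + 1, N_STATES))
    out[0] = pi
    for t, k in enumerate(range(k0, k_end), start=1):
        pi = pi @ surface.matrices[k]
        out[t] = pi
    # closure at Omega: force death for any remaining transient mass
    out[-1, int(State.DEAD)] += out[-1, :3].sum()
    out[-1, :3] = 0.0
    ages = np.concatenate([surface.ages[k0:], [surface.omega]])
    return ages, out


def state_expectancies(surface: TransitionSurface, index_age: float,
                       initial_distribution,
                       half_interval: bool = False) -> LifeExpectancyResult:
    """Expected years in each transient state (and their sum) from an index age.

    Default convention: presence at an interval start earns the full interval
    width.  With ``half_interval=True`` a trapezoid rule is used instead
    (half weight at the index age and at Omega, using pre-closure occupancy).
    """
    k0 = surface.index_of(index_age)
    if surface.missing[k0:, :].any():
        raise ValueError(
            "surface has unfitted (missing) rows between the index age and "
            "Omega; apply smooth_probabilities first"
        )
    pi = _initial_vector(initial_distribution)
    delta = surface.delta
    k_end = len(surface.ages)
    times = np.zeros(3)
    if half_interval:
        times += 0.5 * delta * pi[:3]
        for k in range(k0, k_end):
            pi = pi @ surface.matrices[k]
            w = 0.5 if k == k_end - 1 else 1.0
            times += w * delta * pi[:3]
    else:
        for k in range(k0, k_end):
            times += delta * pi[:3]
            pi = pi @ surface.matrices[k]
    return LifeExpectancyResult(
        index_age=index_age,
        initial_distribution=np.asarray(initial_distribution, dtype=float)[:3],
        total=float(times.sum()),
        by_state=times,
    )


def simulate_lifetimes(surface: TransitionSurface, index_age: float,
                       initial_distribution, n: int,
                       rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Monte-Carlo oracle: sample ``n`` trajectories on the discrete chain.

    Uses the same conventions as :func:`state_expectancies` (full interval
    credit, forced death at Omega).  Returns per-trajectory total lifetime
    and time per transient state, for checking the life-table algebra by
    simulation.
    """
    k0 = surface.index_of(index_age)
    init = _initial_vector(initial_distribution)[:3]
    state = rng.choice(3, size=n, p=init).astype(np.int64)
    alive = np.ones(n, dtype=bool)
    delta = surface.delta
    state_time = np.zeros((n, 3))
    cum = surface.matrices.cumsum(axis=2)
    for k in range(k0, len(surface.ages)):
        idx = np.flatnonzero(alive)
        if len(idx) == 0:
            break
        s = state[idx]
        state_time[idx, s] += delta
        u = rng.random(len(idx))
        nxt = (u[:, None] > cum[k][s]).sum(axis=1)
        state[idx] = nxt
        alive[idx] = nxt != int(State.DEAD)
    return {
        "total": state_time.sum(axis=1),
        "by_state": state_time,
    }
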