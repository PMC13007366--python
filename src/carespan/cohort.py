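"""Array-backed cohort container used by the estimation and rate modules.

A :class:`Cohort` holds the same information as a list of
:class:`~carespan.records.IndividualRecord` but in rectangular numpy arrays,
which makes transition counting and bootstrap resampling cheap.  Monthly
state occupancy is stored as an ``(n_persons, max_months)`` int8 matrix
padded with -1 beyond each person's observed months.

Month-to-age mapping treats a calendar month as exactly 1/12 year, which
differs from true calendar month lengths by at most ~1.5 days over a month;
the induced state-attribution error at 3-month grid ages is negligible
relative to sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np

from .records import DAYS_PER_YEAR, IndividualRecord, add_months, month_index
from .states import EndReason

PAD = -1


@dataclass
class Cohort:
    person_id: np.ndarray       # object, (n,)
    population: np.ndarray      # object, (n,)
    sex: np.ndarray             # object, (n,)
    birth_date: np.ndarray      # datetime64[D], (n,)
    obs_start: np.ndarray       # datetime64[D], (n,)
    obs_end: np.ndarray         # datetime64[D], (n,)
    end_reason: np.ndarray      # object, (n,)
    states: np.ndarray          # int8, (n, max_months), PAD beyond n_months
    n_months: np.ndarray        # int32, (n,)

    def __post_init__(self) -> None:
        self._age_in = (self.obs_start - self.birth_date).astype(float) / DAYS_PER_YEAR
        self._age_out = (self.obs_end - self.birth_date).astype(float) / DAYS_PER_YEAR

    def __len__(self) -> int:
        return len(self.person_id)

    @property
    def age_in(self) -> np.ndarray:
        """Age at observation start (years)."""
        return self._age_in

    @property
    def age_out(self) -> np.ndarray:
        """Age at observation end: death, censoring, or administrative end."""
        return self._age_out

    @property
    def died(self) -> np.ndarray:
        return self.end_reason == EndReason.DEATH

    def subset(self, idx) -> "Cohort":
        """Row-subset (used by bootstrap resampling); idx may repeat."""
        return Cohort(
            person_id=self.person_id[idx],
            population=self.population[idx],
            sex=self.sex[idx],
            birth_date=self.birth_date[idx],
            obs_start=self.obs_start[idx],
            obs_end=self.obs_end[idx],
            end_reason=self.end_reason[idx],
            states=self.states[idx],
            n_months=self.n_months[idx],
        )

    def strata(self):
        """Yield ((population, sex), boolean mask) for each observed stratum."""
        pops = sorted(set(self.population.tolist()))
        sexes = sorted(set(self.sex.tolist()))
        for p in pops:
            for s in sexes:
                mask = (self.population == p) & (self.sex == s)
                if mask.any():
                    yield (p, s), mask

    def filter(self, population=None, sex=None) -> "Cohort":
        mask = np.ones(len(self), dtype=bool)
        if population is not None:
            mask &= self.population == population
        if sex is not None:
            mask &= self.sex == sex
        return self.subset(np.flatnonzero(mask))

    def state_at_age(self, age: float) -> np.ndarray:
        """State occupied in the month containing ``age``; PAD when unobserved.

        Does not encode death: callers combine with ``age_out``/``died``.
        """
        m = np.floor((age - self._age_in) * 12.0 + 1e-6).astype(np.int64)
        valid = (m >= 0) & (m < self.n_months)
        out = np.full(len(self), PAD, dtype=np.int8)
        rows = np.flatnonzero(valid)
        out[rows] = self.states[rows, m[rows]]
        return out

    def age_at(self, when: date) -> np.ndarray:
        """Continuous age of every person at a calendar date."""
        d = np.datetime64(when, "D")
        return (d - self.birth_date).astype(float) / DAYS_PER_YEAR

    def state_in_month(self, when: date) -> np.ndarray:
        """State in the calendar month containing ``when``; PAD if unobserved.

        Assumes panel months align with calendar months of ``obs_start``
        (true for panels written by this package).
        """
        out = np.full(len(self), PAD, dtype=np.int8)
        for i in range(len(self)):
            start = self.obs_start[i].astype(object)
            m = month_index(start, when)
            if 0 <= m < self.n_months[i]:
                out[i] = self.states[i, m]
        return out

    # ---- conversions ----

    @classmethod
    def from_records(cls, records: list[IndividualRecord]) -> "Cohort":
        n = len(records)
        max_m = max((len(r.state_history) for r in records), default=0)
        states = np.full((n, max(max_m, 1)), PAD, dtype=np.int8)
        n_months = np.zeros(n, dtype=np.int32)
        for i, r in enumerate(records):
            k = len(r.state_history)
            n_months[i] = k
            if k:
                states[i, :k] = [s for _, s in r.state_history]
        return cls(
            person_id=np.array([r.person_id for r in records], dtype=object),
            population=np.array([r.population for r in records], dtype=object),
            sex=np.array([r.sex for r in records], dtype=object),
            birth_date=np.array([r.birth_date for r in records], dtype="datetime64[D]"),
            obs_start=np.array([r.obs_start for r in records], dtype="datetime64[D]"),
            obs_end=np.array([r.obs_end for r in records], dtype="datetime64[D]"),
            end_reason=np.array([r.end_reason for r in records], dtype=object),
            states=states,
            n_months=n_months,
        )

    def to_records(self) -> list[IndividualRecord]:
        out = []
        for i in range(len(self)):
            start = self.obs_start[i].astype(object)
            history = [
                (add_months(start, m), int(self.states[i, m]))
                for m in range(int(self.n_months[i]))
            ]
            out.append(
                IndividualRecord(
                    person_id=str(self.person_id[i]),
                    population=str(self.population[i]),
                    sex=str(self.sex[i]),
                    birth_date=self.birth_date[i].astype(object),
                    obs_start=start,
                    obs_end=self.obs_end[i].astype(object),
                    end_reason=str(self.end_reason[i]),
                    state_history=history,
                )
            )
        return out


def as_cohort(data) -> Cohort:
    """Accept either a Cohort or a list of IndividualRecords."""
    if isinstance(data, Cohort):
        return data
    return Cohort.from_records(list(data))
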