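"""Individual trajectory records and monthly-panel I/O.

The canonical on-disk format is a person-month panel CSV with columns

    person_id, population, sex, birth_date, obs_start, obs_end,
    end_reason, month, state

where ``month`` is the 0-based calendar-month offset from ``obs_start`` and
``state`` is an integer code (0 = no care, 1 = home care, 2 = care home).
Death is conveyed by ``end_reason`` and ``obs_end``, not by a state row.
All dates are ISO-8601.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, timedelta

import pandas as pd

from .states import EndReason, State, TRANSIENT_CODES

DAYS_PER_YEAR = 365.25

PANEL_COLUMNS = [
    "person_id",
    "population",
    "sex",
    "birth_date",
    "obs_start",
    "obs_end",
    "end_reason",
    "month",
    "state",
]


class PanelFormatError(ValueError):
    """Raised when a panel file violates the documented schema."""


def age_at(birth_date: date, when: date) -> float:
    """Continuous age in years at ``when`` (elapsed days / 365.25)."""
    return (when - birth_date).days / DAYS_PER_YEAR


def add_months(d: date, k: int) -> date:
    """Shift a date by ``k`` calendar months, clipping the day if needed."""
    y, m = divmod(d.year * 12 + (d.month - 1) + k, 12)
    day = min(d.day, _days_in_month(y, m + 1))
    return date(y, m + 1, day)


def _days_in_month(year: int, month: int) -> int:
    nxt = date(year + (month == 12), month % 12 + 1, 1)
    return (nxt - date(year, month, 1)).days


def month_index(start: date, when: date) -> int:
    """Calendar-month offset of the month containing ``when`` from ``start``'s month."""
    return (when.year - start.year) * 12 + (when.month - start.month)


@dataclass
class IndividualRecord:
    """One person's observed trajectory through the care states.

    ``state_history`` holds ordered ``(date, state)`` pairs; each entry is in
    force from its date until the next entry (or ``obs_end``).  For records
    read from a monthly panel there is one entry per observed month, dated at
    the month covered by the panel row.
    """

    person_id: str
    population: str
    sex: str
    birth_date: date
    obs_start: date
    obs_end: date
    end_reason: str
    state_history: list[tuple[date, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end_reason not in EndReason.ALL:
            raise ValueError(f"unknown end_reason {self.end_reason!r}")
        dates = [d for d, _ in self.state_history]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"{self.person_id}: state-history dates not strictly increasing")
        for d, s in self.state_history:
            if int(s) not in TRANSIENT_CODES:
                raise ValueError(f"{self.person_id}: state code {s} is not a transient state")
            if d < self.obs_start or d > self.obs_end:
                raise ValueError(
                    f"{self.person_id}: state date {d} outside observation "
                    f"[{self.obs_start}, {self.obs_end}]"
                )

    @property
    def died(self) -> bool:
        return self.end_reason == EndReason.DEATH

    def age_at_start(self) -> float:
        return age_at(self.birth_date, self.obs_start)

    def age_at_end(self) -> float:
        return age_at(self.birth_date, self.obs_end)

    def state_at(self, when: date) -> int | None:
        """State in force at ``when``; None if before the first entry."""
        current: int | None = None
        for d, s in self.state_history:
            if d <= when:
                current = int(s)
            else:
                break
        return current


def baseline_state(record: IndividualRecord, baseline_date: date) -> int | None:
    """Care state in the calendar month immediately preceding the baseline month.

    The reference month is the month before ``baseline_date``'s month.  If the
    person occupies several states during that month, the highest care level
    wins.  Returns ``None`` when the person is not under observation at any
    point of the reference month (excluded from baseline, not an error), and
    ``NO_CARE`` when observed but without any formal-care episode covering the
    month.
    """
    ref_start = add_months(date(baseline_date.year, baseline_date.month, 1), -1)
    ref_end = date(baseline_date.year, baseline_date.month, 1) - timedelta(days=1)
    if record.obs_start > ref_end or record.obs_end < ref_start:
        return None
    states: list[int] = []
    entry_at_start = record.state_at(ref_start)
    if entry_at_start is not None:
        states.append(entry_at_start)
    for d, s in record.state_history:
        if ref_start < d <= ref_end:
            states.append(int(s))
    if not states:
        return int(State.NO_CARE)
    return max(states)


def person_years(
    record: IndividualRecord, baseline_date: date, follow_up_years: float
) -> float:
    """Years at risk from baseline to death, censoring, or end of follow-up.

    Records not at risk at baseline (observation starts after, or ends on or
    before, the baseline date) contribute 0.
    """
    if record.obs_start > baseline_date or record.obs_end <= baseline_date:
        return 0.0
    window_days = follow_up_years * DAYS_PER_YEAR
    observed_days = (record.obs_end - baseline_date).days
    return min(observed_days, window_days) / DAYS_PER_YEAR


def follow_up_end(baseline_date: date, follow_up_years: float) -> date:
    """Administrative end of follow-up (whole months when possible)."""
    months = 12 * follow_up_years
    if abs(months - round(months)) < 1e-9:
        return add_months(baseline_date, int(round(months)))
    return baseline_date + timedelta(days=round(follow_up_years * DAYS_PER_YEAR))


def died_within(
    record: IndividualRecord, baseline_date: date, follow_up_years: float
) -> bool:
    """True if the record's death falls inside the follow-up window."""
    if not record.died or record.obs_end <= baseline_date:
        return False
    return (record.obs_end - baseline_date).days <= follow_up_years * DAYS_PER_YEAR


def read_panel(path) -> list[IndividualRecord]:
    """Read a person-month panel CSV into IndividualRecords.

    Rows are validated; schema violations raise :class:`PanelFormatError`
    naming the offending line number (header is line 1).
    """
    df = pd.read_csv(path, dtype={"person_id": str, "state": "Int64", "month": "Int64"})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"panel file missing columns: {missing}")
    if df.empty:
        return []
    df["_line"] = df.index + 2

    bad_state = ~df["state"].isin(sorted(TRANSIENT_CODES))
    if bad_state.any():
        row = df[bad_state].iloc[0]
        raise PanelFormatError(
            f"line {row['_line']}: unknown state code {row['state']!r}"
        )
    dup = df.duplicated(subset=["person_id", "month"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise PanelFormatError(
            f"line {row['_line']}: duplicate (person_id, month) = "
            f"({row['person_id']!r}, {row['month']})"
        )

    records: list[IndividualRecord] = []
    for pid, grp in df.groupby("person_id", sort=True):
        grp = grp.sort_values("month")
        for col in ("population", "sex", "birth_date", "obs_start", "obs_end", "end_reason"):
            if grp[col].nunique() != 1:
                line = int(grp["_line"].iloc[0])
                raise PanelFormatError(
                    f"line {line}: person {pid!r} has inconsistent {col!r} across rows"
                )
        months = grp["month"].to_numpy()
        if months[0] != 0 or (months[1:] - months[:-1] != 1).any():
            line = int(grp["_line"].iloc[0])
            raise PanelFormatError(
                f"line {line}: person {pid!r} months are not contiguous from 0"
            )
        first = grp.iloc[0]
        obs_start = date.fromisoformat(first["obs_start"])
        history = [
            (add_months(obs_start, int(m)), int(s))
            for m, s in zip(grp["month"], grp["state"])
        ]
        records.append(
            IndividualRecord(
                person_id=str(pid),
                population=str(first["population"]),
                sex=str(first["sex"]),
                birth_date=date.fromisoformat(first["birth_date"]),
                obs_start=obs_start,
                obs_end=date.fromisoformat(first["obs_end"]),
                end_reason=str(first["end_reason"]),
                state_history=history,
            )
        )
    return records


def write_panel(records, path) -> None:
    """Write records as a person-month panel CSV in canonical order.

    Canonical order is (person_id, month); dates ISO-8601.  Round-trips
    bit-identically with :func:`read_panel` for panels in canonical form.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PANEL_COLUMNS)
        for rec in sorted(records, key=lambda r: r.person_id):
            for m, (_, s) in enumerate(rec.state_history):
                writer.writerow(
                    [
                        rec.person_id,
                        rec.population,
                        rec.sex,
                        rec.birth_date.isoformat(),
                        rec.obs_start.isoformat(),
                        rec.obs_end.isoformat(),
                        rec.end_reason,
                        m,
                        int(s),
                    ]
                )
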