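"""State space for the long-term-care multistate model.

Three transient care states and one absorbing state (death).  The integer
codes are fixed and used as matrix indices throughout the package; DEAD is
always the last index and is absorbing.
"""

from __future__ import annotations

from enum import IntEnum


class State(IntEnum):
    """Care state occupied by an individual at a point in time."""

    NO_CARE = 0
    HOME_CARE = 1
    CARE_HOME = 2
    DEAD = 3


#: Transient (leavable) states, in matrix index order.
TRANSIENT_STATES: tuple[State, ...] = (State.NO_CARE, State.HOME_CARE, State.CARE_HOME)

#: Number of states including the absorbing one.
N_STATES: int = 4

#: Human-readable labels keyed by integer code (panel-file legend).
STATE_LABELS: dict[int, str] = {
    int(State.NO_CARE): "no_care",
    int(State.HOME_CARE): "home_care",
    int(State.CARE_HOME): "care_home",
    int(State.DEAD): "dead",
}

#: Valid codes for a transient state in a panel file.
TRANSIENT_CODES: frozenset[int] = frozenset(int(s) for s in TRANSIENT_STATES)


class EndReason:
    """Why an individual's observation ended."""

    DEATH = "death"
    CENSORED = "censored"
    ADMIN = "admin"

    ALL = (DEATH, CENSORED, ADMIN)
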