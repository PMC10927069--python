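"""The seven-state labor market affiliation state space.

Four recurrent states (work, sickness absence, unemployment, temporary out)
and three absorbing states (retirement, disability pension, death).  Every
recurrent state may transition to each of the six other states, giving the
24 permitted arrows of the multi-state model; absorbing states have no
outgoing arrows.
"""

from __future__ import annotations

WORK = "work"
SICKNESS = "sickness_absence"
UNEMPLOYMENT = "unemployment"
TEMPORARY_OUT = "temporary_out"
RETIREMENT = "retirement"
DISABILITY = "disability_pension"
DEATH = "death"

RECURRENT_STATES: tuple[str, ...] = (WORK, SICKNESS, UNEMPLOYMENT, TEMPORARY_OUT)
ABSORBING_STATES: tuple[str, ...] = (RETIREMENT, DISABILITY, DEATH)
STATES: tuple[str, ...] = RECURRENT_STATES + ABSORBING_STATES

STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)

#: The 24 permitted transitions: each recurrent state to each other state.
PERMITTED_TRANSITIONS: tuple[tuple[str, str], ...] = tuple(
    (h, j) for h in RECURRENT_STATES for j in STATES if j != h
)

#: Priority when simultaneous records compete for a day.  Absorbing states
#: always dominate recurrent ones; among absorbing states death dominates.
ABSORBING_PRIORITY: tuple[str, ...] = (DEATH, DISABILITY, RETIREMENT)

SEXES: tuple[str, ...] = ("M", "F")
AGE_GROUPS: tuple[str, ...] = ("18-34", "35-49", "50-64")
STRATA: tuple[str, ...] = tuple(f"{s}:{a}" for s in SEXES for a in AGE_GROUPS)

EXPOSURE_LEVELS: tuple[int, ...] = (0, 1, 2, 3)


def is_recurrent(state: str) -> bool:
    return state in RECURRENT_STATES


def is_absorbing(state: str) -> bool:
    return state in ABSORBING_STATES


def validate_state(state: str) -> str:
    if state not in STATE_INDEX:
        raise ValueError(f"unknown labor market state: {state!r}")
    return state
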