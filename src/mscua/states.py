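"""Health-state space of the cohort model.

The disease course is described by four mutually exclusive and exhaustive
health states -- controlled RRMS (the entry state), RRMS relapse, RRMS
remission and all-cause death.  Because patients who relapse on
teriflunomide may switch to a second-line DMT from the second cycle
onwards, the live states are expanded by treatment arm; death is a single
absorbing compartment.  The resulting six-compartment expanded space, in
fixed index order, is::

    0  (CONTROLLED, TERIFLUNOMIDE)
    1  (RELAPSE,    TERIFLUNOMIDE)
    2  (REMISSION,  TERIFLUNOMIDE)
    3  (RELAPSE,    SWITCHED_DMT)
    4  (REMISSION,  SWITCHED_DMT)
    5  DEAD

(CONTROLLED, SWITCHED_DMT) does not exist: controlled RRMS is entry-only
and switching happens out of relapse.
"""

from __future__ import annotations

import enum


class HealthState(str, enum.Enum):
    CONTROLLED = "CONTROLLED"
    RELAPSE = "RELAPSE"
    REMISSION = "REMISSION"
    DEAD = "DEAD"


class Arm(str, enum.Enum):
    TERIFLUNOMIDE = "TERIFLUNOMIDE"
    SWITCHED_DMT = "SWITCHED_DMT"


# Fixed compartment indices for the expanded state space.
CONTROLLED_TERI = 0
RELAPSE_TERI = 1
REMISSION_TERI = 2
RELAPSE_SWITCHED = 3
REMISSION_SWITCHED = 4
DEAD = 5

N_STATES = 6
LIVE_STATES = (CONTROLLED_TERI, RELAPSE_TERI, REMISSION_TERI,
               RELAPSE_SWITCHED, REMISSION_SWITCHED)
TERI_ARM_STATES = (CONTROLLED_TERI, RELAPSE_TERI, REMISSION_TERI)
SWITCHED_ARM_STATES = (RELAPSE_SWITCHED, REMISSION_SWITCHED)

#: (health, arm) of each compartment; DEAD has arm None.
EXPANDED_STATES = (
    (HealthState.CONTROLLED, Arm.TERIFLUNOMIDE),
    (HealthState.RELAPSE, Arm.TERIFLUNOMIDE),
    (HealthState.REMISSION, Arm.TERIFLUNOMIDE),
    (HealthState.RELAPSE, Arm.SWITCHED_DMT),
    (HealthState.REMISSION, Arm.SWITCHED_DMT),
    (HealthState.DEAD, None),
)

STATE_LABELS = (
    "CONTROLLED_TERI",
    "RELAPSE_TERI",
    "REMISSION_TERI",
    "RELAPSE_SWITCHED",
    "REMISSION_SWITCHED",
    "DEAD",
)


def health_of(index: int) -> HealthState:
    return EXPANDED_STATES[index][0]


def arm_of(index: int) -> Arm | None:
    return EXPANDED_STATES[index][1]


def states_of_health(health: HealthState) -> tuple[int, ...]:
    return tuple(i for i in range(N_STATES) if EXPANDED_STATES[i][0] == health)
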