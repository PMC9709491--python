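"""Shared vocabulary: health states and treatment strategies.

The disease course is a discrete-time state machine over 6-month cycles.
Early-stage disease is either *progressive* (flexion deformity follows a
stochastic drift) or *quiescent* (no change in flexion deformity until
quiescence ends).  Crossing the late-stage threshold (>30 deg by default) is
permanent and opens the surgical pathway: up to three percutaneous needle
fasciotomies (PNF), at most one limited fasciectomy and at most one
dermofasciectomy.  Death is absorbing and may occur from any state.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum


class State(IntEnum):
    EARLY_PROGRESSIVE = 0
    EARLY_QUIESCENT = 1
    LATE_UNTREATED = 2
    LATE_POST_PNF_SUCCESS = 3
    LATE_POST_PNF_FAILED = 4
    LATE_POST_FASCIECTOMY = 5
    LATE_POST_DERMOFASCIECTOMY = 6
    DEAD = 7


EARLY_STATES = frozenset({State.EARLY_PROGRESSIVE, State.EARLY_QUIESCENT})
LATE_STATES = frozenset(
    {
        State.LATE_UNTREATED,
        State.LATE_POST_PNF_SUCCESS,
        State.LATE_POST_PNF_FAILED,
        State.LATE_POST_FASCIECTOMY,
        State.LATE_POST_DERMOFASCIECTOMY,
    }
)

#: post-surgical states from which relapse returns the patient to LATE_UNTREATED
POST_SUCCESS_STATES = frozenset(
    {
        State.LATE_POST_PNF_SUCCESS,
        State.LATE_POST_FASCIECTOMY,
        State.LATE_POST_DERMOFASCIECTOMY,
    }
)

#: late states in which a patient may elect (further) surgery
SURGERY_ELIGIBLE_STATES = frozenset({State.LATE_UNTREATED, State.LATE_POST_PNF_FAILED})


@dataclass(frozen=True)
class StrategySpec:
    """A named treatment strategy for early-stage disease.

    ``initial_course``: one course (four intranodular adalimumab doses) is
    given during the trial period.  ``retreat_on_reactivation``: patients who
    were quiescent after the initial course receive a further course each
    time the nodule reactivates, maintaining quiescence indefinitely.
    """

    name: str
    initial_course: bool
    retreat_on_reactivation: bool

    def __post_init__(self) -> None:
        if self.retreat_on_reactivation and not self.initial_course:
            raise ValueError("retreatment requires an initial course")


STANDARD_CARE = StrategySpec("standard_care", initial_course=False, retreat_on_reactivation=False)
ADALIMUMAB_ONCE = StrategySpec("adalimumab_once", initial_course=True, retreat_on_reactivation=False)
ADALIMUMAB_REPEAT = StrategySpec("adalimumab_repeat", initial_course=True, retreat_on_reactivation=True)

DEFAULT_STRATEGIES = (STANDARD_CARE, ADALIMUMAB_ONCE, ADALIMUMAB_REPEAT)

_BY_NAME = {s.name: s for s in DEFAULT_STRATEGIES}


def strategy_by_name(name: str) -> StrategySpec:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown strategy {name!r}; expected one of {sorted(_BY_NAME)}") from None
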