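"""Win-stay/lose-shift learning agent and the alternating allocation schedule.

The agent keeps four memory slots: the score of its latest hunt and, for each
of the three arrowhead attributes, a direction sign (+1/-1) in which that
attribute is to be modified next.  Exploration picks one attribute uniformly
at random and moves it L (=5) units in the memorised direction, clipped to
[1, 100].  Exploitation hunts with the current design; if the observed score
is strictly lower than the previous hunt's, the direction of the attribute
modified in the latest exploration is reversed (lose-shift), otherwise all
directions are kept (win-stay).  Comparisons always use the noisy displayed
scores -- the agent never sees the underlying efficiency.

The allocation strategies considered are the alternating family: trial 1 is
always exploitation, explorations occupy even trials 2, 4, ..., 2*tau, and
all remaining trials are exploitation (0 <= 2*tau <= T-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .landscape import ATTRIBUTES, ATTR_MAX, ATTR_MIN, ArrowheadDesign, FitnessLandscape, hunt

__all__ = [
    "AgentState",
    "AllocationSchedule",
    "DEFAULT_STEP",
    "schedule_actions",
    "explore_step",
    "exploit_step",
]

#: modification step per exploration, in attribute units (median modification
#: level observed in earlier virtual-arrowhead experiments)
DEFAULT_STEP = 5

EXPLORE, EXPLOIT = "explore", "exploit"


@dataclass
class AgentState:
    """Four memory slots: latest hunt score, three direction signs.

    ``last_modified`` tracks which attribute the latest exploration touched so
    that a subsequent losing hunt knows which direction to reverse; it is None
    before the first exploration.
    """

    directions: dict[str, int]
    last_score: Optional[int] = None
    last_modified: Optional[str] = None

    def __post_init__(self) -> None:
        if set(self.directions) != set(ATTRIBUTES):
            raise ValueError(f"directions must cover exactly {ATTRIBUTES}")
        for a, d in self.directions.items():
            if d not in (-1, 1):
                raise ValueError(f"direction for {a} must be +1 or -1, got {d}")

    @classmethod
    def with_random_directions(cls, rng: np.random.Generator) -> "AgentState":
        """Fresh memory with independent uniform +/-1 initial directions."""
        dirs = {a: int(1 - 2 * rng.integers(0, 2)) for a in ATTRIBUTES}
        return cls(directions=dirs)

    def to_json(self) -> dict:
        return {
            "last_score": self.last_score,
            "directions": dict(self.directions),
            "last_modified": self.last_modified,
        }


@dataclass(frozen=True)
class AllocationSchedule:
    """Alternating schedule with ``tau`` explorations over ``T`` trials."""

    tau: int
    T: int = 50

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if not 0 <= 2 * self.tau <= self.T - 1:
            raise ValueError(
                f"tau = {self.tau} violates 0 <= 2*tau <= T-1 with T = {self.T}"
            )

    @property
    def tau_max(self) -> int:
        return (self.T - 1) // 2


def schedule_actions(schedule: AllocationSchedule) -> list[str]:
    """Action per trial (1-based): explore exactly at trials 2, 4, ..., 2*tau."""
    actions = [EXPLOIT] * schedule.T
    for trial in range(2, 2 * schedule.tau + 1, 2):
        actions[trial - 1] = EXPLORE
    return actions


def explore_step(
    state: AgentState,
    design: ArrowheadDesign,
    rng: np.random.Generator,
    L: int = DEFAULT_STEP,
) -> tuple[ArrowheadDesign, AgentState]:
    """One exploration: move a uniformly chosen attribute L units along its sign.

    The move is clipped to the attribute bounds [1, 100]; a clipped move still
    registers as the latest modification (only a losing hunt reverses the
    direction, there is no automatic bounce at the walls).
    """
    attr = ATTRIBUTES[int(rng.integers(0, len(ATTRIBUTES)))]
    value = design.value(attr) + state.directions[attr] * L
    value = min(ATTR_MAX, max(ATTR_MIN, value))
    state.last_modified = attr
    return design.with_value(attr, value), state


def exploit_step(
    state: AgentState,
    design: ArrowheadDesign,
    landscape: FitnessLandscape,
    rng: np.random.Generator,
) -> tuple[int, AgentState]:
    """One hunt with the current design, followed by the win-stay/lose-shift update.

    The direction of the attribute touched by the latest exploration is
    reversed only when the observed score is strictly below the previous
    hunt's score (ties are wins).  The very first hunt just initialises the
    score memory.
    """
    score = hunt(landscape, design, rng)
    if (
        state.last_score is not None
        and state.last_modified is not None
        and score < state.last_score
    ):
        state.directions[state.last_modified] *= -1
    state.last_score = score
    return score, state
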