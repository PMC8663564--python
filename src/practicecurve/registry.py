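"""Metadata for the six active smartphone tests.

Each test produces one primary metric per administration.  Dexterity tests
alternate hands, so their analysis unit is participant x hand; cognition and
mobility tests are analysed per participant.  The app constrains how often a
test can be repeated, which gives each test a minimum intertest interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Direction(str, Enum):
    """Whether larger metric values mean better performance."""

    HIGHER_BETTER = "higher_better"
    LOWER_BETTER = "lower_better"


class Grouping(str, Enum):
    """Level at which repeated administrations form one series."""

    PARTICIPANT = "participant"
    HAND = "hand"


@dataclass(frozen=True)
class TestSpec:
    """Static description of one smartphone test.

    Attributes
    ----------
    name
        Canonical test name.
    metric_units
        Units of the primary metric.
    direction
        Whether higher values are better.  Sway path (Static Balance) is the
        only metric where lower is better.
    grouping
        ``participant`` or ``hand``; hand-grouped tests produce one analysis
        unit per participant x hand.
    min_interval_days
        App-enforced minimum number of days between consecutive
        administrations (per hand for hand-grouped tests).
    """

    name: str
    metric_units: str
    direction: Direction
    grouping: Grouping
    min_interval_days: float

    @property
    def hand_grouped(self) -> bool:
        return self.grouping is Grouping.HAND


E_SDMT = TestSpec("e-SDMT", "correct responses", Direction.HIGHER_BETTER,
                  Grouping.PARTICIPANT, 7.0)
FINGER_PINCHING = TestSpec("FingerPinching", "successful pinches",
                           Direction.HIGHER_BETTER, Grouping.HAND, 2.0)
DRAW_A_SHAPE = TestSpec("DrawAShape", "shapes drawn correctly",
                        Direction.HIGHER_BETTER, Grouping.HAND, 2.0)
TWO_MINUTE_WALK = TestSpec("TwoMinuteWalk", "steps", Direction.HIGHER_BETTER,
                           Grouping.PARTICIPANT, 1.0)
U_TURN = TestSpec("UTurn", "rad/s", Direction.HIGHER_BETTER,
                  Grouping.PARTICIPANT, 1.0)
STATIC_BALANCE = TestSpec("StaticBalance", "m/s^2", Direction.LOWER_BETTER,
                          Grouping.PARTICIPANT, 1.0)

TEST_SPECS: dict[str, TestSpec] = {
    spec.name: spec
    for spec in (E_SDMT, FINGER_PINCHING, DRAW_A_SHAPE, TWO_MINUTE_WALK,
                 U_TURN, STATIC_BALANCE)
}


def get_test_spec(name: str) -> TestSpec:
    """Look up a :class:`TestSpec` by canonical name.

    Raises ``KeyError`` with the list of known tests for unknown names.
    """
    try:
        return TEST_SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown test {name!r}; known tests: {sorted(TEST_SPECS)}"
        ) from None
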