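"""Terminal result of one bargaining triad."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .events import EventRow
from .game import Coalition


class Status(str, enum.Enum):
    FORMED = "FORMED"
    NO_AGREEMENT = "NO_AGREEMENT"
    ABORTED = "ABORTED"

    def __str__(self) -> str:  # plain value in CSV / logs
        return self.value


@dataclass(frozen=True)
class AssignmentRecord:
    """How the roster's agents were seated into bargainer positions.

    ``seat_of_agent[i]`` is the position index assigned to roster agent
    ``i``; ``efforts[i]`` is that agent's effort score (drawn or
    configured), used for ranking in EARNED mode.
    """

    mode: str  # "RANDOM" | "EARNED"
    seat_of_agent: tuple[int, ...]
    efforts: tuple[float, ...]

    @property
    def agent_at(self) -> dict[int, int]:
        """Inverse map: position -> roster agent index."""
        return {seat: i for i, seat in enumerate(self.seat_of_agent)}


@dataclass
class Outcome:
    """What happened to one triad.

    ``allocation`` and ``coalition`` are set only for FORMED outcomes;
    ``bonuses`` maps every position to its real-currency bonus (0 for
    excluded bargainers and non-FORMED statuses).
    """

    triad_id: int
    status: Status
    coalition: Coalition | None
    allocation: dict[int, int] | None
    rounds_used: int
    bonuses: dict[int, float]
    events: list[EventRow] = field(default_factory=list)
    assignment: AssignmentRecord | None = None
    abort_reason: str = ""
    events_ref: str = ""

    def record(self) -> tuple:
        """The CSV-visible identity of this outcome (everything but the
        in-memory event list)."""
        return (
            self.triad_id,
            self.status,
            self.coalition.label if self.coalition else "",
            tuple(sorted(self.allocation.items())) if self.allocation else None,
            self.rounds_used,
            tuple(sorted(self.bonuses.items())),
            self.assignment,
            self.abort_reason,
            self.events_ref,
        )
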