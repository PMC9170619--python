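"""Batch session runner.

Builds triads from an agent roster, seats agents into bargainer
positions (randomly or ranked by effort), runs each triad under the
chosen protocol with deterministic per-triad seed-sequence spawning, and
round-trips outcome tables through a versioned CSV schema.
"""

from __future__ import annotations

import csv
import enum
import io
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .altoffers import run_alt_offers_game
from .agents import AgentStrategy, make_agent
from .game import Coalition, GameConfig, GameError, position_label
from .onestep import run_one_step_game
from .outcome import AssignmentRecord, Outcome, Status

SCHEMA_HEADER = "# coalsim-outcomes v1"


class Protocol(str, enum.Enum):
    ONE_STEP = "one_step"
    ALT_OFFERS = "alt_offers"


class ResourceMode(str, enum.Enum):
    RANDOM = "RANDOM"
    EARNED = "EARNED"


class OutcomesFormatError(GameError):
    """An outcomes CSV file could not be parsed."""


@dataclass(frozen=True)
class AgentSpec:
    """Roster entry: a strategy name plus its constructor parameters
    (e.g. ``timeout_prob``, or a fixed ``effort`` score)."""

    strategy: str
    params: dict[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class SessionConfig:
    game: GameConfig
    protocol: Protocol
    n_triads: int
    roster: tuple[AgentSpec, AgentSpec, AgentSpec]
    resource_mode: ResourceMode = ResourceMode.RANDOM
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_triads < 1:
            raise GameError("n_triads must be >= 1")
        if len(self.roster) != 3:
            raise GameError("roster must yield exactly 3 agents per triad")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise GameError("dropout_prob must be in [0, 1]")


# ---------------------------------------------------------------------------
# Seating


def assign_resources(
    mode: ResourceMode,
    agents: Sequence[AgentStrategy],
    game: GameConfig,
    rng: np.random.Generator,
) -> AssignmentRecord:
    """Seat agents into positions and record how.

    RANDOM: a uniformly random bijection of agents onto positions.
    EARNED: agents ranked by effort score descending take positions in
    descending-resource order; effort ties are broken uniformly at random.
    """
    n = game.n_positions
    if len(agents) != n:
        raise GameError(f"need exactly {n} agents, got {len(agents)}")
    mode = ResourceMode(mode)
    if mode is ResourceMode.RANDOM:
        seats = [int(s) for s in rng.permutation(n)]
    else:
        # random pre-shuffle makes the stable sort break ties uniformly
        order = [int(i) for i in rng.permutation(n)]
        order.sort(key=lambda i: -agents[i].effort)
        positions_by_resource = sorted(range(n), key=lambda p: (-game.resources[p], p))
        seats = [0] * n
        for rank, agent_idx in enumerate(order):
            seats[agent_idx] = positions_by_resource[rank]
    for agent, seat in zip(agents, seats):
        agent.position = seat
    return AssignmentRecord(
        mode=mode.value,
        seat_of_agent=tuple(seats),
        efforts=tuple(a.effort for a in agents),
    )


# ---------------------------------------------------------------------------
# Session loop


_RUNNERS = {
    Protocol.ONE_STEP: run_one_step_game,
    Protocol.ALT_OFFERS: run_alt_offers_game,
}


def run_session(
    session: SessionConfig,
    progress=None,
) -> tuple[list[Outcome], dict[str, Any]]:
    """Run ``n_triads`` independent triads and summarize the results.

    Per-triad randomness comes from children of a single seed sequence,
    so (config, seed) fully determines every outcome and event row.
    ``progress``, if given, is called with each triad id as it finishes.
    Errors raised inside one triad abort only that triad (status ABORTED
    with the error as reason).
    """
    root = np.random.SeedSequence(session.seed)
    runner = _RUNNERS[Protocol(session.protocol)]
    outcomes: list[Outcome] = []
    for triad_id, child in enumerate(root.spawn(session.n_triads)):
        streams = child.spawn(5)
        agents = [
            make_agent(
                spec.strategy,
                np.random.Generator(np.random.PCG64(stream)),
                **spec.params,
            )
            for spec, stream in zip(session.roster, streams[:3])
        ]
        seat_rng = np.random.Generator(np.random.PCG64(streams[3]))
        game_rng = np.random.Generator(np.random.PCG64(streams[4]))
        for agent, spec in zip(agents, session.roster):
            if "effort" not in spec.params:
                agent.effort = float(seat_rng.standard_normal())
        assignment = assign_resources(
            session.resource_mode, agents, session.game, seat_rng
        )
        try:
            outcome = runner(
                session.game,
                agents,
                game_rng,
                triad_id=triad_id,
                dropout_prob=session.dropout_prob,
            )
        except GameError as exc:
            outcome = Outcome(
                triad_id=triad_id,
                status=Status.ABORTED,
                coalition=None,
                allocation=None,
                rounds_used=0,
                bonuses={p: 0.0 for p in session.game.positions},
                abort_reason=f"error:{exc}",
            )
        outcome.assignment = assignment
        outcomes.append(outcome)
        if progress is not None:
            progress(triad_id)
    return outcomes, summarize_session(session, outcomes)


def summarize_session(
    session: SessionConfig, outcomes: Sequence[Outcome]
) -> dict[str, Any]:
    status_counts = Counter(o.status.value for o in outcomes)
    coalition_counts = Counter(
        o.coalition.label for o in outcomes if o.status is Status.FORMED
    )
    return {
        "n_triads": len(outcomes),
        "protocol": Protocol(session.protocol).value,
        "game": session.game.notation(),
        "status_counts": dict(sorted(status_counts.items())),
        "coalition_counts": dict(sorted(coalition_counts.items())),
    }


# ---------------------------------------------------------------------------
# Outcome CSV round-trip


def _columns(n_positions: int) -> list[str]:
    labels = [position_label(p) for p in range(n_positions)]
    return (
        ["triad_id", "status", "coalition"]
        + [f"share_{x}" for x in labels]
        + ["rounds_used"]
        + [f"bonus_{x}" for x in labels]
        + ["abort_reason", "assign_mode", "seats", "efforts", "events_ref"]
    )


def write_outcomes(outcomes: Sequence[Outcome], path) -> None:
    """Write the versioned outcomes CSV (allocation as per-position
    columns; assignment seats/efforts pipe-joined)."""
    with open(path, "w", newline="") as fh:
        _write_outcomes_to(fh, outcomes)


def outcomes_csv_text(outcomes: Sequence[Outcome]) -> str:
    """The outcomes CSV as a string (used for byte-identity checks)."""
    buf = io.StringIO(newline="")
    _write_outcomes_to(buf, outcomes)
    return buf.getvalue()


def _write_outcomes_to(fh, outcomes: Sequence[Outcome]) -> None:
    n = max((len(o.bonuses) for o in outcomes), default=3)
    fh.write(SCHEMA_HEADER + "\n")
    writer = csv.writer(fh)
    writer.writerow(_columns(n))
    for o in outcomes:
        alloc = o.allocation or {}
        row = [o.triad_id, o.status.value, o.coalition.label if o.coalition else ""]
        row += ["" if p not in alloc else alloc[p] for p in range(n)]
        row.append(o.rounds_used)
        row += [repr(o.bonuses.get(p, 0.0)) for p in range(n)]
        row.append(o.abort_reason)
        if o.assignment is not None:
            row += [
                o.assignment.mode,
                "|".join(map(str, o.assignment.seat_of_agent)),
                "|".join(repr(e) for e in o.assignment.efforts),
            ]
        else:
            row += ["", "", ""]
        row.append(o.events_ref)
        writer.writerow(row)


def read_outcomes(path) -> list[Outcome]:
    """Parse a file written by :func:`write_outcomes`; raises
    :class:`OutcomesFormatError` with a line number on malformed input."""
    with open(path, newline="") as fh:
        first = fh.readline().rstrip("\n")
        if first != SCHEMA_HEADER:
            raise OutcomesFormatError(
                f"line 1: expected schema header {SCHEMA_HEADER!r}, got {first!r}"
            )
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise OutcomesFormatError("line 2: missing column header") from None
        share_cols = [c for c in header if c.startswith("share_")]
        n = len(share_cols)
        if n < 3 or header != _columns(n):
            raise OutcomesFormatError("line 2: unexpected column header")
        outcomes = []
        for lineno, row in enumerate(reader, start=3):
            if len(row) != len(header):
                raise OutcomesFormatError(
                    f"line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rec = dict(zip(header, row))
            try:
                status = Status(rec["status"])
                coalition = (
                    Coalition.from_label(rec["coalition"]) if rec["coalition"] else None
                )
                allocation = None
                if coalition is not None:
                    allocation = {
                        p: int(rec[f"share_{position_label(p)}"])
                        for p in range(n)
                        if rec[f"share_{position_label(p)}"] != ""
                    }
                bonuses = {
                    p: float(rec[f"bonus_{position_label(p)}"]) for p in range(n)
                }
                assignment = None
                if rec["assign_mode"]:
                    assignment = AssignmentRecord(
                        mode=rec["assign_mode"],
                        seat_of_agent=tuple(
                            int(s) for s in rec["seats"].split("|")
                        ),
                        efforts=tuple(
                            float(e) for e in rec["efforts"].split("|")
                        ),
                    )
                outcomes.append(
                    Outcome(
                        triad_id=int(rec["triad_id"]),
                        status=status,
                        coalition=coalition,
                        allocation=allocation,
                        rounds_used=int(rec["rounds_used"]),
                        bonuses=bonuses,
                        assignment=assignment,
                        abort_reason=rec["abort_reason"],
                        events_ref=rec["events_ref"],
                    )
                )
            except (ValueError, KeyError, GameError) as exc:
                raise OutcomesFormatError(f"line {lineno}: {exc}") from exc
    return outcomes
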