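"""One-step display protocol.

Each round has three phases.  Phase I: every bargainer simultaneously
makes a mandatory, validated coalition offer.  Phase II: all offers are
displayed (identical offers collapsed into one entry listing all of its
proposers) and every bargainer selects one entry that includes itself —
or, when enabled, no entry at all.  Phase III: an entry selected by every
member of its coalition forms immediately and the game ends; otherwise a
new round starts, up to the configured round limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .agents import (
    ACT,
    NO_COALITION,
    AgentStrategy,
    ProposeView,
    SelectView,
)
from .events import EventRow, format_allocation
from .game import (
    Coalition,
    GameConfig,
    GameError,
    Offer,
    position_label,
    validate_offer,
)
from .outcome import Outcome, Status


class ProtocolError(GameError):
    """A protocol-level rule was violated."""


class DuplicateProposerError(ProtocolError):
    pass


class MissingProposerError(ProtocolError):
    pass


class SelectionError(ProtocolError):
    """An invalid Phase-II selection (non-member entry, unknown entry, or
    NO_COALITION while that option is disabled)."""


# ---------------------------------------------------------------------------
# Board


@dataclass(frozen=True)
class BoardEntry:
    """One distinct offer content on the Phase-II display.

    Identical (coalition, allocation) offers from several bargainers are
    shown once, with every proposer listed.
    """

    coalition: Coalition
    shares: tuple[tuple[int, int], ...]
    proposers: tuple[int, ...]

    @property
    def allocation(self) -> dict[int, int]:
        return dict(self.shares)

    def share_of(self, position: int) -> int:
        return self.allocation[position]

    def describe(self) -> str:
        return f"{self.coalition.label}({format_allocation(self.shares)})"


@dataclass(frozen=True)
class DisplayBoard:
    entries: tuple[BoardEntry, ...]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Selection:
    """One bargainer's Phase-II choice: a board entry or NO_COALITION."""

    selector: int
    choice: object  # BoardEntry | NO_COALITION


@dataclass(frozen=True)
class RoundResult:
    round_number: int
    board: DisplayBoard
    selections: tuple[Selection, ...]
    formed: tuple[Coalition, dict[int, int]] | None


def build_board(offers: Sequence[Offer], n_positions: int | None = None) -> DisplayBoard:
    """Deduplicate the Phase-I offers into display entries.

    Requires exactly one offer per bargainer.  Entry order is
    deterministic: by coalition members, then by allocation (higher shares
    first), so replayed games produce identical boards.
    """
    n = n_positions if n_positions is not None else len(offers)
    seen: set[int] = set()
    for offer in offers:
        if offer.proposer in seen:
            raise DuplicateProposerError(
                f"two offers from {position_label(offer.proposer)}"
            )
        seen.add(offer.proposer)
    missing = set(range(n)) - seen
    if missing:
        raise MissingProposerError(
            "no offer from " + ", ".join(position_label(p) for p in sorted(missing))
        )

    grouped: dict[tuple, list[int]] = {}
    for offer in offers:
        grouped.setdefault((offer.coalition, offer.shares), []).append(offer.proposer)
    entries = [
        BoardEntry(coalition=c, shares=s, proposers=tuple(sorted(props)))
        for (c, s), props in grouped.items()
    ]
    entries.sort(
        key=lambda e: (e.coalition.sorted_members, tuple(-a for _, a in e.shares))
    )
    return DisplayBoard(entries=tuple(entries))


def eligible_entries(
    board: DisplayBoard, selector: int, config: GameConfig
) -> list:
    """Entries the selector may choose: those whose coalition includes it,
    plus NO_COALITION when that option is enabled.  Never empty — the
    selector's own mandatory offer always qualifies."""
    out: list = [e for e in board if selector in e.coalition]
    if config.allow_no_selection:
        out.append(NO_COALITION)
    return out


def resolve_round(
    board: DisplayBoard,
    selections: Sequence[Selection],
    config: GameConfig,
    round_number: int = 1,
) -> RoundResult:
    """Phase III: form the entry selected by all its coalition's members.

    With one selection per bargainer and every pair of feasible coalitions
    in a triad sharing a member, at most one entry can be unanimous.
    """
    by_selector: dict[int, Selection] = {}
    for sel in selections:
        if sel.selector in by_selector:
            raise SelectionError(
                f"two selections from {position_label(sel.selector)}"
            )
        by_selector[sel.selector] = sel
    if set(by_selector) != set(config.positions):
        raise SelectionError("need exactly one selection per bargainer")

    for sel in selections:
        if sel.choice is NO_COALITION:
            if not config.allow_no_selection:
                raise SelectionError(
                    f"{position_label(sel.selector)} selected NO_COALITION "
                    "but that option is disabled"
                )
            continue
        if sel.choice not in board.entries:
            raise SelectionError(
                f"{position_label(sel.selector)} selected an entry not on "
                "the board"
            )
        if sel.selector not in sel.choice.coalition:
            raise SelectionError(
                f"{position_label(sel.selector)} selected entry "
                f"{sel.choice.describe()} which does not include them"
            )

    unanimous = [
        entry
        for entry in board
        if all(by_selector[m].choice == entry for m in entry.coalition)
    ]
    if len(unanimous) > 1:  # impossible in a triad; guards generic misuse
        raise ProtocolError("more than one unanimous entry")
    formed = None
    if unanimous:
        entry = unanimous[0]
        formed = (entry.coalition, entry.allocation)
    return RoundResult(
        round_number=round_number,
        board=board,
        selections=tuple(selections),
        formed=formed,
    )


# ---------------------------------------------------------------------------
# Shared phase runners (used by both protocols)


class TriadAborted(Exception):
    """Internal control flow: a bargainer missed a deadline / dropped out."""

    def __init__(self, position: int, reason: str) -> None:
        super().__init__(reason)
        self.position = position
        self.reason = reason


def _check_deadline(
    agent: AgentStrategy,
    rng: np.random.Generator,
    dropout_prob: float,
) -> None:
    if dropout_prob > 0 and rng.random() < dropout_prob:
        raise TriadAborted(agent.position, "dropout")
    if agent.respond_deadline() is not ACT:
        raise TriadAborted(agent.position, "timeout")


def collect_offers(
    config: GameConfig,
    agents: Sequence[AgentStrategy],
    rng: np.random.Generator,
    dropout_prob: float,
    triad_id: int,
    round_number: int,
    events: list[EventRow],
) -> list[Offer]:
    """Phase I: one mandatory validated offer per bargainer."""
    offers = []
    for agent in sorted(agents, key=lambda a: a.position):
        _check_deadline(agent, rng, dropout_prob)
        offer = agent.propose(ProposeView(config, agent.position, round_number))
        try:
            validate_offer(config, offer)
        except GameError as exc:
            raise ProtocolError(
                f"invalid offer from {position_label(agent.position)}: {exc}"
            ) from exc
        offers.append(offer)
        events.append(
            EventRow(
                triad_id=triad_id,
                round=round_number,
                phase="I",
                actor=position_label(agent.position),
                action="offer",
                coalition=offer.coalition.label,
                allocation=format_allocation(offer.shares),
            )
        )
    return offers


def collect_selections(
    config: GameConfig,
    agents: Sequence[AgentStrategy],
    board: DisplayBoard,
    rng: np.random.Generator,
    dropout_prob: float,
    triad_id: int,
    round_number: int,
    events: list[EventRow],
) -> list[Selection]:
    """Phase II: every bargainer picks an eligible entry (or NO_COALITION)."""
    selections = []
    for agent in sorted(agents, key=lambda a: a.position):
        _check_deadline(agent, rng, dropout_prob)
        elig = eligible_entries(board, agent.position, config)
        choice = agent.select(
            SelectView(config, agent.position, round_number, board, tuple(elig))
        )
        if choice is not NO_COALITION and choice not in elig:
            raise SelectionError(
                f"{position_label(agent.position)} chose an ineligible entry"
            )
        selections.append(Selection(selector=agent.position, choice=choice))
        events.append(
            EventRow(
                triad_id=triad_id,
                round=round_number,
                phase="II",
                actor=position_label(agent.position),
                action="select",
                chosen_entry=(
                    "NO_COALITION" if choice is NO_COALITION else choice.describe()
                ),
            )
        )
    return selections


def _check_roster(config: GameConfig, agents: Sequence[AgentStrategy]) -> None:
    if config.n_positions != 3 or len(agents) != 3:
        raise ProtocolError("bargaining protocols support exactly 3 bargainers")
    if sorted(a.position for a in agents) != [0, 1, 2]:
        raise ProtocolError("agents must be seated at positions A, B, C")


def _formed_outcome(
    config: GameConfig,
    triad_id: int,
    coalition: Coalition,
    allocation: dict[int, int],
    rounds_used: int,
    events: list[EventRow],
) -> Outcome:
    from .game import bonus_payment

    bonuses = {
        p: bonus_payment(config, allocation.get(p, 0)) for p in config.positions
    }
    return Outcome(
        triad_id=triad_id,
        status=Status.FORMED,
        coalition=coalition,
        allocation=dict(allocation),
        rounds_used=rounds_used,
        bonuses=bonuses,
        events=events,
    )


def _unformed_outcome(
    config: GameConfig,
    triad_id: int,
    status: Status,
    rounds_used: int,
    events: list[EventRow],
    abort_reason: str = "",
) -> Outcome:
    return Outcome(
        triad_id=triad_id,
        status=status,
        coalition=None,
        allocation=None,
        rounds_used=rounds_used,
        bonuses={p: 0.0 for p in config.positions},
        events=events,
        abort_reason=abort_reason,
    )


def run_one_step_game(
    config: GameConfig,
    agents: Sequence[AgentStrategy],
    rng: np.random.Generator,
    *,
    triad_id: int = 0,
    dropout_prob: float = 0.0,
) -> Outcome:
    """Play one triad to completion under the one-step protocol.

    Returns a FORMED outcome as soon as a round produces a unanimous
    entry, NO_AGREEMENT after ``max_rounds`` rounds without one, or
    ABORTED the moment any bargainer misses a deadline (the rest of the
    triad is forwarded to the end, per the kick-on-idleness rule).
    """
    _check_roster(config, agents)
    events: list[EventRow] = []
    rounds_used = 0
    try:
        for round_number in range(1, config.max_rounds + 1):
            rounds_used = round_number
            offers = collect_offers(
                config, agents, rng, dropout_prob, triad_id, round_number, events
            )
            board = build_board(offers, config.n_positions)
            selections = collect_selections(
                config, agents, board, rng, dropout_prob,
                triad_id, round_number, events,
            )
            result = resolve_round(board, selections, config, round_number)
            formed = result.formed is not None
            events.append(
                EventRow(
                    triad_id=triad_id,
                    round=round_number,
                    phase="III",
                    actor="",
                    action="resolve",
                    coalition=result.formed[0].label if formed else "",
                    allocation=(
                        format_allocation(sorted(result.formed[1].items()))
                        if formed
                        else ""
                    ),
                    formed_flag=formed,
                )
            )
            if formed:
                coalition, allocation = result.formed
                return _formed_outcome(
                    config, triad_id, coalition, allocation, round_number, events
                )
    except TriadAborted as abort:
        events.append(
            EventRow(
                triad_id=triad_id,
                round=rounds_used,
                phase="",
                actor=position_label(abort.position),
                action="timeout",
            )
        )
        return _unformed_outcome(
            config, triad_id, Status.ABORTED, rounds_used, events,
            abort_reason=f"{abort.reason}:{position_label(abort.position)}",
        )
    return _unformed_outcome(
        config, triad_id, Status.NO_AGREEMENT, config.max_rounds, events
    )
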