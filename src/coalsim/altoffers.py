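"""Alternative-offers protocol.

Phases I and II are identical to the one-step protocol.  A unanimous
Phase-III entry does not form immediately: it becomes a *tentative*
coalition.  The excluded bargainer may then make an alternative offer to
one tentative member (Phase IV); the tentative members ratify, and the
targeted member may instead defect to the alternative — which becomes
the new tentative coalition with a newly excluded bargainer — or, when
enabled, any member may select nothing and send play back to Phase I
(Phase V).  Play ends when a coalition is ratified or the round limit is
reached.

A "round" is one full Phase I-III pass; Phase IV-V defection cycles
within a round are capped separately (default: payoff / granularity, the
maximum number of strictly improving counteroffers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .agents import (
    PASS,
    AgentStrategy,
    CounterProposal,
    CounterView,
    RatifyChoice,
    RatifyView,
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
from .onestep import (
    ProtocolError,
    RoundResult,
    TriadAborted,
    _check_deadline,
    _check_roster,
    _formed_outcome,
    _unformed_outcome,
    build_board,
    collect_offers,
    collect_selections,
    resolve_round,
)
from .outcome import Outcome, Status


@dataclass(frozen=True)
class TentativeCoalition:
    """A unanimously selected but not-yet-binding agreement.

    Never emitted as a formed outcome until every member ratifies it.
    """

    coalition: Coalition
    shares: tuple[tuple[int, int], ...]
    origin: str  # "phase3" or "alternative"

    @property
    def allocation(self) -> dict[int, int]:
        return dict(self.shares)

    def describe(self) -> str:
        return f"{self.coalition.label}({format_allocation(self.shares)})"


@dataclass(frozen=True)
class AlternativeOffer:
    """The excluded bargainer's dyadic counteroffer to one tentative
    member (Phase IV)."""

    proposer: int
    target: int
    offer: Offer


@dataclass(frozen=True)
class RatifyResult:
    kind: str  # "FORMED" | "NEW_TENTATIVE" | "BACK_TO_PHASE_I"
    tentative: TentativeCoalition | None = None


FORMED = "FORMED"
NEW_TENTATIVE = "NEW_TENTATIVE"
BACK_TO_PHASE_I = "BACK_TO_PHASE_I"


def to_tentative(round_result: RoundResult) -> TentativeCoalition | None:
    """Lift a unanimous Phase-III entry into a tentative coalition, or
    return None so the caller loops back to Phase I."""
    if round_result.formed is None:
        return None
    coalition, allocation = round_result.formed
    return TentativeCoalition(
        coalition=coalition,
        shares=tuple(sorted(allocation.items())),
        origin="phase3",
    )


def excluded_position(config: GameConfig, tentative: TentativeCoalition) -> int | None:
    """The single bargainer outside the tentative coalition, or None for
    the grand coalition."""
    outside = set(config.positions) - tentative.coalition.members
    if not outside:
        return None
    if len(outside) != 1:
        raise ProtocolError("tentative coalition leaves more than one outside")
    return outside.pop()


def solicit_alternative(
    tentative: TentativeCoalition,
    excluded_agent: AgentStrategy,
    config: GameConfig,
    rng: np.random.Generator,
    round_number: int = 1,
):
    """Phase IV: ask the excluded bargainer for a counteroffer.

    Returns a validated :class:`AlternativeOffer` or PASS.  Must not be
    called when the tentative coalition is the grand coalition (no one is
    excluded then, so the phase is skipped).
    """
    if excluded_agent.position in tentative.coalition:
        raise ProtocolError("the soliciting agent is inside the tentative coalition")
    proposal = excluded_agent.counter(
        CounterView(config, excluded_agent.position, round_number, tentative)
    )
    if proposal is PASS:
        return PASS
    if not isinstance(proposal, CounterProposal):
        raise ProtocolError("counter() must return a CounterProposal or PASS")
    if proposal.target not in tentative.coalition:
        raise ProtocolError(
            f"alternative targets {position_label(proposal.target)}, who is "
            "not in the tentative coalition"
        )
    expected = Coalition.of(excluded_agent.position, proposal.target)
    if proposal.offer.coalition != expected:
        raise ProtocolError(
            "alternative offer must name exactly the dyad "
            f"{expected.label}, got {proposal.offer.coalition.label}"
        )
    try:
        validate_offer(config, proposal.offer)
    except GameError as exc:
        raise ProtocolError(
            f"invalid alternative offer from "
            f"{position_label(excluded_agent.position)}: {exc}"
        ) from exc
    return AlternativeOffer(
        proposer=excluded_agent.position,
        target=proposal.target,
        offer=proposal.offer,
    )


def ratify(
    tentative: TentativeCoalition,
    alternative: AlternativeOffer | None,
    member_choices: Mapping[int, RatifyChoice],
    config: GameConfig,
) -> RatifyResult:
    """Phase V: resolve the tentative members' ratification choices.

    Precedence: any NONE (the exit option, when enabled) sends play back
    to Phase I; otherwise the target defecting to the alternative makes it
    the new tentative coalition; otherwise unanimous RATIFY forms it.
    """
    members = tentative.coalition.members
    if set(member_choices) != members:
        raise ProtocolError("need exactly one choice per tentative member")
    target = alternative.target if alternative is not None else None
    for position, choice in member_choices.items():
        if choice is RatifyChoice.ALTERNATIVE and position != target:
            raise ProtocolError(
                f"{position_label(position)} chose ALTERNATIVE but is not "
                "the alternative's target"
            )
        if choice is RatifyChoice.NONE and not config.allow_no_selection:
            raise ProtocolError(
                f"{position_label(position)} chose NONE but that option is "
                "disabled"
            )
    if any(c is RatifyChoice.NONE for c in member_choices.values()):
        return RatifyResult(kind=BACK_TO_PHASE_I)
    if target is not None and member_choices[target] is RatifyChoice.ALTERNATIVE:
        return RatifyResult(
            kind=NEW_TENTATIVE,
            tentative=TentativeCoalition(
                coalition=alternative.offer.coalition,
                shares=alternative.offer.shares,
                origin="alternative",
            ),
        )
    return RatifyResult(kind=FORMED, tentative=tentative)


def default_defection_cap(config: GameConfig) -> int:
    """Upper bound on strictly improving counteroffers within one round."""
    return config.payoff // config.payoff_granularity


def run_alt_offers_game(
    config: GameConfig,
    agents: Sequence[AgentStrategy],
    rng: np.random.Generator,
    *,
    triad_id: int = 0,
    dropout_prob: float = 0.0,
    defection_cap: int | None = None,
) -> Outcome:
    """Play one triad to completion under the alternative-offers protocol."""
    _check_roster(config, agents)
    if defection_cap is None:
        defection_cap = default_defection_cap(config)
    by_position = {a.position: a for a in agents}
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
            tentative = to_tentative(result)
            if tentative is None:
                continue
            formed = _ratification_loop(
                config, by_position, tentative, rng, dropout_prob,
                triad_id, round_number, defection_cap, events,
            )
            if formed is not None:
                coalition, allocation = formed
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


def _ratification_loop(
    config: GameConfig,
    by_position: Mapping[int, AgentStrategy],
    tentative: TentativeCoalition,
    rng: np.random.Generator,
    dropout_prob: float,
    triad_id: int,
    round_number: int,
    defection_cap: int,
    events: list[EventRow],
) -> tuple[Coalition, dict[int, int]] | None:
    """Phases IV-V, looping on defections.  Returns the formed (coalition,
    allocation) or None when play goes back to Phase I."""
    for _cycle in range(defection_cap + 1):
        events.append(
            EventRow(
                triad_id=triad_id,
                round=round_number,
                phase="III" if tentative.origin == "phase3" else "V",
                actor="",
                action="tentative",
                coalition=tentative.coalition.label,
                allocation=format_allocation(tentative.shares),
            )
        )
        excluded = excluded_position(config, tentative)
        alternative: AlternativeOffer | None = None
        if excluded is not None:
            agent = by_position[excluded]
            _check_deadline(agent, rng, dropout_prob)
            got = solicit_alternative(tentative, agent, config, rng, round_number)
            if got is PASS:
                events.append(
                    EventRow(
                        triad_id=triad_id,
                        round=round_number,
                        phase="IV",
                        actor=position_label(excluded),
                        action="pass",
                    )
                )
            else:
                alternative = got
                events.append(
                    EventRow(
                        triad_id=triad_id,
                        round=round_number,
                        phase="IV",
                        actor=position_label(excluded),
                        action="alternative",
                        coalition=alternative.offer.coalition.label,
                        allocation=format_allocation(alternative.offer.shares),
                        chosen_entry=position_label(alternative.target),
                    )
                )
        choices: dict[int, RatifyChoice] = {}
        for member in tentative.coalition:
            agent = by_position[member]
            _check_deadline(agent, rng, dropout_prob)
            choice = agent.ratify(
                RatifyView(
                    config=config,
                    position=member,
                    round=round_number,
                    tentative=tentative,
                    alternative=alternative,
                    is_target=(
                        alternative is not None and member == alternative.target
                    ),
                )
            )
            choices[member] = choice
            events.append(
                EventRow(
                    triad_id=triad_id,
                    round=round_number,
                    phase="V",
                    actor=position_label(member),
                    action="ratify",
                    chosen_entry=choice.value,
                )
            )
        result = ratify(tentative, alternative, choices, config)
        if result.kind == FORMED:
            return result.tentative.coalition, result.tentative.allocation
        if result.kind == BACK_TO_PHASE_I:
            return None
        events.append(
            EventRow(
                triad_id=triad_id,
                round=round_number,
                phase="V",
                actor=position_label(alternative.target),
                action="defect",
                coalition=result.tentative.coalition.label,
                allocation=format_allocation(result.tentative.shares),
            )
        )
        tentative = result.tentative
    return None  # defection cap exhausted: back to Phase I
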