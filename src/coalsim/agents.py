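"""Simulated bargainers.

Each agent implements :class:`AgentStrategy`: five decision points
(propose, select, counter, ratify, respond_deadline) driven only by the
view it is handed and a private seeded random stream, so every decision
replays identically under the same seed.

Reference strategies:

``equity``
    Demands a share proportional to the resources it contributes, and
    proposes the feasible coalition maximizing that proportional share.
``equal_split``
    Proposes the cheapest-to-join feasible coalition with equal shares.
``random``
    Uniformly random feasible coalition containing itself with a random
    granular allocation.
``timeout``
    Wraps another strategy and misses deadlines with fixed probability.
"""

from __future__ import annotations

import enum
from abc import ABC, abstractmethod
from dataclasses import dataclass
from fractions import Fraction
from typing import TYPE_CHECKING, Any, Optional, Sequence

import numpy as np

from .game import Coalition, GameConfig, Offer, feasible_coalitions

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from .altoffers import AlternativeOffer, TentativeCoalition
    from .onestep import DisplayBoard


# ---------------------------------------------------------------------------
# Sentinels and choice enums


class _Sentinel:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:
        return self._name


#: Phase-II choice meaning "select no coalition offer at all".
NO_COALITION = _Sentinel("NO_COALITION")
#: Phase-IV choice meaning the excluded bargainer makes no alternative offer.
PASS = _Sentinel("PASS")
#: Deadline responses.
ACT = _Sentinel("ACT")
TIMEOUT = _Sentinel("TIMEOUT")


class RatifyChoice(enum.Enum):
    RATIFY = "RATIFY"
    ALTERNATIVE = "ALTERNATIVE"
    NONE = "NONE"


@dataclass(frozen=True)
class CounterProposal:
    """An excluded bargainer's Phase-IV move: a dyadic offer to one
    member of the tentative coalition."""

    target: int
    offer: Offer


# ---------------------------------------------------------------------------
# Views handed to agents (no hidden state: decisions are functions of these)


@dataclass(frozen=True)
class ProposeView:
    config: GameConfig
    position: int
    round: int


@dataclass(frozen=True)
class SelectView:
    config: GameConfig
    position: int
    round: int
    board: "DisplayBoard"
    eligible: tuple  # BoardEntry entries, plus NO_COALITION when enabled


@dataclass(frozen=True)
class CounterView:
    config: GameConfig
    position: int
    round: int
    tentative: "TentativeCoalition"


@dataclass(frozen=True)
class RatifyView:
    config: GameConfig
    position: int
    round: int
    tentative: "TentativeCoalition"
    alternative: Optional["AlternativeOffer"]
    is_target: bool


# ---------------------------------------------------------------------------
# Allocation helpers


def equity_allocation(
    config: GameConfig, coalition: Coalition, proposer: int
) -> dict[int, int]:
    """Split the payoff in proportion to resources, snapped to granularity.

    Non-proposer shares are floored to the granularity; the proposer takes
    the remainder.  This covers payoffs that cannot be divided exactly
    equitably while keeping conservation exact.
    """
    g = config.payoff_granularity
    total_res = sum(config.resources[m] for m in coalition)
    alloc: dict[int, int] = {}
    for m in coalition:
        if m == proposer:
            continue
        exact = Fraction(config.resources[m] * config.payoff, total_res)
        alloc[m] = int(exact // g) * g
    alloc[proposer] = config.payoff - sum(alloc.values())
    return alloc


def equal_allocation(config: GameConfig, coalition: Coalition) -> dict[int, int]:
    """Equal shares; leftover granules go to the lowest positions first."""
    g = config.payoff_granularity
    members = coalition.sorted_members
    units, extra = divmod(config.payoff // g, len(members))
    return {m: (units + (1 if i < extra else 0)) * g
            for i, m in enumerate(members)}


def equity_fraction(config: GameConfig, coalition: Coalition, position: int) -> Fraction:
    """position's resource share of the coalition's pooled resources."""
    total = sum(config.resources[m] for m in coalition)
    return Fraction(config.resources[position], total)


def random_allocation(
    config: GameConfig, coalition: Coalition, rng: np.random.Generator
) -> dict[int, int]:
    """Uniform multinomial split of the payoff's granules over members."""
    g = config.payoff_granularity
    members = coalition.sorted_members
    counts = rng.multinomial(config.payoff // g, [1 / len(members)] * len(members))
    return {m: int(c) * g for m, c in zip(members, counts)}


def _own_coalitions(config: GameConfig, position: int) -> list[Coalition]:
    """Feasible coalitions containing position, in deterministic label order."""
    return sorted(
        (c for c in feasible_coalitions(config) if position in c),
        key=lambda c: c.label,
    )


# ---------------------------------------------------------------------------
# Strategy contract


class AgentStrategy(ABC):
    """Decision contract for one simulated bargainer.

    ``position`` is assigned by the simulator after seating; ``effort``
    feeds the earned-resources seating mode (strategies shipped here do
    not condition on it).  Subclasses may keep cross-round state, but none
    of the reference strategies do (they are myopic).
    """

    name: str = "base"

    def __init__(
        self,
        rng: np.random.Generator,
        position: int | None = None,
        effort: float = 0.0,
    ) -> None:
        self.rng = rng
        self.position = position
        self.effort = float(effort)

    # -- decision points ----------------------------------------------------

    @abstractmethod
    def propose(self, view: ProposeView) -> Offer:
        """Phase I: return a valid coalition offer."""

    @abstractmethod
    def select(self, view: SelectView):
        """Phase II: return one eligible board entry, or NO_COALITION."""

    def counter(self, view: CounterView):
        """Phase IV: return a CounterProposal or PASS.  Default: PASS."""
        return PASS

    def ratify(self, view: RatifyView) -> RatifyChoice:
        """Phase V choice.  Default: myopic payoff maximization — defect to
        the alternative iff it strictly beats the tentative share."""
        if view.is_target and view.alternative is not None:
            here = view.tentative.allocation[self.position]
            there = view.alternative.offer.share_of(self.position)
            if there > here:
                return RatifyChoice.ALTERNATIVE
        return RatifyChoice.RATIFY

    def respond_deadline(self):
        """Whether the agent acts before its page timer expires."""
        return ACT

    # -- helpers ------------------------------------------------------------

    def _pick(self, candidates: Sequence):
        """Deterministic-seeded uniform choice among tied candidates."""
        if len(candidates) == 1:
            return candidates[0]
        return candidates[int(self.rng.integers(len(candidates)))]

    def __repr__(self) -> str:
        return f"<{type(self).__name__} position={self.position}>"


class EquityAgent(AgentStrategy):
    """Demands resource-proportional shares; selects its best payoff."""

    name = "equity"

    def propose(self, view: ProposeView) -> Offer:
        cands = _own_coalitions(view.config, self.position)
        best = max(equity_fraction(view.config, c, self.position) for c in cands)
        top = [c for c in cands
               if equity_fraction(view.config, c, self.position) == best]
        coalition = self._pick(top)
        alloc = equity_allocation(view.config, coalition, self.position)
        return Offer.make(self.position, coalition, alloc)

    def select(self, view: SelectView):
        entries = [e for e in view.eligible if e is not NO_COALITION]
        best = max(e.share_of(self.position) for e in entries)
        top = [e for e in entries if e.share_of(self.position) == best]
        own = [e for e in top if self.position in e.proposers]
        return self._pick(own or top)

    def counter(self, view: CounterView):
        config = view.config
        feas = feasible_coalitions(config)
        cands = []
        for target in view.tentative.coalition:
            dyad = Coalition.of(self.position, target)
            if dyad in feas:
                cands.append((equity_fraction(config, dyad, self.position), target, dyad))
        if not cands:
            return PASS
        best = max(f for f, _, _ in cands)
        _, target, dyad = self._pick([c for c in cands if c[0] == best])
        alloc = equity_allocation(config, dyad, self.position)
        return CounterProposal(target, Offer.make(self.position, dyad, alloc))


class EqualSplitAgent(AgentStrategy):
    """Proposes the cheapest-to-join feasible coalition, split equally."""

    name = "equal_split"

    def propose(self, view: ProposeView) -> Offer:
        from .game import coalition_resources

        cands = _own_coalitions(view.config, self.position)
        cheapest = min(coalition_resources(view.config, c) for c in cands)
        top = [c for c in cands
               if coalition_resources(view.config, c) == cheapest]
        coalition = self._pick(top)
        return Offer.make(
            self.position, coalition, equal_allocation(view.config, coalition)
        )

    def select(self, view: SelectView):
        entries = [e for e in view.eligible if e is not NO_COALITION]
        best = max(e.share_of(self.position) for e in entries)
        top = [e for e in entries if e.share_of(self.position) == best]
        own = [e for e in top if self.position in e.proposers]
        return self._pick(own or top)

    def counter(self, view: CounterView):
        feas = feasible_coalitions(view.config)
        dyads = [(t, Coalition.of(self.position, t))
                 for t in view.tentative.coalition
                 if Coalition.of(self.position, t) in feas]
        if not dyads:
            return PASS
        target, dyad = self._pick(dyads)
        return CounterProposal(
            target,
            Offer.make(self.position, dyad, equal_allocation(view.config, dyad)),
        )


class RandomAgent(AgentStrategy):
    """Uniformly random but always-valid decisions."""

    name = "random"

    def propose(self, view: ProposeView) -> Offer:
        coalition = self._pick(_own_coalitions(view.config, self.position))
        alloc = random_allocation(view.config, coalition, self.rng)
        return Offer.make(self.position, coalition, alloc)

    def select(self, view: SelectView):
        entries = [e for e in view.eligible if e is not NO_COALITION]
        return self._pick(entries)

    def counter(self, view: CounterView):
        feas = feasible_coalitions(view.config)
        dyads = [(t, Coalition.of(self.position, t))
                 for t in view.tentative.coalition
                 if Coalition.of(self.position, t) in feas]
        if not dyads:
            return PASS
        target, dyad = self._pick(dyads)
        alloc = random_allocation(view.config, dyad, self.rng)
        return CounterProposal(target, Offer.make(self.position, dyad, alloc))

    def ratify(self, view: RatifyView) -> RatifyChoice:
        if view.is_target and view.alternative is not None:
            return self._pick([RatifyChoice.RATIFY, RatifyChoice.ALTERNATIVE])
        return RatifyChoice.RATIFY


class TimeoutAgent(AgentStrategy):
    """Delegates decisions to an inner strategy but may miss deadlines.

    Models the kicked-for-idleness participant: with probability
    ``timeout_prob`` per decision the agent fails to act in time and the
    whole triad is forwarded to the end (ABORTED).
    """

    name = "timeout"

    def __init__(
        self,
        rng: np.random.Generator,
        position: int | None = None,
        effort: float = 0.0,
        timeout_prob: float = 1.0,
        inner: AgentStrategy | None = None,
    ) -> None:
        super().__init__(rng, position, effort)
        if not 0.0 <= timeout_prob <= 1.0:
            raise ValueError("timeout_prob must be in [0, 1]")
        self.timeout_prob = timeout_prob
        self.inner = inner if inner is not None else EqualSplitAgent(rng)
        self.inner.position = self._position

    @property
    def position(self):  # keep inner strategy's seat in sync
        return self._position

    @position.setter
    def position(self, value):
        self._position = value
        if getattr(self, "inner", None) is not None:
            self.inner.position = value

    def respond_deadline(self):
        return TIMEOUT if self.rng.random() < self.timeout_prob else ACT

    def propose(self, view: ProposeView) -> Offer:
        return self.inner.propose(view)

    def select(self, view: SelectView):
        return self.inner.select(view)

    def counter(self, view: CounterView):
        return self.inner.counter(view)

    def ratify(self, view: RatifyView) -> RatifyChoice:
        return self.inner.ratify(view)


STRATEGIES: dict[str, type[AgentStrategy]] = {
    EquityAgent.name: EquityAgent,
    EqualSplitAgent.name: EqualSplitAgent,
    RandomAgent.name: RandomAgent,
    TimeoutAgent.name: TimeoutAgent,
}


def make_agent(
    strategy: str,
    rng: np.random.Generator,
    **params: Any,
) -> AgentStrategy:
    """Instantiate a registered strategy by name with its parameters."""
    try:
        cls = STRATEGIES[strategy]
    except KeyError:
        raise ValueError(
            f"unknown strategy {strategy!r}; known: {sorted(STRATEGIES)}"
        ) from None
    return cls(rng, **params)
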