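"""Weighted majority coalition games: configuration, feasibility, offers.

A simple weighted majority game assigns each of ``k >= 3`` bargainer
positions an integer resource count.  Any coalition of two or more positions
whose pooled resources reach the decision point may claim a fixed payoff,
to be divided among its members in integer multiples of
``payoff_granularity``.  Games are notated ``q(rA-rB-rC)``; in the common
5(4-3-2) game positions A, B and C hold 4, 3 and 2 resources and any pair
can reach the decision point of 5.

Positions are 0-based indices internally and rendered as letters
(A, B, C, ...) in all user-facing output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping


# ---------------------------------------------------------------------------
# Errors


class GameError(Exception):
    """Base class for all game-level errors."""


class ConfigError(GameError):
    """Invalid game configuration."""


class UnknownPositionError(ConfigError):
    """A position index does not exist in the game."""


class OfferError(GameError):
    """Base class for offer validation failures."""


class InfeasibleCoalitionError(OfferError):
    """The proposed coalition cannot form under the game's threshold rules."""


class ProposerNotMemberError(OfferError):
    """The proposer is not a member of the proposed coalition."""


class AllocationKeysError(OfferError):
    """Allocation keys do not match the coalition members exactly."""


class BadShareError(OfferError):
    """A share is negative or not a multiple of the payoff granularity."""


class PayoffSumError(OfferError):
    """Shares do not sum exactly to the payoff."""


# ---------------------------------------------------------------------------
# Position labels


def position_label(position: int) -> str:
    """Render a 0-based position index as a letter: 0 -> 'A', 1 -> 'B', ..."""
    if position < 0:
        raise UnknownPositionError(f"negative position index {position}")
    return chr(ord("A") + position)


def parse_position(label: str) -> int:
    """Inverse of :func:`position_label`."""
    label = label.strip().upper()
    if len(label) != 1 or not "A" <= label <= "Z":
        raise UnknownPositionError(f"not a position label: {label!r}")
    return ord(label) - ord("A")


# ---------------------------------------------------------------------------
# Coalition


@dataclass(frozen=True, order=True)
class Coalition:
    """A set of two or more bargainer positions acting jointly.

    Single positions never constitute a coalition, even when one bargainer's
    resources alone would meet the decision point: coalition formation is
    the *joint* use of resources, so the smallest coalition inside a triad
    is the dyad.
    """

    members: frozenset[int] = field(compare=False)
    _key: tuple[int, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        members = frozenset(self.members)
        if len(members) < 2:
            raise ConfigError("a coalition needs at least 2 members")
        if any(m < 0 for m in members):
            raise UnknownPositionError("negative position index in coalition")
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "_key", tuple(sorted(members)))

    @classmethod
    def of(cls, *positions: int) -> "Coalition":
        return cls(frozenset(positions))

    @classmethod
    def from_label(cls, label: str) -> "Coalition":
        """Build a coalition from a letter string such as ``"BC"``."""
        return cls(frozenset(parse_position(ch) for ch in label.strip()))

    @property
    def label(self) -> str:
        return "".join(position_label(m) for m in self._key)

    @property
    def sorted_members(self) -> tuple[int, ...]:
        return self._key

    def __contains__(self, position: int) -> bool:
        return position in self.members

    def __iter__(self):
        return iter(self._key)

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# GameConfig


#: Keys accepted by the flat key-value config format, in canonical order.
CONFIG_KEYS = (
    "resources",
    "decision_point",
    "payoff",
    "payoff_granularity",
    "grand_coalition",
    "allow_no_selection",
    "max_rounds",
    "conversion_rate",
)


@dataclass(frozen=True)
class GameConfig:
    """Full configuration of one weighted majority game.

    Parameters
    ----------
    resources:
        Resource count per bargainer position, e.g. ``(4, 3, 2)``.
    decision_point:
        Resource threshold a coalition must meet or exceed to be formable.
    payoff:
        Amount (in payoff units) a formed coalition divides among members.
    payoff_granularity:
        Smallest allocatable unit; every share must be a multiple of it.
    allow_grand_coalition:
        Whether the coalition of all positions may form.
    allow_no_selection:
        Whether bargainers may decline to select any offer.
    max_rounds:
        Hard limit on bargaining rounds before the game ends unresolved.
    conversion_rate:
        Bonus currency per payoff unit; 0 means hypothetical payoffs.
    """

    resources: tuple[int, ...]
    decision_point: int
    payoff: int
    payoff_granularity: int = 1
    allow_grand_coalition: bool = False
    allow_no_selection: bool = False
    max_rounds: int = 10
    conversion_rate: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "resources", tuple(int(r) for r in self.resources))
        if len(self.resources) < 3:
            raise ConfigError("need at least 3 bargainer positions")
        if any(r < 0 for r in self.resources):
            raise ConfigError("resources must be non-negative")
        if self.decision_point <= 0:
            raise ConfigError("decision_point must be positive")
        if self.payoff_granularity <= 0:
            raise ConfigError("payoff_granularity must be positive")
        if self.payoff <= 0 or self.payoff % self.payoff_granularity:
            raise ConfigError(
                "payoff must be a positive multiple of payoff_granularity"
            )
        if self.max_rounds < 1:
            raise ConfigError("max_rounds must be >= 1")
        if self.conversion_rate < 0:
            raise ConfigError("conversion_rate must be >= 0")
        if not feasible_coalitions(self):
            raise ConfigError(
                "unwinnable game: no permitted coalition of >= 2 members "
                "reaches the decision point"
            )

    @property
    def n_positions(self) -> int:
        return len(self.resources)

    @property
    def positions(self) -> range:
        return range(self.n_positions)

    @property
    def grand_coalition(self) -> Coalition:
        return Coalition(frozenset(self.positions))

    def notation(self) -> str:
        """The q(rA-rB-rC) shorthand, e.g. ``5(4-3-2)``."""
        return f"{self.decision_point}({'-'.join(map(str, self.resources))})"


# ---------------------------------------------------------------------------
# Core operations


def coalition_resources(config: GameConfig, coalition: Coalition) -> int:
    """Sum the resources held by a coalition's members."""
    for m in coalition.members:
        if m not in config.positions:
            raise UnknownPositionError(
                f"position {m} not in game with {config.n_positions} positions"
            )
    return sum(config.resources[m] for m in coalition.members)


def feasible_coalitions(config: GameConfig) -> frozenset[Coalition]:
    """All coalitions that may form under the game's rules.

    Exhaustive over the powerset of positions: every subset of size >= 2
    whose resources meet the decision point, with the grand coalition
    included only when ``allow_grand_coalition`` is set.
    """
    n = len(config.resources)
    out = []
    for size in range(2, n + 1):
        if size == n and not config.allow_grand_coalition:
            continue
        for members in itertools.combinations(range(n), size):
            if sum(config.resources[m] for m in members) >= config.decision_point:
                out.append(Coalition(frozenset(members)))
    return frozenset(out)


# ---------------------------------------------------------------------------
# Offer


@dataclass(frozen=True)
class Offer:
    """A proposal: a coalition plus an exact division of the payoff.

    ``shares`` is the canonical (position, amount) tuple sorted by position;
    use :meth:`make` to build an offer from a mapping.
    """

    proposer: int
    coalition: Coalition
    shares: tuple[tuple[int, int], ...]

    @classmethod
    def make(
        cls, proposer: int, coalition: Coalition, allocation: Mapping[int, int]
    ) -> "Offer":
        shares = tuple(sorted((int(p), int(a)) for p, a in allocation.items()))
        return cls(proposer=proposer, coalition=coalition, shares=shares)

    @property
    def allocation(self) -> dict[int, int]:
        return dict(self.shares)

    def share_of(self, position: int) -> int:
        return self.allocation[position]

    def describe(self) -> str:
        alloc = ";".join(
            f"{position_label(p)}={a}" for p, a in self.shares
        )
        return f"{self.coalition.label}({alloc})"


def validate_offer(config: GameConfig, offer: Offer) -> Offer:
    """Check every offer invariant; return the offer unchanged if valid.

    Raises a distinct error type per failure mode so that callers (and
    logs) can name exactly what was malformed: proposer not a member,
    allocation keys not matching the members, a negative or non-granular
    share, shares not summing to the payoff, or an infeasible coalition.
    """
    for m in offer.coalition.members:
        if m not in config.positions:
            raise UnknownPositionError(
                f"offer names unknown position {m}"
            )
    if offer.proposer not in offer.coalition:
        raise ProposerNotMemberError(
            f"proposer {position_label(offer.proposer)} is not a member of "
            f"{offer.coalition.label}"
        )
    alloc = offer.allocation
    if set(alloc) != offer.coalition.members:
        raise AllocationKeysError(
            f"allocation positions {sorted(alloc)} do not match coalition "
            f"{offer.coalition.label}"
        )
    for p, amount in offer.shares:
        if amount < 0 or amount % config.payoff_granularity:
            raise BadShareError(
                f"share {amount} for {position_label(p)} is negative or not "
                f"a multiple of {config.payoff_granularity}"
            )
    total = sum(alloc.values())
    if total != config.payoff:
        raise PayoffSumError(
            f"shares sum to {total}, payoff is {config.payoff}"
        )
    if offer.coalition not in feasible_coalitions(config):
        raise InfeasibleCoalitionError(
            f"coalition {offer.coalition.label} cannot form "
            f"(resources {coalition_resources(config, offer.coalition)}, "
            f"decision point {config.decision_point})"
        )
    return offer


def bonus_payment(config: GameConfig, share: float) -> float:
    """Convert a payoff share to bonus currency, rounded half-up to cents."""
    if share < 0:
        raise GameError("share must be >= 0")
    raw = Decimal(str(share)) * Decimal(str(config.conversion_rate))
    return float(raw.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Flat key-value config serialization


def to_config_text(config: GameConfig) -> str:
    """Serialize a config to the flat ``key = value`` format.

    The key names (``resources``, ``decision_point``, ``payoff``,
    ``grand_coalition``, ``allow_no_selection``, ``max_rounds``,
    ``conversion_rate`` plus ``payoff_granularity``) are this package's
    own; round-trips bit-exactly through :func:`from_config_text`.
    """
    values = {
        "resources": ",".join(map(str, config.resources)),
        "decision_point": str(config.decision_point),
        "payoff": str(config.payoff),
        "payoff_granularity": str(config.payoff_granularity),
        "grand_coalition": "true" if config.allow_grand_coalition else "false",
        "allow_no_selection": "true" if config.allow_no_selection else "false",
        "max_rounds": str(config.max_rounds),
        "conversion_rate": repr(config.conversion_rate),
    }
    return "".join(f"{k} = {values[k]}\n" for k in CONFIG_KEYS)


def from_config_text(text: str) -> GameConfig:
    """Parse the flat key-value format produced by :func:`to_config_text`."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in CONFIG_KEYS:
            raise ConfigError(f"line {lineno}: unknown key {key!r}")
        if key in raw:
            raise ConfigError(f"line {lineno}: duplicate key {key!r}")
        raw[key] = value.strip()

    def _bool(s: str) -> bool:
        if s not in ("true", "false"):
            raise ConfigError(f"expected true/false, got {s!r}")
        return s == "true"

    try:
        return GameConfig(
            resources=tuple(int(x) for x in raw["resources"].split(",")),
            decision_point=int(raw["decision_point"]),
            payoff=int(raw["payoff"]),
            payoff_granularity=int(raw.get("payoff_granularity", "1")),
            allow_grand_coalition=_bool(raw.get("grand_coalition", "false")),
            allow_no_selection=_bool(raw.get("allow_no_selection", "false")),
            max_rounds=int(raw.get("max_rounds", "10")),
            conversion_rate=float(raw.get("conversion_rate", "0.0")),
        )
    except KeyError as exc:
        raise ConfigError(f"missing required key {exc.args[0]!r}") from exc
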