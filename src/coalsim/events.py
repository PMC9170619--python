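"""Flat CSV event log shared by both bargaining protocols.

One row per protocol event.  The one-step protocol uses phases I-III
(offer, select, resolve); the alternative-offers protocol adds phases
IV-V (tentative, alternative, pass, ratify, defect) plus timeout rows
when a bargainer misses a deadline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

EVENT_FIELDS = (
    "triad_id",
    "round",
    "phase",
    "actor",
    "action",
    "coalition",
    "allocation",
    "chosen_entry",
    "formed_flag",
)


@dataclass(frozen=True)
class EventRow:
    triad_id: int
    round: int
    phase: str  # I, II, III, IV, V
    actor: str  # position letter, or "" for round-level events
    action: str  # offer|select|resolve|tentative|alternative|pass|ratify|defect|timeout
    coalition: str = ""
    allocation: str = ""  # e.g. "B=55;C=45"
    chosen_entry: str = ""  # e.g. "BC(B=55;C=45)" or "NO_COALITION"
    formed_flag: bool = False


def format_allocation(shares: Sequence[tuple[int, int]]) -> str:
    from .game import position_label

    return ";".join(f"{position_label(p)}={a}" for p, a in sorted(shares))


def write_events(rows: Iterable[EventRow], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_FIELDS)
        for row in rows:
            writer.writerow(
                [getattr(row, f) if f != "formed_flag" else int(row.formed_flag)
                 for f in EVENT_FIELDS]
            )
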