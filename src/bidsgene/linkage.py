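"""Participant-to-genetic pseudo-identifier linkage.

The genetics descriptor links imaging and molecular repositories through two
pseudo-IDs: ``participant_id`` (the imaging label) and ``genetic_id`` (the
biosample label).  This module builds the forward/reverse maps between them
and merges externally supplied link files without ever touching personal
identifiers — conflicting pairs are reported, never silently overwritten.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from .model import ParticipantLinkTable


@dataclass
class LinkMap:
    """Bidirectional participant↔genetic pseudo-ID map.

    ``forward`` holds only linked rows (non-missing genetic_id); ``reverse``
    is its exact transpose and keeps duplicated genetic_ids as multi-entries.
    """

    forward: dict[str, str] = field(default_factory=dict)
    reverse: dict[str, list[str]] = field(default_factory=dict)
    n_linked: int = 0
    n_unlinked: int = 0


@dataclass(frozen=True)
class LinkConflict:
    """A merge pair that could not be applied, with the reason why."""

    participant_id: str
    genetic_id: str
    reason: str  # "unknown_participant" | "conflicting_genetic_id"


def build_link_map(table: ParticipantLinkTable) -> LinkMap:
    """Derive the pseudo-ID map from a participants table."""
    link = LinkMap()
    for rec in table.records:
        if rec.genetic_id is None:
            link.n_unlinked += 1
        else:
            link.forward[rec.participant_id] = rec.genetic_id
            link.reverse.setdefault(rec.genetic_id, []).append(rec.participant_id)
            link.n_linked += 1
    return link


def resolve(link: LinkMap, participant_id: str) -> str | None:
    """Exact-match lookup; None for unknown or unlinked participants."""
    return link.forward.get(participant_id)


def merge_external_links(table: ParticipantLinkTable,
                         pairs: Iterable[tuple[str, str]],
                         ) -> tuple[ParticipantLinkTable, list[LinkConflict]]:
    """Fill missing genetic_ids from an external link file.

    A pair targeting a participant that already carries a *different*
    genetic_id is a conflict and is not applied; pairs naming unknown
    participants are conflicts too.  Re-applying the same pairs is a no-op
    (idempotent).  The input table is not mutated.
    """
    by_pid = {rec.participant_id: i for i, rec in enumerate(table.records)}
    records = [replace(rec, extras=dict(rec.extras)) for rec in table.records]
    conflicts: list[LinkConflict] = []
    for pid, gid in pairs:
        if pid not in by_pid:
            conflicts.append(LinkConflict(pid, gid, "unknown_participant"))
            continue
        rec = records[by_pid[pid]]
        if rec.genetic_id is None:
            rec.genetic_id = gid
        elif rec.genetic_id != gid:
            conflicts.append(LinkConflict(pid, gid, "conflicting_genetic_id"))
    header = list(table.header)
    if "genetic_id" not in header:
        header.append("genetic_id")
    return ParticipantLinkTable(header=header, records=records), conflicts


def read_link_pairs(text: str) -> list[tuple[str, str]]:
    """Parse an external two-column link TSV (participant_id, genetic_id)."""
    from .io import read_participants_table  # same dialect

    table = read_participants_table(text)
    return [(rec.participant_id, rec.genetic_id)
            for rec in table.records if rec.genetic_id is not None]
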