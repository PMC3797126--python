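"""Propagation-trace construction and pattern detection.

A sentence's *trace* is its timeline of occurrences: which lineages carried
it at which releases.  The set of lineages at its earliest occurrence date
is its inferred *origin*; the set at its latest occurrence date its
*terminal* set.  Four characteristic propagation patterns are detected by
set operations over these traces:

``MISSING_ORIGIN``
    The sentence is gone from every lineage it first appeared in, yet some
    other lineage still carried it at a release after the origin lost it
    (origin set and terminal set intersect to the empty set).
``REAPPEARING_ENTRY``
    A lineage carried the sentence, lost it for at least one archived
    release of the same database, then carried it again.
``TRANSIENT``
    A lineage carried the sentence for exactly one release and a later
    release of the same database exists without it.  An occurrence whose
    only release is the most recent one can never be flagged — removal is
    not yet observable.
``TREMBL_ORIGIN``
    The sentence's earliest-dated occurrences are all in TrEMBL and the
    sentence later appears in a Swiss-Prot entry.  A simultaneous first
    appearance in both halves of a synchronised release is ambiguous and
    not flagged.

Two calendar subtleties matter throughout.  First, absence is only counted
against releases that actually exist for a database: early Swiss-Prot and
TrEMBL calendars were unsynchronised, and treating the other database's
release dates as observation points would manufacture spurious gaps (the
"striping" artefact).  Second, detection is lineage-resolved, so entry
merges never masquerade as removal followed by re-addition.
"""

from __future__ import annotations

import datetime
import enum
import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .index import OccurrenceIndex
from .releases import Database, Release


class Pattern(enum.Enum):
    MISSING_ORIGIN = "missing_origin"
    REAPPEARING_ENTRY = "reappearing_entry"
    TRANSIENT = "transient"
    TREMBL_ORIGIN = "trembl_origin"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class PropagationTrace:
    """Per-sentence occurrence timeline with origin and terminal sets."""

    sentence_id: int
    timeline: tuple[tuple[str, frozenset[int]], ...]  # (release_key, lineages)
    origin_set: frozenset[int]
    terminal_set: frozenset[int]
    first_date: datetime.date
    last_date: datetime.date

    def lineages_at(self, release_key: str) -> frozenset[int]:
        for key, lids in self.timeline:
            if key == release_key:
                return lids
        return frozenset()

    @property
    def n_lineages_ever(self) -> int:
        return len({lid for _, lids in self.timeline for lid in lids})


@dataclass(frozen=True)
class PatternHit:
    """One sentence flagged for one pattern, with supporting occurrences."""

    sentence_id: int
    pattern: Pattern
    evidence: tuple[tuple[int, str], ...]  # (lineage_id, release_key)
    extant: bool


def build_trace(index: OccurrenceIndex, sentence_id: int) -> PropagationTrace:
    """Construct the propagation trace of one indexed sentence.

    The timeline is ordered by release date (Swiss-Prot before TrEMBL on a
    shared date) and includes only releases where the sentence occurs;
    releases at which the sentence's database published nothing are "no
    data", not absence, and carry no timeline entry.
    """
    occs = index.occurrences_of(sentence_id)
    per_release: dict[str, set[int]] = defaultdict(set)
    for lid, rkey in occs:
        per_release[rkey].add(lid)
    ordered = sorted(
        per_release.items(),
        key=lambda kv: (index.calendar.get(kv[0]).date, kv[0]),
    )
    dates = [index.calendar.get(k).date for k, _ in ordered]
    first_date, last_date = dates[0], dates[-1]
    origin = frozenset().union(
        *(lids for (k, lids), d in zip(ordered, dates) if d == first_date)
    )
    terminal = frozenset().union(
        *(lids for (k, lids), d in zip(ordered, dates) if d == last_date)
    )
    return PropagationTrace(
        sentence_id=sentence_id,
        timeline=tuple((k, frozenset(lids)) for k, lids in ordered),
        origin_set=origin,
        terminal_set=terminal,
        first_date=first_date,
        last_date=last_date,
    )


def occurrence_timeline(index: OccurrenceIndex, sentence_id: int) -> dict[str, int]:
    """Per-release count of lineages carrying the sentence, in date order."""
    trace = build_trace(index, sentence_id)
    return {key: len(lids) for key, lids in trace.timeline}


def _is_extant(index: OccurrenceIndex, sentence_id: int) -> bool:
    last = index.calendar.last_date
    return any(
        index.calendar.get(rkey).date == last
        for _, rkey in index.occurrences_of(sentence_id)
    )


def _loss_date(
    index: OccurrenceIndex, occs_by_lineage: Mapping[int, list[str]], lid: int
) -> datetime.date | None:
    """Date at which lineage ``lid`` observably lost the sentence.

    The lineage's last occurrence may span both databases (on a shared
    date); loss is observed once every such database has published a later
    release without the sentence.  Returns ``None`` when some database has
    no later release, i.e. the loss cannot (yet) be observed.
    """
    releases = [index.calendar.get(k) for k in occs_by_lineage[lid]]
    last = max(r.date for r in releases)
    loss: datetime.date | None = None
    for db in {r.database for r in releases if r.date == last}:
        later = [r for r in index.calendar.for_database(db) if r.date > last]
        if not later:
            return None
        first_later = min(later, key=lambda r: r.date)
        if loss is None or first_later.date > loss:
            loss = first_later.date
    return loss


def detect_missing_origin(index: OccurrenceIndex) -> list[PatternHit]:
    """Sentences absent from every origin lineage yet retained elsewhere.

    Flags a sentence when its origin and terminal lineage sets are
    disjoint *and* some non-origin lineage still carried it at a release
    dated at or after the point every origin lineage had observably lost
    it.  Evidence lists those retaining occurrences.
    """
    hits: list[PatternHit] = []
    for sid in range(index.n_sentences):
        trace = build_trace(index, sid)
        if trace.origin_set & trace.terminal_set:
            continue
        occs = index.occurrences_of(sid)
        by_lineage: dict[int, list[str]] = defaultdict(list)
        for lid, rkey in occs:
            by_lineage[lid].append(rkey)
        losses = [_loss_date(index, by_lineage, lid) for lid in trace.origin_set]
        if any(loss is None for loss in losses):
            continue
        loss_all = max(losses)  # type: ignore[type-var]
        evidence = sorted(
            (lid, rkey)
            for lid, rkey in occs
            if lid not in trace.origin_set
            and index.calendar.get(rkey).date >= loss_all
        )
        if not evidence:
            continue
        hits.append(
            PatternHit(sid, Pattern.MISSING_ORIGIN, tuple(evidence), _is_extant(index, sid))
        )
    return hits


def detect_reappearing(index: OccurrenceIndex) -> list[PatternHit]:
    """Sentences removed from a lineage and later re-added to it.

    A gap counts only when an archived release of the same database lies
    strictly between two occurrences in the same lineage; missing releases
    of the other database are "no data" and create no gap.  Evidence lists
    the re-appearance occurrences.
    """
    hits: list[PatternHit] = []
    for sid in range(index.n_sentences):
        by_lineage: dict[int, list[Release]] = defaultdict(list)
        for lid, rkey in index.occurrences_of(sid):
            by_lineage[lid].append(index.calendar.get(rkey))
        evidence: list[tuple[int, str]] = []
        for lid, releases in by_lineage.items():
            for db in {r.database for r in releases}:
                present = sorted(
                    (r for r in releases if r.database is db), key=lambda r: r.date
                )
                present_keys = {r.key for r in present}
                db_releases = index.calendar.for_database(db)
                for a, b in zip(present, present[1:]):
                    gap = [
                        r
                        for r in db_releases
                        if a.date < r.date < b.date and r.key not in present_keys
                    ]
                    if gap:
                        evidence.append((lid, b.key))
        if evidence:
            hits.append(
                PatternHit(
                    sid,
                    Pattern.REAPPEARING_ENTRY,
                    tuple(sorted(set(evidence))),
                    _is_extant(index, sid),
                )
            )
    return hits


def detect_transient(index: OccurrenceIndex) -> list[PatternHit]:
    """(sentence, lineage) pairs present for exactly one release.

    Requires a later archived release of the same database, so removal is
    observable; an occurrence whose only release is the latest of its
    database is never flagged.
    """
    hits: list[PatternHit] = []
    for sid in range(index.n_sentences):
        by_lineage: dict[int, list[str]] = defaultdict(list)
        for lid, rkey in index.occurrences_of(sid):
            by_lineage[lid].append(rkey)
        evidence: list[tuple[int, str]] = []
        for lid, rkeys in by_lineage.items():
            if len(rkeys) != 1:
                continue
            release = index.calendar.get(rkeys[0])
            if index.calendar.after(release):
                evidence.append((lid, release.key))
        if evidence:
            hits.append(
                PatternHit(
                    sid, Pattern.TRANSIENT, tuple(sorted(evidence)), _is_extant(index, sid)
                )
            )
    return hits


def detect_trembl_origin(index: OccurrenceIndex) -> list[PatternHit]:
    """Sentences originating in TrEMBL and later appearing in Swiss-Prot.

    All earliest-dated occurrences must be TrEMBL ones; a first appearance
    shared with the Swiss-Prot half of a synchronised release leaves the
    origin ambiguous and is not flagged.  Evidence lists the TrEMBL origin
    occurrences followed by the earliest Swiss-Prot occurrences.
    """
    hits: list[PatternHit] = []
    for sid in range(index.n_sentences):
        occs = [(lid, index.calendar.get(rkey)) for lid, rkey in index.occurrences_of(sid)]
        first_date = min(r.date for _, r in occs)
        origin_occs = [(lid, r) for lid, r in occs if r.date == first_date]
        if any(r.database is not Database.TREMBL for _, r in origin_occs):
            continue
        sp_occs = [(lid, r) for lid, r in occs if r.database is Database.SWISSPROT]
        if not sp_occs:
            continue
        first_sp = min(r.date for _, r in sp_occs)
        evidence = sorted((lid, r.key) for lid, r in origin_occs) + sorted(
            (lid, r.key) for lid, r in sp_occs if r.date == first_sp
        )
        hits.append(
            PatternHit(sid, Pattern.TREMBL_ORIGIN, tuple(evidence), _is_extant(index, sid))
        )
    return hits


_DETECTORS = {
    Pattern.MISSING_ORIGIN: detect_missing_origin,
    Pattern.REAPPEARING_ENTRY: detect_reappearing,
    Pattern.TRANSIENT: detect_transient,
    Pattern.TREMBL_ORIGIN: detect_trembl_origin,
}


def detect_all(index: OccurrenceIndex) -> dict[Pattern, list[PatternHit]]:
    """Run all four detectors."""
    return {pattern: detector(index) for pattern, detector in _DETECTORS.items()}


def pattern_summary(hits: Mapping[Pattern, Sequence[PatternHit]]) -> dict[str, dict[str, int]]:
    """Per-pattern sentence counts, total and still-extant."""
    return {
        pattern.value: {
            "n_sentences": len(pattern_hits),
            "n_extant": sum(1 for h in pattern_hits if h.extant),
        }
        for pattern, pattern_hits in hits.items()
    }


def write_pattern_report(
    index: OccurrenceIndex,
    hits: Iterable[PatternHit],
    path: str | Path,
) -> None:
    """TSV report: one row per (sentence, pattern) hit."""
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            [
                "sentence_text",
                "pattern",
                "n_entries_ever",
                "first_release",
                "last_release",
                "extant_flag",
                "evidence",
            ]
        )
        for hit in hits:
            trace = build_trace(index, hit.sentence_id)
            writer.writerow(
                [
                    index.sentence_text(hit.sentence_id),
                    hit.pattern.value,
                    trace.n_lineages_ever,
                    trace.timeline[0][0],
                    trace.timeline[-1][0],
                    int(hit.extant),
                    json.dumps(
                        [
                            {
                                "accessions": sorted(index.lineage(lid).accessions),
                                "release": rkey,
                            }
                            for lid, rkey in hit.evidence
                        ]
                    ),
                ]
            )


__all__: Sequence[str] = [
    "Pattern",
    "PropagationTrace",
    "PatternHit",
    "build_trace",
    "occurrence_timeline",
    "detect_missing_origin",
    "detect_reappearing",
    "detect_transient",
    "detect_trembl_origin",
    "detect_all",
    "pattern_summary",
    "write_pattern_report",
]
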