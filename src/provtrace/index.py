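"""Sentence occurrence index across releases.

The index is the central container of the analysis: a set of
``(sentence, lineage, release)`` triples stating that a normalised sentence
appeared in an entry at a database release.  Entries are resolved to
*lineages* — the transitive closure of shared-accession links across
releases — so that an entry merge (one primary accession absorbing others
as secondaries) does not look like a removal plus an addition.

From the triples the corpus statistics follow directly: the *total*
(redundant) sentence multiset of a release, its *unique* (distinct) set and
its *singleton* subset (sentences occurring exactly once in the release),
along with per-entry and per-sentence averages and the reuse histogram.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .flatfile import EntryVersion
from .releases import Release, ReleaseCalendar


class ConflictError(ValueError):
    """An accession claimed by two concurrent primary entries in one release."""


@dataclass(frozen=True)
class EntryLineage:
    """All accessions ever associated with one conceptual entry."""

    lineage_id: int
    accessions: frozenset[str]
    first_release: Release


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        root = x
        while self.parent.setdefault(root, root) != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


class OccurrenceIndex:
    """Bidirectional map sentence <-> (lineage, release).  Built by
    :func:`build_index`; treat instances as immutable."""

    def __init__(
        self,
        calendar: ReleaseCalendar,
        sentence_texts: Sequence[str],
        lineages: Sequence[EntryLineage],
        occurrences: frozenset[tuple[int, int, str]],
        entry_counts: Mapping[str, tuple[int, int]],
    ) -> None:
        self.calendar = calendar
        self._sentence_texts = tuple(sentence_texts)
        self._sentence_ids = {t: i for i, t in enumerate(self._sentence_texts)}
        self.lineages = tuple(lineages)
        self._lineage_of_accession = {
            acc: lin.lineage_id for lin in self.lineages for acc in lin.accessions
        }
        self.occurrences = occurrences
        self.entry_counts = dict(entry_counts)
        self._by_release: dict[str, set[tuple[int, int]]] = defaultdict(set)
        self._by_sentence: dict[int, set[tuple[int, str]]] = defaultdict(set)
        for sid, lid, rkey in occurrences:
            self._by_release[rkey].add((sid, lid))
            self._by_sentence[sid].add((lid, rkey))

    # -- identity lookups -------------------------------------------------

    def sentence_id(self, text: str) -> int:
        try:
            return self._sentence_ids[text]
        except KeyError:
            raise KeyError(f"sentence not indexed: {text!r}") from None

    def sentence_text(self, sentence_id: int) -> str:
        return self._sentence_texts[sentence_id]

    @property
    def n_sentences(self) -> int:
        return len(self._sentence_texts)

    def lineage(self, lineage_id: int) -> EntryLineage:
        return self.lineages[lineage_id]

    def lineage_of(self, accession: str) -> EntryLineage:
        try:
            return self.lineages[self._lineage_of_accession[accession]]
        except KeyError:
            raise KeyError(f"unknown accession {accession!r}") from None

    def pairs_at(self, release: Release | str) -> frozenset[tuple[int, int]]:
        """The (sentence_id, lineage_id) pairs present at one release."""
        key = release.key if isinstance(release, Release) else release
        self.calendar.get(key)  # raises on unknown release
        return frozenset(self._by_release.get(key, set()))

    def occurrences_of(self, sentence_id: int) -> frozenset[tuple[int, str]]:
        """All (lineage_id, release_key) occurrences of one sentence."""
        if sentence_id not in self._by_sentence:
            raise KeyError(f"sentence id {sentence_id} has no occurrences")
        return frozenset(self._by_sentence[sentence_id])

    # -- corpus statistics -------------------------------------------------

    def corpus_counts(self, release: Release | str) -> tuple[int, int, int]:
        """(total, unique, singleton) sentence counts for one release."""
        pairs = self.pairs_at(release)
        total = len(pairs)
        per_sentence = Counter(sid for sid, _ in pairs)
        unique = len(per_sentence)
        singleton = sum(1 for n in per_sentence.values() if n == 1)
        return total, unique, singleton

    def entry_stats(self, release: Release | str) -> tuple[float | None, float | None]:
        """(average sentences per annotated entry, % entries without annotation).

        The average is taken over entries carrying at least one sentence
        only; the percentage over all entries of the release.  Both are
        ``None`` for a release with no entries.
        """
        key = release.key if isinstance(release, Release) else release
        self.calendar.get(key)
        total_entries, annotated = self.entry_counts.get(key, (0, 0))
        if total_entries == 0:
            return None, None
        total_sentences = len(self.pairs_at(key))
        avg = total_sentences / annotated if annotated else None
        pct = 100.0 * (total_entries - annotated) / total_entries
        return avg, pct

    def sentence_stats(self, release: Release | str) -> float | None:
        """Mean number of entries each unique sentence appears in."""
        total, unique, _ = self.corpus_counts(release)
        if unique == 0:
            return None
        return total / unique

    def reuse_histogram(self, release: Release | str) -> dict[int, int]:
        """occurrence count -> number of unique sentences with that count."""
        pairs = self.pairs_at(release)
        per_sentence = Counter(sid for sid, _ in pairs)
        hist = Counter(per_sentence.values())
        return dict(sorted(hist.items()))


def build_index(
    entries: Iterable[EntryVersion],
    calendar: ReleaseCalendar,
) -> OccurrenceIndex:
    """Build the occurrence index from parsed entry versions.

    Lineages are the connected components of the shared-accession graph
    over all releases.  Within a single release an accession may appear in
    only one entry; a concurrent claim raises :class:`ConflictError` naming
    both primaries.  A sentence occurring twice in one entry's text yields
    a single triple — the unit of analysis is "sentence appears in entry".
    """
    by_release: dict[str, list[EntryVersion]] = defaultdict(list)
    for entry in entries:
        if entry.release.key not in calendar:
            raise KeyError(f"entry release {entry.release.key!r} not in calendar")
        by_release[entry.release.key].append(entry)

    uf = _UnionFind()
    first_seen: dict[str, Release] = {}
    ordered_releases = list(calendar)
    for release in ordered_releases:
        claimed: dict[str, str] = {}
        for entry in by_release.get(release.key, []):
            for acc in entry.accessions:
                if acc in claimed and claimed[acc] != entry.primary_accession:
                    raise ConflictError(
                        f"accession {acc} claimed by entries "
                        f"{claimed[acc]} and {entry.primary_accession} "
                        f"in release {release.key}"
                    )
                claimed[acc] = entry.primary_accession
                first_seen.setdefault(acc, release)
                uf.union(entry.primary_accession, acc)

    # Stable lineage numbering: by first appearance, then smallest accession.
    components: dict[str, set[str]] = defaultdict(set)
    for acc in first_seen:
        components[uf.find(acc)].add(acc)
    release_order = {r.key: i for i, r in enumerate(ordered_releases)}

    def component_sort_key(accs: set[str]) -> tuple[int, str]:
        first = min(release_order[first_seen[a].key] for a in accs)
        return first, min(accs)

    lineages: list[EntryLineage] = []
    lineage_of: dict[str, int] = {}
    for accs in sorted(components.values(), key=component_sort_key):
        first_idx = min(release_order[first_seen[a].key] for a in accs)
        lin = EntryLineage(
            lineage_id=len(lineages),
            accessions=frozenset(accs),
            first_release=ordered_releases[first_idx],
        )
        lineages.append(lin)
        for acc in accs:
            lineage_of[acc] = lin.lineage_id

    sentence_ids: dict[str, int] = {}
    occurrences: set[tuple[int, int, str]] = set()
    entry_counts: dict[str, tuple[int, int]] = {}
    for release in ordered_releases:
        rel_entries = by_release.get(release.key, [])
        annotated = 0
        for entry in rel_entries:
            if entry.has_annotation:
                annotated += 1
            lid = lineage_of[entry.primary_accession]
            for sentence in entry.sentences:
                sid = sentence_ids.setdefault(sentence, len(sentence_ids))
                occurrences.add((sid, lid, release.key))
        if rel_entries:
            entry_counts[release.key] = (len(rel_entries), annotated)

    texts = [t for t, _ in sorted(sentence_ids.items(), key=lambda kv: kv[1])]
    return OccurrenceIndex(
        calendar=calendar,
        sentence_texts=texts,
        lineages=lineages,
        occurrences=frozenset(occurrences),
        entry_counts=entry_counts,
    )


STATS_COLUMNS = [
    "release_id",
    "database",
    "date",
    "total",
    "unique",
    "singleton",
    "avg_sentences_per_entry",
    "avg_entries_per_sentence",
    "pct_unannotated",
]


def stats_table(index: OccurrenceIndex) -> pd.DataFrame:
    """Per-release corpus statistics, one row per release in date order."""
    rows = []
    for release in index.calendar:
        total, unique, singleton = index.corpus_counts(release)
        avg_per_entry, pct_unannotated = index.entry_stats(release)
        rows.append(
            {
                "release_id": release.release_id,
                "database": release.database.value,
                "date": release.date.isoformat(),
                "total": total,
                "unique": unique,
                "singleton": singleton,
                "avg_sentences_per_entry": avg_per_entry,
                "avg_entries_per_sentence": index.sentence_stats(release),
                "pct_unannotated": pct_unannotated,
            }
        )
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def write_stats_tsv(index: OccurrenceIndex, path: str | Path) -> None:
    stats_table(index).to_csv(path, sep="\t", index=False)


__all__: Sequence[str] = [
    "ConflictError",
    "EntryLineage",
    "OccurrenceIndex",
    "build_index",
    "stats_table",
    "write_stats_tsv",
    "STATS_COLUMNS",
]
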