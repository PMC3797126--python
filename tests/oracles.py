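"""Brute-force reference implementations of the pattern definitions.

These operate on plain occurrence triples (sentence_text, lineage
accession frozenset, release_key) with naive nested loops, independently
of the package's indexed detectors, and serve as the oracle the detectors
are checked against.
"""

from __future__ import annotations

from provtrace.releases import Database, ReleaseCalendar

Triple = tuple[str, frozenset[str], str]


def _occurrences(triples: set[Triple], calendar: ReleaseCalendar, sentence: str):
    return [
        (lineage, calendar.get(rkey))
        for text, lineage, rkey in triples
        if text == sentence
    ]


def brute_missing_origin(triples: set[Triple], calendar: ReleaseCalendar) -> set[str]:
    hits = set()
    for sentence in {t for t, _, _ in triples}:
        occ = _occurrences(triples, calendar, sentence)
        d_min = min(r.date for _, r in occ)
        d_max = max(r.date for _, r in occ)
        origin = {lin for lin, r in occ if r.date == d_min}
        terminal = {lin for lin, r in occ if r.date == d_max}
        if origin & terminal:
            continue
        observable = True
        losses = []
        for lineage in origin:
            last = max(r.date for lin, r in occ if lin == lineage)
            dbs = {r.database for lin, r in occ if lin == lineage and r.date == last}
            lineage_loss = None
            for db in dbs:
                later = [r.date for r in calendar.for_database(db) if r.date > last]
                if not later:
                    observable = False
                    break
                nxt = min(later)
                if lineage_loss is None or nxt > lineage_loss:
                    lineage_loss = nxt
            if not observable:
                break
            losses.append(lineage_loss)
        if not observable:
            continue
        loss_all = max(losses)
        if any(lin not in origin and r.date >= loss_all for lin, r in occ):
            hits.add(sentence)
    return hits


def brute_reappearing(triples: set[Triple], calendar: ReleaseCalendar) -> set[str]:
    hits = set()
    for sentence in {t for t, _, _ in triples}:
        occ = _occurrences(triples, calendar, sentence)
        for lineage in {lin for lin, _ in occ}:
            for db in Database:
                dates = sorted(
                    r.date for lin2, r in occ if lin2 == lineage and r.database is db
                )
                if len(dates) < 2:
                    continue
                # a gap anywhere between the first and last presence
                present_dates = set(dates)
                for r in calendar.for_database(db):
                    if dates[0] < r.date < dates[-1] and r.date not in present_dates:
                        hits.add(sentence)
    return hits


def brute_transient(triples: set[Triple], calendar: ReleaseCalendar) -> set[str]:
    hits = set()
    for sentence in {t for t, _, _ in triples}:
        occ = _occurrences(triples, calendar, sentence)
        for lineage in {lin for lin, _ in occ}:
            releases = [r for lin2, r in occ if lin2 == lineage]
            if len(set(r.key for r in releases)) != 1:
                continue
            release = releases[0]
            if any(r.date > release.date for r in calendar.for_database(release.database)):
                hits.add(sentence)
    return hits


def brute_trembl_origin(triples: set[Triple], calendar: ReleaseCalendar) -> set[str]:
    hits = set()
    for sentence in {t for t, _, _ in triples}:
        occ = _occurrences(triples, calendar, sentence)
        d_min = min(r.date for _, r in occ)
        first = [r for _, r in occ if r.date == d_min]
        if all(r.database is Database.TREMBL for r in first) and any(
            r.database is Database.SWISSPROT for _, r in occ
        ):
            hits.add(sentence)
    return hits


BRUTE_DETECTORS = {
    "missing_origin": brute_missing_origin,
    "reappearing_entry": brute_reappearing,
    "transient": brute_transient,
    "trembl_origin": brute_trembl_origin,
}
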