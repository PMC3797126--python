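from __future__ import annotations

import pytest
from hypothesis import settings as _hyp_settings

import provtrace as pt

_hyp_settings.register_profile("deterministic", derandomize=True)
_hyp_settings.load_profile("deterministic")
from provtrace.flatfile import EntryVersion
from provtrace.releases import Database, ReleaseCalendar, make_release
from provtrace.simulate import release_filename


def make_entry(primary, release, sentences=(), secondaries=()):
    """Construct an EntryVersion directly, bypassing the parser."""
    return EntryVersion(
        primary_accession=primary,
        secondary_accessions=frozenset(secondaries),
        release=release,
        raw_cc="",
        comment_text=" ".join(sentences),
        sentences=tuple(sentences),
    )


def sp_calendar(n=4, start_year=2000):
    """Single-database calendar of n annual Swiss-Prot releases v1..vn."""
    return ReleaseCalendar(
        [
            make_release(f"v{i}", Database.SWISSPROT, f"{start_year + i}-01-01")
            for i in range(1, n + 1)
        ]
    )


def build_toy_index(calendar, rows):
    """rows: (release, primary, secondaries, sentences) tuples."""
    entries = [
        make_entry(primary, release, sentences, secondaries)
        for release, primary, secondaries, sentences in rows
    ]
    return pt.build_index(entries, calendar)


def parse_generated(files, calendar):
    entries = []
    for release in calendar:
        text = files[release_filename(release)]
        entries.extend(pt.parse_flatfile(text.splitlines(), release))
    return entries


def index_triples(index):
    """Occurrence triples of an index in manifest form."""
    return {
        (index.sentence_text(sid), index.lineage(lid).accessions, rkey)
        for sid, lid, rkey in index.occurrences
    }


@pytest.fixture(scope="session")
def generated_corpus():
    """One default-calendar synthetic corpus with its index and manifest."""
    config = pt.GeneratorConfig(seed=7)
    files, manifest = pt.generate_corpus(config)
    entries = parse_generated(files, config.calendar)
    index = pt.build_index(entries, config.calendar)
    return config, files, manifest, index
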