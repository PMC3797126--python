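"""Parsing of UniProtKB-style flat-file releases.

Only the line types that matter for sentence provenance are read: ``ID``
(record presence), ``AC`` (primary and secondary accessions), ``DT``
(ignored beyond record structure) and ``CC`` (the free-text comment
annotation).  Records are terminated by ``//``.  The extraction pipeline
mirrors the flat-file comment structure: capture the CC payload verbatim,
strip the line prefix, drop the copyright/licence block and topic headings
and embedded ``key=value;`` properties, rejoin wrapped lines, then segment
and normalise sentences.

The parser is tolerant by default: a malformed record (missing ID or AC
line) is reported with its line number and skipped, so one bad record in a
multi-gigabyte historical archive does not abort a run.  ``strict=True``
turns those reports into exceptions.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

from .releases import Release
from .segment import normalize_sentence, split_sentences

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A structurally invalid flat-file record."""


@dataclass(frozen=True)
class EntryVersion:
    """One database entry as it appeared in one release."""

    primary_accession: str
    secondary_accessions: frozenset[str]
    release: Release
    raw_cc: str
    comment_text: str
    sentences: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.primary_accession in self.secondary_accessions:
            raise ValueError(
                f"{self.primary_accession} listed as its own secondary accession"
            )

    @property
    def accessions(self) -> frozenset[str]:
        """All accessions carried by this entry version."""
        return self.secondary_accessions | {self.primary_accession}

    @property
    def has_annotation(self) -> bool:
        return bool(self.sentences)


#: Phrases marking the CC copyright/licence block.  The block text changed
#: across eras, so detection is by marker phrase plus the dashed rule lines
#: that bound the block, both configurable.
COPYRIGHT_MARKERS: tuple[str, ...] = (
    "Copyrighted",
    "Distributed under",
    "copyright",
    "License",
)

_CC_PREFIX = re.compile(r"^CC( {3}|$| )?")
_DASH_RULE = re.compile(r"^-{5,}\s*$")
_TOPIC_HEADING = re.compile(r"-!-\s+[A-Z][A-Z0-9 ,/'()\-]*:\s*")
_ORPHAN_MARKER = re.compile(r"-!-\s+")
_SUB_HEADING_LINE = re.compile(r"^[A-Za-z][A-Za-z0-9 _/()\-]*:\s*$")
_PROPERTY = re.compile(r"\S+=\S[^;=]*;")
_WS_RUN = re.compile(r"\s+")


def extract_comment_text(
    raw_cc_payload: str,
    copyright_markers: Iterable[str] = COPYRIGHT_MARKERS,
) -> str:
    """Clean an entry's concatenated CC lines down to plain sentence text.

    Removes the ``CC`` line prefix, the copyright/licence block (bounded by
    dashed rule lines or identified by marker phrases), topic headings of
    the form ``-!- LABEL:``, sub-heading lines (``Kinetic parameters:``)
    and ``key=value;`` property tokens, then rejoins line-wrapped text with
    single spaces.  A ``-!-`` marker whose label does not match the heading
    grammar is retained as text (and logged) rather than silently dropped.
    """
    markers = tuple(copyright_markers)
    kept: list[str] = []
    in_copyright = False
    for line in raw_cc_payload.splitlines():
        line = _CC_PREFIX.sub("", line).rstrip()
        stripped = line.strip()
        if _DASH_RULE.match(stripped):
            in_copyright = not in_copyright
            continue
        if in_copyright:
            continue
        if any(marker.lower() in stripped.lower() for marker in markers):
            continue
        if _SUB_HEADING_LINE.match(stripped):
            logger.debug("dropping sub-heading line: %r", stripped)
            continue
        if stripped:
            kept.append(stripped)
    text = " ".join(kept)
    text = _TOPIC_HEADING.sub(" ", text)
    if _ORPHAN_MARKER.search(text):
        logger.debug("retaining non-heading '-!-' marker as text: %r", text)
        text = _ORPHAN_MARKER.sub(" ", text)
    text = _PROPERTY.sub(" ", text)
    return _WS_RUN.sub(" ", text).strip()


_ACCESSION = re.compile(r"([A-Za-z][A-Za-z0-9_.\-]*)\s*;")


def _finish_record(
    lines: list[tuple[int, str]],
    release: Release,
    strict: bool,
    errors: list[str] | None,
    abbreviations: Iterable[str] | None,
) -> EntryVersion | None:
    if not any(line.startswith(("ID", "AC", "DT", "CC")) for _, line in lines):
        return None  # blank or header-only block between terminators
    first_line = lines[0][0]
    has_id = any(line.startswith("ID") for _, line in lines)
    accessions: list[str] = []
    cc_lines: list[str] = []
    for _, line in lines:
        if line.startswith("AC"):
            accessions.extend(_ACCESSION.findall(line[2:]))
        elif line.startswith("CC"):
            cc_lines.append(line)
    if not has_id or not accessions:
        missing = "ID" if not has_id else "AC"
        message = f"record starting at line {first_line}: missing {missing} line"
        if strict:
            raise ParseError(message)
        logger.warning("%s (record skipped)", message)
        if errors is not None:
            errors.append(message)
        return None
    raw_cc = "\n".join(cc_lines)
    comment_text = extract_comment_text(raw_cc)
    sentences = tuple(
        normalize_sentence(raw)
        for raw in split_sentences(comment_text, abbreviations)
    )
    return EntryVersion(
        primary_accession=accessions[0],
        secondary_accessions=frozenset(accessions[1:]),
        release=release,
        raw_cc=raw_cc,
        comment_text=comment_text,
        sentences=sentences,
    )


def parse_flatfile(
    stream: IO[str] | Iterable[str],
    release: Release,
    *,
    strict: bool = False,
    errors: list[str] | None = None,
    abbreviations: Iterable[str] | None = None,
) -> list[EntryVersion]:
    """Parse one release's flat file into :class:`EntryVersion` records.

    Parameters
    ----------
    stream:
        Text lines of the flat file (an open file object works).
    release:
        The release the file belongs to; attached to every entry.
    strict:
        Abort on the first malformed record instead of skipping it.
    errors:
        Optional list collecting the messages for skipped records.
    abbreviations:
        Override the sentence splitter's abbreviation lexicon.
    """
    entries: list[EntryVersion] = []
    current: list[tuple[int, str]] = []
    for lineno, raw_line in enumerate(stream, start=1):
        line = raw_line.rstrip("\n")
        if line.strip() == "//":
            entry = _finish_record(current, release, strict, errors, abbreviations)
            if entry is not None:
                entries.append(entry)
            current = []
        else:
            current.append((lineno, line))
    if any(line.strip() for _, line in current):
        entry = _finish_record(current, release, strict, errors, abbreviations)
        if entry is not None:
            entries.append(entry)
    return entries


def parse_release_file(path: str | Path, release: Release, **kwargs) -> list[EntryVersion]:
    """Open and parse one flat file from disk."""
    with open(path) as handle:
        return parse_flatfile(handle, release, **kwargs)


def write_sentences_tsv(entries: Iterable[EntryVersion], path: str | Path) -> None:
    """Write one release's extracted sentences as a TSV.

    Columns: release_id, primary_accession, sentence_text, sentence_rank
    (1-based position of the sentence within the entry's comment text).
    """
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["release_id", "primary_accession", "sentence_text", "sentence_rank"]
        )
        for entry in entries:
            for rank, sentence in enumerate(entry.sentences, start=1):
                writer.writerow(
                    [entry.release.release_id, entry.primary_accession, sentence, rank]
                )


__all__: Sequence[str] = [
    "EntryVersion",
    "ParseError",
    "COPYRIGHT_MARKERS",
    "extract_comment_text",
    "parse_flatfile",
    "parse_release_file",
    "write_sentences_tsv",
]
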