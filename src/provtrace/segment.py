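"""Sentence segmentation and normalisation for comment text.

Comment annotation is free-text English peppered with biomedical
abbreviations, EC-style reaction strings and unterminated topic fragments
("belongs to the ycf50 family").  The splitter is deliberately rule based:
a full stop ends a sentence unless it closes a known abbreviation, a
single-letter initial, or sits between digits.  The abbreviation lexicon is
configurable so corpora with different conventions can extend it.

Sentences are stored in a single normalised form — lowercased, whitespace
collapsed — so that comparison across entries and releases is case
insensitive.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

#: Default abbreviation lexicon.  Tokens are matched case-insensitively
#: against the text immediately preceding a candidate full stop.
DEFAULT_ABBREVIATIONS: frozenset[str] = frozenset(
    {
        "e.g.",
        "i.e.",
        "et al.",
        "cf.",
        "approx.",
        "ca.",
        "sp.",
        "spp.",
        "subsp.",
        "var.",
        "str.",
        "vs.",
    }
)

_TERMINATOR = re.compile(r"[.!?]")


def _is_abbreviation(text: str, stop: int, lexicon: frozenset[str]) -> bool:
    """True if the terminator at ``text[stop]`` ends an abbreviation."""
    head = text[: stop + 1]
    low = head.lower()
    for abbr in lexicon:
        if low.endswith(abbr):
            # Require a word boundary before the abbreviation so that e.g.
            # "wasp." is not swallowed by "sp.".
            start = len(low) - len(abbr)
            if start == 0 or not low[start - 1].isalnum():
                return True
    # Single-letter initials: "J. Smith", "c.elegans".
    if re.search(r"(?:^|[\s(])\w\.$", head):
        return True
    return False


def _digit_adjacent(text: str, stop: int) -> bool:
    """True for decimal points such as "1.5" (digit on both sides)."""
    return (
        stop > 0
        and text[stop - 1].isdigit()
        and stop + 1 < len(text)
        and text[stop + 1].isdigit()
    )


def split_sentences(
    clean_text: str,
    abbreviations: Iterable[str] | None = None,
) -> list[str]:
    """Segment cleaned comment text into raw sentence strings.

    A sentence ends at ``.``, ``!`` or ``?`` followed by whitespace or the
    end of the text, except inside abbreviations, initials or decimal
    numbers.  A trailing fragment with no terminator (common for topic
    blocks and list items) counts as one sentence.  Empty input yields an
    empty list.
    """
    lexicon = (
        frozenset(a.lower() for a in abbreviations)
        if abbreviations is not None
        else DEFAULT_ABBREVIATIONS
    )
    text = clean_text.strip()
    if not text:
        return []
    sentences: list[str] = []
    start = 0
    for match in _TERMINATOR.finditer(text):
        stop = match.end() - 1
        nxt = stop + 1
        if nxt < len(text) and not text[nxt].isspace():
            continue  # terminator glued to following text: not a boundary
        if text[stop] == ".":
            if _digit_adjacent(text, stop):
                continue
            if _is_abbreviation(text, stop, lexicon):
                continue
        piece = text[start : stop + 1].strip()
        if piece:
            sentences.append(piece)
        start = stop + 1
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


_WS_RUN = re.compile(r"\s+")


def normalize_sentence(raw: str) -> str:
    """Canonical stored form of a sentence.

    Lowercases, collapses internal whitespace runs to single spaces and
    strips the ends.  Idempotent.  Whitespace-only input raises
    ``ValueError`` — it signals a segmentation bug upstream, not a sentence.
    """
    norm = _WS_RUN.sub(" ", raw).strip().lower()
    if not norm:
        raise ValueError("whitespace-only input is not a sentence")
    return norm


__all__: Sequence[str] = [
    "DEFAULT_ABBREVIATIONS",
    "split_sentences",
    "normalize_sentence",
]
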