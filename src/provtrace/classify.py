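"""Five-way classification of missing-origin sentences.

Whether a propagated sentence left behind by its origin entry is actually
wrong is a curatorial judgement.  The protocol encoded here makes that
judgement reproducible: a four-question decision tree whose answers place
each sentence in one of five classes.

Q1  How many entries did the sentence ever propagate to?  Over the
    feasibility threshold (default 100) it is infeasible to audit
    individually -> TOO_MANY.
Q2  Was the sentence actually propagated between the entries (rather than
    coinciding by chance)?  NO -> ACCURATE (the annotations are
    independent).
Q3  Was the update/removal in the origin entry relevant to the secondary
    entry?  NO -> ACCURATE.
Q4  Did that update affect the accuracy of the secondary entry?
    YES -> ERRONEOUS; NO -> INCONSISTENT (e.g. a grammatical fix that was
    never propagated).

Any consulted question answered UNSURE — not enough evidence for a
confident call — yields POSSIBLY_ERRONEOUS.  Q2–Q4 are inherently human
judgements (they require reading entry context in the version archive);
this module automates the entry count, the tree logic, the
length-stratified sampling of sentences to audit, the class tallies and
the extrapolation of audited fractions to the full pattern population.

A completed audit of 122 missing-origin sentences from the 2012_05-era
UniProtKB corpus ships with the package (``load_bundled_audit``) as a
worked dataset for the tally and extrapolation arithmetic.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class Answer(enum.Enum):
    YES = "yes"
    NO = "no"
    UNSURE = "unsure"


class Klass(enum.Enum):
    ERRONEOUS = "erroneous"
    INCONSISTENT = "inconsistent"
    ACCURATE = "accurate"
    TOO_MANY = "too_many"
    POSSIBLY_ERRONEOUS = "possibly_erroneous"


#: Canonical class order used in reports.
CLASS_ORDER: tuple[Klass, ...] = (
    Klass.ERRONEOUS,
    Klass.INCONSISTENT,
    Klass.ACCURATE,
    Klass.TOO_MANY,
    Klass.POSSIBLY_ERRONEOUS,
)


@dataclass(frozen=True)
class ProtocolAnswers:
    """Inputs to the decision tree.

    Answers beyond the first decisive question may be omitted (``None``);
    a ``None`` at a question the tree actually consults is an error, since
    it is indistinguishable from an unfinished audit.
    """

    n_entries: int
    q2_propagated: Answer | None = None
    q3_update_relevant: Answer | None = None
    q4_affects_accuracy: Answer | None = None

    def __post_init__(self) -> None:
        if self.n_entries < 1:
            raise ValueError("n_entries must be >= 1")


class IncompleteAnswersError(ValueError):
    """A consulted protocol question has no recorded answer."""


def classify_sentence(
    answers: ProtocolAnswers, too_many_threshold: int = 100
) -> Klass:
    """Deterministic five-way classification from protocol answers."""
    if answers.n_entries > too_many_threshold:
        return Klass.TOO_MANY
    consulted = [
        ("q2_propagated", answers.q2_propagated),
        ("q3_update_relevant", answers.q3_update_relevant),
        ("q4_affects_accuracy", answers.q4_affects_accuracy),
    ]
    for name, answer in consulted:
        if answer is None:
            raise IncompleteAnswersError(f"question {name} was consulted but not answered")
        if answer is Answer.UNSURE:
            return Klass.POSSIBLY_ERRONEOUS
        if name in ("q2_propagated", "q3_update_relevant") and answer is Answer.NO:
            return Klass.ACCURATE
        if name == "q4_affects_accuracy":
            return Klass.ERRONEOUS if answer is Answer.YES else Klass.INCONSISTENT
    raise AssertionError("unreachable")  # pragma: no cover


def sample_for_analysis(
    sentences: Iterable[str],
    min_len: int = 20,
    step: int = 100,
) -> list[str]:
    """Length-stratified systematic sample of sentences to audit.

    Sentences longer than ``min_len`` characters are sorted by length
    (ties broken by text, so the sample is invariant to input order) and
    every ``step``-th one is selected, starting at rank ``step``.  The
    length cut removes short-fragment bias: longer sentences carry more
    information content and are the ones worth auditing.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    qualifying = sorted(
        (s for s in sentences if len(s) > min_len), key=lambda s: (len(s), s)
    )
    return qualifying[step - 1 :: step]


@dataclass(frozen=True)
class ClassificationRecord:
    sentence: str
    klass: Klass
    answers: ProtocolAnswers | None = None


def _round_half_up(value: Decimal, exponent: str) -> Decimal:
    return value.quantize(Decimal(exponent), rounding=ROUND_HALF_UP)


def extrapolate(count: int, n_analysed: int, base_total: int) -> int:
    """Scale an audited class count to the full population.

    round-half-up of ``count / n_analysed * base_total``.
    """
    if n_analysed < 1:
        raise ValueError("n_analysed must be >= 1")
    if not 0 <= count <= n_analysed:
        raise ValueError("count must lie in [0, n_analysed]")
    value = Decimal(count) * Decimal(base_total) / Decimal(n_analysed)
    return int(_round_half_up(value, "1"))


@dataclass(frozen=True)
class TallyReport:
    """Class counts, one-decimal percentages and optional extrapolations."""

    counts: Mapping[Klass, int]
    n_analysed: int
    percentages: Mapping[Klass, float] | None
    extrapolations: Mapping[Klass, int] | None
    base_total: int | None

    def to_dict(self) -> dict:
        out: dict = {
            "n_analysed": self.n_analysed,
            "counts": {k.value: self.counts[k] for k in CLASS_ORDER},
        }
        if self.percentages is not None:
            out["percentages"] = {k.value: self.percentages[k] for k in CLASS_ORDER}
        if self.extrapolations is not None:
            out["base_total"] = self.base_total
            out["extrapolations"] = {
                k.value: self.extrapolations[k] for k in CLASS_ORDER
            }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def tally(
    records: Iterable[ClassificationRecord],
    base_total: int | None = None,
) -> TallyReport:
    """Count classes, compute percentages and (optionally) extrapolate.

    Percentages are round-half-up to one decimal.  With ``base_total``
    given, each class count is extrapolated to that population size.
    Empty input yields all-zero counts with absent percentages.
    """
    counts = {k: 0 for k in CLASS_ORDER}
    for record in records:
        counts[record.klass] += 1
    n = sum(counts.values())
    percentages = None
    extrapolations = None
    if n > 0:
        percentages = {
            k: float(_round_half_up(Decimal(counts[k]) * 100 / Decimal(n), "0.1"))
            for k in CLASS_ORDER
        }
        if base_total is not None:
            extrapolations = {
                k: extrapolate(counts[k], n, base_total) for k in CLASS_ORDER
            }
    return TallyReport(
        counts=counts,
        n_analysed=n,
        percentages=percentages,
        extrapolations=extrapolations,
        base_total=base_total if extrapolations is not None else None,
    )


# -- audit file I/O --------------------------------------------------------


def read_classifications_tsv(path: str | Path) -> list[ClassificationRecord]:
    """Read (sentence, classification) rows from a TSV."""
    records = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            records.append(
                ClassificationRecord(
                    sentence=row["sentence"], klass=Klass(row["classification"])
                )
            )
    return records


def read_answers_tsv(
    path: str | Path, too_many_threshold: int = 100
) -> list[ClassificationRecord]:
    """Read an audit answers TSV and classify each row.

    Columns: sentence, n_entries, q2, q3, q4 (q columns yes/no/unsure,
    blank when not consulted).
    """
    def parse(cell: str | None) -> Answer | None:
        cell = (cell or "").strip().lower()
        return Answer(cell) if cell else None

    records = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            answers = ProtocolAnswers(
                n_entries=int(row["n_entries"]),
                q2_propagated=parse(row.get("q2")),
                q3_update_relevant=parse(row.get("q3")),
                q4_affects_accuracy=parse(row.get("q4")),
            )
            records.append(
                ClassificationRecord(
                    sentence=row["sentence"],
                    klass=classify_sentence(answers, too_many_threshold),
                    answers=answers,
                )
            )
    return records


def write_classification_report(
    records: Iterable[ClassificationRecord], path: str | Path
) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["sentence", "classification"])
        for record in records:
            writer.writerow([record.sentence, record.klass.value])


def load_bundled_audit() -> list[ClassificationRecord]:
    """The bundled 122-sentence missing-origin audit (2012_05-era corpus)."""
    ref = resources.files("provtrace.data").joinpath("audit_2012_missing_origin.tsv")
    with resources.as_file(ref) as path:
        return read_classifications_tsv(path)


__all__: Sequence[str] = [
    "Answer",
    "Klass",
    "CLASS_ORDER",
    "ProtocolAnswers",
    "IncompleteAnswersError",
    "ClassificationRecord",
    "TallyReport",
    "classify_sentence",
    "sample_for_analysis",
    "tally",
    "extrapolate",
    "read_classifications_tsv",
    "read_answers_tsv",
    "write_classification_report",
    "load_bundled_audit",
]
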