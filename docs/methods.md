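# Methods

This note records how `provtrace` models sentence provenance, the
decisions taken where the problem is genuinely underdetermined, and what
the synthetic corpora do and do not establish about real archives.

## Units of analysis

**Sentence.** The unit of annotation reuse is the normalised sentence:
lowercased, whitespace-collapsed comment text. Comparison is therefore
case-insensitive and the original casing is not retained. Segmentation
is rule-based: a sentence ends at `.`/`!`/`?` followed by whitespace,
except when the full stop closes a lexicon abbreviation ("e.g.",
"approx.", "et al.", …), a single-letter initial ("E. coli") or a
decimal ("1.5"). Topic blocks and list items without a terminal stop
count as one sentence. The lexicon is configurable; corpora whose
conventions differ can extend it. Exact sentence counts on pathological
inputs (nested semicolon lists, interaction-line dumps) are governed by
this lexicon and are not expected to match any other segmenter
bit-for-bit.

**Comment cleaning.** The `CC` payload is cleaned line-wise first
(copyright/licence block bounded by dashed rules or identified by marker
phrases; sub-heading lines such as `Kinetic parameters:`), then joined —
rejoining the flat file's hard line-wraps with single spaces — and
cleaned text-wise (topic headings matching `-!- UPPERCASE LABEL:`;
`key=value;` property tokens). A `-!-` marker whose label does not match
the heading grammar is retained as text and logged rather than silently
dropped: losing words is worse than keeping an odd label.

**Lineage.** Entries are identified by the transitive closure of
shared-accession links across all releases of both database sections
(union–find over every entry version's primary + secondary accessions).
This is what makes merge events invisible to the detectors: when entry B
is absorbed into A, both map to one lineage for the entire timeline, so
the move of a sentence from B's record to A's is continuity, not
removal-plus-addition. An accession claimed by two concurrent primary
entries within one release is a hard error — it would make lineage
assignment ambiguous.

**Release calendar.** Releases are data (id, database section, date,
era), not code. Dates must strictly increase within a database;
post-consortium release ids must name a same-dated pair. Every absence
judgement in the package is made against this calendar: a date at which
a database published nothing is "no data", never absence. This is the
calendar-correctness guard against the striping artefact of the
unsynchronised early era.

## Corpus statistics

Per release: *total* is the number of distinct (sentence, lineage) pairs
— a sentence repeated inside one entry's text counts once, because the
unit of interest is "sentence appears in entry"; *unique* is the number
of distinct sentences; *singleton* the number with exactly one pair.
The sentences-per-entry average is taken over annotated entries only
(entries with no comment text are excluded from the numerator's
denominator but counted in the unannotated percentage). The
entries-per-sentence average is the unweighted mean over unique
sentences, i.e. total/unique. One consequence of lineage-global
resolution: two same-release entries that are merged in a *later*
release already share a lineage, so a sentence common to both counts one
pair in that earlier release. This keeps every statistic consistent with
the occurrence triples the detectors consume.

## Pattern definitions

Let `occ(s)` be the occurrence set of sentence *s*, `d_min`/`d_max` its
earliest/latest occurrence dates, `first(s)`/`last(s)` the lineage sets
at those dates.

**Missing origin.** Flagged iff `first(s) ∩ last(s) = ∅` *and* the copy
demonstrably outlived the origin: for each origin lineage, its loss
becomes observable at the first same-database release after its last
occurrence (if the lineage's last occurrence spans both sections of a
shared date, every such section must publish a later release — otherwise
the loss is unobservable and the sentence is not flagged); some
non-origin occurrence must be dated at or after the latest of these loss
dates. Both historical and still-extant hits are flagged, distinguished
by an `extant` marker (present at the calendar's final date). Origins
may span multiple lineages — at major-release granularity a sentence can
genuinely first appear in several entries at once.

**Reappearing entry.** For some lineage and database section, an
archived release lies strictly between two occurrences and lacks the
sentence. Gaps are evaluated per section, so the other section's release
dates never create them.

**Transient.** A (sentence, lineage) pair occurring at exactly one
release, where a later release of that occurrence's database exists.
Occurrences confined to a database's latest release are never flagged:
removal cannot yet be observed.

**TrEMBL origin.** All occurrences at `d_min` are TrEMBL occurrences and
a Swiss-Prot occurrence exists later. A first appearance shared between
both halves of a synchronised release leaves the origin ambiguous and is
not flagged.

One hit is recorded per (sentence, pattern); evidence lists all
supporting (lineage, release) occurrences. Counting is per sentence, not
per event, so a sentence that reappears in three lineages is one
reappearing hit with three evidence groups.

## Classification protocol

The decision tree is total over its answer space: over the feasibility
threshold (default 100 entries — above that, per-entry auditing is
impractical) → too-many-results; not propagated → accurate (independent
coincidence); origin update not relevant to the copy → accurate; update
affects the copy's accuracy → erroneous, otherwise inconsistent. An
UNSURE at any consulted question yields possibly-erroneous — the class
for audits without enough evidence for a confident call. A missing
(rather than UNSURE) answer at a consulted question is an error, since
it is indistinguishable from an unfinished audit. Questions 2–4 are
irreducibly human judgements made by reading entry context in the
version archive; the package automates the entry count, the tree, the
sampling and the arithmetic.

Sampling sorts by (length, text) — the text tie-break makes the sample
invariant to input order — and selects ranks step, 2·step, …, starting
at rank = step. Percentages are round-half-up to one decimal;
extrapolations are round-half-up to the nearest integer of
`count / n_analysed × base`. Round-half-up (via `decimal`, not binary
floats) reproduces every published cell of the audit this package ships,
including the pair 1/32 → 3.1% (0.025 below the tie, so rounded down)
and 10/32 → 31.3% (an exact tie, rounded up) that naive banker's
rounding would get half wrong.

The bundled audit (`provtrace/data/audit_2012_missing_origin.tsv`) is a
completed 122-sentence classification of a 2012_05-era missing-origin
population, used as the worked input for tally and extrapolation. Its
extrapolation bases are 8355 (all-versions population) and 3835 (the
extant subpopulation).

## Synthetic corpora

The generator emulates the curation behaviours the analysis depends on:
verbatim sentence copying within a database section (per-entry,
per-release copy probability, default 0.25), database growth (12 initial
entries per section, 3 new per release), entries without any comment
text (15% in the reviewed section, 50% in the automated one, mirroring
the large historical gap between the two), same-section entry merges,
and an early unsynchronised calendar followed by synchronised pairs.
Sentences come from per-section template pools salted with the
segmenter's hard cases (abbreviations, decimals, unterminated topic
fragments); at most one unterminated sentence per entry, rendered last,
so segmentation of the emitted file is unambiguous.

Three structural choices make the manifest exact rather than
approximate: background sentences are never removed once added, pools
and copying/merging never cross sections, and each planted pattern
instance uses a dedicated sentence and dedicated entries scheduled so it
satisfies exactly one pattern definition (e.g. a planted missing-origin
sentence stays in its origin for two releases so it cannot double as a
transient). Under these conditions detector output must equal the
planted labels exactly, and the tests assert precisely that, alongside
an independent brute-force enumeration of each definition.

What passing does **not** show: real archives contain OCR-era format
drift, topic-heading vocabularies and property syntaxes beyond those
emulated, annotation deletions in the background (not only in planted
patterns), and cross-section merges (TrEMBL entries promoted into
Swiss-Prot). The detectors handle cross-section lineages by
construction, but the generator does not exercise promotion, and
segmentation fidelity on real text is bounded by the abbreviation
lexicon. Corpus sizes are desk-scale (tens of entries, tens of releases,
hundreds of occurrence triples) — chosen so the whole suite and the
acceptance script run in seconds; the algorithms are linear-ish in the
number of occurrence triples and have been kept free of per-pair
quadratic loops so they scale to archive-sized inputs.

## Numerical and degenerate-input conventions

* Statistics of an empty release are (0, 0, 0); averages over zero
  entries or zero unique sentences are reported as absent (`None`/empty
  TSV cell), not zero.
* Whitespace-only "sentences" are rejected at normalisation — they
  indicate a segmentation bug, not data.
* Chart specs serialise with sorted keys; identical inputs give
  byte-identical JSON. Propagation charts cap at 100 lineage categories
  (ordered by first appearance, then accession) with an overflow count
  in the spec options.
* Lineage ids are assigned by (first appearance, smallest accession) so
  index construction is order-independent.
* The malformed-record policy is skip-and-report (with line numbers) by
  default, strict abort on request; a single corrupt record should not
  void a multi-gigabyte archive run.

## Limitations

* Provenance is inferred, not recorded: the earliest occurrence at
  major-release granularity may not be the true origin (minor releases,
  external sources, independent identical phrasings).
* The classification's Q2–Q4 judgements are subjective; the protocol
  makes them reproducible in structure, not in outcome.
* Q1's entry count is the number of lineages the sentence ever occurred
  in (not concurrently) — the audit is about everywhere the sentence
  propagated, not a snapshot.
* Visualisation interactivity is limited to what a standalone HTML page
  with an embedded SVG and chart-spec JSON provides; there is no hosted
  service.
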