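"""Synthetic multi-release flat-file corpora with ground truth.

Historical archives of a real annotation database are gigabytes of
download; everything in this package is therefore testable against
generated corpora that emulate the behaviours the analysis cares about:
sentence copying between entries as a matter of curation protocol, entry
merges that turn primary accessions into secondaries, an unsynchronised
early release calendar for the two database sections, and planted
instances of the four propagation patterns.

The generator guarantees that the manifest's pattern labels are exactly
the detectable ones, by construction:

* background sentences, once added to an entry, persist until the final
  release of their database — so the background can never produce a
  transient, reappearing or missing-origin instance;
* background sentence pools are per-database and copying and merging stay
  within a database — so the background can never produce a
  TrEMBL-origin instance;
* each planted instance uses a dedicated sentence and dedicated entries,
  scheduled so that it triggers its own pattern and no other (e.g. a
  missing-origin sentence stays in its origin for two releases, so it is
  never also transient).

Identical configurations (including the seed) produce byte-identical
files and manifests.
"""

from __future__ import annotations

import json
import random
import textwrap
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .releases import Database, Era, Release, ReleaseCalendar, make_release
from .segment import normalize_sentence

# ---------------------------------------------------------------------------
# calendars


def default_calendar() -> ReleaseCalendar:
    """Three-era calendar: unsynchronised early releases, a numbered
    consortium pair, and a monthly-style pair."""
    return ReleaseCalendar(
        [
            make_release("SP_1", Database.SWISSPROT, "1993-07-01"),
            make_release("TR_1", Database.TREMBL, "1996-11-01"),
            make_release("SP_2", Database.SWISSPROT, "1997-02-01"),
            make_release("TR_2", Database.TREMBL, "1997-07-01"),
            make_release("TR_3", Database.TREMBL, "1998-01-01"),
            make_release("SP_3", Database.SWISSPROT, "1998-07-01"),
            make_release("UPKB_2", Database.SWISSPROT, "2004-07-19", Era.UPKB_MAJOR),
            make_release("UPKB_2", Database.TREMBL, "2004-07-19", Era.UPKB_MAJOR),
            make_release("2012_05", Database.SWISSPROT, "2012-05-16", Era.UPKB_MONTHLY),
            make_release("2012_05", Database.TREMBL, "2012-05-16", Era.UPKB_MONTHLY),
        ]
    )


def small_calendar() -> ReleaseCalendar:
    """Six unsynchronised pre-consortium releases (three per database)."""
    return ReleaseCalendar(
        [
            make_release("SP_1", Database.SWISSPROT, "1995-02-01"),
            make_release("TR_1", Database.TREMBL, "1996-01-01"),
            make_release("SP_2", Database.SWISSPROT, "1996-07-01"),
            make_release("TR_2", Database.TREMBL, "1997-03-01"),
            make_release("SP_3", Database.SWISSPROT, "1997-09-01"),
            make_release("TR_3", Database.TREMBL, "1998-03-01"),
        ]
    )


# ---------------------------------------------------------------------------
# configuration


class ConfigError(ValueError):
    """A planted pattern is unachievable under the configured calendar."""


PATTERNS = ("missing_origin", "reappearing_entry", "transient", "trembl_origin")


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic corpus.

    Defaults are desk-scale: a dozen initial entries per database growing
    by a few per release, a per-database pool of reusable sentences, a
    25% chance per entry per release of copying a sentence in from
    another entry, two merge events, and a handful of planted instances
    of each propagation pattern.  Unannotated-entry fractions differ by
    database, mirroring the manually curated section being far better
    annotated than the automated one.
    """

    seed: int = 0
    calendar: ReleaseCalendar = field(default_factory=default_calendar)
    n_entries: int = 12
    n_new_per_release: int = 3
    sentence_pool_size: int = 40
    copy_probability: float = 0.25
    merge_events: int = 2
    max_sentences_per_entry: int = 4
    unannotated_fraction: Mapping[Database, float] = field(
        default_factory=lambda: {Database.SWISSPROT: 0.15, Database.TREMBL: 0.5}
    )
    planted: Mapping[str, int] = field(
        default_factory=lambda: {
            "missing_origin": 3,
            "reappearing_entry": 2,
            "transient": 3,
            "trembl_origin": 2,
        }
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.copy_probability <= 1.0:
            raise ConfigError("copy_probability must lie in [0, 1]")
        for db, frac in self.unannotated_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigError(f"unannotated_fraction[{db}] must lie in [0, 1]")
        unknown = set(self.planted) - set(PATTERNS)
        if unknown:
            raise ConfigError(f"unknown planted pattern(s): {sorted(unknown)}")


# ---------------------------------------------------------------------------
# manifest


@dataclass
class Manifest:
    """Ground truth emitted alongside a generated corpus.

    ``occurrences`` holds (sentence_text, lineage_accessions, release_key)
    triples with lineages resolved over the whole corpus, matching the
    semantics of the occurrence index.
    """

    occurrences: set[tuple[str, frozenset[str], str]]
    pattern_labels: dict[str, list[str]]  # pattern -> sorted sentence texts
    per_release_counts: dict[str, tuple[int, int, int]]  # total/unique/singleton
    entry_counts: dict[str, tuple[int, int]]  # total entries / annotated
    merge_map: dict[str, str]  # absorbed primary -> surviving primary

    def sentence_timeline(self, sentence: str) -> dict[str, int]:
        """release_key -> number of lineages carrying the sentence."""
        per_release: dict[str, set[frozenset[str]]] = defaultdict(set)
        for text, lineage, rkey in self.occurrences:
            if text == sentence:
                per_release[rkey].add(lineage)
        return {k: len(v) for k, v in per_release.items()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "occurrences": sorted(
                [text, sorted(lineage), rkey]
                for text, lineage, rkey in self.occurrences
            ),
            "pattern_labels": self.pattern_labels,
            "per_release_counts": {k: list(v) for k, v in self.per_release_counts.items()},
            "entry_counts": {k: list(v) for k, v in self.entry_counts.items()},
            "merge_map": self.merge_map,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Manifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            occurrences={
                (text, frozenset(lineage), rkey)
                for text, lineage, rkey in payload["occurrences"]
            },
            pattern_labels=payload["pattern_labels"],
            per_release_counts={
                k: tuple(v) for k, v in payload["per_release_counts"].items()
            },
            entry_counts={k: tuple(v) for k, v in payload["entry_counts"].items()},
            merge_map=payload["merge_map"],
        )


# ---------------------------------------------------------------------------
# sentence pools

_TERMINATED_TEMPLATES = [
    "may have an essential function in {a} biosynthesis.",
    "inactivated by {a} under physiological conditions.",
    "catalyzes the conversion of {a} to {b} (by similarity).",
    "interacts with {a} and modulates its downstream signalling.",
    "binds approx. 1.5 {a} ions per subunit.",
    "required for the assembly of the {a} complex, i.e. the core particle.",
    "expressed in several tissues, e.g. liver and {a} glands.",
    "the active-site {a} is encoded by the opal codon, uga.",
    "phosphorylated on serine residues in response to {a} treatment.",
    "component of the {a} pathway together with {b} homologues.",
    "acts as a repressor of {a} transcription in vivo.",
    "secreted in {a} during the early developmental stages.",
    "localizes to the {a} membrane via its n-terminal anchor.",
    "its expression is induced approx. 2.5-fold by {a} stress.",
    "forms a heterodimer with {a} through disulfide bonds.",
]

_TAIL_TEMPLATES = [
    "belongs to the {a} family",
    "to the {a} and the {b} receptors",
]

_FILLERS = [
    "lipopolysaccharide", "cyanide", "selenocysteine", "ferredoxin",
    "ubiquitin", "calmodulin", "thioredoxin", "cellulose", "glucose",
    "laminin", "keratin", "plastocyanin", "methionine", "chitin",
    "heme", "flavin", "biotin", "cobalamin", "arginine", "glycine",
]


def _make_pools(db: Database, size: int) -> tuple[list[str], list[str]]:
    """Deterministic per-database pools of (terminated, tail) sentences."""
    tag = "sp" if db is Database.SWISSPROT else "tr"
    terminated: list[str] = []
    i = 0
    while len(terminated) < size:
        template = _TERMINATED_TEMPLATES[i % len(_TERMINATED_TEMPLATES)]
        a = _FILLERS[i % len(_FILLERS)]
        b = _FILLERS[(i * 7 + 3) % len(_FILLERS)]
        sentence = template.format(a=f"{a}-{tag}{i // len(_TERMINATED_TEMPLATES)}", b=b)
        terminated.append(sentence)
        i += 1
    tails = [
        _TAIL_TEMPLATES[j % len(_TAIL_TEMPLATES)].format(
            a=f"{_FILLERS[j % len(_FILLERS)]}-{tag}{j}", b=f"ycf{j}"
        )
        for j in range(max(4, size // 8))
    ]
    return terminated, tails


# ---------------------------------------------------------------------------
# generator internals


@dataclass
class _Entry:
    primary: str
    database: Database
    secondaries: set[str] = field(default_factory=set)
    sentences: list[str] = field(default_factory=list)  # terminated, ordered
    tail: str | None = None
    alive: bool = True
    background: bool = True

    @property
    def all_sentences(self) -> list[str]:
        return self.sentences + ([self.tail] if self.tail else [])

    @property
    def accessions(self) -> set[str]:
        return {self.primary} | self.secondaries


@dataclass
class _PlantOp:
    kind: str  # "add" | "remove"
    accession: str
    sentence: str


class _Generator:
    def __init__(self, config: GeneratorConfig) -> None:
        self.config = config
        self.rng = random.Random(config.seed)
        self.calendar = config.calendar
        self.entries: dict[str, _Entry] = {}
        self.pools: dict[Database, tuple[list[str], list[str]]] = {
            db: _make_pools(db, config.sentence_pool_size) for db in Database
        }
        self._acc_counter = 0
        self.merge_map: dict[str, str] = {}
        self.pattern_labels: dict[str, list[str]] = {p: [] for p in PATTERNS}
        self.plant_ops: dict[str, list[_PlantOp]] = defaultdict(list)
        self._planted_sentence_counter = 0
        self.occurrences: set[tuple[str, str, str]] = set()  # (text, primary, rkey)
        self.entry_counts: dict[str, tuple[int, int]] = {}
        self.files: dict[str, str] = {}

    # -- helpers --------------------------------------------------------

    def _new_accession(self, db: Database) -> str:
        self._acc_counter += 1
        prefix = "P" if db is Database.SWISSPROT else "Q"
        return f"{prefix}{self._acc_counter:05d}"

    def _new_entry(self, db: Database, background: bool = True) -> _Entry:
        entry = _Entry(primary=self._new_accession(db), database=db, background=background)
        if background and self.rng.random() < 0.2:
            entry.secondaries.add(self._new_accession(db))
        self.entries[entry.primary] = entry
        return entry

    def _populate_background(self, entry: _Entry) -> None:
        db = entry.database
        if self.rng.random() < self.config.unannotated_fraction[db]:
            return
        terminated, tails = self.pools[db]
        k = self.rng.randint(1, self.config.max_sentences_per_entry)
        entry.sentences = self.rng.sample(terminated, min(k, len(terminated)))
        if self.rng.random() < 0.25:
            entry.tail = self.rng.choice(tails)

    def _planted_sentence(self, pattern: str) -> str:
        self._planted_sentence_counter += 1
        n = self._planted_sentence_counter
        return (
            f"planted {pattern.replace('_', ' ')} sentence {n:03d} "
            f"modulates factor f{n:03d} activity."
        )

    # -- planting -------------------------------------------------------

    def _schedule_patterns(self) -> None:
        db_releases = {db: self.calendar.for_database(db) for db in Database}
        dbs_ge3 = [db for db in Database if len(db_releases[db]) >= 3]
        dbs_ge2 = [db for db in Database if len(db_releases[db]) >= 2]

        for i in range(self.config.planted.get("missing_origin", 0)):
            if not dbs_ge3:
                raise ConfigError(
                    "missing_origin needs a database with >= 3 releases"
                )
            db = dbs_ge3[i % len(dbs_ge3)]
            releases = db_releases[db]
            j = self.rng.randint(0, len(releases) - 3)
            sentence = self._planted_sentence("missing_origin")
            origin = self._new_entry(db, background=False)
            secondary = self._new_entry(db, background=False)
            r0, r1, r2 = releases[j], releases[j + 1], releases[j + 2]
            self.plant_ops[r0.key].append(_PlantOp("add", origin.primary, sentence))
            self.plant_ops[r1.key].append(_PlantOp("add", secondary.primary, sentence))
            self.plant_ops[r2.key].append(_PlantOp("remove", origin.primary, sentence))
            self.pattern_labels["missing_origin"].append(sentence)

        for i in range(self.config.planted.get("reappearing_entry", 0)):
            if not dbs_ge3:
                raise ConfigError(
                    "reappearing_entry needs a database with >= 3 releases"
                )
            db = dbs_ge3[(i + 1) % len(dbs_ge3)]
            releases = db_releases[db]
            j = self.rng.randint(0, len(releases) - 3)
            sentence = self._planted_sentence("reappearing_entry")
            entry = self._new_entry(db, background=False)
            r0, r1, r2 = releases[j], releases[j + 1], releases[j + 2]
            self.plant_ops[r0.key].append(_PlantOp("add", entry.primary, sentence))
            self.plant_ops[r1.key].append(_PlantOp("remove", entry.primary, sentence))
            self.plant_ops[r2.key].append(_PlantOp("add", entry.primary, sentence))
            self.pattern_labels["reappearing_entry"].append(sentence)

        for i in range(self.config.planted.get("transient", 0)):
            if not dbs_ge2:
                raise ConfigError("transient needs a database with >= 2 releases")
            db = dbs_ge2[i % len(dbs_ge2)]
            releases = db_releases[db]
            j = self.rng.randint(0, len(releases) - 2)
            sentence = self._planted_sentence("transient")
            entry = self._new_entry(db, background=False)
            r0, r1 = releases[j], releases[j + 1]
            self.plant_ops[r0.key].append(_PlantOp("add", entry.primary, sentence))
            self.plant_ops[r1.key].append(_PlantOp("remove", entry.primary, sentence))
            self.pattern_labels["transient"].append(sentence)

        for i in range(self.config.planted.get("trembl_origin", 0)):
            sp_releases = db_releases[Database.SWISSPROT]
            feasible = [
                t
                for t in db_releases[Database.TREMBL]
                if any(sp.date > t.date for sp in sp_releases)
            ]
            if not feasible:
                raise ConfigError(
                    "trembl_origin needs a TrEMBL release with a later "
                    "Swiss-Prot release"
                )
            t0 = feasible[self.rng.randrange(len(feasible))]
            sp0 = min(
                (sp for sp in sp_releases if sp.date > t0.date), key=lambda r: r.date
            )
            sentence = self._planted_sentence("trembl_origin")
            tr_entry = self._new_entry(Database.TREMBL, background=False)
            sp_entry = self._new_entry(Database.SWISSPROT, background=False)
            self.plant_ops[t0.key].append(_PlantOp("add", tr_entry.primary, sentence))
            self.plant_ops[sp0.key].append(_PlantOp("add", sp_entry.primary, sentence))
            self.pattern_labels["trembl_origin"].append(sentence)

        for pattern in self.pattern_labels:
            self.pattern_labels[pattern].sort()

    def _schedule_merges(self) -> None:
        self.merge_schedule: dict[str, int] = defaultdict(int)
        candidates = [
            r
            for db in Database
            for r in self.calendar.for_database(db)[1:]
        ]
        for _ in range(self.config.merge_events):
            if not candidates:
                break
            release = self.rng.choice(candidates)
            self.merge_schedule[release.key] += 1

    # -- per-release dynamics -------------------------------------------

    def _alive_background(self, db: Database) -> list[_Entry]:
        return [
            e
            for e in self.entries.values()
            if e.alive and e.background and e.database is db
        ]

    def _apply_merges(self, release: Release) -> None:
        for _ in range(self.merge_schedule.get(release.key, 0)):
            pool = self._alive_background(release.database)
            pairs = [
                (a, b)
                for a in pool
                for b in pool
                if a is not b and (a.tail is None or b.tail is None)
            ]
            if not pairs:
                continue
            survivor, absorbed = self.rng.choice(pairs)
            survivor.secondaries |= absorbed.accessions
            for sentence in absorbed.sentences:
                if sentence not in survivor.sentences:
                    survivor.sentences.append(sentence)
            if survivor.tail is None:
                survivor.tail = absorbed.tail
            absorbed.alive = False
            self.merge_map[absorbed.primary] = survivor.primary

    def _apply_copying(self, release: Release) -> None:
        pool = self._alive_background(release.database)
        donors = [s for e in pool for s in e.sentences]
        if not donors:
            return
        for entry in pool:
            if self.rng.random() < self.config.copy_probability:
                sentence = self.rng.choice(sorted(set(donors)))
                if sentence not in entry.sentences:
                    entry.sentences.append(sentence)

    def _apply_plants(self, release: Release) -> None:
        for op in self.plant_ops.get(release.key, []):
            entry = self.entries[op.accession]
            if op.kind == "add":
                if op.sentence not in entry.sentences:
                    entry.sentences.append(op.sentence)
            else:
                entry.sentences.remove(op.sentence)

    # -- emission --------------------------------------------------------

    def _render_entry(self, entry: _Entry, release: Release) -> str:
        lines: list[str] = []
        status = (
            "Reviewed" if entry.database is Database.SWISSPROT else "Unreviewed"
        )
        name = f"{entry.primary}_SYN"
        lines.append(f"ID   {name:<24}{status};{90 + len(entry.sentences) * 7:>10} AA.")
        accs = [entry.primary] + sorted(entry.secondaries)
        for start in range(0, len(accs), 8):
            chunk = accs[start : start + 8]
            lines.append("AC   " + " ".join(f"{a};" for a in chunk))
        section = (
            "Swiss-Prot" if entry.database is Database.SWISSPROT else "TrEMBL"
        )
        lines.append(
            f"DT   {release.date.strftime('%d-%b-%Y').upper()}, "
            f"integrated into UniProtKB/{section}."
        )
        if entry.all_sentences:
            lines.append("CC   " + "-" * 69)
            lines.append(
                "CC   Copyrighted by the UniProt Consortium, see "
                "https://www.uniprot.org/terms"
            )
            lines.append(
                "CC   Distributed under the Creative Commons Attribution License"
            )
            lines.append("CC   " + "-" * 69)
            if entry.sentences:
                body = " ".join(
                    s[0].upper() + s[1:] for s in entry.sentences
                )
                lines.extend(self._wrap_block(f"-!- FUNCTION: {body}"))
            # deterministic decoy: machine-readable properties to be dropped
            if len(entry.sentences) >= 3:
                lines.append("CC   -!- BIOPHYSICOCHEMICAL PROPERTIES:")
                lines.append("CC       Kinetic parameters:")
                lines.append("CC         KM=1.5 mM for ATP;")
            if entry.tail:
                tail = entry.tail[0].upper() + entry.tail[1:]
                lines.extend(self._wrap_block(f"-!- SIMILARITY: {tail}"))
        lines.append("//")
        return "\n".join(lines)

    @staticmethod
    def _wrap_block(text: str) -> list[str]:
        wrapped = textwrap.wrap(
            text, width=69, break_long_words=False, break_on_hyphens=False
        )
        out = [f"CC   {wrapped[0]}"]
        out.extend(f"CC       {line}" for line in wrapped[1:])
        return out

    def _record_release(self, release: Release) -> None:
        alive = sorted(
            (
                e
                for e in self.entries.values()
                if e.alive and e.database is release.database
            ),
            key=lambda e: e.primary,
        )
        annotated = 0
        for entry in alive:
            norm = [normalize_sentence(s) for s in entry.all_sentences]
            if norm:
                annotated += 1
            for sentence in norm:
                self.occurrences.add((sentence, entry.primary, release.key))
        self.entry_counts[release.key] = (len(alive), annotated)
        records = [self._render_entry(e, release) for e in alive]
        filename = f"{release.database.value}_{release.release_id}.dat"
        self.files[filename] = "\n".join(records) + ("\n" if records else "")

    # -- driver ----------------------------------------------------------

    def run(self) -> tuple[dict[str, str], Manifest]:
        self._schedule_patterns()
        self._schedule_merges()
        seen_db: set[Database] = set()
        for release in self.calendar:
            db = release.database
            if db not in seen_db:
                seen_db.add(db)
                for _ in range(self.config.n_entries):
                    self._populate_background(self._new_entry(db))
            else:
                for _ in range(self.config.n_new_per_release):
                    self._populate_background(self._new_entry(db))
                self._apply_copying(release)
                self._apply_merges(release)
            self._apply_plants(release)
            self._record_release(release)
        return self.files, self._build_manifest()

    def _build_manifest(self) -> Manifest:
        # resolve lineages: merge groups plus each entry's own accessions
        group_of: dict[str, str] = {}

        def find(primary: str) -> str:
            while primary in self.merge_map:
                primary = self.merge_map[primary]
            return primary

        groups: dict[str, set[str]] = defaultdict(set)
        for entry in self.entries.values():
            root = find(entry.primary)
            groups[root] |= entry.accessions
            group_of[entry.primary] = root
        lineage_key = {root: frozenset(accs) for root, accs in groups.items()}

        occurrences = {
            (text, lineage_key[group_of[primary]], rkey)
            for text, primary, rkey in self.occurrences
        }
        per_release: dict[str, tuple[int, int, int]] = {}
        by_release: dict[str, set[tuple[str, frozenset[str]]]] = defaultdict(set)
        for text, lineage, rkey in occurrences:
            by_release[rkey].add((text, lineage))
        for release in self.calendar:
            pairs = by_release.get(release.key, set())
            counts: dict[str, int] = defaultdict(int)
            for text, _ in pairs:
                counts[text] += 1
            per_release[release.key] = (
                len(pairs),
                len(counts),
                sum(1 for n in counts.values() if n == 1),
            )
        return Manifest(
            occurrences=occurrences,
            pattern_labels={p: list(v) for p, v in self.pattern_labels.items()},
            per_release_counts=per_release,
            entry_counts=dict(self.entry_counts),
            merge_map=dict(self.merge_map),
        )


# ---------------------------------------------------------------------------
# public API


def generate_corpus(
    config: GeneratorConfig | None = None,
) -> tuple[dict[str, str], Manifest]:
    """Generate flat files (filename -> text) and the ground-truth manifest."""
    return _Generator(config or GeneratorConfig()).run()


def write_corpus(
    config: GeneratorConfig,
    outdir: str | Path,
) -> tuple[dict[str, Path], Manifest]:
    """Generate and write a corpus: one flat file per release, the release
    calendar as TSV and the manifest as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files, manifest = generate_corpus(config)
    paths: dict[str, Path] = {}
    for name, text in files.items():
        path = outdir / name
        path.write_text(text)
        paths[name] = path
    config.calendar.to_tsv(outdir / "calendar.tsv")
    manifest.to_json(outdir / "manifest.json")
    return paths, manifest


def release_filename(release: Release) -> str:
    return f"{release.database.value}_{release.release_id}.dat"


__all__: Sequence[str] = [
    "ConfigError",
    "GeneratorConfig",
    "Manifest",
    "default_calendar",
    "small_calendar",
    "generate_corpus",
    "write_corpus",
    "release_filename",
    "PATTERNS",
]
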