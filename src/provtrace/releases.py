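"""Release calendars for versioned annotation databases.

UniProtKB history spans three naming eras: unsynchronised pre-consortium
Swiss-Prot and TrEMBL releases, numbered UniProtKB major releases, and the
four-weekly ``YYYY_MM`` cycle.  A :class:`ReleaseCalendar` captures that
history as data (id, database, date, era) so the analysis code never needs
to hard-code any particular numbering scheme.
"""

from __future__ import annotations

import csv
import datetime
import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence


class Database(enum.Enum):
    """The two sections of UniProtKB."""

    SWISSPROT = "swissprot"
    TREMBL = "trembl"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Era(enum.Enum):
    """Release-naming era."""

    PRE_CONSORTIUM = "pre_consortium"
    UPKB_MAJOR = "upkb_major"
    UPKB_MONTHLY = "upkb_monthly"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Release:
    """One archived snapshot of one database section.

    Parameters
    ----------
    release_id:
        Opaque label, e.g. ``"SP_9"``, ``"TR_1"``, ``"UPKB_2"`` or
        ``"2012_05"``.  Post-consortium ids are shared by the Swiss-Prot and
        TrEMBL halves of a synchronised release, so ``(release_id,
        database)`` is the unique key; :attr:`key` exposes it.
    database:
        Which section the snapshot belongs to.
    date:
        Release date.
    era:
        Naming era; pre-consortium releases are unsynchronised between the
        two databases, later eras come in same-dated pairs.
    """

    release_id: str
    database: Database
    date: datetime.date
    era: Era

    @property
    def key(self) -> str:
        """Globally unique identifier (``release_id`` qualified by database)."""
        prefix = "SP" if self.database is Database.SWISSPROT else "TR"
        return f"{prefix}:{self.release_id}"


class CalendarError(ValueError):
    """Raised when a release calendar violates its ordering invariants."""


class ReleaseCalendar:
    """An ordered, validated collection of releases.

    Validation enforces the structural facts the downstream set operations
    rely on: dates strictly increase within each database, and every
    post-consortium release id names a same-dated Swiss-Prot/TrEMBL pair.
    """

    def __init__(self, releases: Iterable[Release]) -> None:
        self._releases: tuple[Release, ...] = tuple(
            sorted(releases, key=lambda r: (r.date, r.database.value, r.release_id))
        )
        self._by_key = {r.key: r for r in self._releases}
        if len(self._by_key) != len(self._releases):
            raise CalendarError("duplicate (release_id, database) in calendar")
        self._validate()

    def _validate(self) -> None:
        for db in Database:
            seq = self.for_database(db)
            for a, b in zip(seq, seq[1:]):
                if a.date >= b.date:
                    raise CalendarError(
                        f"dates must strictly increase within {db.value}: "
                        f"{a.release_id} ({a.date}) !< {b.release_id} ({b.date})"
                    )
        paired: dict[str, list[Release]] = {}
        for r in self._releases:
            if r.era is not Era.PRE_CONSORTIUM:
                paired.setdefault(r.release_id, []).append(r)
        for rid, members in paired.items():
            dbs = {m.database for m in members}
            if dbs != {Database.SWISSPROT, Database.TREMBL}:
                raise CalendarError(
                    f"post-consortium release {rid!r} must pair Swiss-Prot and TrEMBL"
                )
            if len({m.date for m in members}) != 1:
                raise CalendarError(
                    f"post-consortium release {rid!r} halves must share a date"
                )

    # -- access -----------------------------------------------------------

    def __iter__(self) -> Iterator[Release]:
        return iter(self._releases)

    def __len__(self) -> int:
        return len(self._releases)

    def __contains__(self, key: str) -> bool:
        return key in self._by_key

    def get(self, key: str) -> Release:
        try:
            return self._by_key[key]
        except KeyError:
            raise KeyError(f"unknown release {key!r}") from None

    def for_database(self, database: Database) -> tuple[Release, ...]:
        return tuple(r for r in self._releases if r.database is database)

    def after(self, release: Release) -> tuple[Release, ...]:
        """Later releases of the same database, in date order."""
        return tuple(
            r for r in self.for_database(release.database) if r.date > release.date
        )

    @property
    def last_date(self) -> datetime.date:
        if not self._releases:
            raise CalendarError("empty calendar")
        return self._releases[-1].date

    def latest(self, database: Database) -> Release:
        seq = self.for_database(database)
        if not seq:
            raise CalendarError(f"no {database.value} releases in calendar")
        return seq[-1]

    # -- serialisation ----------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReleaseCalendar":
        """Read a calendar from a TSV with columns release_id/database/date/era."""
        releases = []
        with open(path, newline="") as handle:
            for row in csv.DictReader(handle, delimiter="\t"):
                releases.append(
                    Release(
                        release_id=row["release_id"],
                        database=Database(row["database"]),
                        date=datetime.date.fromisoformat(row["date"]),
                        era=Era(row["era"]),
                    )
                )
        return cls(releases)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["release_id", "database", "date", "era"])
            for r in self._releases:
                writer.writerow(
                    [r.release_id, r.database.value, r.date.isoformat(), r.era.value]
                )


def make_release(
    release_id: str,
    database: Database | str,
    date: datetime.date | str,
    era: Era | str = Era.PRE_CONSORTIUM,
) -> Release:
    """Convenience constructor accepting plain strings."""
    if isinstance(database, str):
        database = Database(database)
    if isinstance(date, str):
        date = datetime.date.fromisoformat(date)
    if isinstance(era, str):
        era = Era(era)
    return Release(release_id, database, date, era)


__all__: Sequence[str] = [
    "Database",
    "Era",
    "Release",
    "ReleaseCalendar",
    "CalendarError",
    "make_release",
]
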