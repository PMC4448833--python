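"""Sighting records, individual registries, and survey exclusion filters.

The observational unit is a *sighting*: a timestamped group of
photo-identified individuals engaged in a predominant behavioural state
(socialize / travel / forage / other), plus a count of animals that could
not be identified.  Under the gambit of the group, every pair of identified
members of a sighting is treated as associating.

Two field-protocol filters are applied before any network is built:

* dependent calves are removed from group memberships (they mirror their
  mothers and would bias associations);
* pseudo-replicated groups are removed — a sighting is excluded when any
  member was seen less than an hour earlier the same day, or when every
  member had already been seen that day.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
import statistics
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "Activity",
    "ALL",
    "SightingRecord",
    "SightingTable",
    "IndividualRegistry",
    "SamplingSummary",
    "read_sightings",
    "write_sightings",
    "read_registry",
    "write_registry",
    "filter_dependent_calves",
    "filter_resights",
    "summarize_sampling",
    "select_records",
]


class Activity(str, Enum):
    """Predominant behavioural state of a sighted group."""

    SOCIALIZE = "socialize"
    TRAVEL = "travel"
    FORAGE = "forage"
    OTHER = "other"


#: Sentinel accepted wherever an activity filter is expected: use every record.
ALL = "all"


def _coerce_activity(value: "Activity | str | None") -> "Activity | None":
    """Return an Activity, or None meaning 'all records'."""
    if value is None or value == ALL:
        return None
    return Activity(value)


@dataclass(frozen=True)
class SightingRecord:
    """One sighted group.

    ``members`` holds the photo-identified individuals; ``n_unidentified``
    counts animals present but not identified.  Group size is
    ``len(members) + n_unidentified``.
    """

    sighting_id: str
    date: dt.date
    time: dt.time
    activity: Activity
    members: frozenset[str]
    n_unidentified: int = 0

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"sighting {self.sighting_id!r}: members must be non-empty")
        if self.n_unidentified < 0:
            raise ValueError(
                f"sighting {self.sighting_id!r}: n_unidentified must be >= 0"
            )
        if not isinstance(self.activity, Activity):
            object.__setattr__(self, "activity", Activity(self.activity))
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))

    @property
    def group_size(self) -> int:
        return len(self.members) + self.n_unidentified

    @property
    def minutes(self) -> int:
        """Time of day in minutes since midnight."""
        return self.time.hour * 60 + self.time.minute


@dataclass(frozen=True)
class SightingTable:
    """An ordered collection of sightings, sorted by (date, time).

    Sort is stable, so records sharing a timestamp keep their input order;
    sighting_id values must be unique.
    """

    records: tuple[SightingRecord, ...]

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.records, key=lambda r: (r.date, r.time)))
        object.__setattr__(self, "records", ordered)
        ids = [r.sighting_id for r in ordered]
        if len(set(ids)) != len(ids):
            dup = [i for i, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate sighting_id values: {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SightingRecord]:
        return iter(self.records)

    @property
    def individuals(self) -> frozenset[str]:
        out: set[str] = set()
        for rec in self.records:
            out |= rec.members
        return frozenset(out)


@dataclass(frozen=True)
class IndividualRegistry:
    """Maps individual IDs to life-stage flags (currently: dependent calf)."""

    entries: Mapping[str, bool]

    def is_calf(self, individual_id: str) -> bool:
        try:
            return self.entries[individual_id]
        except KeyError:
            raise KeyError(f"individual {individual_id!r} absent from registry") from None

    @property
    def calves(self) -> frozenset[str]:
        return frozenset(i for i, flag in self.entries.items() if flag)


@dataclass(frozen=True)
class SamplingSummary:
    """Survey-effort summary of a sighting table."""

    n_sightings: int
    n_sampling_days: int
    n_individuals: int
    mean_sightings_per_individual: float
    sd_sightings_per_individual: float
    min_sightings_per_individual: int
    max_sightings_per_individual: int
    mean_prop_identified: float
    sd_prop_identified: float


_COLUMNS = ["sighting_id", "date", "time", "activity", "members", "n_unidentified"]


def read_sightings(path: "str | Path") -> SightingTable:
    """Read a sightings CSV.

    Expected header: ``sighting_id,date,time,activity,members,n_unidentified``
    with ISO dates, 24 h HH:MM times, and semicolon-separated member IDs.
    Unknown activity labels are kept with activity mapped to ``other`` (a
    warning is logged).  Malformed rows raise ValueError naming the row.
    """
    path = Path(path)
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row))
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    return SightingTable(tuple(records))


def _parse_row(row: Mapping[str, str]) -> SightingRecord:
    members_field = (row["members"] or "").strip()
    if not members_field:
        raise ValueError("empty members field")
    members = frozenset(m for m in members_field.split(";") if m)
    if not members:
        raise ValueError("empty members field")
    n_unid = int(row["n_unidentified"])
    if n_unid < 0:
        raise ValueError(f"negative n_unidentified: {n_unid}")
    raw_activity = (row["activity"] or "").strip().lower()
    try:
        activity = Activity(raw_activity)
    except ValueError:
        logger.warning(
            "sighting %s: unknown activity %r mapped to 'other'",
            row["sighting_id"], raw_activity,
        )
        activity = Activity.OTHER
    return SightingRecord(
        sighting_id=row["sighting_id"],
        date=dt.date.fromisoformat(row["date"].strip()),
        time=dt.time.fromisoformat(row["time"].strip()),
        activity=activity,
        members=members,
        n_unidentified=n_unid,
    )


def write_sightings(table: SightingTable, path: "str | Path") -> None:
    """Write a sightings CSV (exact round-trip partner of :func:`read_sightings`)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for rec in table:
            writer.writerow(
                [
                    rec.sighting_id,
                    rec.date.isoformat(),
                    rec.time.strftime("%H:%M"),
                    rec.activity.value,
                    ";".join(sorted(rec.members)),
                    rec.n_unidentified,
                ]
            )


def read_registry(path: "str | Path") -> IndividualRegistry:
    """Read a registry CSV with columns ``individual_id,is_calf`` (0/1)."""
    path = Path(path)
    entries: dict[str, bool] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = {"individual_id", "is_calf"} - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            flag = row["is_calf"].strip()
            if flag not in {"0", "1"}:
                raise ValueError(f"{path}: row {lineno}: is_calf must be 0 or 1")
            entries[row["individual_id"]] = flag == "1"
    return IndividualRegistry(entries)


def write_registry(registry: IndividualRegistry, path: "str | Path") -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual_id", "is_calf"])
        for ind in sorted(registry.entries):
            writer.writerow([ind, int(registry.entries[ind])])


def filter_dependent_calves(
    table: SightingTable, registry: IndividualRegistry
) -> SightingTable:
    """Remove dependent calves from every record's membership.

    Records whose membership becomes empty are dropped.  Every member ID
    must be present in the registry.  Apply this *before*
    :func:`filter_resights`: a record retained only because a calf padded
    its membership must not survive the resight screen.
    """
    for rec in table:
        for ind in rec.members:
            if ind not in registry.entries:
                raise KeyError(f"individual {ind!r} absent from registry")
    calves = registry.calves
    kept: list[SightingRecord] = []
    n_removed = 0
    n_dropped = 0
    for rec in table:
        remaining = rec.members - calves
        n_removed += len(rec.members) - len(remaining)
        if not remaining:
            n_dropped += 1
            continue
        if remaining == rec.members:
            kept.append(rec)
        else:
            kept.append(
                SightingRecord(
                    rec.sighting_id, rec.date, rec.time, rec.activity,
                    remaining, rec.n_unidentified,
                )
            )
    logger.info(
        "calf filter: removed %d memberships, dropped %d empty records",
        n_removed, n_dropped,
    )
    return SightingTable(tuple(kept))


def filter_resights(table: SightingTable) -> SightingTable:
    """Drop within-day pseudo-replicated sightings.

    Scanning in time order, a record is excluded when, relative to the
    records retained so far on the same calendar date, either

    a. any of its members was seen less than 60 minutes earlier, or
    b. every one of its members has already been seen that day.

    Exclusions are judged against retained records only, so an excluded
    sighting does not shadow later ones.  The operation is idempotent.
    """
    kept: list[SightingRecord] = []
    last_seen: dict[tuple[dt.date, str], int] = {}
    seen_today: dict[dt.date, set[str]] = {}
    for rec in table:
        day = seen_today.setdefault(rec.date, set())
        recent = any(
            (rec.date, m) in last_seen and rec.minutes - last_seen[(rec.date, m)] < 60
            for m in rec.members
        )
        if recent or rec.members <= day:
            logger.debug("resight filter: excluding %s", rec.sighting_id)
            continue
        kept.append(rec)
        day |= rec.members
        for m in rec.members:
            last_seen[(rec.date, m)] = rec.minutes
    logger.info("resight filter: retained %d of %d records", len(kept), len(table))
    return SightingTable(tuple(kept))


def select_records(
    table: SightingTable, activity: "Activity | str | None"
) -> tuple[SightingRecord, ...]:
    """Records matching an activity, or all records for ``'all'``/None."""
    act = _coerce_activity(activity)
    if act is None:
        return table.records
    return tuple(r for r in table if r.activity is act)


def summarize_sampling(table: SightingTable) -> SamplingSummary:
    """Survey-effort statistics: per-individual sighting counts and the
    per-record proportion of identified animals.

    Standard deviations are sample SDs (ddof=1; zero when n=1).
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty sighting table")
    counts = Counter(ind for rec in table for ind in rec.members)
    per_ind = sorted(counts.values())
    props = [len(r.members) / r.group_size for r in table]
    return SamplingSummary(
        n_sightings=len(table),
        n_sampling_days=len({r.date for r in table}),
        n_individuals=len(counts),
        mean_sightings_per_individual=statistics.fmean(per_ind),
        sd_sightings_per_individual=statistics.stdev(per_ind) if len(per_ind) > 1 else 0.0,
        min_sightings_per_individual=per_ind[0],
        max_sightings_per_individual=per_ind[-1],
        mean_prop_identified=statistics.fmean(props),
        sd_prop_identified=statistics.stdev(props) if len(props) > 1 else 0.0,
    )
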