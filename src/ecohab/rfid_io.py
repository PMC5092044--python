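"""Reading and writing Eco-HAB raw RFID event logs.

The acquisition software records every transponder read-out as one line of a
tab-separated plain-text file, one file per wall-clock hour of operation.
Each line carries an event number, a date, a time with millisecond
resolution, the antenna number (1-8), the read-out duration in ms, the
14-digit transponder code and, optionally, a human-readable tag name taken
from a registry file (``rfid_tags.txt``).

Timestamps are represented internally as integer milliseconds since the Unix
epoch; the on-disk date/time rendering is controlled by a :class:`Dialect`
so exports with different conventions can be read.  Wall-clock text is
interpreted as UTC, which makes parsing independent of the host locale and
timezone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ParseError, ValidationError

__all__ = [
    "Dialect",
    "RawEvent",
    "EventLog",
    "TagRegistry",
    "parse_raw_lines",
    "parse_tag_registry",
    "load_event_log",
    "write_event_log",
    "format_timestamp_ms",
    "parse_timestamp_ms",
]

MS_PER_HOUR = 3_600_000
_EPOCH = datetime(1970, 1, 1, tzinfo=timezone.utc)


@dataclass(frozen=True)
class Dialect:
    """On-disk conventions of a raw log export.

    ``time_format`` uses :mod:`datetime` codes; a trailing ``%f`` is written
    with exactly three digits (milliseconds), matching the hardware's
    resolution, while parsing accepts any fractional-second width.
    """

    date_format: str = "%d.%m.%Y"
    time_format: str = "%H:%M:%S.%f"
    file_prefix: str = "ecohab"

    def filename(self, hour_start_ms: int) -> str:
        dt = _EPOCH + timedelta(milliseconds=hour_start_ms)
        return f"{self.file_prefix}_{dt:%Y%m%d}_{dt:%H}.txt"


DEFAULT_DIALECT = Dialect()


def parse_timestamp_ms(date_text: str, time_text: str, dialect: Dialect = DEFAULT_DIALECT) -> int:
    dt = datetime.strptime(f"{date_text} {time_text}", f"{dialect.date_format} {dialect.time_format}")
    dt = dt.replace(tzinfo=timezone.utc)
    return round(dt.timestamp() * 1000)


def format_timestamp_ms(ts_ms: int, dialect: Dialect = DEFAULT_DIALECT) -> tuple[str, str]:
    """Render a timestamp as the dialect's (date, time) pair of strings."""
    dt = _EPOCH + timedelta(milliseconds=int(ts_ms))
    date_s = dt.strftime(dialect.date_format)
    time_s = dt.strftime(dialect.time_format)
    if dialect.time_format.endswith("%f"):
        time_s = time_s[:-3]  # %f renders microseconds; keep milliseconds
    return date_s, time_s


@dataclass(frozen=True)
class RawEvent:
    """One antenna detection of one transponder."""

    event_number: int
    timestamp_ms: int
    antenna_id: int
    readout_duration_ms: int
    transponder_code: str
    tag_name: str | None = None

    def __post_init__(self) -> None:
        if not (len(self.transponder_code) == 14 and self.transponder_code.isdigit()):
            raise ValidationError(
                f"transponder code must be exactly 14 digits, got {self.transponder_code!r}"
            )
        if not 1 <= self.antenna_id <= 8:
            raise ValidationError(f"antenna id must be in 1..8, got {self.antenna_id}")
        if self.readout_duration_ms < 0:
            raise ValidationError(f"read-out duration must be >= 0, got {self.readout_duration_ms}")

    @property
    def mouse(self) -> str:
        """Identity used downstream: the tag name when known, else the code."""
        return self.tag_name if self.tag_name else self.transponder_code

    def identity(self) -> tuple[int, int, str]:
        """Physical identity of a detection; event numbers restart per file."""
        return (self.timestamp_ms, self.antenna_id, self.transponder_code)


class EventLog:
    """A chronologically sorted stream of :class:`RawEvent` for one cohort."""

    def __init__(self, events: Sequence[RawEvent]):
        self.events: tuple[RawEvent, ...] = tuple(
            sorted(events, key=lambda e: (e.timestamp_ms, e.antenna_id, e.event_number))
        )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def time_span(self) -> tuple[int, int]:
        if not self.events:
            raise ValidationError("empty event log has no time span")
        return self.events[0].timestamp_ms, self.events[-1].timestamp_ms

    def mice(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.mouse)
        return list(seen)

    def events_for(self, mouse: str) -> list[RawEvent]:
        """Per-mouse sub-sequence, preserving global chronological order."""
        return [e for e in self.events if e.mouse == mouse]


TagRegistry = Mapping[str, str]


def _parse_line(line: str, lineno: int, dialect: Dialect) -> RawEvent:
    fields = line.split("\t")
    if len(fields) not in (6, 7):
        raise ParseError(f"line {lineno}: expected 6 or 7 tab-separated fields, got {len(fields)}")
    try:
        event_number = int(fields[0])
    except ValueError:
        raise ParseError(f"line {lineno}: bad event number {fields[0]!r}") from None
    try:
        ts = parse_timestamp_ms(fields[1], fields[2], dialect)
    except ValueError:
        raise ParseError(f"line {lineno}: bad date/time {fields[1]!r} {fields[2]!r}") from None
    try:
        antenna = int(fields[3])
        duration = int(fields[4])
    except ValueError:
        raise ParseError(f"line {lineno}: bad antenna/duration {fields[3]!r}/{fields[4]!r}") from None
    tag = fields[6] if len(fields) == 7 and fields[6] else None
    try:
        return RawEvent(event_number, ts, antenna, duration, fields[5], tag)
    except ValidationError as exc:
        raise ValidationError(f"line {lineno}: {exc}") from None


def parse_raw_lines(text: str, dialect: Dialect = DEFAULT_DIALECT) -> list[RawEvent]:
    """Parse the content of one raw log file into events, in file order."""
    events = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        events.append(_parse_line(line.rstrip("\n"), lineno, dialect))
    return events


def format_event(event: RawEvent, dialect: Dialect = DEFAULT_DIALECT) -> str:
    date_s, time_s = format_timestamp_ms(event.timestamp_ms, dialect)
    fields = [
        str(event.event_number),
        date_s,
        time_s,
        str(event.antenna_id),
        str(event.readout_duration_ms),
        event.transponder_code,
    ]
    if event.tag_name is not None:
        fields.append(event.tag_name)
    return "\t".join(fields)


def parse_tag_registry(text: str) -> dict[str, str]:
    """Parse an ``rfid_tags.txt`` mapping of transponder code to tag name."""
    registry: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise ParseError(f"registry line {lineno}: expected 'code<TAB>name'")
        code, name = fields
        if code in registry:
            raise ValidationError(f"registry line {lineno}: duplicate transponder code {code}")
        registry[code] = name
    return registry


def _expand_files(file_set) -> list[Path]:
    if isinstance(file_set, (str, Path)):
        file_set = [file_set]
    paths: list[Path] = []
    for item in file_set:
        p = Path(item)
        if p.is_dir():
            paths.extend(sorted(p.glob("*.txt")))
        else:
            paths.append(p)
    return paths


def load_event_log(
    file_set,
    registry: TagRegistry | None = None,
    dialect: Dialect = DEFAULT_DIALECT,
) -> EventLog:
    """Load and merge one or more raw files into a single sorted log.

    Exact physical duplicates — same timestamp, antenna and transponder —
    are dropped (hourly files may overlap at boundaries).  Near-duplicate
    read bursts are intentionally kept: the sessionizer's threshold rule is
    responsible for eliminating them.
    """
    paths = _expand_files(file_set)
    if not paths:
        raise ValidationError("no raw files to load")
    seen: dict[tuple[int, int, str], RawEvent] = {}
    for path in paths:
        for event in parse_raw_lines(Path(path).read_text(), dialect):
            seen.setdefault(event.identity(), event)
    events = list(seen.values())
    if registry:
        events = [
            replace(e, tag_name=registry[e.transponder_code])
            if e.transponder_code in registry
            else e
            for e in events
        ]
    return EventLog(events)


def write_event_log(
    log: EventLog,
    destination,
    dialect: Dialect = DEFAULT_DIALECT,
) -> list[Path]:
    """Write a log as hourly files, re-sequencing event numbers per file.

    Events are partitioned by wall-clock hour boundary; a 61-minute log
    therefore produces two files.  The written format round-trips through
    :func:`parse_raw_lines` on every field except the file-local numbering.
    """
    if len(log) == 0:
        raise ValidationError("refusing to write an empty event log")
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    by_hour: dict[int, list[RawEvent]] = {}
    for event in log:
        by_hour.setdefault(event.timestamp_ms // MS_PER_HOUR, []).append(event)
    written = []
    for hour in sorted(by_hour):
        path = dest / dialect.filename(hour * MS_PER_HOUR)
        lines = [
            format_event(replace(e, event_number=i), dialect)
            for i, e in enumerate(by_hour[hour], start=1)
        ]
        path.write_text("\n".join(lines) + "\n")
        written.append(path)
    return written
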