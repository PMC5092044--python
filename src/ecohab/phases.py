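"""Experiment phases and time masking.

Experiments are divided into named phases (adaptation dark/light phases,
stimulus presentation, ...) declared in an INI-style ``config.txt``::

    [ADAPTATION - 1. dark phase]
    startdate = 16.02.2015
    starttime = 12:00
    enddate = 17.02.2015
    endtime = 00:00

All intervals are half-open ``[t1, t2)`` so adjacent phases never
double-count an instant.  Two masking modes are provided: the start-based
rule of the original scripts (keep sessions *starting* inside the window,
whole) and a clip mode that truncates boundary-straddling sessions to the
window — the default for every duration-bearing measure, since start-based
masking either drops or over-counts time at the window edges.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .errors import ConfigError, ValidationError
from .rfid_io import DEFAULT_DIALECT, Dialect, parse_timestamp_ms
from .sessionizer import Session, SessionLog

__all__ = [
    "Interval",
    "Phase",
    "PhaseTable",
    "parse_phase_config",
    "mask_sessions",
    "subtract_exclusions",
]


@dataclass(frozen=True)
class Interval:
    """Half-open time interval [t1, t2); units follow the caller (epoch ms
    throughout the measurement pipeline)."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not self.t2 > self.t1:
            raise ValidationError(f"interval end must exceed start: [{self.t1}, {self.t2})")

    @property
    def length(self) -> float:
        return self.t2 - self.t1

    def overlaps(self, other: "Interval") -> bool:
        return self.t1 < other.t2 and other.t1 < self.t2


@dataclass(frozen=True)
class Phase:
    name: str
    start_ms: int
    end_ms: int

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ConfigError(f"phase {self.name!r}: end does not follow start")

    @property
    def interval(self) -> Interval:
        return Interval(self.start_ms, self.end_ms)


class PhaseTable:
    """Ordered collection of uniquely named phases (overlap is allowed)."""

    def __init__(self, phases: Sequence[Phase]):
        self._phases: dict[str, Phase] = {}
        for phase in phases:
            if phase.name in self._phases:
                raise ConfigError(f"duplicate phase name {phase.name!r}")
            self._phases[phase.name] = phase

    def __len__(self) -> int:
        return len(self._phases)

    def __iter__(self):
        return iter(self._phases.values())

    def names(self) -> list[str]:
        return list(self._phases)

    def __getitem__(self, name: str) -> Phase:
        try:
            return self._phases[name]
        except KeyError:
            raise ConfigError(f"unknown phase name {name!r}") from None

    def interval(self, name: str) -> Interval:
        return self[name].interval


_REQUIRED_KEYS = ("startdate", "starttime", "enddate", "endtime")


def parse_phase_config(text: str, dialect: Dialect = DEFAULT_DIALECT) -> PhaseTable:
    """Parse a ``config.txt`` phase definition file.

    Dates use the raw-file dialect (DD.MM.YYYY by default); times are HH:MM,
    with seconds optionally allowed.
    """
    parser = configparser.ConfigParser(interpolation=None, strict=True)
    try:
        parser.read_string(text)
    except configparser.DuplicateSectionError as exc:
        raise ConfigError(f"duplicate phase section {exc.section!r}") from None
    except configparser.Error as exc:
        raise ConfigError(f"bad phase config: {exc}") from None
    phases = []
    for section in parser.sections():
        values = {}
        for key in _REQUIRED_KEYS:
            if not parser.has_option(section, key):
                raise ConfigError(f"phase {section!r}: missing key {key!r}")
            values[key] = parser.get(section, key).strip()
        phases.append(
            Phase(
                name=section,
                start_ms=_parse_dt(values["startdate"], values["starttime"], dialect, section),
                end_ms=_parse_dt(values["enddate"], values["endtime"], dialect, section),
            )
        )
    return PhaseTable(phases)


def _parse_dt(date_text: str, time_text: str, dialect: Dialect, section: str) -> int:
    hhmm = Dialect(date_format=dialect.date_format, time_format="%H:%M")
    hhmmss = Dialect(date_format=dialect.date_format, time_format="%H:%M:%S")
    for d in (hhmm, hhmmss):
        try:
            return parse_timestamp_ms(date_text, time_text, d)
        except ValueError:
            continue
    raise ConfigError(f"phase {section!r}: bad date/time {date_text!r} {time_text!r}")


def mask_sessions(
    slog: SessionLog,
    iv: Interval,
    mode: Literal["start_based", "clip"] = "clip",
) -> SessionLog:
    """Restrict a session log to a time window.

    ``start_based`` keeps, unmodified, every session starting inside the
    window (the original scripts' behavior); ``clip`` keeps every session
    overlapping the window and truncates it to the window.
    """
    if mode == "start_based":
        kept: list[Session] = [s for s in slog if iv.t1 <= s.start_ms < iv.t2]
    elif mode == "clip":
        kept = []
        for s in slog:
            lo = max(s.start_ms, iv.t1)
            hi = min(s.end_ms, iv.t2)
            if hi > lo:
                kept.append(
                    Session(s.mouse, s.compartment, int(lo), int(hi), s.antennas_consecutive)
                )
    else:
        raise ValidationError(f"unknown masking mode {mode!r}")
    return SessionLog(kept, slog.diagnostics)


def subtract_exclusions(iv: Interval, exclusions: Iterable[Interval]) -> list[Interval]:
    """Remove user-declared corrupted segments from an analysis interval,
    returning the remaining sub-intervals in order."""
    remaining = [iv]
    for excl in exclusions:
        next_remaining: list[Interval] = []
        for piece in remaining:
            if not piece.overlaps(excl):
                next_remaining.append(piece)
                continue
            if piece.t1 < excl.t1:
                next_remaining.append(Interval(piece.t1, excl.t1))
            if excl.t2 < piece.t2:
                next_remaining.append(Interval(excl.t2, piece.t2))
        remaining = next_remaining
    return remaining
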