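"""Reading and writing timestamped plain-text event logs.

The canonical dialect is a versioned, TAB-separated text format: a block of
``#``-prefixed ``key: value`` header lines followed by one event per line::

    <t_ms> TAB <code> TAB <port> TAB <arg>

``t_ms`` is an integer millisecond offset from the session start recorded in
the header, ``code`` is a symbolic event name from the closed code table
below, ``port`` is one of ``L``/``C``/``R`` or ``-`` when no port is
involved, and ``arg`` is an optional numeric payload (e.g. the solenoid open
time in ms on a REWARD line) or empty.  Timestamps are integers throughout so
write -> read round trips are bit exact.

Multiple session files for one subject are concatenated by rebasing each
file's millisecond offsets onto a wall-clock axis via its header's
``session_start``; gaps between files are preserved as-is.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

__all__ = [
    "EVENT_CODES",
    "EventRecord",
    "LogHeader",
    "LogParseError",
    "write_log",
    "read_log",
    "read_logs",
    "epoch_ms",
]

SCHEMA_VERSION = "1"

#: Closed, versioned code table: symbolic name -> fixed integer code.
EVENT_CODES: Mapping[str, int] = {
    "POKE_IN": 1,
    "POKE_OUT": 2,
    "CUE_ON": 3,
    "CUE_BLINK_ON": 4,
    "CUE_OFF": 5,
    "REWARD": 6,          # arg = solenoid open time, ms
    "TRIAL_INIT": 7,
    "DELAY_START": 8,
    "CUE_PHASE_START": 9,
    "OUTCOME_CORRECT": 10,
    "OUTCOME_INCORRECT": 11,
    "OUTCOME_OMISSION": 12,
    "ITI_START": 13,
    "PARADIGM_SWITCH": 14,
    "RETRIEVAL": 15,
}

PORTS = ("L", "C", "R")
NO_PORT = "-"


class LogParseError(ValueError):
    """Malformed log line or header, reported with file and line number."""


@dataclass(frozen=True)
class EventRecord:
    """One timestamped apparatus event.

    ``t`` is milliseconds since session start (or since the epoch after
    rebasing by :func:`read_logs`).  ``code`` is a symbolic name from
    :data:`EVENT_CODES`; unknown codes read from foreign files are preserved
    verbatim.  ``arg`` carries a numeric payload or ``None``.
    """

    t: int
    code: str
    port: str = NO_PORT
    arg: Union[int, float, None] = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"event timestamp must be >= 0 ms, got {self.t}")
        if self.port not in PORTS and self.port != NO_PORT:
            raise ValueError(f"unknown port {self.port!r}")


@dataclass(frozen=True)
class LogHeader:
    """Session metadata carried in the ``#`` header block of a log file."""

    subject_id: str
    paradigm_id: str
    session_start: datetime
    box_id: str = "BOX0"
    lights_on_hour: int = 7
    ir_status: Mapping[str, str] = field(
        default_factory=lambda: {"L": "OK", "C": "OK", "R": "OK"}
    )
    schema_version: str = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if not 0 <= int(self.lights_on_hour) <= 23:
            raise ValueError(f"lights_on_hour must be in 0..23, got {self.lights_on_hour}")
        missing = [p for p in PORTS if p not in self.ir_status]
        if missing:
            raise ValueError(f"ir_status missing ports: {missing}")


def _format_arg(arg: Union[int, float, None]) -> str:
    if arg is None:
        return ""
    if isinstance(arg, float) and arg.is_integer():
        return str(int(arg))
    return repr(arg) if isinstance(arg, float) else str(arg)


def _parse_arg(text: str) -> Union[int, float, None]:
    if text == "":
        return None
    try:
        return int(text)
    except ValueError:
        return float(text)


def write_log(
    header: LogHeader,
    events: Sequence[EventRecord],
    destination: Union[str, Path, TextIO],
) -> None:
    """Write a header and time-ordered events as canonical log text.

    Output is byte-identical for identical input.  Raises ``ValueError`` if
    the events are not non-decreasing in time.
    """
    for prev, cur in zip(events, events[1:]):
        if cur.t < prev.t:
            raise ValueError(
                f"events out of order: t={cur.t} ms after t={prev.t} ms"
            )
    lines = [
        f"# schema_version: {header.schema_version}",
        f"# box_id: {header.box_id}",
        f"# subject_id: {header.subject_id}",
        f"# paradigm_id: {header.paradigm_id}",
        f"# session_start: {header.session_start.isoformat()}",
        f"# lights_on_hour: {int(header.lights_on_hour)}",
        "# ir_status: " + ",".join(f"{p}={header.ir_status[p]}" for p in PORTS),
    ]
    for ev in events:
        lines.append(f"{ev.t}\t{ev.code}\t{ev.port}\t{_format_arg(ev.arg)}")
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)


def _parse_header(pairs: Mapping[str, str], where: str) -> LogHeader:
    try:
        ir = dict(
            item.split("=", 1) for item in pairs["ir_status"].split(",") if item
        )
        return LogHeader(
            schema_version=pairs.get("schema_version", SCHEMA_VERSION),
            box_id=pairs.get("box_id", "BOX0"),
            subject_id=pairs["subject_id"],
            paradigm_id=pairs["paradigm_id"],
            session_start=datetime.fromisoformat(pairs["session_start"]),
            lights_on_hour=int(pairs.get("lights_on_hour", 7)),
            ir_status=ir,
        )
    except (KeyError, ValueError) as exc:
        raise LogParseError(f"{where}: bad or missing header field: {exc}") from exc


def read_log(
    source: Union[str, Path, TextIO],
    column_map: Sequence[str] = ("t", "code", "port", "arg"),
) -> tuple[LogHeader, list[EventRecord], list[str]]:
    """Parse one log file.

    Returns ``(header, events, unknown_codes)`` where ``unknown_codes`` lists
    event codes found in the file that are not in :data:`EVENT_CODES`
    (preserved verbatim in the records, flagged here).

    ``column_map`` names the meaning of each TAB column for foreign dialects;
    it must contain ``t``, ``code`` and ``port`` (extra columns may be
    skipped with ``None``-like name ``"_"``).
    """
    if isinstance(source, (str, Path)):
        name = str(source)
        fh: TextIO = open(source, "r")
        close = True
    else:
        name = getattr(source, "name", "<stream>")
        fh, close = source, False
    try:
        pairs: dict[str, str] = {}
        events: list[EventRecord] = []
        unknown: list[str] = []
        col = {c: i for i, c in enumerate(column_map) if c != "_"}
        for missing in ("t", "code", "port"):
            if missing not in col:
                raise ValueError(f"column_map must include {missing!r}")
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, val = body.split(":", 1)
                    pairs[key.strip()] = val.strip()
                continue
            fields = line.split("\t")
            if len(fields) < len([c for c in column_map if c != "_"]):
                raise LogParseError(
                    f"{name}:{lineno}: expected {len(column_map)} TAB-separated "
                    f"fields, got {len(fields)}: {line!r}"
                )
            try:
                t = int(fields[col["t"]])
                code = fields[col["code"]]
                port = fields[col["port"]]
                arg = _parse_arg(fields[col["arg"]]) if "arg" in col else None
                ev = EventRecord(t=t, code=code, port=port, arg=arg)
            except ValueError as exc:
                raise LogParseError(f"{name}:{lineno}: {exc}") from exc
            if events and ev.t < events[-1].t:
                raise LogParseError(
                    f"{name}:{lineno}: timestamp {ev.t} ms precedes previous "
                    f"event at {events[-1].t} ms"
                )
            if code not in EVENT_CODES and code not in unknown:
                unknown.append(code)
            events.append(ev)
        header = _parse_header(pairs, name)
        return header, events, unknown
    finally:
        if close:
            fh.close()


def epoch_ms(dt: datetime) -> int:
    return int(round(dt.timestamp() * 1000))


def read_logs(
    paths: Iterable[Union[str, Path]],
    column_map: Sequence[str] = ("t", "code", "port", "arg"),
) -> tuple[list[LogHeader], list[EventRecord]]:
    """Read and concatenate several session files for one subject.

    Each file's millisecond offsets are rebased onto a single wall-clock axis
    (ms since the Unix epoch) using its header ``session_start``; the unified
    sequence is globally time-ordered and gaps between sessions are preserved
    (no interpolation).  Overlapping time ranges across files for a single
    subject raise ``ValueError``.
    """
    parsed = []
    for p in paths:
        header, events, _unknown = read_log(p, column_map=column_map)
        parsed.append((header, events, str(p)))
    parsed.sort(key=lambda item: item[0].session_start)

    headers: list[LogHeader] = []
    unified: list[EventRecord] = []
    prev_end, prev_name = None, None
    for header, events, name in parsed:
        base = epoch_ms(header.session_start)
        if prev_end is not None and base < prev_end:
            raise ValueError(
                f"log {name} (starting {header.session_start.isoformat()}) "
                f"overlaps the time range of {prev_name}"
            )
        headers.append(header)
        rebased = [replace(ev, t=base + ev.t) for ev in events]
        unified.extend(rebased)
        if rebased:
            prev_end, prev_name = rebased[-1].t, name
        else:
            prev_end, prev_name = base, name
    return headers, unified


def write_logs_text(header: LogHeader, events: Sequence[EventRecord]) -> str:
    """Render a log to a string (convenience wrapper around write_log)."""
    buf = io.StringIO()
    write_log(header, events, buf)
    return buf.getvalue()
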