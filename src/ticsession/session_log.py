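"""Plain-text ``.ttsd`` session-log format (dialect ``ttw-spec-1``).

A log is line-oriented UTF-8: a version line, tab-separated header
fields, one tab-separated line per event (``<offset_ms>\\t<kind>\\t<detail>``),
then a sentinel line introducing the appended summary block.  Offsets
are integer milliseconds from session start; the only wall-clock value
is the header start datetime (local time, second precision, matching
the archive filename).

Archive filenames follow ``<research_id>_<YYYYMMDD-HHMMSS>_<condition>.ttsd``,
e.g. ``au5_20200622-153043_baseline.ttsd``.

Serialization is deterministic byte output for a given record, and
``parse(serialize(record))`` reproduces the record field-for-field.  The
parser recomputes the summary from the event lines and rejects logs
whose embedded summary disagrees.
"""

from __future__ import annotations

import datetime as _dt
import math
import re
from pathlib import Path
from typing import Union

from . import metrics
from .session_engine import (
    Condition,
    ConfigurationError,
    SessionConfig,
    SessionEvent,
    SessionRecord,
    StateError,
    validate_research_id,
)

__all__ = [
    "FORMAT_VERSION",
    "ParseError",
    "serialize",
    "parse",
    "archive_filename",
    "parse_archive_filename",
    "archive",
    "load",
]

FORMAT_VERSION = "ttw-spec-1"
_SUMMARY_SENTINEL = "==== summary ===="
_DT_FMT = "%Y-%m-%d %H:%M:%S"
_STAMP_FMT = "%Y%m%d-%H%M%S"

_EVENT_LINE = re.compile(r"^\d")
_FILENAME = re.compile(
    r"^([^\s_/\\]+)_(\d{8}-\d{6})_(baseline|verbal|DRZ|NCR)\.ttsd$"
)

_REQUIRED_HEADER = (
    "research_id",
    "condition",
    "start_datetime",
    "planned_duration_ms",
    "dro_interval_ms",
)
_OPTIONAL_HEADER = ("ncr_source_file", "ncr_source_reward_count")

_SUMMARY_INT_FIELDS = (
    "tic_count",
    "reward_count",
    "undelivered_reward_count",
    "duration_ms",
    "longest_tic_free_interval_ms",
)
_SUMMARY_FLOAT_FIELDS = ("tics_per_minute", "mean_inter_tic_interval_ms")


class ParseError(ValueError):
    """A ``.ttsd`` log violated the documented grammar; carries the
    1-based line number where parsing failed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


def _fmt_float(value: float | None) -> str:
    return "NA" if value is None else format(value, ".6f")


def serialize(record: SessionRecord) -> str:
    """Render a finalized record as deterministic ``.ttsd`` text."""
    if not record.events or record.events[-1].kind != "session_end":
        raise StateError("cannot serialize an unfinalized session record")
    summary = record.summary if record.summary is not None else metrics.summarize(record)

    lines = [FORMAT_VERSION]
    lines.append(f"research_id\t{record.research_id}")
    lines.append(f"condition\t{record.condition.value}")
    lines.append(f"start_datetime\t{record.start_datetime.strftime(_DT_FMT)}")
    lines.append(f"planned_duration_ms\t{record.config.planned_duration_ms}")
    lines.append(f"dro_interval_ms\t{record.config.dro_interval_ms}")
    if record.ncr_source_filename is not None:
        lines.append(f"ncr_source_file\t{record.ncr_source_filename}")
    if record.ncr_source_reward_total is not None:
        lines.append(f"ncr_source_reward_count\t{record.ncr_source_reward_total}")
    for ev in record.events:
        if "\t" in ev.detail or "\n" in ev.detail:
            raise ValueError("event detail may not contain tabs or newlines")
        lines.append(f"{ev.offset_ms}\t{ev.kind}\t{ev.detail}")
    lines.append(_SUMMARY_SENTINEL)
    lines.append(f"tic_count\t{summary.tic_count}")
    lines.append(f"reward_count\t{summary.reward_count}")
    lines.append(f"undelivered_reward_count\t{summary.undelivered_reward_count}")
    lines.append(f"duration_ms\t{summary.duration_ms}")
    lines.append(f"tics_per_minute\t{_fmt_float(summary.tics_per_minute)}")
    lines.append(
        f"mean_inter_tic_interval_ms\t{_fmt_float(summary.mean_inter_tic_interval_ms)}"
    )
    lines.append(
        f"longest_tic_free_interval_ms\t{summary.longest_tic_free_interval_ms}"
    )
    return "\n".join(lines) + "\n"


def _split_kv(line: str, lineno: int) -> tuple[str, str]:
    if "\t" not in line:
        raise ParseError(f"expected a tab-separated key/value line, got {line!r}", lineno)
    key, value = line.split("\t", 1)
    return key, value


def parse(text: str) -> SessionRecord:
    """Parse ``.ttsd`` text into a :class:`SessionRecord`.

    Events are re-sorted defensively by (offset, kind priority); the
    summary is recomputed from the events and checked against the
    embedded block.  Malformed input raises :class:`ParseError` with the
    offending line number.
    """
    lines = text.splitlines()
    if not lines or lines[0] != FORMAT_VERSION:
        raise ParseError(
            f"unsupported or missing format version (expected {FORMAT_VERSION!r})", 1
        )

    header: dict[str, str] = {}
    i = 1
    while i < len(lines) and not _EVENT_LINE.match(lines[i]):
        if lines[i] == _SUMMARY_SENTINEL:
            raise ParseError("summary block before any event line", i + 1)
        key, value = _split_kv(lines[i], i + 1)
        if key not in _REQUIRED_HEADER + _OPTIONAL_HEADER:
            raise ParseError(f"unknown header field {key!r}", i + 1)
        if key in header:
            raise ParseError(f"duplicate header field {key!r}", i + 1)
        header[key] = value
        i += 1
    for key in _REQUIRED_HEADER:
        if key not in header:
            raise ParseError(f"missing header field {key!r}", i + 1)

    try:
        condition = Condition(header["condition"])
    except ValueError:
        raise ParseError(f"unknown condition code {header['condition']!r}", 3) from None
    try:
        start_dt = _dt.datetime.strptime(header["start_datetime"], _DT_FMT)
    except ValueError:
        raise ParseError(
            f"malformed start_datetime {header['start_datetime']!r}", 4
        ) from None
    try:
        config = SessionConfig(
            condition=condition,
            planned_duration_ms=int(header["planned_duration_ms"]),
            research_id=header["research_id"],
            dro_interval_ms=int(header["dro_interval_ms"]),
        )
    except (ConfigurationError, ValueError) as exc:
        raise ParseError(f"invalid header: {exc}", 2) from None

    events: list[SessionEvent] = []
    prev_key: tuple[int, int] | None = None
    while i < len(lines) and lines[i] != _SUMMARY_SENTINEL:
        parts = lines[i].split("\t")
        if len(parts) < 2 or len(parts) > 3:
            raise ParseError(f"malformed event line {lines[i]!r}", i + 1)
        offset_s, kind = parts[0], parts[1]
        detail = parts[2] if len(parts) == 3 else ""
        try:
            ev = SessionEvent(int(offset_s), kind, detail)
        except ValueError as exc:
            raise ParseError(str(exc), i + 1) from None
        if prev_key is not None and ev.sort_key() < prev_key:
            raise ParseError("event offsets are not monotone", i + 1)
        prev_key = ev.sort_key()
        events.append(ev)
        i += 1
    if i >= len(lines):
        raise ParseError("missing summary block", len(lines))
    summary_start = i + 1
    events.sort(key=SessionEvent.sort_key)

    if not events or events[0].kind != "session_start" or events[0].offset_ms != 0:
        raise ParseError("log must open with session_start at offset 0", summary_start)
    if sum(1 for e in events if e.kind == "session_start") != 1:
        raise ParseError("multiple session_start events", summary_start)
    ends = [e for e in events if e.kind == "session_end"]
    if len(ends) != 1 or events[-1].kind != "session_end":
        raise ParseError(
            "log must close with a single session_end at the maximal offset",
            summary_start,
        )
    if ends[0].detail not in ("",) + tuple(
        r for r in ("duration elapsed", "rater ended", "connection closed")
    ):
        raise ParseError(f"unknown end reason {ends[0].detail!r}", summary_start)
    if ends[0].offset_ms > config.planned_duration_ms:
        raise ParseError("session_end beyond the planned duration", summary_start)
    if not condition.rewards_enabled and any(e.kind == "reward" for e in events):
        raise ParseError(
            f"reward event in the no-reward condition {condition.value!r}",
            summary_start,
        )

    embedded: dict[str, str] = {}
    embedded_lineno: dict[str, int] = {}
    j = summary_start
    while j < len(lines):
        if lines[j] == "":
            j += 1
            continue
        key, value = _split_kv(lines[j], j + 1)
        if key not in _SUMMARY_INT_FIELDS + _SUMMARY_FLOAT_FIELDS:
            raise ParseError(f"unknown summary field {key!r}", j + 1)
        embedded[key] = value
        embedded_lineno[key] = j + 1
        j += 1

    ncr_total = None
    if "ncr_source_reward_count" in header:
        try:
            ncr_total = int(header["ncr_source_reward_count"])
        except ValueError:
            raise ParseError("malformed ncr_source_reward_count", 7) from None

    record = SessionRecord(
        config=config,
        start_datetime=start_dt,
        events=tuple(events),
        ncr_source_filename=header.get("ncr_source_file"),
        ncr_source_reward_total=ncr_total,
    )
    computed = metrics.summarize(record)

    for key in _SUMMARY_INT_FIELDS:
        if key not in embedded:
            raise ParseError(f"missing summary field {key!r}", len(lines))
        if int(embedded[key]) != getattr(computed, _summary_attr(key)):
            raise ParseError(
                f"summary field {key!r} ({embedded[key]}) disagrees with the "
                f"event lines ({getattr(computed, _summary_attr(key))})",
                embedded_lineno[key],
            )
    for key in _SUMMARY_FLOAT_FIELDS:
        if key not in embedded:
            raise ParseError(f"missing summary field {key!r}", len(lines))
        got = None if embedded[key] == "NA" else float(embedded[key])
        want = getattr(computed, _summary_attr(key))
        if (got is None) != (want is None) or (
            got is not None and not math.isclose(got, want, rel_tol=1e-9, abs_tol=1e-6)
        ):
            raise ParseError(
                f"summary field {key!r} ({embedded[key]}) disagrees with the "
                f"event lines ({want})",
                embedded_lineno[key],
            )

    record.summary = computed
    return record


def _summary_attr(key: str) -> str:
    return key


def archive_filename(
    research_id: str,
    start_datetime: _dt.datetime,
    condition: Condition | str,
) -> str:
    """``<research_id>_<YYYYMMDD-HHMMSS>_<condition>.ttsd``."""
    validate_research_id(research_id)
    if not isinstance(condition, Condition):
        condition = Condition(condition)
    return f"{research_id}_{start_datetime.strftime(_STAMP_FMT)}_{condition.value}.ttsd"


def parse_archive_filename(name: str) -> tuple[str, _dt.datetime, Condition]:
    """Invert :func:`archive_filename`; raises :class:`ParseError` on a
    name outside the convention."""
    m = _FILENAME.match(name)
    if not m:
        raise ParseError(f"filename {name!r} does not match the archive convention")
    rid, stamp, cond = m.groups()
    return rid, _dt.datetime.strptime(stamp, _STAMP_FMT), Condition(cond)


def archive(record: SessionRecord, directory: Union[str, Path]) -> Path:
    """Serialize ``record`` into ``directory`` under its archive filename."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / archive_filename(
        record.research_id, record.start_datetime, record.condition
    )
    path.write_text(serialize(record), encoding="utf-8")
    return path


def load(path: Union[str, Path]) -> SessionRecord:
    """Read and parse a ``.ttsd`` file."""
    return parse(Path(path).read_text(encoding="utf-8"))
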