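"""State machine for one tic-suppression-paradigm (TSP) session.

A TSP session observes a participant under one of four experimental
conditions:

``baseline``
    Observation only: no instruction, no rewards.
``verbal``
    The participant is asked to suppress tics; no rewards.  The engine
    treats this identically to baseline — the instruction is delivered
    by the rater, not the software — so the two differ only in their
    condition code and log label.
``DRZ``
    Differential reinforcement of zero-rate ticcing (DRO): a reward is
    dispensed after every fixed-length tic-free interval, 10 s by
    default.  The countdown restarts at every tic and at every reward
    delivery, so rewards recur once per interval during sustained
    suppression.
``NCR``
    Noncontingent reinforcement: rewards are replayed at the offsets at
    which they were delivered in a previously archived session of the
    *same* subject, irrespective of tics.

The engine runs on an integer-millisecond virtual clock measured from
session start; the only wall-clock value is the start datetime recorded
once for archiving.  All operations are deterministic, which makes the
engine directly testable against a brute-force 1-ms-step reference
simulation, and lets the same code drive a real-time loop (feed it the
monotonic clock) or a batch replay (feed it recorded offsets).

Boundary rules: a reward is due at exactly ``last_reset + interval``
(closed right endpoint); a tic landing on the exact due offset pre-empts
the DRZ reward — an interval containing a tic is never rewarded.  At
equal offsets a tic orders before a reward.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Any, Iterable, Sequence

from enum import Enum

if TYPE_CHECKING:  # pragma: no cover
    from .metrics import SessionSummary

__all__ = [
    "Condition",
    "ConfigurationError",
    "StateError",
    "SessionConfig",
    "SessionEvent",
    "SessionState",
    "SessionRecord",
    "END_REASONS",
    "DEFAULT_DRO_INTERVAL_MS",
    "start_session",
    "record_tic",
    "next_reward_due",
    "advance",
    "end_session",
    "finalize",
    "run_session",
    "validate_research_id",
]

#: End-of-session reasons are a fixed vocabulary so logs stay machine-parseable.
END_REASONS = ("duration elapsed", "rater ended", "connection closed")

DEFAULT_DRO_INTERVAL_MS = 10_000


class ConfigurationError(ValueError):
    """A session configuration violates its invariants."""


class StateError(RuntimeError):
    """An operation was applied to a session state that cannot accept it."""


class Condition(str, Enum):
    """The four experimental conditions of the tic suppression paradigm."""

    BASELINE = "baseline"
    VERBAL = "verbal"
    DRZ = "DRZ"  # archive code for the DRO condition
    NCR = "NCR"

    @property
    def rewards_enabled(self) -> bool:
        """Rewards may be emitted only under DRZ and NCR."""
        return self in (Condition.DRZ, Condition.NCR)


_KIND_PRIORITY = {"session_start": 0, "tic": 1, "reward": 2, "session_end": 3}
EVENT_KINDS = tuple(_KIND_PRIORITY)

# research IDs become the first underscore-delimited field of archive
# filenames, so they must not contain '_', path separators or whitespace
_RESEARCH_ID_RE = re.compile(r"^[^\s_/\\]+$")


def validate_research_id(research_id: str) -> str:
    if not isinstance(research_id, str) or not _RESEARCH_ID_RE.match(research_id):
        raise ConfigurationError(
            f"research_id: {research_id!r} must be a non-empty token without "
            "underscores, path separators or whitespace"
        )
    return research_id


@dataclass(frozen=True)
class SessionEvent:
    """One timestamped session event (offset in ms from session start)."""

    offset_ms: int
    kind: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in _KIND_PRIORITY:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.offset_ms < 0:
            raise ValueError("event offset must be >= 0")

    def sort_key(self) -> tuple[int, int]:
        return (self.offset_ms, _KIND_PRIORITY[self.kind])


def _source_research_id(source: Any) -> str:
    rid = getattr(source, "source_research_id", None)
    if rid is None:
        rid = getattr(source, "research_id", None)
    if rid is None:
        raise ConfigurationError(
            "ncr_source: expected a RewardSchedule or SessionRecord"
        )
    return rid


def _source_reward_offsets(source: Any) -> tuple[int, ...]:
    offsets = getattr(source, "offsets_ms", None)
    if offsets is None:
        events = getattr(source, "events", None)
        if events is None:
            raise ConfigurationError(
                "ncr_source: expected a RewardSchedule or SessionRecord"
            )
        offsets = [e.offset_ms for e in events if e.kind == "reward"]
    return tuple(int(o) for o in offsets)


@dataclass
class SessionConfig:
    """Configuration for one session.

    Parameters
    ----------
    condition
        One of the four experimental conditions (or its string code).
    planned_duration_ms
        Planned session length in ms; must be positive.
    research_id
        Subject token used in archive filenames; no underscores, path
        separators or whitespace.
    dro_interval_ms
        Tic-free interval length earning one reward under DRZ.
        Default 10 000 ms.
    ncr_source
        For NCR sessions only: the ``RewardSchedule`` (or source
        ``SessionRecord``) whose reward offsets are replayed.  Must come
        from the same subject.  Excluded from equality: it is a runtime
        reference, not a persisted field.
    """

    condition: Condition
    planned_duration_ms: int
    research_id: str
    dro_interval_ms: int = DEFAULT_DRO_INTERVAL_MS
    ncr_source: Any = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.condition, Condition):
            self.condition = Condition(self.condition)
        self.planned_duration_ms = int(self.planned_duration_ms)
        self.dro_interval_ms = int(self.dro_interval_ms)
        if self.planned_duration_ms <= 0:
            raise ConfigurationError("planned_duration_ms: must be positive")
        if self.dro_interval_ms <= 0:
            raise ConfigurationError("dro_interval_ms: must be positive")
        validate_research_id(self.research_id)

    def validate_for_start(self) -> None:
        """Checks that only apply when the config is used to start a session."""
        if self.condition is Condition.NCR:
            if self.ncr_source is None:
                raise ConfigurationError(
                    "ncr_source: an NCR session requires a source session "
                    "previously recorded with the current subject"
                )
            src_id = _source_research_id(self.ncr_source)
            if src_id != self.research_id:
                raise ConfigurationError(
                    f"ncr_source: source subject {src_id!r} does not match "
                    f"research_id {self.research_id!r}"
                )
        elif self.ncr_source is not None:
            raise ConfigurationError(
                "ncr_source: only NCR sessions take a source session"
            )

    def ncr_offsets(self) -> tuple[int, ...]:
        """Reward offsets replayed by an NCR session (sorted)."""
        if self.ncr_source is None:
            return ()
        return tuple(sorted(_source_reward_offsets(self.ncr_source)))


@dataclass
class SessionState:
    """Mutable state of a running session.

    ``last_reset_ms`` is the start of the current tic-free countdown: the
    maximum of session start, the latest tic and the latest reward.
    """

    config: SessionConfig
    start_datetime: _dt.datetime
    elapsed_ms: int = 0
    last_reset_ms: int = 0
    live: bool = True
    events: list[SessionEvent] = field(default_factory=list)
    _ncr_offsets: tuple[int, ...] = ()
    _ncr_next: int = 0  # index of the next undelivered replay offset


@dataclass
class SessionRecord:
    """A finalized session: config, ordered events and computed summary.

    This is the unit of archival; `ticsession.session_log` serializes it
    to and from the plain-text ``.ttsd`` format.
    """

    config: SessionConfig
    start_datetime: _dt.datetime
    events: tuple[SessionEvent, ...]
    summary: "SessionSummary | None" = None
    ncr_source_filename: str | None = None
    ncr_source_reward_total: int | None = None

    @property
    def research_id(self) -> str:
        return self.config.research_id

    @property
    def condition(self) -> Condition:
        return self.config.condition

    @property
    def duration_ms(self) -> int:
        """Actual session duration: the session_end offset."""
        return self.events[-1].offset_ms

    @property
    def end_reason(self) -> str:
        return self.events[-1].detail

    def tic_offsets(self) -> tuple[int, ...]:
        return tuple(e.offset_ms for e in self.events if e.kind == "tic")

    def reward_offsets(self) -> tuple[int, ...]:
        return tuple(e.offset_ms for e in self.events if e.kind == "reward")


def start_session(
    config: SessionConfig, start_datetime: _dt.datetime | None = None
) -> SessionState:
    """Validate ``config`` and open a live session at offset 0."""
    config.validate_for_start()
    if start_datetime is None:
        start_datetime = _dt.datetime.now().replace(microsecond=0)
    state = SessionState(
        config=config,
        start_datetime=start_datetime,
        _ncr_offsets=config.ncr_offsets(),
    )
    state.events.append(SessionEvent(0, "session_start"))
    return state


def _require_live(state: SessionState) -> None:
    if not state.live:
        raise StateError("session has already ended")


def next_reward_due(state: SessionState) -> int | None:
    """Offset at which the next reward is due, or ``None`` if no reward
    is pending for this condition.

    Pure: does not mutate ``state``.  For DRZ the due time is
    ``last_reset + interval`` (it may lie beyond the planned duration, in
    which case it will never be emitted); for NCR it is the earliest
    source offset not yet delivered, within the planned duration —
    replay offsets are never skipped, even when one coincides exactly
    with a tic (the tic merely orders first).
    """
    _require_live(state)
    cfg = state.config
    if cfg.condition is Condition.DRZ:
        return state.last_reset_ms + cfg.dro_interval_ms
    if cfg.condition is Condition.NCR:
        if state._ncr_next < len(state._ncr_offsets):
            due = state._ncr_offsets[state._ncr_next]
            if due <= cfg.planned_duration_ms:
                return due
        return None
    return None


def _emit_due_rewards(
    state: SessionState, upto_ms: int, *, inclusive: bool
) -> list[SessionEvent]:
    """Emit every pending reward due up to ``upto_ms`` (closed endpoint
    when ``inclusive``), resetting the DRO countdown at each emission."""
    emitted: list[SessionEvent] = []
    while True:
        due = next_reward_due(state)
        if due is None:
            break
        if due > upto_ms or (not inclusive and due >= upto_ms):
            break
        ev = SessionEvent(due, "reward")
        state.events.append(ev)
        emitted.append(ev)
        if state.config.condition is Condition.NCR:
            state._ncr_next += 1
        state.elapsed_ms = max(state.elapsed_ms, due)
        state.last_reset_ms = max(state.last_reset_ms, due)
    return emitted


def record_tic(state: SessionState, now_ms: int) -> SessionState:
    """Append a tic at offset ``now_ms``, restarting the DRO countdown.

    Rewards that fell due strictly before ``now_ms`` are flushed first,
    so batch replay of a tic list is equivalent to live operation with a
    continuously advancing clock.  A DRZ reward due exactly at ``now_ms``
    is pre-empted by the tic; an NCR reward at the same offset is still
    delivered later (ordered after the tic), since the replay schedule is
    unaffected by tics.
    """
    _require_live(state)
    now_ms = int(now_ms)
    if now_ms < state.elapsed_ms:
        raise StateError(
            f"tic at {now_ms} ms precedes the session clock ({state.elapsed_ms} ms)"
        )
    if now_ms >= state.config.planned_duration_ms:
        raise StateError("tic at or after the planned session end")
    _emit_due_rewards(state, now_ms, inclusive=False)
    state.events.append(SessionEvent(now_ms, "tic"))
    state.elapsed_ms = now_ms
    state.last_reset_ms = max(state.last_reset_ms, now_ms)
    return state


def advance(
    state: SessionState, now_ms: int
) -> tuple[SessionState, list[SessionEvent]]:
    """Advance the session clock to ``now_ms``, emitting every reward due
    in ``(elapsed, min(now, planned_duration)]`` in order.

    If ``now_ms`` reaches the planned duration the session ends there
    with reason ``"duration elapsed"``.  Returns the state and the list
    of emitted events (rewards, possibly followed by the session_end).
    """
    _require_live(state)
    now_ms = int(now_ms)
    if now_ms < state.elapsed_ms:
        raise StateError(
            f"cannot advance backwards to {now_ms} ms (clock at {state.elapsed_ms} ms)"
        )
    planned = state.config.planned_duration_ms
    target = min(now_ms, planned)
    emitted = _emit_due_rewards(state, target, inclusive=True)
    state.elapsed_ms = target
    if now_ms >= planned:
        end = SessionEvent(planned, "session_end", "duration elapsed")
        state.events.append(end)
        emitted.append(end)
        state.live = False
    return state, emitted


def end_session(state: SessionState, now_ms: int, reason: str) -> SessionRecord:
    """End the session at ``min(now, planned_duration)`` and finalize.

    ``reason`` must be one of :data:`END_REASONS`.  Rewards still pending
    up to the end offset are delivered first.  Ending twice is an error.
    """
    _require_live(state)
    if reason not in END_REASONS:
        raise ValueError(f"end reason must be one of {END_REASONS}, got {reason!r}")
    now_ms = int(now_ms)
    if now_ms < state.elapsed_ms:
        raise StateError(
            f"cannot end at {now_ms} ms (clock at {state.elapsed_ms} ms)"
        )
    target = min(now_ms, state.config.planned_duration_ms)
    _emit_due_rewards(state, target, inclusive=True)
    state.events.append(SessionEvent(target, "session_end", reason))
    state.elapsed_ms = target
    state.live = False
    return finalize(state)


def finalize(state: SessionState) -> SessionRecord:
    """Freeze an ended session into a :class:`SessionRecord` with its
    summary computed."""
    if state.live:
        raise StateError(
            "session still live; advance past the planned duration or call end_session"
        )
    events = tuple(sorted(state.events, key=SessionEvent.sort_key))
    cfg = state.config
    ncr_file = None
    ncr_total = None
    if cfg.condition is Condition.NCR and cfg.ncr_source is not None:
        ncr_file = getattr(cfg.ncr_source, "source_filename", None)
        ncr_total = len(cfg.ncr_offsets())
    record = SessionRecord(
        config=cfg,
        start_datetime=state.start_datetime,
        events=events,
        ncr_source_filename=ncr_file,
        ncr_source_reward_total=ncr_total,
    )
    from . import metrics  # deferred: metrics imports this module's types

    record.summary = metrics.summarize(record)
    return record


def run_session(
    config: SessionConfig,
    tic_offsets: Iterable[int] = (),
    *,
    start_datetime: _dt.datetime | None = None,
    end_at_ms: int | None = None,
    end_reason: str = "rater ended",
) -> SessionRecord:
    """Run a whole session from a list of tic offsets and finalize it.

    Convenience driver for batch use (simulation, replay, tests): tics
    are applied in order, the clock is advanced to the end, and the
    finalized record is returned.  ``end_at_ms`` ends the session early
    with ``end_reason``; otherwise it runs to the planned duration.
    """
    state = start_session(config, start_datetime=start_datetime)
    planned = config.planned_duration_ms
    stop = planned if end_at_ms is None else min(int(end_at_ms), planned)
    for t in sorted(int(t) for t in tic_offsets):
        if t >= stop:
            break
        record_tic(state, t)
    if end_at_ms is not None and end_at_ms < planned:
        return end_session(state, end_at_ms, end_reason)
    advance(state, planned)
    return finalize(state)
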