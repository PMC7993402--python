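"""Noncontingent-reinforcement (NCR) replay schedules.

An NCR session delivers rewards at the same offsets (relative to session
start) at which they were delivered in a previously archived session of
the same subject, at times unrelated to the subject's tics.  This module
extracts that schedule from an archived record and builds the NCR
session configuration, enforcing the same-subject requirement via
research-ID equality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Union

from . import session_log
from .session_engine import (
    Condition,
    ConfigurationError,
    DEFAULT_DRO_INTERVAL_MS,
    SessionConfig,
    SessionRecord,
)

__all__ = ["RewardSchedule", "extract_reward_schedule", "make_ncr_config", "load_schedule"]


@dataclass(frozen=True)
class RewardSchedule:
    """Reward offsets lifted from a source session, with its identity."""

    offsets_ms: tuple[int, ...]
    source_filename: str
    source_research_id: str
    source_condition: Condition | None = None

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.offsets_ms, self.offsets_ms[1:])):
            raise ValueError("reward offsets must be strictly increasing")


def extract_reward_schedule(record: SessionRecord) -> RewardSchedule:
    """Project a parsed record onto its reward offsets.

    An empty schedule is allowed (e.g. a baseline source contains no
    rewards).  Replaying a log that is itself an NCR log is permitted —
    offsets are offsets — but warned about, since it is usually a
    rater's mistake.
    """
    if record.condition is Condition.NCR:
        warnings.warn(
            "replaying an NCR log: reward offsets are second-hand copies of "
            "the original DRO session",
            stacklevel=2,
        )
    return RewardSchedule(
        offsets_ms=record.reward_offsets(),
        source_filename=session_log.archive_filename(
            record.research_id, record.start_datetime, record.condition
        ),
        source_research_id=record.research_id,
        source_condition=record.condition,
    )


def make_ncr_config(
    schedule: RewardSchedule,
    duration_ms: int,
    research_id: str,
    dro_interval_ms: int = DEFAULT_DRO_INTERVAL_MS,
) -> SessionConfig:
    """NCR session configuration replaying ``schedule``.

    The source must have been recorded with the current subject; a
    mismatched research ID is a configuration error.  Schedule offsets
    beyond ``duration_ms`` are silently dropped by the engine and show up
    in the session summary as undelivered.
    """
    if schedule.source_research_id != research_id:
        raise ConfigurationError(
            f"ncr_source: schedule was recorded with subject "
            f"{schedule.source_research_id!r}, not {research_id!r}"
        )
    return SessionConfig(
        condition=Condition.NCR,
        planned_duration_ms=duration_ms,
        research_id=research_id,
        dro_interval_ms=dro_interval_ms,
        ncr_source=schedule,
    )


def load_schedule(path: Union[str, Path]) -> RewardSchedule:
    """Read an archived ``.ttsd`` log and extract its reward schedule."""
    return extract_reward_schedule(session_log.load(path))
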