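"""Per-session summary statistics and cross-condition suppression measures.

The summary block appended to every ``.ttsd`` log is computed here, and
recomputed (and checked) whenever a log is parsed.  Tic-free intervals
are taken over the gaps between consecutive tics *plus* the two boundary
gaps (session start to first tic, last tic to session end), so a session
with zero tics has a single tic-free interval equal to its duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import fmean
from typing import TYPE_CHECKING, Iterable

from .session_engine import Condition, StateError

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd

    from .session_engine import SessionRecord

__all__ = ["SessionSummary", "summarize", "suppression_ratio", "summary_table"]


@dataclass(frozen=True)
class SessionSummary:
    """Descriptive statistics of one finalized session."""

    tic_count: int
    reward_count: int
    undelivered_reward_count: int
    duration_ms: int
    tics_per_minute: float
    mean_inter_tic_interval_ms: float | None  # defined only for >= 2 tics
    longest_tic_free_interval_ms: int


def summarize(record: "SessionRecord") -> SessionSummary:
    """Compute the summary of a finalized record from its events.

    For NCR sessions the undelivered-reward count is the number of source
    schedule offsets that were not delivered (they fell beyond the
    session's actual duration), taken against the source total carried in
    the record header.
    """
    events = record.events
    if not events or events[-1].kind != "session_end":
        raise StateError("cannot summarize an unfinalized session record")
    duration = events[-1].offset_ms
    tics = [e.offset_ms for e in events if e.kind == "tic"]
    rewards = [e.offset_ms for e in events if e.kind == "reward"]

    tics_per_minute = len(tics) / (duration / 60000.0) if duration > 0 else 0.0
    mean_iti = (
        fmean(b - a for a, b in zip(tics, tics[1:])) if len(tics) >= 2 else None
    )
    if tics:
        gaps = [tics[0]] + [b - a for a, b in zip(tics, tics[1:])]
        gaps.append(duration - tics[-1])
        longest = max(gaps)
    else:
        longest = duration

    undelivered = 0
    if (
        record.config.condition is Condition.NCR
        and record.ncr_source_reward_total is not None
    ):
        undelivered = max(0, record.ncr_source_reward_total - len(rewards))

    return SessionSummary(
        tic_count=len(tics),
        reward_count=len(rewards),
        undelivered_reward_count=undelivered,
        duration_ms=duration,
        tics_per_minute=tics_per_minute,
        mean_inter_tic_interval_ms=mean_iti,
        longest_tic_free_interval_ms=longest,
    )


def suppression_ratio(
    dro: SessionSummary, baseline: SessionSummary
) -> float | None:
    """Tic rate under DRO divided by tic rate at baseline.

    Values below 1 indicate suppression.  Returns ``None`` (not
    computable) when the baseline rate is zero.
    """
    if dro.duration_ms <= 0 or baseline.duration_ms <= 0:
        raise ValueError("suppression ratio requires positive session durations")
    if baseline.tics_per_minute == 0:
        return None
    return dro.tics_per_minute / baseline.tics_per_minute


def summary_table(records: Iterable["SessionRecord"]) -> "pd.DataFrame":
    """One row per session, for cross-session analysis or TSV export."""
    import pandas as pd

    rows = []
    for rec in records:
        s = rec.summary if rec.summary is not None else summarize(rec)
        rows.append(
            {
                "research_id": rec.research_id,
                "condition": rec.condition.value,
                "start_datetime": rec.start_datetime,
                "duration_ms": s.duration_ms,
                "tic_count": s.tic_count,
                "reward_count": s.reward_count,
                "undelivered_reward_count": s.undelivered_reward_count,
                "tics_per_minute": s.tics_per_minute,
                "mean_inter_tic_interval_ms": s.mean_inter_tic_interval_ms,
                "longest_tic_free_interval_ms": s.longest_tic_free_interval_ms,
            }
        )
    return pd.DataFrame(rows)
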