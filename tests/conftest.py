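from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from ticsession import (
    Condition,
    SessionConfig,
    SessionRecord,
    extract_reward_schedule,
    make_ncr_config,
    run_session,
)

START = dt.datetime(2020, 6, 22, 15, 30, 43)


def make_config(
    condition="DRZ",
    duration_ms=300_000,
    research_id="au5",
    dro_interval_ms=10_000,
    ncr_source=None,
) -> SessionConfig:
    return SessionConfig(
        condition=condition,
        planned_duration_ms=duration_ms,
        research_id=research_id,
        dro_interval_ms=dro_interval_ms,
        ncr_source=ncr_source,
    )


def random_tics(rng: np.random.Generator, duration_ms: int, max_n: int = 30) -> list[int]:
    n = int(rng.integers(0, max_n + 1))
    if n == 0:
        return []
    return sorted(set(int(t) for t in rng.integers(1, duration_ms, size=n)))


def random_record(rng: np.random.Generator, condition=None) -> SessionRecord:
    """One randomized finalized session record, any condition."""
    if condition is None:
        condition = Condition(
            str(rng.choice(["baseline", "verbal", "DRZ", "NCR"]))
        )
    duration = int(rng.integers(5_000, 120_000))
    interval = int(rng.integers(1_000, 15_000))
    tics = random_tics(rng, duration)
    start = START + dt.timedelta(seconds=int(rng.integers(0, 10_000_000)))
    source = None
    if condition is Condition.NCR:
        src = run_session(
            make_config("DRZ", duration_ms=duration, dro_interval_ms=interval),
            random_tics(rng, duration),
            start_datetime=start - dt.timedelta(hours=1),
        )
        source = extract_reward_schedule(src)
        config = make_ncr_config(source, duration, "au5", dro_interval_ms=interval)
    else:
        config = make_config(condition, duration_ms=duration, dro_interval_ms=interval)
    end_at = None
    if rng.random() < 0.3:
        end_at = int(rng.integers(1, duration))
    reason = str(rng.choice(["rater ended", "connection closed"]))
    return run_session(
        config, tics, start_datetime=start, end_at_ms=end_at, end_reason=reason
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20200622)
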