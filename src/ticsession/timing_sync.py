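"""Lag-compensated client check-in protocol for reward delivery.

The session clock lives on the server; the subject-facing client only
displays rewards.  The client periodically asks the server whether a
reward is due; the server answers with the time remaining until the
next due moment.  The client halves its measured round-trip time (RTT)
as a one-way lag estimate, schedules its reward display for the locally
estimated due moment (receipt time + remaining − RTT/2), and sleeps that
long before checking back.  The next poll doubles as confirmation: the
server is authoritative, so a tic that arrived in the meantime
invalidates the provisionally scheduled display, which is cancelled.

This module runs that loop on a virtual clock against the
:mod:`~ticsession.session_engine` state machine, with the round-trip
lag drawn from a configurable distribution, and returns the per-reward
scheduled vs delivered offsets for accuracy analysis.  Real-time
operation would wire the identical loop to the system monotonic clock;
no transport is modeled.

Each simulated round trip is split asymmetrically between the request
and response legs (uniform random fraction), while the client's
estimator assumes a symmetric link — the residual delivery error is
driven by that asymmetry, plus polling granularity around tic resets.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .session_engine import (
    SessionConfig,
    SessionRecord,
    SessionState,
    StateError,
    advance,
    finalize,
    next_reward_due,
    record_tic,
    start_session,
)
from .tic_simulator import TicStreamModel, simulate_tics

__all__ = [
    "LagModel",
    "DeliveryTrace",
    "remaining_until_reward",
    "next_check_delay",
    "run_checkin_loop",
    "delivery_error_experiment",
]

#: Minimum sleep between consecutive polls, to avoid a busy loop when the
#: estimated remaining time is ~0.
POLL_FLOOR_MS = 10.0


@dataclass(frozen=True)
class LagModel:
    """Distribution of client-server round-trip times (ms, all > 0)."""

    distribution: str  # "constant" | "uniform" | "lognormal"
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.distribution not in ("constant", "uniform", "lognormal"):
            raise ValueError(f"unknown lag distribution {self.distribution!r}")
        if self.distribution in ("constant", "uniform") and any(
            p < 0 for p in self.params
        ):
            raise ValueError("round-trip times must be nonnegative")

    @classmethod
    def constant(cls, rtt_ms: float) -> "LagModel":
        return cls("constant", (float(rtt_ms),))

    @classmethod
    def uniform(cls, low_ms: float, high_ms: float) -> "LagModel":
        if high_ms < low_ms:
            raise ValueError("uniform lag requires low <= high")
        return cls("uniform", (float(low_ms), float(high_ms)))

    @classmethod
    def lognormal(cls, median_ms: float, sigma: float = 0.5) -> "LagModel":
        if median_ms <= 0:
            raise ValueError("lognormal median must be positive")
        return cls("lognormal", (float(median_ms), float(sigma)))

    def sample_rtt(self, rng: np.random.Generator) -> float:
        if self.distribution == "constant":
            return self.params[0]
        if self.distribution == "uniform":
            return float(rng.uniform(*self.params))
        median, sigma = self.params
        return float(median * np.exp(sigma * rng.standard_normal()))


@dataclass(frozen=True)
class DeliveryTrace:
    """Per-reward (scheduled, delivered) offset pairs from one session."""

    pairs: tuple[tuple[float, float], ...]
    record: SessionRecord = field(compare=False, repr=False, default=None)

    @property
    def scheduled(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs])

    @property
    def delivered(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs])

    @property
    def errors(self) -> np.ndarray:
        """Signed delivery errors, delivered − scheduled, in ms."""
        return self.delivered - self.scheduled

    def median_abs_error(self) -> float:
        if not self.pairs:
            return 0.0
        return float(np.median(np.abs(self.errors)))


def remaining_until_reward(state: SessionState, now_ms: float) -> float | None:
    """Server's answer to a check-in: time remaining until the next
    reward is due, floored at 0; ``None`` when no reward is pending."""
    if not state.live:
        raise StateError("session has already ended")
    due = next_reward_due(state)
    if due is None:
        return None
    return max(0.0, float(due) - float(now_ms))


def next_check_delay(remaining_ms: float, rtt_ms: float) -> float:
    """How long the client sleeps before checking back: the reported
    remaining time minus the one-way lag estimate (half the measured
    round trip), floored at 0."""
    if remaining_ms < 0 or rtt_ms < 0:
        raise ValueError("remaining and rtt must be >= 0")
    return max(0.0, remaining_ms - rtt_ms / 2.0)


def run_checkin_loop(
    config: SessionConfig,
    tic_offsets: Sequence[int],
    lag: LagModel,
    seed: int,
    *,
    compensate: bool = True,
    poll_floor_ms: float = POLL_FLOOR_MS,
) -> DeliveryTrace:
    """Discrete-event simulation of the check-in protocol on a virtual clock.

    The server runs the real session engine; rater tics reach it at their
    true offsets.  The client polls, receives the remaining time after
    the sampled network delay, and schedules its reward display as
    described in the module docstring.  ``compensate=False`` disables the
    RTT/2 correction (the client sleeps the raw remaining time), for
    quantifying what the compensation buys.

    Returns the :class:`DeliveryTrace`; ``trace.record`` carries the
    finalized server-side session record, whose reward events are the
    authoritative scheduled offsets.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    state = start_session(config)
    T = config.planned_duration_ms
    tics = deque(sorted(int(t) for t in tic_offsets))
    if tics and (tics[0] < 0 or tics[-1] >= T):
        raise ValueError("tic offsets must lie within the session duration")

    claims: dict[int, float] = {}  # due offset -> provisional display time
    pairs: list[tuple[float, float]] = []
    seen = 0

    def new_rewards() -> list[int]:
        nonlocal seen
        out = [e.offset_ms for e in state.events[seen:] if e.kind == "reward"]
        seen = len(state.events)
        return out

    def feed_server(upto_ms: int) -> None:
        while tics and tics[0] <= upto_ms and state.live:
            t0 = tics.popleft()
            if t0 >= state.elapsed_ms:
                record_tic(state, t0)
        if state.live and upto_ms >= state.elapsed_ms:
            advance(state, upto_ms)

    t = 0.0  # client clock == server clock (skew is out of scope)
    while state.live and t < T:
        rtt = lag.sample_rtt(rng)
        up_fraction = rng.uniform()  # asymmetric split of this round trip
        s_time = t + rtt * up_fraction
        feed_server(min(int(s_time), T))
        t_rx = t + rtt
        for offset in new_rewards():
            # emitted since the last poll: deliver at the provisionally
            # scheduled moment, or now if the client never scheduled it
            pairs.append((float(offset), claims.pop(offset, t_rx)))
        if not state.live:
            break
        due = next_reward_due(state)
        if due is None or due > T:
            break  # nothing further this session; the client idles
        remaining = max(0.0, due - s_time)
        est = next_check_delay(remaining, rtt if compensate else 0.0)
        if est <= 0.0:
            claims.setdefault(due, t_rx)  # due by the client's estimate
            t = t_rx + poll_floor_ms
        else:
            delay = max(est, poll_floor_ms)
            claims.setdefault(due, t_rx + delay)
            t = t_rx + delay

    if state.live:
        feed_server(T)
    for offset in new_rewards():
        pairs.append((float(offset), claims.pop(offset, float(T))))
    return DeliveryTrace(pairs=tuple(pairs), record=finalize(state))


def delivery_error_experiment(
    n_sessions: int = 50,
    *,
    duration_ms: int = 300_000,
    tic_rate_per_min: float = 6.0,
    lag: LagModel | None = None,
    dro_interval_ms: int = 10_000,
    seed: int = 0,
    compensate: bool = True,
) -> np.ndarray:
    """Pooled signed delivery errors over seeded DRZ check-in simulations.

    Each session draws an independent Poisson tic stream and lag stream
    from a generator seeded by ``seed``.  The default arguments are the
    reference accuracy experiment: 50 sessions of 300 s, 6 tics/min,
    RTT ~ uniform(20, 200) ms.
    """
    if lag is None:
        lag = LagModel.uniform(20.0, 200.0)
    rng = np.random.default_rng(seed)
    errors: list[np.ndarray] = []
    for i in range(n_sessions):
        tic_seed = int(rng.integers(0, 2**31 - 1))
        lag_seed = int(rng.integers(0, 2**31 - 1))
        tics = simulate_tics(
            TicStreamModel(base_rate_per_min=tic_rate_per_min, seed=tic_seed),
            duration_ms,
        )
        config = SessionConfig(
            condition="DRZ",
            planned_duration_ms=duration_ms,
            research_id=f"sim{i}",
            dro_interval_ms=dro_interval_ms,
        )
        trace = run_checkin_loop(
            config, tics, lag, seed=lag_seed, compensate=compensate
        )
        errors.append(trace.errors)
    return np.concatenate(errors) if errors else np.empty(0)
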