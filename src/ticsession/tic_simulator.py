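"""Synthetic tic streams and rater-latency perturbations.

No generative model of tic timing is claimed here: the point-process
generators exist so that every other module is testable without human
data.  Two renewal processes are offered — Poisson (exponential
inter-tic intervals) and a gamma renewal process whose shape parameter
tunes regularity — with a multiplicative rate reduction standing in for
voluntary suppression under the DRZ/verbal conditions.

The default test persona is a base rate of 6 tics/min with a
suppression multiplier of 0.3 under reinforcement: plausible magnitudes
for a child with a recent-onset tic disorder, chosen to exercise the
engine, not fitted to any subject.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .session_engine import (
    Condition,
    DEFAULT_DRO_INTERVAL_MS,
    SessionConfig,
    SessionRecord,
    run_session,
)

__all__ = [
    "TicStreamModel",
    "RaterLatencyModel",
    "simulate_tics",
    "apply_rater_latency",
    "simulate_session",
]


@dataclass(frozen=True)
class TicStreamModel:
    """Stochastic tic-stream parameters.

    ``base_rate_per_min`` is the unsuppressed tic rate;
    ``suppression_multiplier`` in (0, 1] scales it (1 leaves the process
    unchanged), modeling voluntary suppression under DRZ or verbal
    instruction.  ``shape`` applies to the gamma renewal process only:
    shape 1 recovers Poisson, larger shapes give more regular streams.
    """

    process: str = "poisson"  # "poisson" | "gamma_renewal"
    base_rate_per_min: float = 6.0
    shape: float = 1.0
    suppression_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.process not in ("poisson", "gamma_renewal"):
            raise ValueError(f"unknown process {self.process!r}")
        if not self.base_rate_per_min > 0:
            raise ValueError("base_rate_per_min must be positive")
        if not self.shape > 0:
            raise ValueError("shape must be positive")
        if not 0 < self.suppression_multiplier <= 1:
            raise ValueError("suppression_multiplier must be in (0, 1]")

    @property
    def effective_rate_per_min(self) -> float:
        return self.base_rate_per_min * self.suppression_multiplier


@dataclass(frozen=True)
class RaterLatencyModel:
    """Nonnegative latency between a tic and the rater's keypress."""

    distribution: str = "constant"  # "constant" | "lognormal"
    mean_ms: float = 0.0
    sigma: float = 0.5  # log-scale spread, lognormal only

    def __post_init__(self) -> None:
        if self.distribution not in ("constant", "lognormal"):
            raise ValueError(f"unknown latency distribution {self.distribution!r}")
        if self.mean_ms < 0:
            raise ValueError("mean_ms must be >= 0")


def simulate_tics(model: TicStreamModel, duration_ms: int) -> list[int]:
    """Sorted integer tic offsets in the open interval (0, duration).

    Renewal gaps are drawn with mean ``1 / effective rate`` so the
    expected count over a window of length T is rate × T regardless of
    the process; offsets are rounded to the engine's millisecond grid
    (collisions, which are vanishingly rare at realistic rates, are
    dropped).
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    rng = np.random.default_rng(model.seed)
    mean_gap_ms = 60000.0 / model.effective_rate_per_min

    times: list[float] = []
    t = 0.0
    while t < duration_ms:
        if model.process == "poisson":
            gaps = rng.exponential(mean_gap_ms, size=64)
        else:
            gaps = rng.gamma(model.shape, mean_gap_ms / model.shape, size=64)
        for g in gaps:
            t += g
            if t >= duration_ms:
                break
            times.append(t)

    offsets = sorted({int(round(x)) for x in times})
    return [o for o in offsets if 0 < o < duration_ms]


def apply_rater_latency(
    offsets: Sequence[int], model: RaterLatencyModel, seed: int
) -> list[int]:
    """Shift each true tic offset by an i.i.d. nonnegative rater latency.

    Models the gap between a tic and the rater's keypress; the result is
    re-sorted (a slow mark can overtake a fast one).
    """
    offsets = list(offsets)
    if any(b < a for a, b in zip(offsets, offsets[1:])):
        raise ValueError("offsets must be sorted")
    rng = np.random.default_rng(seed)
    if model.distribution == "constant":
        lat = np.full(len(offsets), model.mean_ms)
    else:
        # parametrized so the latency mean equals mean_ms
        mu = np.log(model.mean_ms) - model.sigma**2 / 2 if model.mean_ms > 0 else None
        lat = (
            rng.lognormal(mu, model.sigma, size=len(offsets))
            if mu is not None
            else np.zeros(len(offsets))
        )
    return sorted(int(round(o + l)) for o, l in zip(offsets, lat))


def simulate_session(
    condition: Condition | str,
    duration_ms: int,
    model: TicStreamModel,
    research_id: str,
    *,
    dro_interval_ms: int = DEFAULT_DRO_INTERVAL_MS,
    ncr_source=None,
    latency: RaterLatencyModel | None = None,
    start_datetime: _dt.datetime | None = None,
    end_at_ms: int | None = None,
    end_reason: str = "rater ended",
) -> SessionRecord:
    """Run one fully simulated session and return its finalized record.

    Drives the engine with a simulated tic stream; handy for emitting
    ``.ttsd`` fixtures (pass the result to ``session_log.archive``).
    """
    config = SessionConfig(
        condition=condition,
        planned_duration_ms=duration_ms,
        research_id=research_id,
        dro_interval_ms=dro_interval_ms,
        ncr_source=ncr_source,
    )
    tics = simulate_tics(model, duration_ms)
    if latency is not None:
        tics = [t for t in apply_rater_latency(tics, latency, model.seed + 1) if t < duration_ms]
    return run_session(
        config,
        tics,
        start_datetime=start_datetime,
        end_at_ms=end_at_ms,
        end_reason=end_reason,
    )
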