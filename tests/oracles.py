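"""Independent reference implementations used to check the engine.

The brute-force simulator walks the session clock one millisecond at a
time and applies the contingency rules literally, with no scheduling
shortcuts; it shares no code with the engine.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def brute_force_rewards(
    condition: str,
    duration_ms: int,
    dro_interval_ms: int,
    tic_offsets: Iterable[int],
    ncr_offsets: Sequence[int] = (),
) -> list[int]:
    """Reward offsets from a 1-ms-step walk of one session.

    DRZ: a reward fires at the first millisecond at which the time since
    the last tic *or* reward equals the interval; a tic landing on that
    exact millisecond pre-empts the reward.  NCR: rewards fire at the
    replayed offsets regardless of tics.  Other conditions never reward.
    """
    tics = set(int(t) for t in tic_offsets)
    ncr = set(int(o) for o in ncr_offsets)
    rewards: list[int] = []
    last_reset = 0
    for t in range(1, int(duration_ms) + 1):
        is_tic = t in tics
        if is_tic:
            last_reset = t
        if condition == "DRZ" and not is_tic and t - last_reset == dro_interval_ms:
            rewards.append(t)
            last_reset = t
        if condition == "NCR" and t in ncr:
            rewards.append(t)
    return rewards
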