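"""Engine behavior: condition gating, DRO countdown, NCR replay, liveness."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_config
from oracles import brute_force_rewards
from ticsession import (
    Condition,
    ConfigurationError,
    RewardSchedule,
    SessionConfig,
    StateError,
    advance,
    end_session,
    next_reward_due,
    record_tic,
    run_session,
    start_session,
)


class TestStartSession:
    def test_baseline_construction(self):
        state = start_session(make_config("baseline"))
        assert state.live
        assert len(state.events) == 1
        assert state.events[0].kind == "session_start"
        assert state.events[0].offset_ms == 0
        assert state.last_reset_ms == 0

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(condition="NCR"), "ncr_source"),
            (dict(duration_ms=0), "planned_duration_ms"),
            (dict(duration_ms=-5), "planned_duration_ms"),
            (dict(dro_interval_ms=0), "dro_interval_ms"),
            (dict(research_id="a_5"), "research_id"),
            (dict(research_id="a 5"), "research_id"),
            (dict(research_id=""), "research_id"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            start_session(make_config(**kwargs))

    def test_non_ncr_session_rejects_source(self):
        sched = RewardSchedule((10_000,), "au5_20200622-153125_DRZ.ttsd", "au5")
        with pytest.raises(ConfigurationError, match="ncr_source"):
            start_session(make_config("DRZ", ncr_source=sched))

    def test_ncr_source_must_match_subject(self):
        sched = RewardSchedule((10_000,), "au5_20200622-153125_DRZ.ttsd", "au5")
        with pytest.raises(ConfigurationError, match="subject"):
            start_session(make_config("NCR", research_id="bu7", ncr_source=sched))

    def test_first_drz_reward_due_one_interval_in(self):
        state = start_session(make_config("DRZ"))
        assert next_reward_due(state) == 10_000


class TestDroCountdown:
    def test_countdown_restarts_at_each_tic(self):
        # tics at 3 s and 7 s: first full tic-free interval ends at 17 s
        rec = run_session(make_config("DRZ"), [3_000, 7_000])
        expected = brute_force_rewards("DRZ", 300_000, 10_000, [3_000, 7_000])
        assert rec.reward_offsets()[0] == 17_000
        assert list(rec.reward_offsets()) == expected

    def test_tic_free_session_rewards_on_interval_grid(self):
        rec = run_session(make_config("DRZ"), [])
        assert list(rec.reward_offsets()) == list(range(10_000, 300_001, 10_000))
        assert rec.events[-1].kind == "session_end"
        assert rec.events[-1].detail == "duration elapsed"

    def test_advance_strictly_before_due_emits_nothing(self):
        state = start_session(make_config("DRZ"))
        _, emitted = advance(state, 9_999)
        assert emitted == []

    def test_tic_on_exact_due_offset_preempts_reward(self):
        rec = run_session(make_config("DRZ", duration_ms=25_000), [10_000])
        assert list(rec.reward_offsets()) == [20_000]

    def test_reward_resets_countdown(self):
        # after the 10 s reward, a tic at 12 s restarts from 12 s, not 10 s
        rec = run_session(make_config("DRZ", duration_ms=30_000), [12_000])
        assert list(rec.reward_offsets()) == [10_000, 22_000]


class TestNcr:
    def _config(self, offsets, duration_ms=300_000):
        sched = RewardSchedule(
            tuple(offsets), "au5_20200622-153125_DRZ.ttsd", "au5"
        )
        return make_config("NCR", duration_ms=duration_ms, ncr_source=sched)

    def test_replay_ignores_tics(self):
        rec = run_session(self._config([10_000, 20_000]), [9_999])
        assert list(rec.reward_offsets()) == [10_000, 20_000]

    def test_next_due_is_first_undelivered_offset(self):
        state = start_session(self._config([10_000, 20_000, 35_000]))
        advance(state, 15_000)
        assert next_reward_due(state) == 20_000

    def test_offsets_beyond_duration_are_dropped(self):
        rec = run_session(self._config([10_000, 400_000]))
        assert list(rec.reward_offsets()) == [10_000]
        assert rec.summary.undelivered_reward_count == 1

    def test_reward_coinciding_with_tic_is_still_delivered_after_it(self):
        rec = run_session(self._config([10_000]), [10_000])
        kinds = [e.kind for e in rec.events if e.offset_ms == 10_000]
        assert kinds == ["tic", "reward"]


class TestConditionGating:
    @pytest.mark.parametrize("condition", ["baseline", "verbal"])
    def test_no_reward_pathway(self, condition):
        state = start_session(make_config(condition))
        assert next_reward_due(state) is None
        rec = run_session(make_config(condition), [1_000, 2_000])
        assert rec.reward_offsets() == ()

    def test_rewards_enabled_flag(self):
        assert Condition.DRZ.rewards_enabled and Condition.NCR.rewards_enabled
        assert not (Condition.BASELINE.rewards_enabled or Condition.VERBAL.rewards_enabled)


class TestLiveness:
    def test_tic_after_session_end_errors(self):
        state = start_session(make_config("DRZ", duration_ms=20_000))
        advance(state, 20_000)
        with pytest.raises(StateError):
            record_tic(state, 21_000)

    def test_double_end_errors(self):
        state = start_session(make_config("baseline"))
        end_session(state, 10_000, "rater ended")
        with pytest.raises(StateError):
            end_session(state, 11_000, "rater ended")

    def test_early_end_records_given_duration_and_reason(self):
        state = start_session(make_config("baseline"))
        rec = end_session(state, 150_000, "rater ended")
        assert rec.duration_ms == 150_000
        assert rec.end_reason == "rater ended"

    def test_end_beyond_planned_duration_is_clamped(self):
        state = start_session(make_config("baseline"))
        rec = end_session(state, 400_000, "connection closed")
        assert rec.duration_ms == 300_000

    def test_unknown_end_reason_rejected(self):
        state = start_session(make_config("baseline"))
        with pytest.raises(ValueError, match="end reason"):
            end_session(state, 1_000, "gave up")

    def test_clock_cannot_move_backwards(self):
        state = start_session(make_config("DRZ"))
        advance(state, 5_000)
        with pytest.raises(StateError):
            record_tic(state, 4_000)


@st.composite
def session_cases(draw):
    duration = draw(st.integers(2_000, 40_000))
    interval = draw(st.integers(500, 15_000))
    tics = sorted(
        set(draw(st.lists(st.integers(1, duration - 1), max_size=30)))
    )
    return duration, interval, tics


@settings(max_examples=120, derandomize=True, deadline=None)
@given(session_cases())
def test_engine_matches_millisecond_oracle(case):
    """The scheduling engine reproduces a literal 1-ms-step simulation."""
    duration, interval, tics = case
    rec = run_session(
        make_config("DRZ", duration_ms=duration, dro_interval_ms=interval), tics
    )
    assert list(rec.reward_offsets()) == brute_force_rewards(
        "DRZ", duration, interval, tics
    )
    assert list(rec.tic_offsets()) == tics


@settings(max_examples=120, derandomize=True, deadline=None)
@given(session_cases())
def test_dro_safety_and_spacing(case):
    """No reward lands within one interval of a preceding tic, and
    consecutive rewards are at least one interval apart."""
    duration, interval, tics = case
    rec = run_session(
        make_config("DRZ", duration_ms=duration, dro_interval_ms=interval), tics
    )
    rewards = rec.reward_offsets()
    for r in rewards:
        assert not any(r - interval < t <= r for t in tics)
    assert all(b - a >= interval for a, b in zip(rewards, rewards[1:]))


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(2_000, 200_000), st.integers(500, 15_000))
def test_tic_free_session_reward_count(duration, interval):
    """A tic-free DRZ session of duration T yields floor(T / interval) rewards."""
    rec = run_session(
        make_config("DRZ", duration_ms=duration, dro_interval_ms=interval), []
    )
    assert len(rec.reward_offsets()) == duration // interval


def test_event_ordering_invariant():
    rec = run_session(make_config("DRZ"), [3_000, 7_000, 17_000])
    keys = [e.sort_key() for e in rec.events]
    assert keys == sorted(keys)
    assert rec.events[0].kind == "session_start"
    assert rec.events[-1].kind == "session_end"
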