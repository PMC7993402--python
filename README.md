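# ticsession

A headless, testable session engine for the **tic suppression paradigm**
(TSP), the Woods–Himle experimental protocol used in Tourette-syndrome
and Provisional Tic Disorder research to quantify how well a participant
can voluntarily suppress tics under different reinforcement conditions.

A TSP visit consists of short observation sessions run by a tic-expert
rater under four conditions:

| condition  | instruction | rewards |
|------------|-------------|---------|
| `baseline` | none        | none    |
| `verbal`   | "please suppress your tics" | none |
| `DRZ`      | suppress    | one reward after **every 10-s tic-free interval** (differential reinforcement of zero-rate ticcing, DRO) |
| `NCR`      | none        | rewards **replayed at the exact offsets** of a previous session of the same subject, irrespective of tics (noncontingent reinforcement) |

`ticsession` provides:

- a deterministic **session state machine** on an integer-millisecond
  virtual clock (`session_engine`): tic marks in, reward and termination
  events out, for all four conditions;
- the plain-text **`.ttsd` session-log format** (`session_log`): streamed
  event lines, an appended summary block, a strict parser, and the
  archive naming convention `<id>_<YYYYMMDD-HHMMSS>_<condition>.ttsd`;
- **NCR replay** (`ncr_replay`): extract a reward schedule from an
  archived log and drive a new session with it, enforcing the
  same-subject requirement;
- **summary statistics** (`metrics`): tic counts and rates, inter-tic
  intervals, longest tic-free gap, undelivered NCR rewards, and the
  suppression ratio (DRO rate / baseline rate; < 1 indicates
  suppression);
- a **lag-compensated delivery simulation** (`timing_sync`): in a
  remote, browser-based deployment the session clock lives on a server
  and the subject's client must display each reward on time despite
  network lag.  The client polls, the server answers with the time
  remaining until the next reward is due, and the client subtracts half
  its measured round-trip time (RTT) before scheduling the display.
  This module simulates that whole loop on a virtual clock and measures
  per-reward delivery error;
- a **synthetic tic-stream generator** (`tic_simulator`): Poisson or
  gamma-renewal processes with a suppression multiplier, plus a
  rater-keypress latency model, so every component is testable without
  human data;
- a **CLI** (`ticsession`): live keyboard-driven sessions, fully
  simulated sessions, NCR replay, and log summarization.

## The DRO contingency, precisely

Let `I` be the reward interval (default 10 000 ms) and `last_reset` the
most recent of session start, last tic, and last reward.  A reward is
due at exactly `last_reset + I`; delivering it restarts the countdown,
so an undisturbed suppression streak earns one reward per interval.  A
tic at the exact due instant pre-empts the reward — an interval
containing a tic is never rewarded.  A tic-free session of duration `T`
therefore yields exactly `⌊T / I⌋` rewards.

Reward timing under lag: the client's one-way lag estimate is RTT/2, so
after receiving "remaining = R" over a round trip of `r` ms it schedules
the display `max(0, R − r/2)` ms later and confirms on its next poll
(the server is authoritative; an intervening tic cancels the
provisional display).  The residual delivery error is driven by the
asymmetry between the request and response legs, which the simulation
draws at random within each sampled round trip.

## Worked example

```sh
ticsession simulate --condition baseline --id au5 --duration 300 --rate 6 --seed 11 \
    --at 2020-06-22T15:30:43 --out logs
ticsession simulate --condition DRZ --id au5 --duration 300 --rate 6 --seed 11 \
    --at 2020-06-22T15:31:25 --out logs
ticsession replay --source logs/au5_20200622-153125_DRZ.ttsd --id au5 \
    --duration 300 --rate 6 --seed 12 --at 2020-06-22T15:32:14 --out logs
ticsession summarize logs/*.ttsd
```

The DRZ run prints:

```
condition:              DRZ
duration:               300.0 s (duration elapsed)
tics:                   12 (2.40/min)
rewards delivered:      23
longest tic-free gap:   126.4 s
archived: logs/au5_20200622-153125_DRZ.ttsd
```

Twelve simulated tics (the generator applies its default suppression
multiplier of 0.3 under DRZ, thinning the 6/min base rate) reset the
10-s countdown twelve times, leaving 23 of the 30 possible rewards.
The replay run delivers rewards at *exactly* those 23 offsets — its own
25 tics at 5.0/min are irrelevant to reward timing, which is the point
of the NCR control.  The suppression ratio for this pair is

```python
>>> from ticsession import load, suppression_ratio
>>> drz = load("logs/au5_20200622-153125_DRZ.ttsd").summary
>>> base = load("logs/au5_20200622-153043_baseline.ttsd").summary
>>> suppression_ratio(drz, base)
0.4444444444444445
```

i.e. the simulated subject ticced at 44 % of their baseline rate under
reinforcement.  Each archived `.ttsd` file is line-oriented UTF-8 — a
header, one tab-separated line per event, and an appended summary —
e.g.:

```
ttw-spec-1
research_id	au5
condition	DRZ
start_datetime	2020-06-22 15:31:25
planned_duration_ms	300000
dro_interval_ms	10000
0	session_start	
7653	tic	
...
==== summary ====
tic_count	12
reward_count	23
...
```

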