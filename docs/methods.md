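# Methods

## Session model

A session is a totally ordered stream of events — `session_start`,
`tic`, `reward`, `session_end` — at integer-millisecond offsets from
session start.  At equal offsets events order by kind priority
(start < tic < reward < end).  The engine is a deterministic state
machine over `(elapsed, last_reset, events, live)` where `last_reset`
is the start of the current tic-free countdown: the maximum of session
start, latest tic and latest reward.  Wall-clock time appears exactly
once, as the start datetime recorded for archiving; everything else is
session-relative, which makes runs reproducible on a virtual clock and
lets the identical engine drive live keyboard sessions.

Condition semantics:

- **baseline / verbal** — no reward pathway; the verbal instruction is
  delivered by the rater, not the software, so the engine treats the two
  identically apart from the condition code in logs.
- **DRZ (DRO)** — reward due at `last_reset + I`, default
  `I = 10 000 ms`.  The countdown restarts at every tic *and* at every
  reward, so sustained suppression earns one reward per interval.  The
  due time is a closed right endpoint, and a tic landing on the exact
  due millisecond pre-empts the reward: an interval containing a tic is
  never rewarded.  (Whether the original apparatus restarts its timer at
  reward delivery or runs a fixed grid is unobservable from tic-free
  behavior — the two coincide there; restart-at-reward is the
  conservative contingency and is what this package implements.)
- **NCR** — rewards replay the offsets of a prior session of the same
  subject (enforced by research-ID equality; the enforcement mechanism
  is this package's choice).  Replay offsets are tracked by a pointer,
  not by clock comparison, so an offset coinciding exactly with a tic is
  still delivered (ordered after the tic).  Offsets beyond the NCR
  session's duration are dropped and counted in the summary as
  undelivered.  Ending an NCR session early simply stops the replay;
  the remainder is likewise counted undelivered.

Sessions end when the planned duration elapses, or early with reason
`"rater ended"` or `"connection closed"`; the three reason strings are a
fixed vocabulary so logs stay machine-parseable.  End offsets are
clamped to the planned duration.  Rewards still pending at the end
offset are delivered before the end event.

`record_tic` flushes any rewards that fell due strictly before the tic
offset before appending the tic.  In live operation `advance` runs
continuously and this never triggers; in batch replay it makes a tic
list produce exactly the live event sequence.

## Log format (`ttw-spec-1`)

`.ttsd` files are line-oriented UTF-8: a version line, tab-separated
header fields (subject, condition, start datetime to the second, planned
duration, DRO interval, and for NCR the source filename and its total
reward count), one `offset<TAB>kind<TAB>detail` line per event, a
sentinel line, then the summary block.  Serialization is byte-
deterministic; the parser re-sorts events defensively, recomputes the
summary from the event lines, and rejects any log whose embedded summary
disagrees (integers exactly, rates to 1 µ-unit tolerance).  The NCR
source reward total is carried in the header because the undelivered
count cannot be recovered from delivered events alone; without it the
round-trip and summary-consistency guarantees could not both hold.
Archive names are `<research_id>_<YYYYMMDD-HHMMSS>_<condition>.ttsd`;
research IDs therefore may not contain underscores, path separators or
whitespace.  The grammar is this package's documented dialect,
versioned in the first line; byte compatibility with other tools'
`.ttsd` files is not claimed.

## Lag-compensated delivery protocol

In remote deployment the server owns the session clock and the
subject's client only displays rewards.  The simulated protocol:

1. The client polls at `t`; the request arrives after the uplink delay;
   the server applies any rater tics up to its current clock and
   answers with `remaining = max(0, due − now_server)`.
2. The client receives the answer at `t + r` (measured round trip `r`)
   and schedules its reward display `max(0, remaining − r/2)` ms later —
   `r/2` being its one-way lag estimate under a symmetric-link
   assumption.  If the adjusted remaining is already ≤ 0 it displays
   immediately.
3. The client checks back at the scheduled moment (one poll per computed
   delay; a 10 ms polling floor prevents busy-looping near a due time).
   The server is authoritative: a tic that arrived after the last answer
   shifts or cancels the due time, the provisional display is cancelled,
   and the loop continues with the fresh answer.  A reward the server
   emitted that the client never scheduled (possible after late-session
   resets) is displayed at the next poll receipt.

Delivery error is `delivered − scheduled` per reward, where the
scheduled offsets are the engine's authoritative reward events.  Each
simulated round trip is drawn from the configured distribution
(constant, uniform or lognormal) and split between request and response
legs by an independent uniform fraction; the client's `r/2` estimator is
exact only for a symmetric split, so the residual error is the
leg asymmetry `(down − up)/2`, bounded by `r/2`.  With constant
`r = 100 ms` every error is within 50 ms (closed form); with
`r ~ uniform(20, 200) ms` the median absolute error is ≈ 20–25 ms.
Disabling the compensation (sleeping the raw remaining time) roughly
doubles the median error to ≈ the downlink delay, which is what the
`compensate=False` switch quantifies.  With zero lag the trace
degenerates to the engine's own schedule exactly.

Clock skew between client and server is out of scope (both run on the
simulation's single virtual clock), as is any real transport.

## Synthetic tic streams

`tic_simulator` generates renewal processes with mean gap
`60000 / (base_rate × suppression_multiplier)` ms: exponential gaps
(Poisson) or gamma gaps whose shape parameter tunes regularity (shape 1
is Poisson; larger shapes emulate the quasi-rhythmic streams some
subjects show).  The default persona — 6 tics/min base rate, multiplier
0.3 under reinforcement — is a plausible magnitude for a child with a
recent-onset tic disorder, chosen once to exercise the contingency
machinery; it is not fitted to any subject.  A rater-latency model
(constant or lognormal with matched mean) shifts true tic times by
nonnegative keypress delays.  What the generator does *not* emulate:
tic bouts and hazard-rate dependence on time-since-reward, rater misses
and false alarms, and within-session drift in tic rate.  Passing tests
therefore demonstrate the correctness of the scheduling, logging and
timing machinery under realistic event densities — not any clinical
claim about tic dynamics.

## Numerical and testing choices

- All engine arithmetic is integer milliseconds; the timing simulation
  uses float milliseconds and only converts to the engine grid when
  feeding the server clock.
- The engine is verified against an independent 1-ms-step brute-force
  simulator (literal rule application, no scheduling): exact event-list
  equality over randomized sessions.  Property tests use sessions of
  2–90 s with intervals of 0.5–15 s so the millisecond-step oracle stays
  cheap; the contingency has no duration-dependent behavior beyond the
  reward count, and the reference 300-s tic-free grid is checked
  explicitly.
- The delivery-accuracy experiment defaults to 50 sessions × 300 s,
  matching the reference configuration reported by the acceptance
  script; session-level seeds are drawn below 2³¹ from one root
  generator so the whole experiment is reproducible from a single seed.
- Degenerate inputs: empty tic streams, empty NCR schedules, sessions
  ended at offset < first due time, and tic/reward offset collisions all
  have defined behavior and dedicated tests.

## Known limitations

- The interactive `run` subcommand requires a tty and is exercised only
  for flag validation in the automated suite.
- The lag model is stationary and i.i.d. per round trip; bursty loss or
  autocorrelated congestion would widen the error tails.
- `suppression_ratio` compares raw rates and deliberately implements no
  inferential statistics across subjects or visits.
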