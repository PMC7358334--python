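# Methods

This document states what the simulator and analysis pipeline actually
compute: the task model, the synthetic mouse, the estimators, and every
numerical convention a reader would need to reproduce a number.

## Task model

The controller is a discrete-event state machine over three nosepoke ports
(L, C, R) and integer-millisecond time. Between events the state is one of
four phases:

| Phase | Meaning |
|---|---|
| `ITI` | intertrial interval; ports dark |
| `AWAIT_INITIATION` | center port blinking; a center poke starts the trial (self-initiation paradigms only) |
| `DELAY` | post-initiation hold period before the cue (2-CSRTT only) |
| `CUE` | cue lit; the subject's response (or the window expiring) closes the trial |

Two kinds of input drive transitions: subject pokes and timer expiries.
When a poke and a timer expiry fall on the same millisecond, **the poke is
processed first**. The transition function (`nosepoke.engine.step`) is pure:
given a state, a paradigm spec, an event and a random stream, it returns
the next state and the event records to log, so the controller can be
replayed and unit-tested in isolation.

### Paradigms

| ID | Cue | Response window | Self-initiated | Incorrect side |
|---|---|---|---|---|
| P1 | center lit | unlimited | no | — |
| P2 | both sides lit | unlimited | no | — (both are correct) |
| P3 | both sides lit | unlimited | yes | — |
| P4a | one random side | unlimited | yes | no consequence; trial continues |
| P4b | one random side | 5 s | yes | terminates the trial |
| P4c | one random side | 1.5 s | yes | terminates the trial |
| CSRTT | one random side, after a 3/6/9 s delay | 1.5 s | yes | terminates the trial |

Rewards are always dispensed at the center port. In P2 the center poke that
collects the reward is additionally tagged as a retrieval. During the CSRTT
delay, side pokes are logged as premature responses but have no
programmed consequence (the trial is not aborted); this is the task's
impulsivity readout. Each trial closes with exactly one outcome —
correct, incorrect, or omission — so `initiated = correct + incorrect +
omitted` holds identically.

### Intertrial interval

The default ITI law is uniform on [30, 60] s (mean 45 s); fixed and
exponential laws with the same mean are available. The uniform bounds are
validated to average to the paradigm's stated ITI mean.

### Truncated trials

A session or log file can end mid-trial. The engine's live counters count
only closed trials, and the offline reconstruction drops an unclosed final
trial with a warning, so the two pipelines agree exactly. A
paradigm-switch marker likewise closes the bookkeeping without inventing an
outcome.

## Calibration

Dispensed volume is linear in solenoid open time:
`v(ml) = 0.156 · t(s) − 0.00134` (r² = 0.999, dispense CV ≈ 3.4%).
Firmware open times are whole milliseconds, **rounded down** so a dispense
never exceeds its target; a 10 µl target therefore maps to 72 ms, which
the line evaluates to 9.89 µl. Open times below the valve's effective
minimum (where the line predicts negative volume) are rejected.

## Synthetic mouse

The agent sees only what a real mouse could see — cue states, never the
controller's internal timers — and produces pokes from four mechanisms:

1. **Spontaneous poking.** A piecewise-homogeneous Poisson process over the
   12/12 light cycle, with separate hourly rates per port in dark
   (default 20) and light (default 2). Dark-dominant rates make the agent
   nocturnal; trial initiation then concentrates in the dark phase without
   any explicit circadian engagement term.
2. **Engagement.** On each entry into a response-relevant phase the agent
   decides once (Bernoulli, `p_engage`) whether to engage, and if so draws
   an exponential latency (`engage_latency_scale`) to the center port.
3. **Cue responses.** When a cue is lit the agent responds after an
   exponential latency (`response_latency_scale`, default 0.35 s), choosing
   the correct port with probability `p_correct` (default 0.85). Omissions
   are not a separate mechanism: they occur whenever the latency draw
   exceeds the response window.
4. **Premature responses.** During the delay, side pokes arrive as a
   Poisson process with constant hazard `premature_hazard` (default
   0.1 /s), in addition to the spontaneous background. A constant hazard
   predicts premature counts proportional to delay length, which the
   simulated data reproduce.

The agent does **not** model satiety, learning, motor refractory periods,
or within-phase attention drift; rates and probabilities are stationary
within a light phase.

## Parameter recovery

`nosepoke.agent.recover_params` inverts the model by method of moments,
from events alone:

- `p_correct` = correct / (correct + incorrect) over attempted trials.
- `premature_hazard` = side pokes per second of delay time, minus the
  spontaneous per-port background estimated from idle spans (below).
- `rate_dark`, `rate_light` = side-port pokes during idle spans (ITI +
  awaiting-initiation), divided by 2 × idle time in the corresponding
  light phase. Only side pokes are used because idle spans end on center
  pokes: counting center pokes there would bias the rate upward by
  construction, whereas side pokes are selection-free. Phase boundaries
  crossing a span are split at the lights transition.

At realistic scales (≳1000–2000 trials) accuracy comes back within ±0.03
and the hazard within ~10%; the light-phase rate is the noisiest estimate
because little idle time falls in the light phase.

## Log format

One header block of `# key: value` lines (schema version, box, subject,
paradigm, ISO-8601 session start, lights-on hour, IR-beam status), then one
TAB-separated line per event: `t_ms  code  port  arg`. The event-code
table is closed (15 codes: pokes, cue transitions, phase markers, reward,
outcomes, retrieval, paradigm switch); unknown codes in foreign files are
preserved and reported rather than dropped. A `column_map` lets the reader
ingest dialects with reordered columns. Multi-file concatenation rebases
each file by its wall-clock session start and refuses overlapping files.

## Metrics conventions

- Trials are reconstructed from phase markers; each is assigned to a bin by
  its **initiation time**. Pokes and rewards are binned by their own
  timestamps.
- Bins are half-open `[start, end)`, anchored at the lights-on boundary, so
  "daily" means lights-on to lights-on, not midnight to midnight.
- Proportions over an empty bin are **missing (NaN), never zero**; the same
  holds for accuracy over bins with no attempted trials.
- Available schemes: `hourly`, `two_hour`, `daily`, `light_dark_phase`,
  `relative_to` (a reference time with custom hour edges, e.g. around an
  injection), `per_delay_3day_average` (per-day averages grouped by delay),
  and `session` (one bin).
- Welfare: a subject is flagged for removal on the third consecutive day
  with ≤100 rewards, or immediately on >10% loss from baseline weight.
  Missing days or weights are an error, not silently skipped.

Every metrics cell is cross-checked in the test suite against an
independent brute-force recount (`tests/oracle.py`) that shares no code
with the pipeline and finds trials by backward scans from outcome markers.

## Determinism and seeding

All randomness flows from `numpy.random.SeedSequence`. A session seed is
spawned into separate engine and agent streams; the batch simulator derives
per-subject, per-day seeds as `SeedSequence([master, subject, day])` (all
below 2³¹). Identical seeds produce byte-identical log files.

## Limitations

The simulator models the task contingencies and a stationary stochastic
subject, not mouse physiology: there is no acquisition curve, no
within-session satiation, and no inter-individual variability beyond the
supplied parameters. Hardware imperfections (beam-break chatter, solenoid
wear, clock drift between boxes) are not modeled, although the log reader
tolerates and reports unknown event codes from such sources.
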