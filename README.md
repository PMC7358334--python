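# nosepoke

Simulation and analysis of homecage operant nosepoke tasks, centered on a
two-choice serial reaction time task (2-CSRTT) for measuring impulsive
action in mice.

In the real apparatus a mouse lives with a three-port nosepoke wall (left,
center, right) and works for ~10 µl water rewards around the clock, with no
experimenter-imposed sessions. Training progresses through staged paradigms
— reward retrieval, continuous reinforcement, self-initiation, cue
discrimination — and culminates in the 2-CSRTT: the animal initiates a
trial at the blinking center port, must withhold responding through a 3, 6
or 9 s delay, then respond to a brief side cue. Side pokes during the delay
are *premature responses*, the operational readout of impulsive action.

This package provides the full loop in software:

- **`nosepoke.engine`** — a deterministic discrete-event controller for
  every training paradigm (P1–P4c and the 2-CSRTT), implemented as a pure
  state-transition function plus a closed-loop session runner.
- **`nosepoke.agent`** — a synthetic mouse: nocturnal spontaneous poking
  (piecewise-Poisson over the 12/12 light cycle), probabilistic engagement,
  cue accuracy, response latencies, and a constant premature-response
  hazard during the delay. Also method-of-moments recovery of those
  parameters back from a log.
- **`nosepoke.logio`** — a plain-text TAB-separated event-log dialect with
  a closed event-code table, plus multi-file concatenation on a wall-clock
  axis.
- **`nosepoke.metrics`** — trial reconstruction from raw events, binned
  behavioral measures (hourly / two-hour / daily / light-dark phase /
  relative-to-reference / per-delay averages), and welfare monitoring
  flags.
- **`nosepoke.calibration`** — the linear solenoid open-time ↔ volume
  model used to dispense calibrated rewards.
- **`nosepoke.cli`** — a thin `nosepoke` command wrapping simulate /
  analyze / schedule / calibrate.

## A worked example

Simulate a 24-hour session at each delay and recount premature responses
from the logs alone (`examples/premature_by_delay.py`):

```python
from nosepoke import (AgentParams, CircadianClock, ParadigmSpec,
                      bin_metrics, reconstruct_trials, run_session)

params = AgentParams(premature_hazard=0.15)   # pokes per second of delay
for delay in (3.0, 6.0, 9.0):
    spec = ParadigmSpec.named("CSRTT", delay=delay)
    res = run_session(spec, params, duration_hours=24.0, seed=int(delay) * 101)
    trials, _ = reconstruct_trials(res.events)
    clock = CircadianClock(res.header.session_start, 7)
    row = bin_metrics(trials, res.events, "session", clock=clock).iloc[0]
    print(delay, row["trials_initiated"], row["premature_per_trial"],
          row["prop_correct"])
```

Output:

```
delay (s)  trials  premature/trial  prop_correct
       3     213             0.51          0.85
       6     234             1.02          0.83
       9     213             1.54          0.85
```

Premature responding rises with delay while accuracy holds steady — the
signature the task is designed to elicit. More narrative walkthroughs live
in `examples/`: calibration arithmetic, single-session simulation with log
output, and parameter recovery.

The same loop from the shell:

```sh
nosepoke simulate --subjects 4 --days 3 --seed 7 -o run1/
nosepoke analyze run1/ --scheme daily -o metrics.csv
nosepoke schedule            # the staged training protocol
nosepoke calibrate --volume 10
```

`simulate` writes one log file per subject per day plus a
`config_snapshot.yaml` recording the exact configuration; identical seeds
give byte-identical logs. `analyze` groups files by subject and writes a
per-subject metrics table and a group mean ± SEM summary.

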