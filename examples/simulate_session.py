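"""Simulate one serial-reaction-time session and write its event log.

A synthetic mouse (nocturnal spontaneous poking, 85% cue accuracy, a
premature-response hazard during the delay) runs a 6-s-delay session for
24 h.  The engine's live counters summarize the session; the log is the
same plain-text format a physical box would produce.
"""

from datetime import datetime
from pathlib import Path

from nosepoke import AgentParams, ParadigmSpec, run_session, write_log

spec = ParadigmSpec.named("CSRTT", delay=6.0)
params = AgentParams()  # defaults: dark-dominant poking, p_correct 0.85

res = run_session(
    spec, params, duration_hours=24.0, seed=12345,
    session_start=datetime(2021, 6, 1, 10, 0, 0), subject_id="demo01",
)

c = res.counters
print(f"paradigm {spec.paradigm_id}, delay {spec.delay} s, 24 h")
print(f"trials initiated : {c.trials_initiated}")
print(f"  correct        : {c.correct}")
print(f"  incorrect      : {c.incorrect}")
print(f"  omissions      : {c.omissions}")
print(f"rewards earned   : {c.rewards}")
print(f"delay side pokes : {c.delay_side_pokes}  (premature responses)")
print("a healthy subject earns well over 100 rewards per day")

out = Path("demo01_csrtt6.log")
write_log(res.header, res.events, out)
print(f"\nwrote {len(res.events)} events to {out}")
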