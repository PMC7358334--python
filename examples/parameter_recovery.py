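"""Recover the generative agent parameters back from an event log.

A simulation is only trustworthy if the analysis pipeline can read the
generating parameters back out of its logs.  Here we simulate 36 h with
known parameters, then estimate them from the raw events by method of
moments and compare.
"""

from nosepoke import AgentParams, CircadianClock, ParadigmSpec, run_session
from nosepoke.agent import recover_params

truth = AgentParams(
    rate_dark=20.0, rate_light=2.0,        # spontaneous pokes per hour
    p_correct=0.85, premature_hazard=0.2,  # hazard in pokes per delay second
    p_engage=1.0, engage_latency_scale=0.5, response_latency_scale=0.2,
)
spec = ParadigmSpec.named("CSRTT", delay=9.0)
res = run_session(spec, truth, duration_hours=36.0, seed=2024)

clock = CircadianClock(res.header.session_start, 7)
rec = recover_params(res.events, clock=clock)

print(f"trials used: {rec.n_trials}\n")
print(f"{'parameter':18}{'true':>8}{'recovered':>12}")
for name, t, r in [
    ("p_correct", truth.p_correct, rec.p_correct),
    ("premature_hazard", truth.premature_hazard, rec.premature_hazard),
    ("rate_dark", truth.rate_dark, rec.rate_dark),
    ("rate_light", truth.rate_light, rec.rate_light),
]:
    print(f"{name:18}{t:8.2f}{r:12.2f}")

print("\naccuracy and hazard come back within a few percent at this scale;")
print("the light-phase rate is the noisiest (little light-phase idle time).")
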