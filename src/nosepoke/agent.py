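"""Generative synthetic-mouse model.

The agent produces the poke stream that drives the paradigm engine.  It is
deliberately simple — a stationary stochastic behavioral model, not a
learning animal — but reproduces the structural features the metrics
pipeline must handle:

* **Circadian activity**: spontaneous nosepoking is a Poisson process whose
  per-port rate steps between a dark-phase and a light-phase level
  (nocturnal by default).
* **Trial engagement**: when the center port blinks, the agent initiates
  with probability ``p_engage`` at an exponential latency; independently,
  spontaneous center pokes also initiate trials, which is what concentrates
  trial initiation in the dark phase.
* **Cue-guided responding**: after self-initiating, the agent responds to
  the cue at an exponential latency, choosing the lit port with probability
  ``p_correct``; a latency draw that outruns the response window becomes an
  omission.
* **Premature responding**: during the pre-cue delay the agent emits extra
  side pokes as a Poisson process with rate ``premature_hazard``, on top of
  its spontaneous background — the impulsive-action signal.

The agent sees only what a mouse could (cue states, plus the memory of
having just initiated); it never reads engine timers.  All randomness comes
from one explicit stream, so a seeded closed-loop simulation is exactly
reproducible.

:func:`recover_params` closes the validation loop: method-of-moments
estimates of the generative parameters from an event log alone, used to
check that simulation plus metric extraction preserves what was put in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from typing import Optional, Sequence

import numpy as np

from .logio import EventRecord

__all__ = [
    "AgentParams",
    "CircadianClock",
    "MouseAgent",
    "RecoveredParams",
    "recover_params",
]

_PORTS = ("L", "C", "R")
_SIDES = ("L", "R")
_MS_PER_H = 3_600_000
_HALF_DAY_MS = 12 * _MS_PER_H
_DAY_MS = 24 * _MS_PER_H


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of the synthetic mouse.

    Rates are spontaneous pokes per hour per port; latency scales are the
    means of exponential distributions in seconds; ``premature_hazard`` is
    side pokes per second during the delay period.  Defaults describe a
    water-motivated nocturnal mouse that has acquired the task: ~85% cue
    accuracy, rare omissions, roughly an order of magnitude more activity
    in the dark phase, and a premature-poke hazard of 0.1 /s.
    """

    rate_dark: float = 20.0
    rate_light: float = 2.0
    p_engage: float = 0.1
    engage_latency_scale: float = 30.0
    p_correct: float = 0.85
    response_latency_scale: float = 0.35
    premature_hazard: float = 0.1

    def __post_init__(self) -> None:
        for name in ("rate_dark", "rate_light", "engage_latency_scale",
                     "response_latency_scale", "premature_hazard"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_engage", "p_correct"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


class CircadianClock:
    """Maps session-relative milliseconds onto the 12/12 light/dark cycle."""

    def __init__(self, session_start: datetime, lights_on_hour: int) -> None:
        self.session_start = session_start
        self.lights_on_hour = int(lights_on_hour)
        sod_ms = (
            session_start.hour * _MS_PER_H
            + session_start.minute * 60_000
            + session_start.second * 1000
            + session_start.microsecond // 1000
        )
        # ms since the most recent lights-on at session start
        self._offset = (sod_ms - self.lights_on_hour * _MS_PER_H) % _DAY_MS

    def is_dark(self, t_ms: float) -> bool:
        return (self._offset + t_ms) % _DAY_MS >= _HALF_DAY_MS

    def next_boundary(self, t_ms: float) -> float:
        """Next light<->dark transition strictly after ``t_ms``."""
        phase = (self._offset + t_ms) % _HALF_DAY_MS
        return t_ms + (_HALF_DAY_MS - phase)

    def dark_overlap_ms(self, a: float, b: float) -> float:
        """Total dark-phase time within the interval [a, b)."""
        total, t = 0.0, a
        while t < b:
            nb = min(self.next_boundary(t), b)
            if self.is_dark(t):
                total += nb - t
            t = nb
        return total


class MouseAgent:
    """Stateful behavioral model driven by the engine's visible state.

    ``next_action(view, t_now, horizon)`` returns the agent's earliest poke
    ``(t_ms, port)`` in ``[t_now, horizon]``, or ``None`` if it would not
    poke before the horizon.  Calls consume the random stream, but every
    process involved is memoryless (or memoized per phase entry), so
    repeated querying across events is statistically consistent.
    """

    def __init__(
        self,
        params: AgentParams,
        rng: np.random.Generator,
        clock: CircadianClock,
    ) -> None:
        self.params = params
        self.rng = rng
        self.clock = clock
        self._await_key: Optional[int] = None
        self._await_poke_ms: Optional[float] = None

    # -- elementary processes -------------------------------------------------

    def _spontaneous_rate_per_ms(self, t_ms: float) -> float:
        p = self.params
        rate_h = p.rate_dark if self.clock.is_dark(t_ms) else p.rate_light
        return 3.0 * rate_h / _MS_PER_H

    def _next_spontaneous(self, t: float, horizon: float):
        """Next background poke in (t, horizon], honoring rate steps at
        light/dark boundaries (piecewise-homogeneous Poisson)."""
        cur = float(t)
        while cur <= horizon:
            rate = self._spontaneous_rate_per_ms(cur)
            boundary = self.clock.next_boundary(cur)
            if rate <= 0:
                cur = boundary
                continue
            cand = cur + self.rng.exponential(1.0 / rate)
            if cand > boundary:
                cur = boundary
                continue
            if cand > horizon:
                return None
            return cand, _PORTS[int(self.rng.integers(3))]
        return None

    def _next_premature(self, t: float, horizon: float):
        h = self.params.premature_hazard
        if h <= 0:
            return None
        cand = t + self.rng.exponential(1000.0 / h)
        if cand > horizon:
            return None
        return cand, _SIDES[int(self.rng.integers(2))]

    # -- policy ---------------------------------------------------------------

    def next_action(self, view, t_now: int, horizon: int):
        from .engine import Phase  # local import to avoid a module cycle

        p = self.params
        if view.phase in (Phase.ITI, Phase.DELAY):
            cands = []
            sp = self._next_spontaneous(t_now, horizon)
            if sp is not None:
                cands.append(sp)
            if view.phase is Phase.DELAY:
                pm = self._next_premature(t_now, horizon)
                if pm is not None:
                    cands.append(pm)
            if not cands:
                return None
            t_poke, port = min(cands, key=lambda c: c[0])
            return max(int(math.ceil(t_poke)), t_now), port

        if view.phase is Phase.AWAIT_INITIATION:
            # One engagement decision per trial availability.
            if self._await_key != view.phase_entry_time:
                self._await_key = view.phase_entry_time
                if self.rng.random() < p.p_engage:
                    latency_ms = self.rng.exponential(p.engage_latency_scale) * 1000
                    self._await_poke_ms = view.phase_entry_time + latency_ms
                else:
                    self._await_poke_ms = None
            cands = []
            if self._await_poke_ms is not None:
                cands.append((max(self._await_poke_ms, float(t_now)), "C"))
            sp = self._next_spontaneous(t_now, horizon)
            if sp is not None:
                cands.append(sp)
            cands = [c for c in cands if c[0] <= horizon]
            if not cands:
                return None
            t_poke, port = min(cands, key=lambda c: c[0])
            return max(int(math.ceil(t_poke)), t_now), port

        if view.phase is Phase.CUE:
            if not view.self_initiated:
                # Not attending a cue it initiated: background poking only.
                sp = self._next_spontaneous(t_now, horizon)
                if sp is None:
                    return None
                t_poke, port = sp
                return max(int(math.ceil(t_poke)), t_now), port
            # Attentive response at exponential latency (memoryless, so a
            # fresh draw per query is consistent).
            if p.response_latency_scale > 0:
                latency_ms = self.rng.exponential(p.response_latency_scale) * 1000
            else:
                latency_ms = 0.0
            t_poke = t_now + latency_ms
            if t_poke > horizon:
                return None
            lit = view.lit_ports
            if len(lit) == 1 and lit[0] in _SIDES:
                if self.rng.random() < p.p_correct:
                    port = lit[0]
                else:
                    port = "L" if lit[0] == "R" else "R"
            elif lit:
                port = lit[int(self.rng.integers(len(lit)))]
            else:
                return None
            return max(int(math.ceil(t_poke)), t_now), port

        raise ValueError(f"agent cannot act in phase {view.phase}")


@dataclass(frozen=True)
class RecoveredParams:
    """Method-of-moments estimates of generative agent parameters."""

    p_correct: Optional[float]
    premature_hazard: Optional[float]
    rate_dark: Optional[float]
    rate_light: Optional[float]
    n_trials: int


def _phase_spans(events: Sequence[EventRecord]):
    """Extract between-trial and delay spans plus classified pokes.

    Returns ``(idle_spans, delay_spans, idle_side_pokes, delay_side_pokes)``
    where spans are ``[start_ms, end_ms)`` pairs.  "Idle" covers the ITI and
    the trial-available (blinking-center) period — all time with no trial
    running.  Only side-port pokes are collected for the idle spans: idle
    windows end on center pokes (initiation) and center pokes include
    obligatory reward retrieval, so side pokes are the clean readout of the
    spontaneous background rate.
    """
    idle_spans, delay_spans = [], []
    idle_side, delay_side = [], []
    phase = None
    phase_start = 0
    end_t = events[-1].t if events else 0
    for ev in events:
        if ev.code == "ITI_START":
            phase, phase_start = "IDLE", ev.t
        elif ev.code == "DELAY_START":
            if phase == "IDLE":
                idle_spans.append((phase_start, ev.t))
            phase, phase_start = "DELAY", ev.t
        elif ev.code == "CUE_PHASE_START":
            if phase == "IDLE":
                idle_spans.append((phase_start, ev.t))
            elif phase == "DELAY":
                delay_spans.append((phase_start, ev.t))
            phase = None
        elif ev.code == "POKE_IN" and ev.port in _SIDES:
            if phase == "IDLE":
                idle_side.append(ev)
            elif phase == "DELAY":
                delay_side.append(ev)
    if phase == "IDLE":
        idle_spans.append((phase_start, end_t))
    elif phase == "DELAY":
        delay_spans.append((phase_start, end_t))
    return idle_spans, delay_spans, idle_side, delay_side


def recover_params(
    events: Sequence[EventRecord],
    clock: Optional[CircadianClock] = None,
) -> RecoveredParams:
    """Estimate agent parameters back from an event log.

    * ``p_correct``: correct / (correct + incorrect) over cue responses.
    * ``premature_hazard``: side pokes per second of delay time, with the
      spontaneous side-poke background (estimated from between-trial
      activity) subtracted.
    * ``rate_dark`` / ``rate_light``: per-port hourly spontaneous rates,
      estimated from side-port pokes over between-trial time, split by
      circadian phase (requires ``clock``).  Side pokes are used because
      between-trial windows end on center pokes, making side poking the
      selection-free readout of the background rate.

    Raises ``ValueError`` for a log with no attempted trials, where
    accuracy is undefined.
    """
    correct = sum(1 for e in events if e.code == "OUTCOME_CORRECT")
    incorrect = sum(1 for e in events if e.code == "OUTCOME_INCORRECT")
    n_init = sum(1 for e in events if e.code == "TRIAL_INIT")
    if correct + incorrect == 0:
        raise ValueError("log contains no attempted trials; accuracy undefined")
    p_correct = correct / (correct + incorrect)

    idle_spans, delay_spans, idle_side, delay_side = _phase_spans(events)
    idle_ms = sum(b - a for a, b in idle_spans)
    delay_ms = sum(b - a for a, b in delay_spans)

    rate_dark = rate_light = None
    per_port_rate_s = 0.0
    if idle_ms > 0:
        per_port_rate_s = len(idle_side) / (idle_ms / 1000.0) / 2.0
        if clock is not None:
            dark_ms = sum(clock.dark_overlap_ms(a, b) for a, b in idle_spans)
            light_ms = idle_ms - dark_ms
            dark_pokes = sum(1 for e in idle_side if clock.is_dark(e.t))
            light_pokes = len(idle_side) - dark_pokes
            if dark_ms > 0:
                rate_dark = dark_pokes / (dark_ms / _MS_PER_H) / 2.0
            if light_ms > 0:
                rate_light = light_pokes / (light_ms / _MS_PER_H) / 2.0

    hazard = None
    if delay_ms > 0:
        raw = len(delay_side) / (delay_ms / 1000.0)
        hazard = max(raw - 2.0 * per_port_rate_s, 0.0)

    return RecoveredParams(
        p_correct=p_correct,
        premature_hazard=hazard,
        rate_dark=rate_dark,
        rate_light=rate_light,
        n_trials=n_init,
    )
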