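"""Discrete-event state machines for homecage operant paradigms.

A box has three noseports (left, center, right), each with a cue LED, an
infrared poke detector and a solenoid-metered water spout.  Training
proceeds through a fixed sequence of paradigms:

* **P1** (reward retrieval): the center cue lights after a variable
  intertrial interval (ITI); a center poke delivers water.
* **P2** (continuous reinforcement): both side cues light indefinitely; a
  poke to either side is rewarded at the center port.
* **P3** (self-initiation): the center port blinks at 1 Hz; a center poke
  starts the trial, after which both side cues light as in P2.
* **P4** (cue discrimination): only one randomly chosen side lights.
  P4a: incorrect pokes have no consequence and the window is unlimited;
  P4b: incorrect pokes terminate the trial and the response window is 5 s;
  P4c: the window shortens to 1.5 s.
* **2-CSRTT** (two-choice serial reaction time task): a delay of 3, 6 or
  9 s separates trial initiation from cue onset.  Side pokes during the
  delay are *premature responses* — the operational measure of impulsive
  action — and are logged but never alter the trial's outcome.

Throughout, the ITI averages 45 s, the reward is 10 ul, and there is no
timeout or punishment: ITI and delay pokes are recorded but inert.

The engine is a pure state machine: :func:`step` maps (state, paradigm,
input event) to (new state, emitted log events), with all randomness (ITI
draws, cue-side selection) taken from an explicit seeded stream.  Time is
integer milliseconds; when a poke and a timer expiry coincide on the same
millisecond the poke is processed first.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Optional, Sequence, Union

import numpy as np

from .calibration import DEFAULT_CALIBRATION, CalibrationModel
from .logio import EventRecord, LogHeader

__all__ = [
    "Phase",
    "ITILaw",
    "ParadigmSpec",
    "TaskState",
    "Poke",
    "TimerExpiry",
    "AgentView",
    "SessionCounters",
    "SessionResult",
    "step",
    "draw_iti",
    "choose_cue_side",
    "run_session",
    "make_schedule",
    "PARADIGM_IDS",
]

PARADIGM_IDS = ("P1", "P2", "P3", "P4a", "P4b", "P4c", "CSRTT")
SIDE_PORTS = ("L", "R")


class Phase(enum.Enum):
    ITI = "ITI"
    AWAIT_INITIATION = "AWAIT_INITIATION"
    DELAY = "DELAY"
    CUE = "CUE"


@dataclass(frozen=True)
class ITILaw:
    """Distribution of the variable intertrial interval.

    ``family`` is ``"uniform"`` (bounded, the default), ``"fixed"`` or
    ``"exponential"``.  For the uniform family the bounds must average to
    the paradigm's ITI mean.
    """

    family: str = "uniform"
    low: float = 30.0
    high: float = 60.0

    def draw(self, mean: float, rng: np.random.Generator) -> float:
        if self.family == "uniform":
            return float(rng.uniform(self.low, self.high))
        if self.family == "fixed":
            return float(mean)
        if self.family == "exponential":
            return float(rng.exponential(mean))
        raise ValueError(f"unknown ITI law family {self.family!r}")


@dataclass(frozen=True)
class ParadigmSpec:
    """Full parameterization of one paradigm variant.

    Prefer the :meth:`named` constructor, which fills in the canonical
    settings for each training-stage identifier.
    """

    paradigm_id: str
    reward_volume: float = 10.0          # ul
    iti_mean: float = 45.0               # s
    iti_law: ITILaw = field(default_factory=ITILaw)
    response_window: Optional[float] = None   # s; None = unlimited
    delay: float = 0.0                   # s; nonzero only under CSRTT
    incorrect_terminates: bool = False
    side_cue_rule: str = "CENTER"        # CENTER | BOTH | SINGLE_RANDOM
    requires_initiation: bool = False
    reward_at_center: bool = True
    max_side_run: Optional[int] = None   # optional cap on identical-side runs

    def __post_init__(self) -> None:
        if self.paradigm_id not in PARADIGM_IDS:
            raise ValueError(f"unknown paradigm_id {self.paradigm_id!r}")
        if self.iti_mean <= 0:
            raise ValueError("iti_mean must be > 0")
        if self.reward_volume <= 0:
            raise ValueError("reward_volume must be > 0")
        if self.delay != 0 and self.paradigm_id != "CSRTT":
            raise ValueError("delay must be 0 except under CSRTT")
        if self.paradigm_id == "CSRTT" and self.delay <= 0:
            raise ValueError("CSRTT requires a positive delay")
        if self.side_cue_rule not in ("CENTER", "BOTH", "SINGLE_RANDOM"):
            raise ValueError(f"unknown side_cue_rule {self.side_cue_rule!r}")
        if self.iti_law.family == "uniform":
            if abs((self.iti_law.low + self.iti_law.high) / 2 - self.iti_mean) > 1e-9:
                raise ValueError(
                    "uniform ITI bounds must average to iti_mean "
                    f"({self.iti_law.low}, {self.iti_law.high}) vs {self.iti_mean}"
                )

    @classmethod
    def named(cls, paradigm_id: str, delay: float = 3.0, **overrides) -> "ParadigmSpec":
        """Canonical spec for a training-stage identifier.

        For CSRTT, ``delay`` selects the delay length (3, 6 or 9 s).
        Keyword overrides adjust individual fields.
        """
        presets = {
            "P1": dict(side_cue_rule="CENTER", requires_initiation=False),
            "P2": dict(side_cue_rule="BOTH", requires_initiation=False),
            "P3": dict(side_cue_rule="BOTH", requires_initiation=True),
            "P4a": dict(side_cue_rule="SINGLE_RANDOM", requires_initiation=True,
                        reward_at_center=False),
            "P4b": dict(side_cue_rule="SINGLE_RANDOM", requires_initiation=True,
                        reward_at_center=False, incorrect_terminates=True,
                        response_window=5.0),
            "P4c": dict(side_cue_rule="SINGLE_RANDOM", requires_initiation=True,
                        reward_at_center=False, incorrect_terminates=True,
                        response_window=1.5),
            # CSRTT inherits the 1.5-s window from P4c, which it follows.
            "CSRTT": dict(side_cue_rule="SINGLE_RANDOM", requires_initiation=True,
                          reward_at_center=False, incorrect_terminates=True,
                          response_window=1.5, delay=delay),
        }
        if paradigm_id not in presets:
            raise ValueError(f"unknown paradigm_id {paradigm_id!r}")
        kwargs = dict(presets[paradigm_id])
        kwargs.update(overrides)
        return cls(paradigm_id=paradigm_id, **kwargs)

    @property
    def lit_ports_at_cue(self) -> tuple[str, ...]:
        if self.side_cue_rule == "CENTER":
            return ("C",)
        if self.side_cue_rule == "BOTH":
            return SIDE_PORTS
        return ()  # SINGLE_RANDOM: decided per trial


@dataclass(frozen=True)
class TaskState:
    """Instantaneous controller state between events."""

    phase: Phase
    phase_entry_time: int                 # ms
    phase_end_time: Optional[int] = None  # ms; None = no pending timer
    active_cue_port: Optional[str] = None  # lit side under SINGLE_RANDOM
    trial_index: int = 0
    awaiting_retrieval: bool = False
    last_side: Optional[str] = None
    side_run: int = 0


@dataclass(frozen=True)
class Poke:
    t: int
    port: str


@dataclass(frozen=True)
class TimerExpiry:
    t: int


InputEvent = Union[Poke, TimerExpiry]


def draw_iti(spec: ParadigmSpec, rng: np.random.Generator) -> float:
    """Draw one intertrial interval (seconds) from the paradigm's ITI law."""
    if spec.iti_mean <= 0:
        raise ValueError("iti_mean must be > 0")
    return spec.iti_law.draw(spec.iti_mean, rng)


def choose_cue_side(
    spec: ParadigmSpec,
    rng: np.random.Generator,
    last_side: Optional[str] = None,
    side_run: int = 0,
) -> str:
    """Pick the side to illuminate for a single-cue trial.

    An unbiased coin flip from the seeded stream; if ``spec.max_side_run``
    is set and the same side has already appeared that many times in a row,
    the opposite side is forced.
    """
    if spec.side_cue_rule != "SINGLE_RANDOM":
        raise ValueError(
            f"choose_cue_side is undefined under side_cue_rule={spec.side_cue_rule}"
        )
    if (
        spec.max_side_run is not None
        and last_side is not None
        and side_run >= spec.max_side_run
    ):
        return "L" if last_side == "R" else "R"
    return SIDE_PORTS[int(rng.integers(2))]


def _ms(seconds: float) -> int:
    return int(round(seconds * 1000))


def _enter_cue(
    state: TaskState,
    spec: ParadigmSpec,
    t: int,
    rng: np.random.Generator,
) -> tuple[TaskState, list[EventRecord]]:
    emitted = [EventRecord(t, "CUE_PHASE_START")]
    if spec.side_cue_rule == "SINGLE_RANDOM":
        side = choose_cue_side(spec, rng, state.last_side, state.side_run)
        run = state.side_run + 1 if side == state.last_side else 1
        emitted.append(EventRecord(t, "CUE_ON", side))
        state = replace(state, active_cue_port=side, last_side=side, side_run=run)
    else:
        for p in spec.lit_ports_at_cue:
            emitted.append(EventRecord(t, "CUE_ON", p))
        state = replace(state, active_cue_port=None)
    end = None if spec.response_window is None else t + _ms(spec.response_window)
    state = replace(state, phase=Phase.CUE, phase_entry_time=t, phase_end_time=end)
    return state, emitted


def _lit_ports(state: TaskState, spec: ParadigmSpec) -> tuple[str, ...]:
    if spec.side_cue_rule == "SINGLE_RANDOM":
        return (state.active_cue_port,) if state.active_cue_port else ()
    return spec.lit_ports_at_cue


def _start_iti(
    state: TaskState,
    spec: ParadigmSpec,
    t: int,
    rng: np.random.Generator,
    emitted: list[EventRecord],
) -> TaskState:
    emitted.append(EventRecord(t, "ITI_START"))
    end = t + _ms(draw_iti(spec, rng))
    return replace(
        state,
        phase=Phase.ITI,
        phase_entry_time=t,
        phase_end_time=end,
        active_cue_port=None,
    )


def step(
    state: TaskState,
    spec: ParadigmSpec,
    event: InputEvent,
    rng: np.random.Generator,
    calibration: CalibrationModel = DEFAULT_CALIBRATION,
) -> tuple[TaskState, list[EventRecord]]:
    """Advance the paradigm state machine by one input event.

    ``event`` is a :class:`Poke` or a :class:`TimerExpiry` (the pending
    phase timer firing).  Returns the new state and the apparatus events
    emitted, in order.  Deterministic given state, spec, event and the
    state of ``rng`` (which supplies ITI draws and cue-side choices).
    """
    t = event.t
    if t < state.phase_entry_time:
        raise ValueError(
            f"event at t={t} ms precedes phase entry at {state.phase_entry_time} ms"
        )
    if isinstance(event, Poke) and event.port not in ("L", "C", "R"):
        raise ValueError(f"poke on unknown port {event.port!r}")

    emitted: list[EventRecord] = []

    if isinstance(event, TimerExpiry):
        if state.phase_end_time is None:
            raise ValueError("timer expiry received but no timer is pending")
        if t != state.phase_end_time:
            raise ValueError(
                f"timer expiry at t={t} ms does not match pending timer "
                f"at {state.phase_end_time} ms"
            )
        if state.phase is Phase.ITI:
            # Trial becomes available.
            if spec.requires_initiation:
                emitted.append(EventRecord(t, "CUE_BLINK_ON", "C"))
                state = replace(
                    state,
                    phase=Phase.AWAIT_INITIATION,
                    phase_entry_time=t,
                    phase_end_time=None,
                )
            else:
                state, cue_events = _enter_cue(state, spec, t, rng)
                emitted.extend(cue_events)
            return state, emitted
        if state.phase is Phase.DELAY:
            state, cue_events = _enter_cue(state, spec, t, rng)
            emitted.extend(cue_events)
            return state, emitted
        if state.phase is Phase.CUE:
            # Response window elapsed: omission.
            for p in _lit_ports(state, spec):
                emitted.append(EventRecord(t, "CUE_OFF", p))
            emitted.append(EventRecord(t, "OUTCOME_OMISSION"))
            state = _start_iti(state, spec, t, rng, emitted)
            return state, emitted
        raise ValueError(f"unexpected timer expiry in phase {state.phase}")

    # --- poke ---
    port = event.port
    emitted.append(EventRecord(t, "POKE_IN", port))
    if state.awaiting_retrieval and port == "C":
        emitted.append(EventRecord(t, "RETRIEVAL", "C"))
        state = replace(state, awaiting_retrieval=False)

    if state.phase is Phase.ITI:
        return state, emitted  # logged, inert: no timeout or punishment

    if state.phase is Phase.AWAIT_INITIATION:
        if port != "C":
            return state, emitted
        emitted.append(EventRecord(t, "CUE_OFF", "C"))  # blinking stops
        emitted.append(EventRecord(t, "TRIAL_INIT", "C"))
        state = replace(state, trial_index=state.trial_index + 1)
        if spec.delay > 0:
            emitted.append(EventRecord(t, "DELAY_START"))
            state = replace(
                state,
                phase=Phase.DELAY,
                phase_entry_time=t,
                phase_end_time=t + _ms(spec.delay),
            )
        else:
            state, cue_events = _enter_cue(state, spec, t, rng)
            emitted.extend(cue_events)
        return state, emitted

    if state.phase is Phase.DELAY:
        # Recorded but no influence on the trial's outcome or timing.
        return state, emitted

    if state.phase is Phase.CUE:
        lit = _lit_ports(state, spec)
        if port in lit:
            reward_port = "C" if spec.reward_at_center else port
            open_ms = calibration.solenoid_ms_for_volume(spec.reward_volume)
            for p in lit:
                emitted.append(EventRecord(t, "CUE_OFF", p))
            emitted.append(EventRecord(t, "REWARD", reward_port, open_ms))
            emitted.append(EventRecord(t, "OUTCOME_CORRECT"))
            if reward_port == "C" and port != "C":
                state = replace(state, awaiting_retrieval=True)
            state = _start_iti(state, spec, t, rng, emitted)
            return state, emitted
        if port in SIDE_PORTS and spec.incorrect_terminates:
            for p in lit:
                emitted.append(EventRecord(t, "CUE_OFF", p))
            emitted.append(EventRecord(t, "OUTCOME_INCORRECT"))
            state = _start_iti(state, spec, t, rng, emitted)
            return state, emitted
        # Unlit-port poke without termination (P4a) or center poke: inert.
        return state, emitted

    raise ValueError(f"unhandled phase {state.phase}")


@dataclass(frozen=True)
class AgentView:
    """What the animal can perceive (plus its own memory of initiating).

    Exposes cue states and phase identity only — never the engine's pending
    timers — so a behavioral model cannot anticipate cue onset.
    """

    phase: Phase
    lit_ports: tuple[str, ...]
    blinking_ports: tuple[str, ...]
    self_initiated: bool
    phase_entry_time: int


def _view(state: TaskState, spec: ParadigmSpec) -> AgentView:
    lit: tuple[str, ...] = ()
    blinking: tuple[str, ...] = ()
    if state.phase is Phase.CUE:
        lit = _lit_ports(state, spec)
    elif state.phase is Phase.AWAIT_INITIATION:
        blinking = ("C",)
    return AgentView(
        phase=state.phase,
        lit_ports=lit,
        blinking_ports=blinking,
        self_initiated=spec.requires_initiation,
        phase_entry_time=state.phase_entry_time,
    )


@dataclass
class SessionCounters:
    """The engine's own running tallies for one session.

    Maintained event-by-event while simulating, independently of the
    offline trial-reconstruction pipeline, so the two can be cross-checked.
    """

    rewards: int = 0
    trials_initiated: int = 0
    correct: int = 0
    incorrect: int = 0
    omissions: int = 0
    delay_side_pokes: int = 0
    retrievals: int = 0
    pokes: dict = field(default_factory=lambda: {"L": 0, "C": 0, "R": 0})
    iti_pokes: dict = field(default_factory=lambda: {"L": 0, "C": 0, "R": 0})
    cue_pokes: dict = field(default_factory=lambda: {"L": 0, "C": 0, "R": 0})

    def update(
        self,
        prev_phase: Phase,
        event: InputEvent,
        emitted: Sequence[EventRecord],
    ) -> None:
        codes = [e.code for e in emitted]
        self.rewards += codes.count("REWARD")
        self.trials_initiated += codes.count("TRIAL_INIT")
        self.correct += codes.count("OUTCOME_CORRECT")
        self.incorrect += codes.count("OUTCOME_INCORRECT")
        self.omissions += codes.count("OUTCOME_OMISSION")
        if isinstance(event, Poke):
            self.pokes[event.port] += 1
            if prev_phase is Phase.ITI:
                if "RETRIEVAL" in codes:
                    self.retrievals += 1
                else:
                    self.iti_pokes[event.port] += 1
            elif prev_phase is Phase.DELAY and event.port in SIDE_PORTS:
                self.delay_side_pokes += 1
            elif prev_phase is Phase.CUE:
                self.cue_pokes[event.port] += 1


@dataclass
class SessionResult:
    """Everything a simulated session produced."""

    header: LogHeader
    events: list[EventRecord]
    counters: SessionCounters
    spec: ParadigmSpec
    duration_ms: int


def run_session(
    spec: ParadigmSpec,
    agent_params,
    duration_hours: float,
    seed: int,
    session_start: Optional[datetime] = None,
    lights_on_hour: int = 7,
    calibration: CalibrationModel = DEFAULT_CALIBRATION,
    subject_id: str = "SIM",
    box_id: str = "BOX0",
) -> SessionResult:
    """Closed-loop simulation of one session: engine driven by a synthetic mouse.

    ``agent_params`` is an :class:`~nosepoke.agent.AgentParams` (or an already
    constructed agent exposing ``next_action``).  The session starts, by
    default, five hours after lights-on — paradigms are switched mid light
    phase — and runs for ``duration_hours``.  Identical inputs and seed give
    a byte-identical event log.
    """
    from .agent import AgentParams, CircadianClock, MouseAgent

    if duration_hours <= 0:
        raise ValueError("duration must be > 0")
    if session_start is None:
        session_start = datetime(2021, 6, 1, (lights_on_hour + 5) % 24, 0, 0)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    engine_ss, agent_ss = ss.spawn(2)
    rng_engine = np.random.default_rng(engine_ss)

    clock = CircadianClock(session_start, lights_on_hour)
    if isinstance(agent_params, AgentParams):
        agent = MouseAgent(agent_params, np.random.default_rng(agent_ss), clock)
    else:
        agent = agent_params

    duration_ms = _ms(duration_hours * 3600)
    events: list[EventRecord] = [EventRecord(0, "PARADIGM_SWITCH", arg=None)]
    counters = SessionCounters()

    first_iti_end = _ms(draw_iti(spec, rng_engine))
    events.append(EventRecord(0, "ITI_START"))
    state = TaskState(phase=Phase.ITI, phase_entry_time=0, phase_end_time=first_iti_end)

    t = 0
    while True:
        timer_t = state.phase_end_time
        horizon = duration_ms if timer_t is None else min(timer_t, duration_ms)
        action = agent.next_action(_view(state, spec), t, horizon)
        if action is not None:
            poke_t, poke_port = action
            if poke_t < t:
                raise ValueError("agent produced a poke in the past")
            # Tie with a pending timer resolves in favor of the poke.
            if poke_t <= horizon and poke_t < duration_ms:
                ev: InputEvent = Poke(poke_t, poke_port)
            else:
                action = None
        if action is None:
            if timer_t is not None and timer_t < duration_ms:
                ev = TimerExpiry(timer_t)
            else:
                break
        prev_phase = state.phase
        state, emitted = step(state, spec, ev, rng_engine, calibration)
        counters.update(prev_phase, ev, emitted)
        events.extend(emitted)
        t = ev.t

    closed = counters.correct + counters.incorrect + counters.omissions
    if counters.trials_initiated > closed:
        # A trial left open when the session ends is dropped from the
        # tallies, matching the offline pipeline's handling of truncated
        # trials; its pokes remain counted by context.
        counters.trials_initiated = closed

    pid = spec.paradigm_id if spec.delay == 0 else f"{spec.paradigm_id}-d{spec.delay:g}"
    header = LogHeader(
        subject_id=subject_id,
        paradigm_id=pid,
        session_start=session_start,
        box_id=box_id,
        lights_on_hour=lights_on_hour,
    )
    return SessionResult(header, events, counters, spec, duration_ms)


#: days per stage of the canonical training schedule
_FULL_TRAINING = (
    ("P1", 3), ("P2", 3), ("P3", 4), ("P4a", 3), ("P4b", 2), ("P4c", 2),
    ("CSRTT-3", 3), ("CSRTT-6", 3), ("CSRTT-9", 3),
)


def make_schedule(
    protocol: str = "full_training",
    p4c_days: int = 2,
) -> list[tuple[ParadigmSpec, int]]:
    """Ordered (paradigm, days) stages for a named training protocol.

    ``full_training`` is the canonical progression: P1 x3 d, P2 x3 d,
    P3 x4 d, P4a x3 d, P4b x2 d, P4c (default 2 d), then the 2-CSRTT at
    delays 3, 6 and 9 s for 3 d each.
    """
    if protocol != "full_training":
        raise ValueError(f"unknown protocol {protocol!r}")
    out: list[tuple[ParadigmSpec, int]] = []
    for name, days in _FULL_TRAINING:
        if name.startswith("CSRTT"):
            delay = float(name.split("-")[1])
            out.append((ParadigmSpec.named("CSRTT", delay=delay), days))
        elif name == "P4c":
            out.append((ParadigmSpec.named("P4c"), p4c_days))
        else:
            out.append((ParadigmSpec.named(name), days))
    return out
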