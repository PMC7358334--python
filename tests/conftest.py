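from datetime import datetime

import pytest

from nosepoke import AgentParams, ParadigmSpec
from nosepoke.logio import EventRecord, LogHeader


@pytest.fixture
def csrtt9():
    return ParadigmSpec.named("CSRTT", delay=9.0)


@pytest.fixture
def eager_agent():
    """High-throughput attentive agent: initiates every trial almost at once,
    no spontaneous background, so trial counts accumulate quickly."""
    return AgentParams(
        rate_dark=0.0, rate_light=0.0,
        p_engage=1.0, engage_latency_scale=1.0,
        p_correct=0.85, response_latency_scale=0.35,
        premature_hazard=0.2,
    )


@pytest.fixture
def toy_header():
    return LogHeader(
        subject_id="M1", paradigm_id="CSRTT-d3",
        session_start=datetime(2021, 6, 1, 12, 0, 0), lights_on_hour=7,
    )


@pytest.fixture
def toy_events():
    """Hand-written two-trial log: one correct trial with 3 delay pokes
    (3-s delay, 400-ms response latency), then one omission."""
    E = EventRecord
    return [
        E(0, "ITI_START"),
        E(1000, "CUE_BLINK_ON", "C"),
        E(2000, "POKE_IN", "C"),
        E(2000, "CUE_OFF", "C"),
        E(2000, "TRIAL_INIT", "C"),
        E(2000, "DELAY_START"),
        E(2500, "POKE_IN", "L"),
        E(3000, "POKE_IN", "R"),
        E(3500, "POKE_IN", "L"),
        E(5000, "CUE_PHASE_START"),
        E(5000, "CUE_ON", "L"),
        E(5400, "POKE_IN", "L"),
        E(5400, "CUE_OFF", "L"),
        E(5400, "REWARD", "L", 72),
        E(5400, "OUTCOME_CORRECT"),
        E(5400, "ITI_START"),
        E(6400, "CUE_BLINK_ON", "C"),
        E(7000, "POKE_IN", "C"),
        E(7000, "CUE_OFF", "C"),
        E(7000, "TRIAL_INIT", "C"),
        E(7000, "DELAY_START"),
        E(10000, "CUE_PHASE_START"),
        E(10000, "CUE_ON", "R"),
        E(11500, "CUE_OFF", "R"),
        E(11500, "OUTCOME_OMISSION"),
        E(11500, "ITI_START"),
    ]
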