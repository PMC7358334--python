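"""Naive brute-force recount of every behavioral metric, for cross-checking.

Deliberately written as a separate, simple-minded pass over raw events:
trials are found by scanning backward from each outcome marker, and poke
contexts are re-derived from the most recent mode-changing marker.  Shares
no code with nosepoke.metrics.
"""

import math

SIDES = ("L", "R")
OUTCOMES = ("OUTCOME_CORRECT", "OUTCOME_INCORRECT", "OUTCOME_OMISSION")


def brute_force_table(events, label):
    """Recount all per-bin metrics.  ``label(t_ms)`` maps a timestamp to a
    bin key (or None = out of range).  Returns {bin: {column: value}}."""
    ev = [(e.t, e.code, e.port) for e in events]

    # trials: scan backward from each outcome to its start marker
    trials = []  # (start_t, outcome, delay_pokes)
    last_close = -1
    for i, (t, code, port) in enumerate(ev):
        if code not in OUTCOMES:
            continue
        start_i = None
        init_i = None
        for j in range(i - 1, last_close, -1):
            cj = ev[j][1]
            if cj == "TRIAL_INIT":
                init_i = j
                break
            if cj == "CUE_PHASE_START" and start_i is None:
                start_i = j
        if init_i is not None:
            start_i = init_i
        assert start_i is not None, "outcome without a trial start"
        # delay pokes: side pokes between DELAY_START and CUE_PHASE_START
        dstart = dend = None
        for j in range(start_i, i):
            if ev[j][1] == "DELAY_START":
                dstart = j
            elif ev[j][1] == "CUE_PHASE_START" and dstart is not None and dend is None:
                dend = j
        dp = 0
        if dstart is not None and dend is not None:
            dp = sum(
                1 for j in range(dstart, dend)
                if ev[j][1] == "POKE_IN" and ev[j][2] in SIDES
            )
        trials.append((ev[start_i][0], code, dp))
        last_close = i

    # poke contexts from the most recent marker
    retrieval_ts = {t for t, c, p in ev if c == "RETRIEVAL"}
    mode = None
    pokes = []  # (t, port, context)
    for t, code, port in ev:
        if code == "ITI_START":
            mode = "ITI"
        elif code == "CUE_BLINK_ON":
            mode = "AWAIT"
        elif code == "DELAY_START":
            mode = "DELAY"
        elif code == "CUE_PHASE_START":
            mode = "CUE"
        elif code in OUTCOMES or code == "PARADIGM_SWITCH":
            mode = None
        elif code == "POKE_IN":
            ctx = mode
            if mode == "ITI" and port == "C" and t in retrieval_ts:
                ctx = "RETRIEVAL"
            pokes.append((t, port, ctx))

    bins = {}

    def row(b):
        if b not in bins:
            bins[b] = {
                "rewards": 0,
                "pokes_L": 0, "pokes_C": 0, "pokes_R": 0,
                "iti_pokes_L": 0, "iti_pokes_C": 0, "iti_pokes_R": 0,
                "cue_pokes": 0, "delay_pokes": 0,
                "trials_initiated": 0, "correct": 0, "incorrect": 0,
                "omissions": 0, "_trial_delay_pokes": 0,
            }
        return bins[b]

    for t, code, port in ev:
        if code == "REWARD":
            b = label(t)
            if b is not None:
                row(b)["rewards"] += 1
    for t, port, ctx in pokes:
        b = label(t)
        if b is None:
            continue
        r = row(b)
        r[f"pokes_{port}"] += 1
        if ctx == "ITI":
            r[f"iti_pokes_{port}"] += 1
        elif ctx == "CUE":
            r["cue_pokes"] += 1
        elif ctx == "DELAY" and port in SIDES:
            r["delay_pokes"] += 1
    for start_t, outcome, dp in trials:
        b = label(start_t)
        if b is None:
            continue
        r = row(b)
        r["trials_initiated"] += 1
        r["_trial_delay_pokes"] += dp
        if outcome == "OUTCOME_CORRECT":
            r["correct"] += 1
        elif outcome == "OUTCOME_INCORRECT":
            r["incorrect"] += 1
        else:
            r["omissions"] += 1

    for r in bins.values():
        n = r["trials_initiated"]
        att = r["correct"] + r["incorrect"]
        tdp = r.pop("_trial_delay_pokes")
        r["premature_per_trial"] = tdp / n if n else math.nan
        r["prop_correct"] = r["correct"] / n if n else math.nan
        r["prop_incorrect"] = r["incorrect"] / n if n else math.nan
        r["prop_omitted"] = r["omissions"] / n if n else math.nan
        r["prop_correct_attempted"] = r["correct"] / att if att else math.nan
    return bins
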