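"""Trial reconstruction and behavioral metrics from event logs.

Given a timestamped event log — simulated or recorded — this module
rebuilds the trial structure (initiation, delay pokes, outcome, response
latency) and computes the standard per-subject measures: rewards, pokes to
each port split by task context (ITI, delay, cue presentation, reward
retrieval), trials initiated, outcome counts and proportions, accuracy on
attempted trials, and premature responses per trial (side-port pokes during
the delay divided by self-initiated trials — the impulsive-action measure).

Measures are aggregated over configurable time bins: hourly, 2-hourly,
daily, light/dark phase, or bins relative to an arbitrary reference time
(e.g. 1-6 h and 7-12 h after a drug injection).  Days and phases are
anchored at the lights-on boundary of the 12/12 cycle, not at midnight,
since behavior tracks the circadian cycle.  A trial belongs wholly to the
bin of its initiation time; bin edges are half-open ``[start, end)``.
Bins with no initiated trials report missing proportions, not zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .agent import CircadianClock
from .logio import EventRecord, epoch_ms, read_logs

__all__ = [
    "Trial",
    "reconstruct_trials",
    "bin_metrics",
    "outcome_proportions",
    "accuracy_attempted",
    "flag_welfare",
    "summarize_groups",
    "analyze_logs",
    "BIN_SCHEMES",
]

logger = logging.getLogger(__name__)

_SIDES = ("L", "R")
_MS_PER_H = 3_600_000
BIN_SCHEMES = ("hourly", "two_hour", "daily", "light_dark_phase",
               "relative_to", "per_delay_3day_average", "session")

#: documented column dictionary of the metrics table
METRIC_COLUMNS = {
    "rewards": "reward deliveries in the bin",
    "pokes_L": "total left-port pokes", "pokes_C": "total center-port pokes",
    "pokes_R": "total right-port pokes",
    "iti_pokes_L": "left pokes during the ITI (retrieval excluded)",
    "iti_pokes_C": "center pokes during the ITI (retrieval excluded)",
    "iti_pokes_R": "right pokes during the ITI (retrieval excluded)",
    "cue_pokes": "pokes during cue presentation",
    "delay_pokes": "side-port pokes during the delay (premature responses)",
    "trials_initiated": "trials begun in the bin",
    "correct": "correct trials", "incorrect": "incorrect trials",
    "omissions": "omitted trials",
    "premature_per_trial": "delay_pokes / trials_initiated",
    "prop_correct": "correct / initiated", "prop_incorrect": "incorrect / initiated",
    "prop_omitted": "omissions / initiated",
    "prop_correct_attempted": "correct / (correct + incorrect)",
}


@dataclass(frozen=True)
class Trial:
    """One reconstructed trial."""

    init_time: int                      # ms; trial-start (initiation or cue onset)
    cue_side: Optional[str]             # 'L'/'R'/'BOTH'/'C' or None if never cued
    delay: float                        # s between initiation and cue onset
    delay_pokes: int                    # side-port pokes during the delay
    outcome: Optional[str]              # CORRECT / INCORRECT / OMISSION
    response_latency: Optional[int]     # ms from cue onset to first cue poke
    rewarded: bool
    self_initiated: bool

    def __post_init__(self) -> None:
        if self.rewarded and self.outcome != "CORRECT":
            raise ValueError("rewarded trial must have outcome CORRECT")
        if self.delay == 0 and self.delay_pokes != 0:
            raise ValueError("delay_pokes must be 0 when delay is 0")


_OUTCOME_CODES = {
    "OUTCOME_CORRECT": "CORRECT",
    "OUTCOME_INCORRECT": "INCORRECT",
    "OUTCOME_OMISSION": "OMISSION",
}


def reconstruct_trials(
    events: Sequence[EventRecord],
) -> tuple[list[Trial], pd.DataFrame]:
    """Rebuild trials and context-classified pokes from a time-ordered log.

    Returns ``(trials, pokes)`` where ``pokes`` is a DataFrame with columns
    ``t``, ``port`` and ``context`` (ITI / AWAIT / DELAY / CUE / RETRIEVAL /
    NONE).  A truncated final trial is dropped with a logged warning; an
    outcome marker without an open trial raises ``ValueError``.
    """
    retrieval_ts = {(e.t, "C") for e in events if e.code == "RETRIEVAL"}

    trials: list[Trial] = []
    poke_rows: list[tuple[int, str, str]] = []

    context: Optional[str] = None
    open_trial = False
    init_t = 0
    delay_start: Optional[int] = None
    cue_start: Optional[int] = None
    cue_side: Optional[str] = None
    delay_pokes = 0
    latency: Optional[int] = None
    rewarded = False
    self_initiated = False

    def _reset_trial() -> None:
        nonlocal open_trial, delay_start, cue_start, cue_side
        nonlocal delay_pokes, latency, rewarded, self_initiated
        open_trial = False
        delay_start = cue_start = cue_side = None
        delay_pokes = 0
        latency = None
        rewarded = False
        self_initiated = False

    for ev in events:
        code = ev.code
        if code == "PARADIGM_SWITCH":
            # Session boundary: a trial left open by a truncated session is
            # dropped rather than spliced onto the next session.
            if open_trial:
                logger.warning(
                    "dropping trial truncated at session boundary (t=%d ms)", ev.t
                )
                _reset_trial()
            context = None
        elif code == "ITI_START":
            context = "ITI"
        elif code == "CUE_BLINK_ON":
            context = "AWAIT"
        elif code == "TRIAL_INIT":
            if open_trial:
                raise ValueError(f"TRIAL_INIT at {ev.t} ms with a trial already open")
            open_trial = True
            init_t = ev.t
            self_initiated = True
        elif code == "DELAY_START":
            context = "DELAY"
            delay_start = ev.t
        elif code == "CUE_PHASE_START":
            context = "CUE"
            cue_start = ev.t
            if not open_trial:          # P1/P2: trial = cue availability
                open_trial = True
                init_t = ev.t
        elif code == "CUE_ON" and context == "CUE":
            cue_side = ev.port if cue_side is None else "BOTH"
        elif code == "POKE_IN":
            if (ev.t, ev.port) in retrieval_ts and context == "ITI":
                ctx = "RETRIEVAL"
            else:
                ctx = context or "NONE"
            poke_rows.append((ev.t, ev.port, ctx))
            if ctx == "DELAY" and ev.port in _SIDES and open_trial:
                delay_pokes += 1
            elif ctx == "CUE" and open_trial and latency is None:
                latency = ev.t - cue_start if cue_start is not None else None
        elif code == "REWARD":
            if open_trial:
                rewarded = True
        elif code in _OUTCOME_CODES:
            if not open_trial:
                raise ValueError(
                    f"{code} at {ev.t} ms without an open trial"
                )
            delay_s = (
                (cue_start - delay_start) / 1000.0
                if delay_start is not None and cue_start is not None
                else 0.0
            )
            trials.append(
                Trial(
                    init_time=init_t,
                    cue_side=cue_side,
                    delay=delay_s,
                    delay_pokes=delay_pokes,
                    outcome=_OUTCOME_CODES[code],
                    response_latency=latency,
                    rewarded=rewarded,
                    self_initiated=self_initiated,
                )
            )
            _reset_trial()
            context = None  # ITI_START follows immediately in well-formed logs

    if open_trial:
        logger.warning("dropping truncated final trial initiated at %d ms", init_t)

    pokes = pd.DataFrame(poke_rows, columns=["t", "port", "context"])
    return trials, pokes


def outcome_proportions(trials: Sequence[Trial]) -> tuple[float, float, float]:
    """(correct, incorrect, omitted) proportions over all initiated trials.

    Returns NaNs for an empty bin (missing, not zero).
    """
    n = len(trials)
    if n == 0:
        return (float("nan"),) * 3
    c = sum(t.outcome == "CORRECT" for t in trials)
    i = sum(t.outcome == "INCORRECT" for t in trials)
    o = sum(t.outcome == "OMISSION" for t in trials)
    return c / n, i / n, o / n


def accuracy_attempted(trials: Sequence[Trial]) -> float:
    """Proportion correct of attempted (non-omitted) trials; NaN if none."""
    c = sum(t.outcome == "CORRECT" for t in trials)
    i = sum(t.outcome == "INCORRECT" for t in trials)
    if c + i == 0:
        return float("nan")
    return c / (c + i)


# ---------------------------------------------------------------------------
# binning


def _bin_fn(scheme, clock, t0=None, edges_h=None):
    """Return label(t_ms) -> bin label (or None = outside all bins)."""
    off = clock._offset if clock is not None else 0  # ms past lights-on at t=0

    if scheme == "hourly":
        return lambda t: int((off + t) // _MS_PER_H)
    if scheme == "two_hour":
        return lambda t: int((off + t) // (2 * _MS_PER_H))
    if scheme == "daily":
        return lambda t: int((off + t) // (24 * _MS_PER_H))
    if scheme == "light_dark_phase":
        def label(t):
            day = int((off + t) // (24 * _MS_PER_H))
            phase = "dark" if ((off + t) % (24 * _MS_PER_H)) >= 12 * _MS_PER_H else "light"
            return (day, phase)
        return label
    if scheme == "session":
        return lambda t: 0
    if scheme == "relative_to":
        if t0 is None or edges_h is None:
            raise ValueError("relative_to binning requires t0 and edges_h")
        edges_ms = [t0 + e * _MS_PER_H for e in edges_h]
        labels = [
            f"{edges_h[i]:g}-{edges_h[i + 1]:g}h" for i in range(len(edges_h) - 1)
        ]
        def label(t):
            for i in range(len(edges_ms) - 1):
                if edges_ms[i] <= t < edges_ms[i + 1]:
                    return labels[i]
            return None
        return label
    raise ValueError(f"unknown binning scheme {scheme!r}")


def _table_for_bins(
    trials_by_bin: dict,
    pokes: pd.DataFrame,
    rewards_by_bin: dict,
    label_fn,
    all_bins: list,
    subject: str,
) -> pd.DataFrame:
    pokes = pokes.copy()
    if len(pokes):
        pokes["bin"] = pokes["t"].map(label_fn)
        pokes = pokes[pokes["bin"].notna()]
    rows = []
    for b in all_bins:
        tr = trials_by_bin.get(b, [])
        pk = pokes[pokes["bin"] == b] if len(pokes) else pokes
        row = {"subject": subject, "bin": b}
        row["rewards"] = rewards_by_bin.get(b, 0)
        for port in ("L", "C", "R"):
            row[f"pokes_{port}"] = int((pk["port"] == port).sum()) if len(pk) else 0
            row[f"iti_pokes_{port}"] = (
                int(((pk["port"] == port) & (pk["context"] == "ITI")).sum())
                if len(pk) else 0
            )
        row["cue_pokes"] = int((pk["context"] == "CUE").sum()) if len(pk) else 0
        row["delay_pokes"] = (
            int(((pk["context"] == "DELAY") & (pk["port"].isin(_SIDES))).sum())
            if len(pk) else 0
        )
        n = len(tr)
        row["trials_initiated"] = n
        row["correct"] = sum(t.outcome == "CORRECT" for t in tr)
        row["incorrect"] = sum(t.outcome == "INCORRECT" for t in tr)
        row["omissions"] = sum(t.outcome == "OMISSION" for t in tr)
        trial_delay_pokes = sum(t.delay_pokes for t in tr)
        row["premature_per_trial"] = (
            trial_delay_pokes / n if n > 0 else float("nan")
        )
        pc, pi, po = outcome_proportions(tr)
        row["prop_correct"], row["prop_incorrect"], row["prop_omitted"] = pc, pi, po
        row["prop_correct_attempted"] = accuracy_attempted(tr)
        rows.append(row)
    return pd.DataFrame(rows)


def bin_metrics(
    trials: Sequence[Trial],
    events: Sequence[EventRecord],
    scheme: str,
    clock: Optional[CircadianClock] = None,
    subject: str = "S0",
    t0: Optional[int] = None,
    edges_h: Optional[Sequence[float]] = None,
    span_ms: Optional[tuple[int, int]] = None,
) -> pd.DataFrame:
    """Aggregate trials and pokes into a per-bin metrics table.

    ``scheme`` is one of :data:`BIN_SCHEMES`.  ``clock`` anchors days and
    light/dark phases at the lights-on boundary (required for the phase
    scheme; for the others it defaults to session-start anchoring).
    ``relative_to`` needs ``t0`` (ms, same axis as the events) and
    ``edges_h`` (monotone bin edges in hours after ``t0``).  ``span_ms``
    optionally forces the time range covered, so trailing empty bins are
    materialized.

    Every poke and trial falls in exactly one bin (trials by initiation
    time); per-bin counts therefore sum to whole-log counts.
    """
    if scheme == "per_delay_3day_average":
        return _per_delay_average(trials, events, clock, subject)
    if scheme == "light_dark_phase" and clock is None:
        raise ValueError("light_dark_phase binning requires a CircadianClock")
    label_fn = _bin_fn(scheme, clock, t0=t0, edges_h=edges_h)

    _, pokes = reconstruct_trials(events) if events else (None, pd.DataFrame(
        columns=["t", "port", "context"]))

    trials_by_bin: dict = {}
    for tr in trials:
        b = label_fn(tr.init_time)
        if b is not None:
            trials_by_bin.setdefault(b, []).append(tr)
    rewards_by_bin: dict = {}
    for ev in events:
        if ev.code == "REWARD":
            b = label_fn(ev.t)
            if b is not None:
                rewards_by_bin[b] = rewards_by_bin.get(b, 0) + 1

    if scheme == "relative_to":
        all_bins = [
            f"{edges_h[i]:g}-{edges_h[i + 1]:g}h" for i in range(len(edges_h) - 1)
        ]
    elif scheme == "session":
        all_bins = [0]
    else:
        ts = [ev.t for ev in events] + [tr.init_time for tr in trials] or [0]
        lo = span_ms[0] if span_ms else min(ts)
        hi = span_ms[1] - 1 if span_ms else max(ts)
        blo, bhi = label_fn(lo), label_fn(hi)
        if scheme == "light_dark_phase":
            all_bins = []
            t = lo
            while t <= hi:
                b = label_fn(t)
                if b not in all_bins:
                    all_bins.append(b)
                t += 12 * _MS_PER_H
            b = label_fn(hi)
            if b not in all_bins:
                all_bins.append(b)
        else:
            all_bins = list(range(blo, bhi + 1))

    return _table_for_bins(trials_by_bin, pokes, rewards_by_bin, label_fn,
                           all_bins, subject)


def _per_delay_average(trials, events, clock, subject) -> pd.DataFrame:
    """Daily sums averaged across days within each delay length.

    Mirrors the reporting convention for the serial reaction time stage:
    each measure is summed per (lights-on-anchored) day, days are grouped by
    the delay length in force that day, and the group mean is reported.
    """
    daily = bin_metrics(trials, events, "daily", clock=clock, subject=subject)
    # Delay in force on a day = modal trial delay that day.
    label_fn = _bin_fn("daily", clock)
    day_delay: dict = {}
    for tr in trials:
        d = label_fn(tr.init_time)
        day_delay.setdefault(d, []).append(tr.delay)
    rows = []
    delays = sorted({float(pd.Series(v).mode().iloc[0]) for v in day_delay.values()})
    for delay in delays:
        days = [d for d, v in day_delay.items()
                if float(pd.Series(v).mode().iloc[0]) == delay]
        sub = daily[daily["bin"].isin(days)]
        row = {"subject": subject, "bin": delay}
        for col in sub.columns:
            if col in ("subject", "bin"):
                continue
            row[col] = float(sub[col].mean())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# welfare


def flag_welfare(
    daily_rewards: Union[Sequence[float], pd.Series],
    weights: Optional[Union[Sequence[float], pd.Series]] = None,
    baseline_weight: Optional[float] = None,
    reward_threshold: float = 100.0,
    max_low_days: int = 2,
    weight_loss_fraction: float = 0.10,
) -> pd.DataFrame:
    """Per-day welfare flags for one subject.

    A subject is flagged for removal when it fails to exceed
    ``reward_threshold`` rewards per day for more than ``max_low_days``
    consecutive days (with the defaults: flagged on the third consecutive
    sub-threshold day), or when bodyweight drops more than
    ``weight_loss_fraction`` below ``baseline_weight``.

    ``daily_rewards`` must be a complete, consecutive day series.  If
    ``weights`` is given it must align with the days and contain no missing
    values; ``baseline_weight`` is then required.
    """
    rewards = pd.Series(daily_rewards, dtype=float)
    if rewards.isna().any():
        raise ValueError("daily reward series contains missing days")
    low = rewards <= reward_threshold
    run = []
    streak = 0
    for is_low in low:
        streak = streak + 1 if is_low else 0
        run.append(streak)
    out = pd.DataFrame(
        {"rewards": rewards.to_numpy(), "low_reward_run": run},
        index=rewards.index,
    )
    out["flag_rewards"] = out["low_reward_run"] > max_low_days

    if weights is not None:
        w = pd.Series(weights, dtype=float)
        if w.isna().any():
            raise ValueError("weight series contains missing values")
        if baseline_weight is None:
            raise ValueError("baseline_weight required when weights are given")
        out["weight"] = w.to_numpy()
        out["flag_weight"] = out["weight"] < (1.0 - weight_loss_fraction) * baseline_weight
    else:
        out["flag_weight"] = False
    out["remove"] = out["flag_rewards"] | out["flag_weight"]
    return out


def analyze_logs(
    paths: Sequence,
    scheme: str = "daily",
    lights_on_hour: Optional[int] = None,
    t0: Optional[int] = None,
    edges_h: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Read one subject's session files and compute a binned metrics table.

    Files are concatenated on a wall-clock axis, then re-expressed as
    milliseconds since the first session's start; days and circadian phases
    are anchored at the lights-on hour from the log headers (overridable).
    ``t0`` for the ``relative_to`` scheme is likewise ms since the first
    session start.
    """
    from dataclasses import replace as _replace

    headers, unified = read_logs(paths)
    if not headers:
        raise ValueError("no log files given")
    base = epoch_ms(headers[0].session_start)
    events = [_replace(ev, t=ev.t - base) for ev in unified]
    loh = headers[0].lights_on_hour if lights_on_hour is None else lights_on_hour
    clock = CircadianClock(headers[0].session_start, loh)
    trials, _pokes = reconstruct_trials(events)
    return bin_metrics(
        trials, events, scheme, clock=clock,
        subject=headers[0].subject_id, t0=t0, edges_h=edges_h,
    )


def summarize_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Across-subject mean and SEM for every metric column, per bin."""
    metric_cols = [c for c in table.columns if c not in ("subject", "bin")]
    g = table.groupby("bin")[metric_cols]
    mean = g.mean()
    sem = g.sem()
    out = pd.concat({"mean": mean, "sem": sem}, axis=1)
    out.columns = [f"{col}_{stat}" for stat, col in out.columns]
    return out.reset_index()
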