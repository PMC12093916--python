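"""Prospective-memory cognitive load from pending-task memory chunks.

Players who defer victims must hold each pending victim's location and
status in declarative memory until they return to it.  The probability of
forgetting a chunk with activation ``A`` is logistic in the distance to the
retrieval threshold ``tau``::

    P(forget) = 1 / (1 + exp(-(tau - A) / t))

and the cognitive load of a set of pending chunks is the sum of each
chunk's *odds* of being forgotten::

    load = sum_i exp((tau - A_i) / t)

so a chunk exactly at threshold contributes 1, a stronger chunk
exponentially less, a weaker chunk exponentially more.  Chunk activation
here uses the base-level (recency/frequency) term only: there is no probe
context to match and noise is absorbed into the scale ``t``, making the
measure a deterministic analytic.

A victim chunk is created at first ENCOUNTER, rehearsed by each processing
step (TRIAGE, MOVE, MARK), and retired from the load at EVACUATE.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "LoadParams",
    "EventKind",
    "VictimEvent",
    "VictimMemoryState",
    "VictimMemory",
    "LoadSeries",
    "p_forget",
    "chunk_load",
    "apply_event",
    "total_load",
    "load_series",
    "victim_forgetting_profile",
    "count_errors",
    "correlate",
    "read_victim_events",
    "write_victim_events",
]

# Smallest lag used when evaluating activation at (or numerically at) a
# rehearsal instant; keeps the power law finite at zero lag.
MIN_LAG = 0.05


@dataclass(frozen=True)
class LoadParams:
    """Forgetting-analytic parameters.

    tau
        retrieval threshold: activation at which a chunk is as likely as
        not to be forgotten (default 0.0).
    t_scale
        logistic scale reflecting activation noise (default 0.25).
    decay
        base-level decay exponent shared with the memory model.
    """

    tau: float = 0.0
    t_scale: float = 0.25
    decay: float = 0.5

    def __post_init__(self) -> None:
        if not self.t_scale > 0:
            raise ValueError("t_scale must be > 0")


class EventKind(str, enum.Enum):
    ENCOUNTER = "ENCOUNTER"
    TRIAGE = "TRIAGE"
    MOVE = "MOVE"
    MARK = "MARK"
    EVACUATE = "EVACUATE"


#: event kinds that rehearse the victim chunk (add a presentation)
REHEARSAL_KINDS = frozenset(
    {EventKind.ENCOUNTER, EventKind.TRIAGE, EventKind.MOVE, EventKind.MARK}
)


@dataclass(frozen=True)
class VictimEvent:
    """One task event in a victim's processing history."""

    time: float
    victim_id: str
    victim_type: str  # "critical" | "noncritical"
    kind: EventKind
    location: str = ""

    def __post_init__(self) -> None:
        if self.victim_type not in ("critical", "noncritical"):
            raise ValueError(f"unknown victim type {self.victim_type!r}")


@dataclass
class VictimMemoryState:
    """Presentation history and status of one victim chunk."""

    victim_id: str
    victim_type: str
    presentation_times: list[float] = field(default_factory=list)
    active: bool = True
    encounter_time: float = 0.0
    evacuate_time: float | None = None


class VictimMemory:
    """Event-driven collection of victim chunks."""

    def __init__(self) -> None:
        self.states: dict[str, VictimMemoryState] = {}

    def active_states(self) -> list[VictimMemoryState]:
        return [s for s in self.states.values() if s.active]


def p_forget(activation: float | np.ndarray, params: LoadParams) -> float | np.ndarray:
    """Probability of forgetting a chunk: logistic in (tau - A) / t."""
    out = expit((params.tau - np.asarray(activation, dtype=float)) / params.t_scale)
    return float(out) if out.ndim == 0 else out


def chunk_load(activation: float | np.ndarray, params: LoadParams) -> float | np.ndarray:
    """Per-chunk load term: the odds of forgetting, exp((tau - A) / t)."""
    out = np.exp((params.tau - np.asarray(activation, dtype=float)) / params.t_scale)
    return float(out) if out.ndim == 0 else out


def apply_event(memory: VictimMemory, event: VictimEvent) -> VictimMemory:
    """Update victim memory with one event, enforcing ordering invariants."""
    state = memory.states.get(event.victim_id)
    if event.kind == EventKind.ENCOUNTER:
        if state is not None:
            raise ValueError(f"duplicate ENCOUNTER for victim {event.victim_id!r}")
        memory.states[event.victim_id] = VictimMemoryState(
            victim_id=event.victim_id,
            victim_type=event.victim_type,
            presentation_times=[event.time],
            active=True,
            encounter_time=event.time,
        )
        return memory
    if state is None:
        raise ValueError(f"{event.kind.value} before ENCOUNTER for victim {event.victim_id!r}")
    if not state.active:
        raise ValueError(f"event after EVACUATE for victim {event.victim_id!r}")
    if event.time < state.presentation_times[-1]:
        raise ValueError("time regression in victim events")
    if event.kind == EventKind.EVACUATE:
        state.active = False
        state.evacuate_time = event.time
    else:  # TRIAGE / MOVE / MARK rehearse the chunk
        state.presentation_times.append(event.time)
    return memory


def _base_level(presentation_times: Sequence[float], now: float, decay: float) -> float:
    """Base-level activation with lags clamped at MIN_LAG (finite at now)."""
    lags = np.maximum(now - np.asarray(presentation_times, dtype=float), MIN_LAG)
    return float(np.log(np.sum(lags**-decay)))


def total_load(
    memory: VictimMemory | Iterable[VictimMemoryState],
    now: float,
    params: LoadParams,
) -> float:
    """Sum of forgetting odds over active chunks (0 with none active)."""
    states = memory.active_states() if isinstance(memory, VictimMemory) else list(memory)
    total = 0.0
    for state in states:
        if state.presentation_times and state.presentation_times[-1] > now:
            raise ValueError("non-causal now: precedes a presentation")
        activation = _base_level(state.presentation_times, now, params.decay)
        total += float(chunk_load(activation, params))
    return total


@dataclass(frozen=True)
class LoadSeries:
    """Sampled total cognitive load over one run."""

    sample_times: np.ndarray
    load_values: np.ndarray
    max_load: float
    mean_load: float  # time-weighted (trapezoidal) mean


def _replay_samples(
    events: Sequence[VictimEvent],
    sample_times: np.ndarray,
    params: LoadParams,
) -> np.ndarray:
    ordered = sorted(events, key=lambda e: e.time)
    memory = VictimMemory()
    loads = np.empty(len(sample_times))
    i = 0
    for j, t in enumerate(sample_times):
        while i < len(ordered) and ordered[i].time <= t:
            apply_event(memory, ordered[i])
            i += 1
        loads[j] = total_load(memory, t, params)
    return loads


def load_series(
    events: Sequence[VictimEvent],
    run_duration: float,
    params: LoadParams,
    sample_dt: float = 1.0,
) -> LoadSeries:
    """Sample total load on a regular grid plus at every event time.

    The time-weighted mean is the trapezoidal integral divided by the run
    duration; the maximum is over all samples.
    """
    if not sample_dt > 0:
        raise ValueError("sample_dt must be > 0")
    if any(e.time > run_duration for e in events):
        raise ValueError("events beyond run_duration")
    grid = np.arange(0.0, run_duration + sample_dt / 2, sample_dt)
    times = np.union1d(grid, np.array([e.time for e in events], dtype=float))
    times = times[(times >= 0.0) & (times <= run_duration)]
    loads = _replay_samples(events, times, params)
    mean = float(np.trapezoid(loads, times) / run_duration) if run_duration > 0 else 0.0
    return LoadSeries(
        sample_times=times,
        load_values=loads,
        max_load=float(loads.max(initial=0.0)),
        mean_load=mean,
    )


def victim_forgetting_profile(
    events: Sequence[VictimEvent],
    run_duration: float,
    params: LoadParams,
    sample_dt: float = 1.0,
) -> pd.DataFrame:
    """Per-victim time-weighted mean forgetting probability over the run.

    A victim is *processed* if evacuated before the run ends; its active
    interval runs from encounter to evacuation (or run end).
    """
    ordered = sorted(events, key=lambda e: e.time)
    memory = VictimMemory()
    for ev in ordered:
        apply_event(memory, ev)
    rows = []
    for state in memory.states.values():
        end = state.evacuate_time if state.evacuate_time is not None else run_duration
        start = state.encounter_time
        span = end - start
        times = np.union1d(
            np.arange(start, end + sample_dt / 2, sample_dt),
            np.array([t for t in state.presentation_times if t <= end] + [end]),
        )
        times = times[(times >= start) & (times <= end)]
        probs = np.array(
            [
                p_forget(
                    _base_level(
                        [t for t in state.presentation_times if t <= t_s], t_s, params.decay
                    )
                    if any(t <= t_s for t in state.presentation_times)
                    else -np.inf,
                    params,
                )
                for t_s in times
            ]
        )
        mean_p = float(np.trapezoid(probs, times) / span) if span > 0 else float(probs[-1])
        rows.append(
            {
                "victim_id": state.victim_id,
                "victim_type": state.victim_type,
                "processed": state.evacuate_time is not None
                and state.evacuate_time <= run_duration,
                "mean_p_forget": mean_p,
                "active_span": span,
            }
        )
    return pd.DataFrame(rows)


def count_errors(events: Sequence[VictimEvent], run_duration: float) -> int:
    """Victims encountered but never evacuated by the end of the run."""
    encountered = set()
    evacuated = set()
    for ev in events:
        if ev.time > run_duration:
            continue
        if ev.kind == EventKind.ENCOUNTER:
            encountered.add(ev.victim_id)
        elif ev.kind == EventKind.EVACUATE:
            evacuated.add(ev.victim_id)
    return len(encountered - evacuated)


def correlate(summaries: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations of load summaries with errors and score.

    ``summaries`` must contain columns max_load, mean_load, errors, score,
    one row per run; requires >= 3 runs and non-degenerate variance.
    """
    required = {"max_load", "mean_load", "errors", "score"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(summaries) < 3:
        raise ValueError("need at least 3 runs to correlate")
    rows = []
    for measure in ("max_load", "mean_load"):
        for target in ("errors", "score"):
            x = summaries[measure].to_numpy(dtype=float)
            y = summaries[target].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                raise ValueError(f"zero variance in {measure} or {target}")
            r, p = stats.pearsonr(x, y)
            rows.append({"load_measure": measure, "target": target, "r": r, "p_value": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# line-delimited victim-event I/O

def write_victim_events(events: Sequence[VictimEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                json.dumps(
                    {
                        "time": ev.time,
                        "victim_id": ev.victim_id,
                        "victim_type": ev.victim_type,
                        "kind": ev.kind.value,
                        "location": ev.location,
                    }
                )
                + "\n"
            )


def read_victim_events(path: str | Path) -> list[VictimEvent]:
    events: list[VictimEvent] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            events.append(
                VictimEvent(
                    time=float(rec["time"]),
                    victim_id=str(rec["victim_id"]),
                    victim_type=str(rec["victim_type"]),
                    kind=EventKind(rec["kind"]),
                    location=str(rec.get("location", "")),
                )
            )
    return events
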