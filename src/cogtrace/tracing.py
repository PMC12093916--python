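"""Model tracing: personalizing the decision model to an observed player.

For each observed decision the freshly bootstrapped model first registers
its own prediction from its current memory, then is forced to take the
player's action and store the player's observed outcome.  Predictions are
therefore always made from the same history of experiences as the player's,
and never see the action they are scored against.

Ambiguous contexts (no non-critical victims, where the two strategies
prescribe identical behaviour) are scored correct for either prediction;
they can be excluded from accuracy summaries via a flag.  Two context-blind
baselines are provided for comparison: the recency heuristic (predict the
previous choice) and the frequency heuristic (predict the modal choice).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .decision import (
    DEFAULT_BASE_POINTS,
    DEFAULT_BASE_TIME,
    Action,
    DecisionOutcome,
    Expectation,
    TriageContext,
    bootstrap_store,
    decide,
    default_similarity,
    record_outcome,
)
from .memory import MemoryParams

__all__ = [
    "TraceEvent",
    "PredictionRecord",
    "trace_player",
    "recency_predict",
    "frequency_predict",
    "baseline_records",
    "accuracy_curve",
    "accuracy_by_difficulty",
    "read_trace",
    "write_trace",
    "records_to_frame",
    "write_predictions",
]


@dataclass(frozen=True)
class TraceEvent:
    """One observed decision with its context and outcome."""

    time: float
    context: TriageContext
    observed_action: Action
    observed_points: float
    observed_duration: float
    map_id: str = ""
    run_index: int = 0

    def __post_init__(self) -> None:
        if not self.observed_duration > 0:
            raise ValueError("observed_duration must be positive")


@dataclass(frozen=True)
class PredictionRecord:
    """A pre-registered prediction for one observed decision."""

    predicted_action: Action
    observed_action: Action
    ambiguous: bool
    correct: bool
    experience_index: int
    expectation: Expectation | None = None
    time: float = 0.0
    map_id: str = ""
    run_index: int = 0

    @property
    def difficulty(self) -> float | None:
        return None if self.expectation is None else self.expectation.difficulty


def _validate_events(events: Sequence[TraceEvent]) -> None:
    if not events:
        raise ValueError("empty event list")
    last = 0.0  # the bootstrap instances live at task time 0
    for ev in events:
        if ev.time <= last:
            raise ValueError("out-of-order events: times must be strictly increasing and > 0")
        last = ev.time


def trace_player(
    events: Sequence[TraceEvent],
    params: MemoryParams | None = None,
    bootstrap_mode: str = "biased",
    base_points: float = DEFAULT_BASE_POINTS,
    base_time: float = DEFAULT_BASE_TIME,
    numeric_range: float | None = None,
    rng: np.random.Generator | None = None,
) -> list[PredictionRecord]:
    """Trace one player's full event sequence through a fresh model.

    The store persists across runs and maps (the task clock must be globally
    monotonic across the player's events).  ``numeric_range`` defaults to
    the largest victim count observed in the events.
    """
    _validate_events(events)
    params = params or MemoryParams()
    if rng is None:
        rng = params.rng()
    if numeric_range is None:
        numeric_range = max(
            1.0,
            float(max(max(e.context.n_critical, e.context.n_noncritical) for e in events)),
        )
    similarity = default_similarity(numeric_range)
    store = bootstrap_store(bootstrap_mode, base_points, base_time)
    records: list[PredictionRecord] = []
    for i, ev in enumerate(events):
        predicted, expectation = decide(
            store, ev.context, params, similarity, now=ev.time, noise_source=rng
        )
        ambiguous = ev.context.ambiguous
        correct = ambiguous or predicted == ev.observed_action
        records.append(
            PredictionRecord(
                predicted_action=predicted,
                observed_action=ev.observed_action,
                ambiguous=ambiguous,
                correct=correct,
                experience_index=i,
                expectation=expectation,
                time=ev.time,
                map_id=ev.map_id,
                run_index=ev.run_index,
            )
        )
        record_outcome(
            store,
            ev.context,
            ev.observed_action,
            DecisionOutcome(ev.observed_points, ev.observed_duration),
            now=ev.time,
        )
    return records


def recency_predict(history: Sequence[Action]) -> Action:
    """Predict the previous choice; before any observation, CRITICAL_FIRST."""
    return history[-1] if history else Action.CRITICAL_FIRST


def frequency_predict(history: Sequence[Action]) -> Action:
    """Predict the modal past choice; ties and empty history -> CRITICAL_FIRST."""
    n_cf = sum(1 for a in history if a == Action.CRITICAL_FIRST)
    return Action.CRITICAL_FIRST if n_cf >= len(history) - n_cf else Action.IN_ORDER


def baseline_records(
    events: Sequence[TraceEvent],
    predictor: Callable[[Sequence[Action]], Action],
) -> list[PredictionRecord]:
    """Score a history-based heuristic on the same events as the model.

    The heuristic sees only the sequence of previously observed actions; the
    ambiguity scoring rule is applied identically to the model's.
    """
    _validate_events(events)
    history: list[Action] = []
    records: list[PredictionRecord] = []
    for i, ev in enumerate(events):
        predicted = predictor(history)
        ambiguous = ev.context.ambiguous
        records.append(
            PredictionRecord(
                predicted_action=predicted,
                observed_action=ev.observed_action,
                ambiguous=ambiguous,
                correct=ambiguous or predicted == ev.observed_action,
                experience_index=i,
                expectation=None,
                time=ev.time,
                map_id=ev.map_id,
                run_index=ev.run_index,
            )
        )
        history.append(ev.observed_action)
    return records


def _filter(records: Sequence[PredictionRecord], exclude_ambiguous: bool):
    if exclude_ambiguous:
        return [r for r in records if not r.ambiguous]
    return list(records)


def accuracy_curve(
    records: Sequence[PredictionRecord],
    bin_width: int = 5,
    exclude_ambiguous: bool = False,
) -> pd.DataFrame:
    """Proportion correct by experience bin, pooled across players.

    Binning uses each record's within-player experience index; records from
    several players may simply be concatenated.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    recs = _filter(records, exclude_ambiguous)
    if not recs:
        raise ValueError("no records to summarize")
    df = pd.DataFrame(
        {
            "bin": [r.experience_index // bin_width for r in recs],
            "correct": [r.correct for r in recs],
        }
    )
    out = df.groupby("bin")["correct"].agg(["mean", "size"]).reset_index()
    out.columns = ["experience_bin", "accuracy", "n"]
    out["first_decision"] = out["experience_bin"] * bin_width
    return out[["experience_bin", "first_decision", "n", "accuracy"]]


def accuracy_by_difficulty(
    records: Sequence[PredictionRecord],
    bin_edges: Sequence[float] | None = None,
    n_bins: int = 5,
    exclude_ambiguous: bool = False,
) -> pd.DataFrame:
    """Proportion correct by decision difficulty (|rate gap|) bin.

    Default bins are quantiles of the observed difficulty distribution.
    Empty bins are omitted with a warning.
    """
    recs = [r for r in _filter(records, exclude_ambiguous) if r.expectation is not None]
    if not recs:
        raise ValueError("no records with expectations")
    diffs = np.array([r.difficulty for r in recs])
    if bin_edges is None:
        qs = np.linspace(0, 1, n_bins + 1)
        bin_edges = np.unique(np.quantile(diffs, qs))
        if len(bin_edges) < 2:
            bin_edges = np.array([diffs.min(), diffs.max() + 1e-12])
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.clip(np.searchsorted(edges, diffs, side="right") - 1, 0, len(edges) - 2)
    df = pd.DataFrame({"bin": idx, "correct": [r.correct for r in recs], "difficulty": diffs})
    grouped = df.groupby("bin").agg(
        accuracy=("correct", "mean"), n=("correct", "size"),
        mean_difficulty=("difficulty", "mean"),
    ).reset_index()
    if len(grouped) < len(edges) - 1:
        warnings.warn("some difficulty bins are empty and were omitted")
    grouped["low_edge"] = edges[grouped["bin"].to_numpy()]
    grouped["high_edge"] = edges[grouped["bin"].to_numpy() + 1]
    return grouped[["bin", "low_edge", "high_edge", "mean_difficulty", "n", "accuracy"]]


# ---------------------------------------------------------------------------
# line-delimited trace I/O

_TRACE_KEYS = (
    "time", "map_id", "run_index", "room_id",
    "n_critical", "n_noncritical", "action", "points", "duration",
)


def write_trace(events: Sequence[TraceEvent], path: str | Path) -> None:
    """Write decision events as one JSON object per line."""
    with open(path, "w") as fh:
        for ev in events:
            fh.write(
                json.dumps(
                    {
                        "time": ev.time,
                        "map_id": ev.map_id,
                        "run_index": ev.run_index,
                        "room_id": ev.context.room_id,
                        "n_critical": ev.context.n_critical,
                        "n_noncritical": ev.context.n_noncritical,
                        "action": ev.observed_action.value,
                        "points": ev.observed_points,
                        "duration": ev.observed_duration,
                    }
                )
                + "\n"
            )


def read_trace(path: str | Path) -> list[TraceEvent]:
    """Read and validate a line-delimited decision trace."""
    events: list[TraceEvent] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            missing = [k for k in _TRACE_KEYS if k not in rec]
            if missing:
                raise ValueError(f"line {lineno}: missing keys {missing}")
            events.append(
                TraceEvent(
                    time=float(rec["time"]),
                    context=TriageContext(
                        n_critical=int(rec["n_critical"]),
                        n_noncritical=int(rec["n_noncritical"]),
                        time=float(rec["time"]),
                        room_id=str(rec["room_id"]),
                    ),
                    observed_action=Action(rec["action"]),
                    observed_points=float(rec["points"]),
                    observed_duration=float(rec["duration"]),
                    map_id=str(rec["map_id"]),
                    run_index=int(rec["run_index"]),
                )
            )
    _validate_events(events)
    return events


def records_to_frame(
    events: Sequence[TraceEvent], records: Sequence[PredictionRecord]
) -> pd.DataFrame:
    """Tabulate predictions next to the observed events they scored."""
    if len(events) != len(records):
        raise ValueError("misaligned record sets")
    rows = []
    for ev, rec in zip(events, records):
        exp = rec.expectation
        rows.append(
            {
                "time": ev.time,
                "map_id": ev.map_id,
                "run_index": ev.run_index,
                "room_id": ev.context.room_id,
                "n_critical": ev.context.n_critical,
                "n_noncritical": ev.context.n_noncritical,
                "action": ev.observed_action.value,
                "points": ev.observed_points,
                "duration": ev.observed_duration,
                "predicted_action": rec.predicted_action.value,
                "expected_rate_cf": None if exp is None else exp.rate(Action.CRITICAL_FIRST),
                "expected_rate_io": None if exp is None else exp.rate(Action.IN_ORDER),
                "ambiguous": rec.ambiguous,
                "correct": rec.correct,
            }
        )
    return pd.DataFrame(rows)


def write_predictions(
    events: Sequence[TraceEvent],
    records: Sequence[PredictionRecord],
    path: str | Path,
) -> None:
    records_to_frame(events, records).to_csv(path, index=False)
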