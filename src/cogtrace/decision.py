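"""The two-strategy triage decision model.

In the search-and-rescue task a player entering a room with victims decides
between two strategies: triage victims *in the order encountered*, or
*prioritize critical victims* (which are worth more points but expire at a
mid-run deadline) and return to the others later.  The model generates a
blended expected outcome (points, duration) for each strategy from its
instance store, converts each to a points/time rate, and deterministically
selects the higher rate; stochasticity enters only through activation noise.

Each executed decision is stored back as a single new instance holding the
*observed* outcome (no expectations stored, no counterfactual instance for
the action not taken).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .memory import (
    InstanceStore,
    MemoryParams,
    Probe,
    SimilaritySpec,
    blended_outcomes,
)

__all__ = [
    "Action",
    "TriageContext",
    "DecisionOutcome",
    "Expectation",
    "default_similarity",
    "bootstrap_store",
    "expected_outcomes",
    "decide",
    "record_outcome",
    "DEFAULT_BASE_POINTS",
    "DEFAULT_BASE_TIME",
]


class Action(str, enum.Enum):
    """The two triage strategies."""

    CRITICAL_FIRST = "CRITICAL_FIRST"
    IN_ORDER = "IN_ORDER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ACTIONS = (Action.CRITICAL_FIRST, Action.IN_ORDER)

# Prior-outcome magnitudes for the two bootstrap instances.  Only the 2:1
# rate ratio between strategies is theoretically constrained; magnitudes are
# set on the scale of actual per-room outcomes (tens of points, around a
# minute of processing) so that experienced rates can overturn the prior.
DEFAULT_BASE_POINTS = 10.0
DEFAULT_BASE_TIME = 60.0

#: smallest admissible blended duration when forming a rate
_MIN_TIME = 1e-9


@dataclass(frozen=True)
class TriageContext:
    """Decision context: victim counts in the room, clock time, room id.

    A context with no non-critical victims is *ambiguous*: both strategies
    prescribe the same behaviour, so no prediction can be wrong there.
    """

    n_critical: int
    n_noncritical: int
    time: float = 0.0
    room_id: str = ""

    def __post_init__(self) -> None:
        if self.n_critical < 0 or self.n_noncritical < 0:
            raise ValueError("victim counts must be non-negative")

    @property
    def ambiguous(self) -> bool:
        return self.n_noncritical == 0


@dataclass(frozen=True)
class DecisionOutcome:
    """Observed result of a decision: points collected and time taken."""

    points: float
    duration: float

    def __post_init__(self) -> None:
        if self.points < 0:
            raise ValueError("points must be >= 0")
        if not self.duration > 0:
            raise ValueError("duration must be strictly positive")

    @property
    def rate(self) -> float:
        return self.points / self.duration


@dataclass(frozen=True)
class Expectation:
    """Blended expected outcomes and rates for both strategies."""

    expected_points: dict[Action, float]
    expected_time: dict[Action, float]

    def rate(self, action: Action) -> float:
        return self.expected_points[action] / max(self.expected_time[action], _MIN_TIME)

    @property
    def difficulty(self) -> float:
        """Absolute rate gap between the two strategies (decision difficulty)."""
        return abs(self.rate(Action.CRITICAL_FIRST) - self.rate(Action.IN_ORDER))


def default_similarity(numeric_range: float) -> SimilaritySpec:
    """Similarity spec for triage decisions.

    Victim counts are numeric attributes scaled by ``numeric_range`` (the
    largest victim count in play); the action label is a symbolic attribute
    with the maximal -10 mismatch, which effectively restricts blending to
    same-action instances while keeping a single retrieval mechanism.
    """
    if not numeric_range > 0:
        raise ValueError("numeric_range must be positive")
    return SimilaritySpec(
        kinds={"n_critical": "numeric", "n_noncritical": "numeric", "action": "symbolic"},
        numeric_ranges={"n_critical": numeric_range, "n_noncritical": numeric_range},
    )


def _instance_attributes(context: TriageContext, action: Action) -> dict:
    return {
        "n_critical": context.n_critical,
        "n_noncritical": context.n_noncritical,
        "action": action.value,
    }


def bootstrap_store(
    mode: str = "biased",
    base_points: float = DEFAULT_BASE_POINTS,
    base_time: float = DEFAULT_BASE_TIME,
) -> InstanceStore:
    """Create the two prior instances, one per strategy, at task time 0.

    ``biased`` gives the critical-first strategy exactly twice the
    points/time rate of the in-order strategy (mirroring the human prior for
    high-value critical victims); ``unbiased`` gives both strategies equal
    expected outcomes.
    """
    if mode not in ("biased", "unbiased"):
        raise ValueError(f"invalid bootstrap mode {mode!r}")
    if not (base_points > 0 and base_time > 0):
        raise ValueError("bootstrap magnitudes must be positive")
    neutral = TriageContext(n_critical=1, n_noncritical=1, time=0.0, room_id="bootstrap")
    store = InstanceStore()
    cf_points = 2.0 * base_points if mode == "biased" else base_points
    store.add(
        _instance_attributes(neutral, Action.CRITICAL_FIRST),
        {"points": cf_points, "duration": base_time},
        now=0.0,
    )
    store.add(
        _instance_attributes(neutral, Action.IN_ORDER),
        {"points": base_points, "duration": base_time},
        now=0.0,
    )
    return store


def expected_outcomes(
    store: InstanceStore,
    context: TriageContext,
    action: Action,
    params: MemoryParams,
    similarity: SimilaritySpec,
    now: float,
    noise: np.ndarray | None = None,
    noise_source: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Blended (expected_points, expected_time) for taking ``action`` now."""
    probe = Probe(_instance_attributes(context, action), similarity)
    vals = blended_outcomes(
        store, probe, params, now, ("points", "duration"),
        noise=noise, noise_source=noise_source,
    )
    return vals["points"], vals["duration"]


def decide(
    store: InstanceStore,
    context: TriageContext,
    params: MemoryParams,
    similarity: SimilaritySpec,
    now: float,
    noise_source: np.random.Generator | None = None,
) -> tuple[Action, Expectation]:
    """Select the strategy with the higher expected points/time rate.

    One transient-noise draw per instance is shared across the two action
    probes, so a single decision sees one consistent noisy memory state.
    Exact rate ties break toward CRITICAL_FIRST (the documented prior).
    """
    if params.noise_s == 0:
        noise = np.zeros(len(store))
    else:
        rng = noise_source if noise_source is not None else params.rng()
        noise = rng.logistic(0.0, params.noise_s, size=len(store))
    points: dict[Action, float] = {}
    times: dict[Action, float] = {}
    for action in ACTIONS:
        p, t = expected_outcomes(store, context, action, params, similarity, now, noise=noise)
        points[action], times[action] = p, t
    expectation = Expectation(points, times)
    if expectation.rate(Action.CRITICAL_FIRST) >= expectation.rate(Action.IN_ORDER):
        return Action.CRITICAL_FIRST, expectation
    return Action.IN_ORDER, expectation


def record_outcome(
    store: InstanceStore,
    context: TriageContext,
    action: Action,
    outcome: DecisionOutcome,
    now: float,
) -> int:
    """Store the observed experience as exactly one new instance."""
    return store.add(
        _instance_attributes(context, action),
        {"points": outcome.points, "duration": outcome.duration},
        now=now,
    )
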