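"""Seeded synthetic search-and-rescue task: maps, players, runs, cohorts.

The simulator emulates the statistical structure of the study task: 15-min
runs through a building of rooms containing critical and non-critical
victims, a mid-run deadline after which critical victims expire, a triage
decision at each victim-bearing room entered before the deadline, per-victim
processing events (encounter, triage, move, mark, evacuate), and per-run
score and error counts.

Strategy semantics: IN_ORDER processes a room's victims as encountered;
CRITICAL_FIRST processes critical victims immediately and defers
non-critical ones to a return phase (rehearsing their memory chunks via
optional marker/move events).  In a room without critical victims the two
strategies coincide.  A critical victim scores points only if evacuated by
the deadline.  The decision outcome charged to memory is the points and
processing time of the immediate (pre-deferral) work.

Synthetic players come in three kinds: FIXED (always the same strategy),
CONTEXT_RULE (threshold rule on the critical/non-critical ratio), and
SOFTMAX_IBL (an instance-based learner of its own, choosing by a Boltzmann
rule over its expected rates -- the decision process the traced model
assumes of humans).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .decision import (
    Action,
    DecisionOutcome,
    MemoryParams,
    TriageContext,
    bootstrap_store,
    decide,
    default_similarity,
    record_outcome,
)
from .load import (
    REHEARSAL_KINDS,
    EventKind,
    LoadParams,
    VictimEvent,
    _base_level,
    count_errors,
    p_forget,
)
from .tracing import TraceEvent

__all__ = [
    "MapConfig",
    "Victim",
    "GeneratedMap",
    "PlayerProfile",
    "SyntheticPlayer",
    "SimTrace",
    "PlayerTraces",
    "generate_map",
    "simulate_run",
    "simulate_cohort",
    "inject_forgetting",
    "score_from_events",
]

DIFFICULTY_PRESETS = {
    # rooms, mean victims/room, traversal range (s)
    "easy": (8, 2.0, (10.0, 20.0)),
    "medium": (12, 2.5, (15.0, 30.0)),
    "hard": (16, 3.0, (20.0, 40.0)),
}


@dataclass(frozen=True)
class MapConfig:
    """Static description of one building map.

    Default magnitudes: critical victims are worth 30 points and take 60 s
    to process but expire at the mid-run deadline; non-critical victims are
    worth 10 points and take 15 s.  A run lasts 900 s (15 min) with the
    critical deadline at half time.
    """

    map_id: str = "map-0"
    difficulty: str = "medium"
    n_rooms: int = 12
    mean_victims_per_room: float = 2.5
    critical_fraction: float = 0.3
    traversal_range: tuple[float, float] = (15.0, 30.0)
    points_critical: float = 30.0
    points_noncritical: float = 10.0
    time_critical: float = 60.0
    time_noncritical: float = 15.0
    run_duration: float = 900.0
    critical_deadline: float | None = None

    def __post_init__(self) -> None:
        if self.n_rooms < 1:
            raise ValueError("infeasible config: need at least one room")
        if self.mean_victims_per_room < 0 or not (0 <= self.critical_fraction <= 1):
            raise ValueError("infeasible victim distribution")
        lo, hi = self.traversal_range
        if not (0 < lo <= hi):
            raise ValueError("traversal times must be positive")
        if min(self.time_critical, self.time_noncritical) <= 0 or self.run_duration <= 0:
            raise ValueError("all times must be positive")
        if self.deadline >= self.run_duration:
            raise ValueError("critical_deadline must precede run end")

    @property
    def deadline(self) -> float:
        return (
            self.critical_deadline
            if self.critical_deadline is not None
            else self.run_duration / 2
        )

    @classmethod
    def preset(cls, difficulty: str, map_id: str | None = None, **overrides) -> "MapConfig":
        n_rooms, mean_v, trav = DIFFICULTY_PRESETS[difficulty]
        return cls(
            map_id=map_id or f"map-{difficulty}",
            difficulty=difficulty,
            n_rooms=n_rooms,
            mean_victims_per_room=mean_v,
            traversal_range=trav,
            **overrides,
        )

    def victim(self, vtype: str) -> tuple[float, float]:
        """(points, processing time) for a victim type."""
        if vtype == "critical":
            return self.points_critical, self.time_critical
        return self.points_noncritical, self.time_noncritical


@dataclass(frozen=True)
class Victim:
    victim_id: str
    vtype: str  # "critical" | "noncritical"


@dataclass(frozen=True)
class GeneratedMap:
    config: MapConfig
    rooms: tuple[tuple[Victim, ...], ...]

    @property
    def max_room_count(self) -> int:
        """Largest per-type victim count in any room (>= 1)."""
        best = 1
        for room in self.rooms:
            n_c = sum(1 for v in room if v.vtype == "critical")
            best = max(best, n_c, len(room) - n_c)
        return best


def generate_map(config: MapConfig, seed: int | np.random.Generator) -> GeneratedMap:
    """Draw a concrete map: per-room Poisson victim counts, Bernoulli types."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rooms = []
    for r in range(config.n_rooms):
        n = int(rng.poisson(config.mean_victims_per_room))
        room = []
        for k in range(n):
            vtype = "critical" if rng.random() < config.critical_fraction else "noncritical"
            room.append(Victim(f"{config.map_id}-r{r}-v{k}", vtype))
        rooms.append(tuple(room))
    return GeneratedMap(config=config, rooms=tuple(rooms))


@dataclass(frozen=True)
class PlayerProfile:
    """Behavioural profile of one synthetic player.

    policy
        "fixed", "context_rule", or "softmax_ibl".
    fixed_action
        the strategy of a fixed-policy player.
    threshold
        context rule: choose CRITICAL_FIRST iff
        ``n_critical >= threshold * n_noncritical``.
    choice_temperature
        Boltzmann temperature over expected rates for softmax players.
    rehearsal_diligence
        probability that a deferred victim receives a MARK/MOVE rehearsal.
    skill_noise
        fractional jitter on processing times.
    """

    policy: str = "softmax_ibl"
    fixed_action: Action | None = None
    threshold: float = 1.0
    memory: MemoryParams = field(default_factory=MemoryParams)
    choice_temperature: float = 0.1
    bootstrap_mode: str = "biased"
    rehearsal_diligence: float = 0.5
    skill_noise: float = 0.1
    player_id: str = "player-0"

    def __post_init__(self) -> None:
        if self.policy not in ("fixed", "context_rule", "softmax_ibl"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.policy == "fixed" and self.fixed_action is None:
            raise ValueError("fixed policy needs an action")
        if not 0 <= self.rehearsal_diligence <= 1:
            raise ValueError("rehearsal_diligence must be in [0, 1]")
        if self.policy == "softmax_ibl" and not self.choice_temperature > 0:
            raise ValueError("choice_temperature must be > 0")


class SyntheticPlayer:
    """Stateful player executing a profile; softmax players carry their own
    instance store across runs."""

    def __init__(
        self,
        profile: PlayerProfile,
        rng: np.random.Generator,
        numeric_range: float = 6.0,
    ) -> None:
        self.profile = profile
        self.rng = rng
        if profile.policy == "softmax_ibl":
            self.store = bootstrap_store(profile.bootstrap_mode)
            self.similarity = default_similarity(numeric_range)
        else:
            self.store = None
            self.similarity = None

    def choose(self, context: TriageContext, now: float) -> Action:
        prof = self.profile
        if prof.policy == "fixed":
            return prof.fixed_action
        if prof.policy == "context_rule":
            if context.n_critical >= prof.threshold * context.n_noncritical:
                return Action.CRITICAL_FIRST
            return Action.IN_ORDER
        # softmax_ibl: Boltzmann choice over the two expected rates
        _, expectation = decide(
            self.store, context, prof.memory, self.similarity, now, noise_source=self.rng
        )
        gap = expectation.rate(Action.CRITICAL_FIRST) - expectation.rate(Action.IN_ORDER)
        p_cf = 1.0 / (1.0 + np.exp(-gap / prof.choice_temperature))
        return Action.CRITICAL_FIRST if self.rng.random() < p_cf else Action.IN_ORDER

    def learn(
        self, context: TriageContext, action: Action, outcome: DecisionOutcome, now: float
    ) -> None:
        if self.store is not None:
            record_outcome(self.store, context, action, outcome, now)


@dataclass
class SimTrace:
    """Everything one simulated run produced."""

    map_id: str
    run_index: int
    player_id: str
    config: MapConfig
    decisions: list[TraceEvent]
    victim_events: list[VictimEvent]
    score: float
    errors: int
    n_marks: int
    n_moves: int
    deferred_returns: dict[str, float]  # victim_id -> scheduled return time


def score_from_events(events: Sequence[VictimEvent], config: MapConfig) -> float:
    """Recompute the run score from the event log alone.

    Each evacuated victim scores its point value; a critical victim scores
    zero if evacuated after the deadline.
    """
    score = 0.0
    for ev in events:
        if ev.kind != EventKind.EVACUATE or ev.time > config.run_duration:
            continue
        points, _ = config.victim(ev.victim_type)
        if ev.victim_type == "critical" and ev.time > config.deadline:
            points = 0.0
        score += points
    return score


def _process_victim(
    victim: Victim,
    t: float,
    cfg: MapConfig,
    skill_noise: float,
    rng: np.random.Generator,
    events: list[VictimEvent],
    room_id: str,
) -> tuple[float, float, bool]:
    """Triage+evacuate one victim starting at t.

    Returns (new clock, points scored, completed flag); emits events that
    fit inside the run.
    """
    points, proc = cfg.victim(victim.vtype)
    if skill_noise > 0:
        proc *= 1.0 + skill_noise * rng.uniform(-1.0, 1.0)
    proc = max(proc, 1.0)
    triage_t = t + 0.6 * proc
    evac_t = t + proc
    if evac_t > cfg.run_duration:
        if triage_t <= cfg.run_duration:
            events.append(
                VictimEvent(triage_t, victim.victim_id, victim.vtype, EventKind.TRIAGE, room_id)
            )
        return cfg.run_duration, 0.0, False
    events.append(
        VictimEvent(triage_t, victim.victim_id, victim.vtype, EventKind.TRIAGE, room_id)
    )
    events.append(
        VictimEvent(evac_t, victim.victim_id, victim.vtype, EventKind.EVACUATE, room_id)
    )
    if victim.vtype == "critical" and evac_t > cfg.deadline:
        points = 0.0
    return evac_t, points, True


def simulate_run(
    gmap: GeneratedMap,
    player: SyntheticPlayer,
    rng: np.random.Generator,
    run_index: int = 0,
    clock_offset: float = 0.0,
) -> SimTrace:
    """Walk the map's rooms, decide, process, and log one run.

    Victim-event times are run-local (0 at run start); decision-trace times
    are global (``clock_offset`` + local) so a player's memory clock stays
    monotonic across runs.
    """
    cfg = gmap.config
    prof = player.profile
    t = 0.0
    decisions: list[TraceEvent] = []
    events: list[VictimEvent] = []
    pending: list[tuple[Victim, str]] = []
    deferred_returns: dict[str, float] = {}
    score = 0.0
    n_marks = n_moves = 0

    # phase 1: sweep rooms until the critical deadline, deciding per room
    room_idx = 0
    while room_idx < len(gmap.rooms):
        victims = gmap.rooms[room_idx]
        t += rng.uniform(*cfg.traversal_range)
        if t >= min(cfg.deadline, cfg.run_duration):
            break
        room_id = f"{cfg.map_id}-r{room_idx}"
        if not victims:
            room_idx += 1
            continue
        for v in victims:
            events.append(VictimEvent(t, v.victim_id, v.vtype, EventKind.ENCOUNTER, room_id))
        criticals = [v for v in victims if v.vtype == "critical"]
        noncriticals = [v for v in victims if v.vtype == "noncritical"]
        context = TriageContext(
            n_critical=len(criticals),
            n_noncritical=len(noncriticals),
            time=clock_offset + t,
            room_id=room_id,
        )
        action = player.choose(context, clock_offset + t)
        # With no criticals present the strategies prescribe the same
        # behaviour; defer only when CRITICAL_FIRST has something to
        # prioritize.
        if action is Action.CRITICAL_FIRST and criticals:
            immediate, deferred = criticals, noncriticals
        else:
            immediate, deferred = list(victims), []
        start = t
        points = 0.0
        for v in immediate:
            t, pts, done = _process_victim(v, t, cfg, prof.skill_noise, rng, events, room_id)
            points += pts
            if not done:
                break
        score += points
        duration = max(t - start, 1.0)
        outcome = DecisionOutcome(points, duration)
        decisions.append(
            TraceEvent(
                time=clock_offset + start,
                context=context,
                observed_action=action,
                observed_points=points,
                observed_duration=duration,
                map_id=cfg.map_id,
                run_index=run_index,
            )
        )
        player.learn(context, action, outcome, clock_offset + start)
        for v in deferred:
            mark_t = min(t, cfg.run_duration)
            if rng.random() < prof.rehearsal_diligence and mark_t < cfg.run_duration:
                if rng.random() < 0.7:
                    kind = EventKind.MARK
                    n_marks += 1
                else:
                    kind = EventKind.MOVE
                    n_moves += 1
                events.append(VictimEvent(mark_t, v.victim_id, v.vtype, kind, room_id))
            pending.append((v, room_id))
        room_idx += 1
        if t >= cfg.run_duration:
            break

    # phase 2: return to deferred victims in encounter order ("previously
    # encountered ... until the end of the trial")
    lo, hi = cfg.traversal_range
    for v, room_id in pending:
        if t >= cfg.run_duration:
            break
        t += rng.uniform(lo, hi) / 2.0
        if t >= cfg.run_duration:
            break
        deferred_returns[v.victim_id] = t
        t, pts, done = _process_victim(v, t, cfg, prof.skill_noise, rng, events, room_id)
        score += pts
        if not done:
            break

    # phase 3: clear remaining rooms in order (no strategy decision left)
    for rest_idx in range(room_idx, len(gmap.rooms)):
        if t >= cfg.run_duration:
            break
        t += rng.uniform(*cfg.traversal_range)
        if t >= cfg.run_duration:
            break
        room_id = f"{cfg.map_id}-r{rest_idx}"
        for v in gmap.rooms[rest_idx]:
            events.append(VictimEvent(t, v.victim_id, v.vtype, EventKind.ENCOUNTER, room_id))
        for v in gmap.rooms[rest_idx]:
            t, pts, done = _process_victim(v, t, cfg, prof.skill_noise, rng, events, room_id)
            score += pts
            if not done:
                break

    events.sort(key=lambda e: (e.time, e.kind != EventKind.ENCOUNTER))
    errors = count_errors(events, cfg.run_duration)
    return SimTrace(
        map_id=cfg.map_id,
        run_index=run_index,
        player_id=prof.player_id,
        config=cfg,
        decisions=decisions,
        victim_events=events,
        score=score,
        errors=errors,
        n_marks=n_marks,
        n_moves=n_moves,
        deferred_returns=deferred_returns,
    )


@dataclass
class PlayerTraces:
    """All runs of one player, in order."""

    player_id: str
    profile: PlayerProfile
    runs: list[SimTrace]

    @property
    def decisions(self) -> list[TraceEvent]:
        return [ev for run in self.runs for ev in run.decisions]


def simulate_cohort(
    maps: Sequence[GeneratedMap],
    profiles: Sequence[PlayerProfile],
    seed: int,
) -> list[PlayerTraces]:
    """Run every player through the map sequence; fully seed-reproducible.

    The task clock continues monotonically across a player's runs, so traced
    memory ages realistically between maps.
    """
    if not profiles:
        raise ValueError("need at least one player profile")
    numeric_range = float(max(gm.max_room_count for gm in maps))
    root = np.random.SeedSequence(seed)
    cohort: list[PlayerTraces] = []
    for prof, child in zip(profiles, root.spawn(len(profiles))):
        rng = np.random.default_rng(child)
        player = SyntheticPlayer(prof, rng, numeric_range=numeric_range)
        offset = 0.0
        runs = []
        for run_index, gmap in enumerate(maps):
            runs.append(simulate_run(gmap, player, rng, run_index, clock_offset=offset))
            offset += gmap.config.run_duration
        cohort.append(PlayerTraces(player_id=prof.player_id, profile=prof, runs=runs))
    return cohort


def inject_forgetting(
    trace: SimTrace,
    params: LoadParams,
    seed: int | np.random.Generator,
) -> SimTrace:
    """Make the forgetting model the generative error mechanism.

    For each deferred victim, at its scheduled return time the remaining
    processing is dropped with the victim chunk's current probability of
    forgetting; score and error count are recomputed from the modified log.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    forgotten: set[str] = set()
    for vid, return_time in sorted(trace.deferred_returns.items()):
        presentations = [
            e.time
            for e in trace.victim_events
            if e.victim_id == vid and e.kind in REHEARSAL_KINDS and e.time < return_time
        ]
        if not presentations:
            continue
        activation = _base_level(presentations, return_time, params.decay)
        if rng.random() < p_forget(activation, params):
            forgotten.add(vid)
    if not forgotten:
        return trace
    new_events = [
        e
        for e in trace.victim_events
        if not (
            e.victim_id in forgotten
            and e.time >= trace.deferred_returns[e.victim_id]
            and e.kind in (EventKind.TRIAGE, EventKind.EVACUATE)
        )
    ]
    new_returns = {k: v for k, v in trace.deferred_returns.items() if k not in forgotten}
    return replace(
        trace,
        victim_events=new_events,
        score=score_from_events(new_events, trace.config),
        errors=count_errors(new_events, trace.config.run_duration),
        deferred_returns=new_returns,
    )
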