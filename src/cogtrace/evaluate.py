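"""End-to-end experiments: simulate a cohort, trace it, analyze load.

`run_experiment` wires the full pipeline together: generate maps, simulate a
synthetic cohort, trace every player with the cognitive model and the two
baseline heuristics, compute accuracy tables (by experience, by decision
difficulty, by map), per-run cognitive-load summaries with
forgetting-injected errors, and load/error/score correlations.  Everything
is derived from an :class:`ExperimentConfig` plus a seed, and every output
table is reproducible bit-identically from those two.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import metadata as importlib_metadata
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .decision import Action
from .load import LoadParams, correlate, load_series
from .memory import MemoryParams
from .synthetic import (
    GeneratedMap,
    MapConfig,
    PlayerProfile,
    PlayerTraces,
    generate_map,
    inject_forgetting,
    simulate_cohort,
)
from .tracing import (
    PredictionRecord,
    accuracy_curve,
    baseline_records,
    frequency_predict,
    recency_predict,
    trace_player,
)

__all__ = [
    "ExperimentConfig",
    "ReportBundle",
    "build_profiles",
    "build_maps",
    "per_player_cohort",
    "context_dependent_profiles",
    "stationary_profiles",
    "trace_cohort",
    "compare_predictors",
    "load_summaries",
    "run_experiment",
]

PREDICTORS = ("model", "frequency", "recency")


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one reproducible experiment."""

    seed: int = 0
    n_players: int = 20
    profile_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "fixed_cf": 0.2,
            "fixed_io": 0.2,
            "context_rule": 0.2,
            "softmax_ibl": 0.4,
        }
    )
    maps: Sequence[str] = ("easy", "medium", "hard")
    map_cycles: int = 2
    bootstrap_mode: str = "biased"
    memory: MemoryParams = field(default_factory=MemoryParams)
    base_points: float = 10.0
    base_time: float = 60.0
    load: LoadParams = field(default_factory=LoadParams)
    exclude_ambiguous: bool = False
    bin_width: int = 5
    inject_errors: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        model = raw.pop("model", {})
        memory = MemoryParams(
            decay=model.get("decay", 0.5),
            mismatch_penalty=model.get("mismatch_penalty", 1.0),
            noise_s=model.get("noise_s", 0.1),
            temperature=model.get("temperature", 1.0),
            rng_seed=model.get("seed", raw.get("seed", 0)),
        )
        load_raw = raw.pop("load", {})
        load = LoadParams(
            tau=load_raw.get("tau", 0.0),
            t_scale=load_raw.get("t_scale", 0.25),
            decay=load_raw.get("decay", 0.5),
        )
        kwargs = dict(
            seed=raw.get("seed", 0),
            n_players=raw.get("n_players", 20),
            profile_mix=raw.get("profile_mix", None),
            maps=tuple(raw.get("maps", ("easy", "medium", "hard"))),
            map_cycles=raw.get("map_cycles", 2),
            bootstrap_mode=model.get("bootstrap", "biased"),
            memory=memory,
            base_points=model.get("base_points", 10.0),
            base_time=model.get("base_time", 60.0),
            load=load,
            exclude_ambiguous=raw.get("exclude_ambiguous", False),
            bin_width=raw.get("bin_width", 5),
            inject_errors=raw.get("inject_errors", True),
        )
        if kwargs["profile_mix"] is None:
            kwargs.pop("profile_mix")
        if seed is not None:
            kwargs["seed"] = seed
        return cls(**kwargs)

    def canonical_dict(self) -> dict:
        d = asdict(self)
        d["profile_mix"] = dict(self.profile_mix)
        d["maps"] = list(self.maps)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def build_profiles(
    n_players: int,
    mix: Mapping[str, float],
    seed: int | np.random.Generator,
) -> list[PlayerProfile]:
    """Assemble a cohort of player profiles from a policy mix.

    Fractions are converted to counts by largest remainder; context-rule
    thresholds and rehearsal diligence vary across players so that cohorts
    span a spread of strategy usage and memory pressure.
    """
    if n_players < 1:
        raise ValueError("n_players must be >= 1")
    total = sum(mix.values())
    if total <= 0:
        raise ValueError("profile mix must have positive mass")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keys = sorted(mix)
    quota = {k: mix[k] / total * n_players for k in keys}
    counts = {k: int(np.floor(quota[k])) for k in keys}
    remainders = sorted(keys, key=lambda k: quota[k] - counts[k], reverse=True)
    i = 0
    while sum(counts.values()) < n_players:
        counts[remainders[i % len(remainders)]] += 1
        i += 1
    profiles: list[PlayerProfile] = []
    idx = 0
    for kind in keys:
        for _ in range(counts[kind]):
            diligence = float(rng.uniform(0.1, 0.9))
            common = dict(
                rehearsal_diligence=diligence,
                player_id=f"player-{idx:03d}",
            )
            if kind == "fixed_cf":
                profiles.append(
                    PlayerProfile(policy="fixed", fixed_action=Action.CRITICAL_FIRST, **common)
                )
            elif kind == "fixed_io":
                profiles.append(
                    PlayerProfile(policy="fixed", fixed_action=Action.IN_ORDER, **common)
                )
            elif kind == "context_rule":
                profiles.append(
                    PlayerProfile(
                        policy="context_rule",
                        threshold=float(rng.uniform(0.5, 2.0)),
                        **common,
                    )
                )
            elif kind == "softmax_ibl":
                profiles.append(PlayerProfile(policy="softmax_ibl", **common))
            else:
                raise ValueError(f"unknown profile kind {kind!r}")
            idx += 1
    return profiles


def per_player_cohort(
    profiles: Sequence[PlayerProfile],
    seed: int,
    n_maps: int = 10,
    difficulty: str = "medium",
) -> list[PlayerTraces]:
    """Simulate a cohort in which every player gets independent map draws.

    Sharing one map realization across players (as teams in a live study
    would) correlates all players' context sequences, which confounds
    pooled accuracy-by-experience curves; independent draws make per-bin
    averages across players meaningful.
    """
    cohort: list[PlayerTraces] = []
    for prof, kid in zip(profiles, np.random.SeedSequence(seed).spawn(len(profiles))):
        rng = np.random.default_rng(kid)
        maps = [
            generate_map(MapConfig.preset(difficulty, map_id=f"map-{c}"), rng)
            for c in range(n_maps)
        ]
        sub_seed = int(kid.generate_state(1)[0] % 2**31)
        cohort.extend(simulate_cohort(maps, [prof], seed=sub_seed))
    return cohort


def context_dependent_profiles(
    n_players: int, seed: int | np.random.Generator
) -> list[PlayerProfile]:
    """Profiles whose choices depend on room context: half threshold-rule
    players (varied thresholds), half instance-based softmax deciders."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profiles = []
    for i in range(n_players):
        common = dict(
            rehearsal_diligence=float(rng.uniform(0.1, 0.9)),
            player_id=f"player-{i:03d}",
        )
        if i % 2 == 0:
            profiles.append(
                PlayerProfile(
                    policy="context_rule", threshold=float(rng.uniform(0.5, 2.0)), **common
                )
            )
        else:
            profiles.append(PlayerProfile(policy="softmax_ibl", **common))
    return profiles


def stationary_profiles(
    n_players: int, seed: int | np.random.Generator
) -> list[PlayerProfile]:
    """Stationary-policy profiles (fixed threshold rules): the reference
    cohort for properties that assume a time-invariant choice process."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [
        PlayerProfile(
            policy="context_rule",
            threshold=float(rng.uniform(0.5, 2.0)),
            rehearsal_diligence=float(rng.uniform(0.1, 0.9)),
            player_id=f"player-{i:03d}",
        )
        for i in range(n_players)
    ]


def build_maps(
    difficulties: Sequence[str], cycles: int, seed: int | np.random.Generator
) -> list[GeneratedMap]:
    """Generate the map sequence each player will run, in order."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    maps = []
    for c in range(cycles):
        for diff in difficulties:
            cfg = MapConfig.preset(diff, map_id=f"map-{diff}-{c}")
            maps.append(generate_map(cfg, rng))
    return maps


def trace_cohort(
    cohort: Sequence[PlayerTraces],
    config: ExperimentConfig,
) -> dict[str, list[PredictionRecord]]:
    """Trace every player with the model and both baselines.

    Records are concatenated across players in cohort order, aligned
    index-by-index across predictors.
    """
    root = np.random.SeedSequence(config.seed).spawn(1)[0].spawn(len(cohort))
    out: dict[str, list[PredictionRecord]] = {name: [] for name in PREDICTORS}
    for pt, child in zip(cohort, root):
        events = pt.decisions
        if not events:
            continue
        out["model"].extend(
            trace_player(
                events,
                params=config.memory,
                bootstrap_mode=config.bootstrap_mode,
                base_points=config.base_points,
                base_time=config.base_time,
                rng=np.random.default_rng(child),
            )
        )
        out["recency"].extend(baseline_records(events, recency_predict))
        out["frequency"].extend(baseline_records(events, frequency_predict))
    return out


def _check_aligned(records_by_predictor: Mapping[str, Sequence[PredictionRecord]]) -> None:
    lengths = {k: len(v) for k, v in records_by_predictor.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"misaligned record sets: {lengths}")
    ref = next(iter(records_by_predictor.values()))
    for name, recs in records_by_predictor.items():
        for a, b in zip(ref, recs):
            if a.observed_action != b.observed_action or a.ambiguous != b.ambiguous:
                raise ValueError("misaligned record sets: observed events differ")


def compare_predictors(
    records_by_predictor: Mapping[str, Sequence[PredictionRecord]],
    bin_width: int = 5,
    n_difficulty_bins: int = 5,
    exclude_ambiguous: bool = False,
) -> pd.DataFrame:
    """Aligned long-format accuracy table: predictor x (dimension, bin).

    Dimensions: experience bin, decision-difficulty bin (difficulty taken
    from the model's expectations for every predictor, so bins align), and
    map.  One row per (predictor, dimension, bin).
    """
    _check_aligned(records_by_predictor)
    if "model" not in records_by_predictor:
        raise ValueError("need a 'model' record set to define difficulty bins")
    model_recs = list(records_by_predictor["model"])
    rows = []

    for name, recs in records_by_predictor.items():
        curve = accuracy_curve(recs, bin_width, exclude_ambiguous)
        for _, r in curve.iterrows():
            rows.append(
                {
                    "predictor": name,
                    "dimension": "experience",
                    "bin": str(int(r["experience_bin"])),
                    "n": int(r["n"]),
                    "accuracy": float(r["accuracy"]),
                }
            )

    # difficulty bins from the model's |rate gap|, shared across predictors
    keep = [
        i
        for i, r in enumerate(model_recs)
        if r.expectation is not None and not (exclude_ambiguous and r.ambiguous)
    ]
    if keep:
        diffs = np.array([model_recs[i].difficulty for i in keep])
        edges = np.unique(np.quantile(diffs, np.linspace(0, 1, n_difficulty_bins + 1)))
        if len(edges) < 2:
            edges = np.array([diffs.min(), diffs.max() + 1e-12])
        idx = np.clip(np.searchsorted(edges, diffs, side="right") - 1, 0, len(edges) - 2)
        for name, recs in records_by_predictor.items():
            correct = np.array([recs[i].correct for i in keep])
            for b in np.unique(idx):
                sel = idx == b
                rows.append(
                    {
                        "predictor": name,
                        "dimension": "difficulty",
                        "bin": f"{edges[b]:.4g}..{edges[b + 1]:.4g}",
                        "n": int(sel.sum()),
                        "accuracy": float(correct[sel].mean()),
                    }
                )

    for name, recs in records_by_predictor.items():
        sub = [r for r in recs if not (exclude_ambiguous and r.ambiguous)]
        df = pd.DataFrame(
            {"map_id": [r.map_id for r in sub], "correct": [r.correct for r in sub]}
        )
        for map_id, grp in df.groupby("map_id"):
            rows.append(
                {
                    "predictor": name,
                    "dimension": "map",
                    "bin": str(map_id),
                    "n": int(len(grp)),
                    "accuracy": float(grp["correct"].mean()),
                }
            )
    return pd.DataFrame(rows)


def load_summaries(
    cohort: Sequence[PlayerTraces],
    params: LoadParams,
    seed: int,
    inject: bool = True,
    sample_dt: float = 1.0,
) -> pd.DataFrame:
    """Per-run load/error/score table, optionally with forgetting-driven
    errors injected from the same forgetting model."""
    root = np.random.SeedSequence(seed).spawn(2)[1]
    rng = np.random.default_rng(root)
    rows = []
    for pt in cohort:
        for run in pt.runs:
            trace = inject_forgetting(run, params, rng) if inject else run
            series = load_series(
                trace.victim_events, trace.config.run_duration, params, sample_dt
            )
            rows.append(
                {
                    "run_id": f"{trace.player_id}/{trace.run_index}",
                    "player_id": trace.player_id,
                    "run_index": trace.run_index,
                    "map_id": trace.map_id,
                    "max_load": series.max_load,
                    "mean_load": series.mean_load,
                    "errors": trace.errors,
                    "score": trace.score,
                    "n_marks": trace.n_marks,
                    "n_moves": trace.n_moves,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ReportBundle:
    """Machine-readable experiment report."""

    predictor_table: pd.DataFrame
    accuracy_by_experience: pd.DataFrame
    run_table: pd.DataFrame
    correlations: pd.DataFrame
    metadata: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.predictor_table.to_csv(out / "predictor_accuracy.csv", index=False)
        self.accuracy_by_experience.to_csv(out / "model_accuracy_by_experience.csv", index=False)
        self.run_table.to_csv(out / "run_load_summary.csv", index=False)
        self.correlations.to_csv(out / "load_correlations.csv", index=False)
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)


def run_experiment(config: ExperimentConfig) -> ReportBundle:
    """Simulate, trace, and analyze one full experiment."""
    seq = np.random.SeedSequence(config.seed)
    maps_seed, profiles_seed, cohort_seed = seq.spawn(3)
    maps = build_maps(config.maps, config.map_cycles, np.random.default_rng(maps_seed))
    profiles = build_profiles(
        config.n_players, config.profile_mix, np.random.default_rng(profiles_seed)
    )
    cohort = simulate_cohort(maps, profiles, seed=config.seed)
    records = trace_cohort(cohort, config)
    predictor_table = compare_predictors(
        records, bin_width=config.bin_width, exclude_ambiguous=config.exclude_ambiguous
    )
    by_experience = accuracy_curve(
        records["model"], config.bin_width, config.exclude_ambiguous
    )
    run_table = load_summaries(
        cohort, config.load, seed=config.seed, inject=config.inject_errors
    )
    correlations = correlate(run_table)
    try:
        version = importlib_metadata.version("cogtrace")
    except importlib_metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    metadata = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.canonical_dict(),
        "cogtrace_version": version,
        "n_records": len(records["model"]),
        "n_runs": int(len(run_table)),
    }
    return ReportBundle(
        predictor_table=predictor_table,
        accuracy_by_experience=by_experience,
        run_table=run_table,
        correlations=correlations,
        metadata=metadata,
    )
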